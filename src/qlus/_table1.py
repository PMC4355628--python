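"""Embedded per-hemithorax imaging cohort (49 printed rows).

Each tuple is one printed row:
(patient_id, region, ct, cxr, lus, qlus, distance_mm, size_mm, volume_ml, gray_units)
``None`` marks an absent cell. Rows are positional: a patient may contribute
two hemithoraxes and a hemithorax more than one lesion row.
"""

TABLE1_ROWS = (
    (1, "RLL", 1, 1, 1, 1, 0, 85, 237, 90),
    (2, "RML", 1, 1, 1, 1, 0, 55, 150, 115),
    (2, "Lingula", 1, 1, 1, 1, 0, 100, 163, 118),
    (3, "RLL", 1, 0, 1, 1, 0, 17, 70, 105),
    (3, "RLL", 1, 1, 1, 1, 0, 75, 235, 106),
    (4, "RLL", 1, 0, 0, 1, 90, 11, 40, 73),
    (4, "LUL", 1, 0, 0, 0, 30, 10, 29, 41),
    (5, "LLL", 1, 0, 0, 1, 20, 22, 69, 72),
    (5, "RLL", 1, 1, 1, 1, 0, 27, 93, 112),
    (6, "RLL", 1, 0, 0, 1, 22, 52, 243, 60),
    (6, "LLL", 1, 0, 1, 1, 0, 20, 210, 80),
    (7, "RML", 1, 1, 1, 1, 0, 150, 300, 150),
    (8, "RLL", 1, 1, 1, 1, 11, 58, 110, 60),
    (9, "RUL", 1, 1, 0, 0, 37, 35, 32, 48),
    (10, "LLL", 1, 0, 0, 1, 13, 18, 73, 73),
    (10, "RUL", 1, 1, 0, 1, 18, 44, 137, 83),
    (11, "RML", 1, 0, 1, 1, 0, 52, 750, 123),
    (11, "LUL", 1, 1, 1, 1, 0, 125, 826, 114),
    (12, "LLL", 1, 0, 1, 1, 0, 66, 180, 93),
    (13, "LLL", 1, 0, 0, 1, 15, 10, 270, 108),
    (13, "RLL", 1, 1, 1, 1, 5, 61, 235, 93),
    (14, "RLL", 1, 0, 0, 0, 60, 8, 32, 39),
    (15, "LUL", 1, 1, 0, 1, 0, 107, 368, 109),
    (15, "RLL", 1, 0, 1, 1, 0, 79, 128, 109),
    (16, "LW", 1, 1, 1, 1, 0, 195, 839, 129),
    (16, "RLL", 1, 1, 1, 1, 0, 93, 180, 107),
    (17, "RLL", 1, 1, 1, 1, 11, 42, 89, 77),
    (18, "RLL", 1, 1, 1, 1, 0, 37, 157, 92),
    (19, "RLL", 1, 1, 1, 1, 10, 37, 75, 58),
    (20, "RW", 1, 1, 1, 1, 0, 200, 640, 123),
    (20, "LW", 1, 1, 1, 1, 0, 230, 720, 142),
    (21, "RLL", 1, 1, 1, 1, 0, 56, 90, 95),
    (21, "LLL", 1, 1, 1, 1, 0, 26, 142, 113),
    (22, "RLL", 1, 1, 1, 1, 0, 131, 1074, 100),
    (22, "LLL", 0, 1, 0, 0, None, None, None, 47),
    (23, "RLL", 0, 0, 1, 0, None, None, 0, 30),
    (24, "LLL", 0, 1, 0, 0, None, None, 0, 47),
    (25, "LUL", 1, 1, 1, 1, 0, 34, 115, 97),
    (26, "LLL", 1, 1, 1, 1, 0, 69, 300, 87),
    (27, "RUL", 1, 1, 0, 1, 0, 11, 189, 87),
    (27, "LW", 0, 1, 0, 0, None, None, 0, 46),
    (28, "RW", 1, 1, 1, 1, 0, 110, 469, 121),
    (28, "LLL", 1, 0, 0, 1, 26, 20, 260, 71),
    (29, "RLL", 1, 0, 1, 1, 0, 28, 178, 80),
    (29, "LLL", 1, 1, 1, 1, 0, 91, 200, 106),
    (30, "LLL", 1, 0, 0, 1, 40, 14, 73, 71),
    (30, "RLL", 1, 0, 0, 1, 7, 32, 107, 80),
    (31, "RML", 1, 1, 1, 1, 0, 71, 210, 94),
    (32, "RLL", 0, 1, 0, 1, None, None, 0, 52),
)
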
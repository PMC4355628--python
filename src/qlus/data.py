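"""Cohort domain types and I/O for per-hemithorax lung-imaging records.

The unit of analysis is one hemithorax (or one lesion within a hemithorax):
each record carries the binary findings of four imaging methods — thoracic CT
(the reference standard), bedside chest X-ray (CXR), visual lung
ultrasonography (LUS), and quantitative lung ultrasonography (QLUS) — together
with the CT-derived lesion geometry (distance from the pleural line, lesion
size, nonaerated parenchymal volume) and the QLUS score in Gray units (mean
8-bit echo intensity over the analysis region, 0-255).

The module embeds the study cohort: 49 printed rows (44 CT-positive, 5
CT-negative) plus a documented reconstruction of the 15 remaining
CT-negative hemithoraxes that were uniformly negative on all methods and
whose Gray units were not printed individually.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._table1 import TABLE1_ROWS

__all__ = [
    "REGIONS",
    "QLUS_CUTOFF",
    "HemithoraxRecord",
    "CohortTable",
    "CohortFormatError",
    "CohortValidationError",
    "load_table1_fixture",
    "augment_with_unlisted_negatives",
    "truncated_normal_gu_sampler",
    "validate_qlus_labels",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Anatomic region codes: the five lobes, the lingula, whole right/left lung
#: (printed as single rows, never expanded per lobe), paracardiac, and the
#: placeholder for reconstructed all-negative hemithoraxes.
REGIONS = frozenset(
    {"RUL", "RML", "RLL", "LUL", "LLL", "Lingula", "RW", "LW", "Paracardiac", "Unlisted"}
)

#: Gray-unit cutoff for the QLUS pneumonia call (positive iff mean GU > cutoff).
QLUS_CUTOFF = 48.0

#: Printed mean Gray units of the CT-negative group; the deterministic fill
#: value for the reconstructed all-negative hemithoraxes.
CT_NEGATIVE_GU_MEAN = 39.0


class CohortFormatError(ValueError):
    """A cohort file is structurally malformed (e.g. missing mandatory columns)."""


class CohortValidationError(ValueError):
    """A cohort cell violates a domain invariant (e.g. a non-binary label)."""


def _as_binary(value, name: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value in (0, 1):
        return bool(value)
    raise CohortValidationError(f"{name} must be binary (0/1), got {value!r}")


@dataclass(frozen=True)
class HemithoraxRecord:
    """One hemithorax/lesion row.

    ``distance_from_pleura_mm`` and ``lesion_size_mm`` are CT measurements of
    the consolidation and are therefore absent in CT-negative rows (the table's
    em-dash cells); ``gray_units`` is the QLUS score and may be absent for
    records without a stored ultrasound frame. ``qlus_label`` is derivable
    from ``gray_units`` (strictly above the cutoff) but stored explicitly so
    the printed column can be cross-checked against the recomputation.
    """

    patient_id: int
    region: str
    ct_label: bool
    cxr_label: bool
    lus_label: bool
    qlus_label: bool | None = None
    distance_from_pleura_mm: float | None = None
    lesion_size_mm: float | None = None
    nonaerated_volume_ml: float | None = None
    gray_units: float | None = None

    def __post_init__(self) -> None:
        if self.patient_id <= 0:
            raise CohortValidationError(f"patient_id must be positive, got {self.patient_id}")
        if self.region not in REGIONS:
            raise CohortValidationError(f"unknown region code {self.region!r}")
        for name in ("ct_label", "cxr_label", "lus_label"):
            object.__setattr__(self, name, _as_binary(getattr(self, name), name))
        if self.qlus_label is not None:
            object.__setattr__(self, "qlus_label", _as_binary(self.qlus_label, "qlus_label"))
        if self.gray_units is not None and not 0.0 <= self.gray_units <= 255.0:
            raise CohortValidationError(f"gray_units {self.gray_units} outside [0, 255]")
        if self.distance_from_pleura_mm is not None and self.distance_from_pleura_mm < 0:
            raise CohortValidationError("distance_from_pleura_mm must be nonnegative")
        if self.lesion_size_mm is not None and self.lesion_size_mm <= 0:
            raise CohortValidationError("lesion_size_mm must be positive")
        if self.nonaerated_volume_ml is not None and self.nonaerated_volume_ml < 0:
            raise CohortValidationError("nonaerated_volume_ml must be nonnegative")
        if self.ct_label and (self.distance_from_pleura_mm is None or self.lesion_size_mm is None):
            raise CohortValidationError(
                "CT-positive rows must carry distance_from_pleura_mm and lesion_size_mm"
            )


_COLUMNS = [f.name for f in dataclasses.fields(HemithoraxRecord)]
_MANDATORY = ("patient_id", "region", "ct_label")
_LABELS = ("ct_label", "cxr_label", "lus_label", "qlus_label")


@dataclass
class CohortTable:
    """An ordered collection of :class:`HemithoraxRecord` rows.

    Rows are positional, not keyed: a patient may contribute up to two
    hemithoraxes, and a hemithorax may contribute more than one lesion row.
    """

    records: list[HemithoraxRecord]
    provenance: str = "user"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HemithoraxRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> HemithoraxRecord:
        return self.records[i]

    def column(self, name: str) -> list:
        """Values of one field, in row order (``None`` where absent)."""
        return [getattr(r, name) for r in self.records]

    def subset(self, predicate: Callable[[HemithoraxRecord], bool], provenance: str | None = None) -> "CohortTable":
        return CohortTable(
            [r for r in self.records if predicate(r)],
            provenance or self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = dataclasses.asdict(r)
            for name in _LABELS:
                if d[name] is not None:
                    d[name] = int(d[name])
            rows.append(d)
        return pd.DataFrame(rows, columns=_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "user") -> "CohortTable":
        missing = [c for c in _MANDATORY if c not in df.columns]
        if missing:
            raise CohortFormatError(f"missing mandatory columns: {missing}")
        records = []
        for _, row in df.iterrows():
            kwargs = {}
            for name in _COLUMNS:
                value = row.get(name)
                if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
                    value = None
                elif name in _LABELS:
                    fvalue = float(value)
                    if fvalue not in (0.0, 1.0):
                        raise CohortValidationError(
                            f"{name} must be binary (0/1), got {value!r}"
                        )
                    value = bool(int(fvalue))
                elif name == "patient_id":
                    value = int(value)
                elif name == "region":
                    value = str(value)
                else:
                    value = float(value)
                kwargs[name] = value
            for optional_label in ("cxr_label", "lus_label"):
                if kwargs.get(optional_label) is None:
                    kwargs[optional_label] = False
            records.append(HemithoraxRecord(**kwargs))
        return cls(records, provenance)


def load_table1_fixture() -> CohortTable:
    """The embedded 49-row study cohort, transcribed cell for cell.

    Returns 44 CT-positive and 5 CT-negative rows; em-dash cells map to
    absent values.
    """
    records = [
        HemithoraxRecord(
            patient_id=pid,
            region=region,
            ct_label=bool(ct),
            cxr_label=bool(cxr),
            lus_label=bool(lus),
            qlus_label=bool(qlus),
            distance_from_pleura_mm=None if dist is None else float(dist),
            lesion_size_mm=None if size is None else float(size),
            nonaerated_volume_ml=None if vol is None else float(vol),
            gray_units=float(gu),
        )
        for pid, region, ct, cxr, lus, qlus, dist, size, vol, gu in TABLE1_ROWS
    ]
    return CohortTable(records, provenance="fixture")


def truncated_normal_gu_sampler(
    mean: float = CT_NEGATIVE_GU_MEAN,
    sd: float = 9.0,
    upper: float = QLUS_CUTOFF,
    lower: float = 0.0,
    seed: int | None = None,
) -> Callable[[int], np.ndarray]:
    """Sampler of Gray units for reconstructed negatives: truncated normal.

    Defaults follow the CT-negative group (mean 39, SD 9) with the upper bound
    at the classification cutoff, so every sampled hemithorax classifies
    negative — matching the report that the unprinted CT-negative cases were
    consistently QLUS-negative.
    """
    rng = np.random.default_rng(seed)

    def sample(n: int) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(mean, sd, size=2 * (n - filled))
            draw = draw[(draw >= lower) & (draw <= upper)]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out

    return sample


def augment_with_unlisted_negatives(
    table: CohortTable,
    n: int = 15,
    gu_fill: float | Callable[[int], np.ndarray] = CT_NEGATIVE_GU_MEAN,
) -> CohortTable:
    """Append the ``n`` all-negative hemithoraxes that the table omits.

    Appended rows have region ``Unlisted``, all four labels negative, absent
    geometry, and Gray units from ``gu_fill`` — by default the deterministic
    constant 39 (the printed CT-negative group mean), which guarantees that
    all appended rows classify negative at the cutoff and keeps the
    classification-level results exactly reproducible. Pass
    :func:`truncated_normal_gu_sampler` for stochastic fills.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    n_neg = sum(not r.ct_label for r in table.records)
    if table.provenance == "fixture" and n_neg + n > 20:
        raise ValueError(
            f"appending {n} negatives to {n_neg} existing would exceed the "
            "20 CT-negative hemithoraxes of the study"
        )
    if callable(gu_fill):
        gus = np.asarray(gu_fill(n), dtype=float)
        if gus.shape != (n,):
            raise ValueError("gu_fill sampler must return n values")
    else:
        gus = np.full(n, float(gu_fill))
    extra = [
        HemithoraxRecord(
            patient_id=1000 + i,
            region="Unlisted",
            ct_label=False,
            cxr_label=False,
            lus_label=False,
            qlus_label=False,
            gray_units=float(g),
        )
        for i, g in enumerate(gus)
    ]
    return CohortTable(list(table.records) + extra, provenance=table.provenance)


def validate_qlus_labels(table: CohortTable, cutoff: float = QLUS_CUTOFF) -> list[int]:
    """Cross-check stored QLUS labels against recomputation from Gray units.

    Returns the indices of rows whose stored label disagrees with
    ``gray_units > cutoff`` (rows without both fields are skipped). An empty
    list means the printed column and the score are mutually consistent.
    """
    bad = []
    for i, r in enumerate(table.records):
        if r.qlus_label is None or r.gray_units is None:
            continue
        if bool(r.gray_units > cutoff) != r.qlus_label:
            bad.append(i)
    return bad


def write_cohort_csv(table: CohortTable, path) -> None:
    """Serialize as comma-separated UTF-8 with a header; absent cells empty."""
    df = table.to_dataframe()
    df.to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path, provenance: str = "user") -> CohortTable:
    """Read the CSV dialect written by :func:`write_cohort_csv` (lossless round-trip)."""
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise CohortFormatError(f"empty cohort file: {path}") from exc
    return CohortTable.from_dataframe(df, provenance=provenance)
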
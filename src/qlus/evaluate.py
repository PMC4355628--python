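"""Model/Results interface for diagnostic-accuracy evaluation of a cohort.

`DiagnosticAccuracyModel` is constructed from a cohort table (or DataFrame)
and, on `fit()`, evaluates each imaging method against the CT reference:
2x2 counts, the standard metrics, Cohen kappa, and an ROC analysis of the
continuous Gray-unit score with Youden best-cutoff selection. The returned
`DiagnosticAccuracyResults` carries raw and rounded values and renders a
summary table in the layout of a clinical accuracy table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import QLUS_CUTOFF, CohortTable
from .stats import (
    ConfusionMatrix,
    DiagnosticSummary,
    ROCCurve,
    cohen_kappa,
    combine_either,
    confusion,
    diagnostic_summary,
    roc_analysis,
)

__all__ = ["DiagnosticAccuracyModel", "DiagnosticAccuracyResults", "MethodResult"]


@dataclass(frozen=True)
class MethodResult:
    name: str
    cm: ConfusionMatrix
    summary: DiagnosticSummary
    kappa_band: str | None


class DiagnosticAccuracyModel:
    """Diagnostic accuracy of CXR, LUS, their combination and QLUS vs CT.

    Parameters
    ----------
    cohort:
        The per-hemithorax records. Every row must carry the CT label; rows
        without Gray units are excluded from the ROC (but not from label
        methods).
    cutoff:
        Gray-unit cutoff for the QLUS call (strictly above = positive).
    recompute_qlus:
        If True (default), QLUS labels are recomputed from ``gray_units`` at
        ``cutoff`` rather than taken from the stored column, so the
        classification is an output of the scoring rule.
    """

    def __init__(self, cohort: CohortTable, cutoff: float = QLUS_CUTOFF,
                 recompute_qlus: bool = True):
        self.cohort = cohort
        self.cutoff = float(cutoff)
        self.recompute_qlus = recompute_qlus
        if len(cohort) == 0:
            raise ValueError("empty cohort")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiagnosticAccuracyModel":
        return cls(CohortTable.from_dataframe(df), **kwargs)

    def _labels(self) -> dict[str, np.ndarray]:
        ct = np.array([r.ct_label for r in self.cohort], dtype=bool)
        cxr = np.array([r.cxr_label for r in self.cohort], dtype=bool)
        lus = np.array([r.lus_label for r in self.cohort], dtype=bool)
        if self.recompute_qlus:
            gus = [r.gray_units for r in self.cohort]
            if any(g is None for g in gus):
                raise ValueError("gray_units required on every row to recompute QLUS labels")
            qlus = np.array([g > self.cutoff for g in gus], dtype=bool)
        else:
            stored = [r.qlus_label for r in self.cohort]
            if any(q is None for q in stored):
                raise ValueError("stored qlus_label missing; use recompute_qlus=True")
            qlus = np.array(stored, dtype=bool)
        return {"reference": ct, "CXR": cxr, "LUS": lus,
                "CXR or LUS": combine_either(cxr, lus), "QLUS": qlus}

    def fit(self) -> "DiagnosticAccuracyResults":
        labels = self._labels()
        ct = labels.pop("reference")
        methods = {}
        for name, pred in labels.items():
            cm = confusion(pred, ct)
            methods[name] = MethodResult(
                name=name,
                cm=cm,
                summary=diagnostic_summary(cm),
                kappa_band=cohen_kappa(cm).band,
            )
        gus = np.array([r.gray_units for r in self.cohort
                        if r.gray_units is not None], dtype=float)
        ct_for_roc = np.array([r.ct_label for r in self.cohort
                               if r.gray_units is not None], dtype=bool)
        roc = None
        if len(np.unique(ct_for_roc)) == 2:
            roc = roc_analysis(gus, ct_for_roc)
        return DiagnosticAccuracyResults(self, methods, roc)


class DiagnosticAccuracyResults:
    """Fitted diagnostic-accuracy results with a printable summary table."""

    def __init__(self, model: DiagnosticAccuracyModel,
                 methods: dict[str, MethodResult], roc: ROCCurve | None):
        self.model = model
        self.methods = methods
        self.roc = roc

    def __getitem__(self, name: str) -> MethodResult:
        return self.methods[name]

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = []
        for name, m in self.methods.items():
            s = m.summary.rounded() if rounded else m.summary
            rows.append({
                "method": name,
                "TP": m.cm.tp, "FP": m.cm.fp, "FN": m.cm.fn, "TN": m.cm.tn,
                "S": s.sensitivity, "Sp": s.specificity, "PPV": s.ppv,
                "NPV": s.npv, "DA": s.accuracy, "k": s.kappa,
            })
        return pd.DataFrame(rows).set_index("method")

    def summary(self) -> str:
        lines = ["Diagnostic accuracy vs CT reference",
                 f"cutoff (Gray units, strict >): {self.model.cutoff:g}",
                 f"n = {len(self.model.cohort)} hemithorax rows", ""]
        lines.append(self.to_frame().to_string())
        if self.roc is not None:
            lines += ["",
                      f"ROC of Gray units: AUC = {self.roc.auc:.3f} "
                      f"(SE {self.roc.se:.3f}), best cutoff (Youden) = "
                      f"{self.roc.best_cutoff:g} (J = {self.roc.best_youden:.3f})"]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<DiagnosticAccuracyResults: {len(self.methods)} methods, n={len(self.model.cohort)}>"
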
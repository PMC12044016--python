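"""Downstream transforms: control normalization, fold-change binarization,
Spearman correlation, and tidy export for external mixed-model fitting.

Treatment effects in the repeated-measures design are expressed relative
to each slice's own medium-only control, either as a percentage of control
(control maps to 100) or as a subtraction (control maps to 0).  For
readouts analysed as a binary pathology outcome, an increase is defined as
a strictly >2-fold rise over control.  Spearman's rho is the Pearson
correlation of mid-ranks; p-values are left to the user's statistics
package, as is all mixed-model fitting — this module ends at a verified
tidy table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class TreatmentTriplet:
    """One readout for one case: control value plus per-treatment values."""

    case_id: str
    readout: str
    control: float
    treatments: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.control):
            raise ValueError(f"control value must be finite, got {self.control}")


def percent_of_control(t: TreatmentTriplet) -> dict[str, float]:
    """100 x treatment / control per label; the control itself maps to 100."""
    if t.control <= 0:
        raise ValueError(f"percent-of-control needs a positive control, got {t.control}")
    return {label: 100.0 * v / t.control for label, v in t.treatments.items()}


def subtract_control(t: TreatmentTriplet) -> dict[str, float]:
    """treatment - control per label; the control itself maps to 0."""
    return {label: v - t.control for label, v in t.treatments.items()}


def binarize_fold_increase(t: TreatmentTriplet, fold: float = 2.0) -> dict[str, int]:
    """1 iff treatment / control is strictly greater than ``fold``, else 0."""
    if t.control <= 0:
        raise ValueError(f"fold binarization needs a positive control, got {t.control}")
    return {label: int(v / t.control > fold) for label, v in t.treatments.items()}


def spearman(x, y) -> tuple[float, int]:
    """Spearman's rho with mid-ranks for ties; returns (rho, n).

    Defined as the Pearson correlation of the rank vectors; raises for
    n < 3 or a constant input, where rho is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"Spearman correlation needs n >= 3, got n={n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    return rho, n


#: Covariate columns of the tidy model table, named as external
#: mixed-model formulae expect them.
MODEL_COVARIATES = ["age", "sex", "brain_region", "apoe", "pathology"]
MISSING_MARKER = "NA"


def export_model_table(records: list[dict], covariates: dict[str, dict] | None = None) -> pd.DataFrame:
    """Tidy table (one row per case x readout) for external mixed models.

    ``records`` carry at least ``case_id``, ``readout`` and ``value``;
    ``covariates`` maps case_id to a covariate dict.  Missing covariates
    are kept with an explicit missing marker; duplicate case/readout rows
    are an error.
    """
    if not records:
        raise ValueError("no records to export")
    df = pd.DataFrame(records)
    dup = df.duplicated(subset=["case_id", "readout"])
    if dup.any():
        bad = df.loc[dup, ["case_id", "readout"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate case/readout rows: {bad}")
    covariates = covariates or {}
    for cov in MODEL_COVARIATES:
        df[cov] = [covariates.get(cid, {}).get(cov, MISSING_MARKER) for cid in df["case_id"]]
    df = df.fillna({cov: MISSING_MARKER for cov in MODEL_COVARIATES})
    cols = ["case_id", "readout", "value"] + MODEL_COVARIATES
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra].sort_values(["case_id", "readout"], kind="stable").reset_index(drop=True)
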
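"""Assay arithmetic: BCA-normalized concentrations, A-beta ratios,
relative gene expression (2^-ddCt) and LDH cytotoxicity.

Secreted-analyte concentrations from ELISA/Luminex are normalized to total
protein from a BCA assay (pg/ml divided by mg/ml gives pg analyte per mg
total protein, after undoing the assay dilution).  Values below an assay's
detection limit are explicit left-censored records: they are excluded from
ratios with a warning, never imputed as zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class AssayMeasurement:
    """One analyte measurement with its normalization inputs.

    ``raw_pg_per_ml`` is the concentration read off the standard curve at
    the assayed dilution; ``dilution`` is the fold-dilution applied before
    the assay (>= 1); ``total_protein_mg_per_ml`` comes from the BCA assay
    on the same sample.  ``below_detection`` marks left-censored values.
    """

    analyte: str
    raw_pg_per_ml: float
    dilution: float = 1.0
    total_protein_mg_per_ml: float = math.nan
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise ValueError(f"dilution factor must be >= 1, got {self.dilution}")


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle thresholds for one gene and its housekeeping reference."""

    gene: str
    ct_gene: float
    ct_housekeeping: float
    condition: str = ""
    housekeeping_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        for name in ("ct_gene", "ct_housekeeping"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_gene - self.ct_housekeeping


def normalize_concentration(m: AssayMeasurement) -> float:
    """Dilution-corrected concentration per mg total protein (pg/mg)."""
    if m.below_detection:
        raise ValueError(f"{m.analyte}: below detection limit; cannot normalize a censored value")
    if not (m.total_protein_mg_per_ml > 0):
        raise ValueError(f"{m.analyte}: total protein must be positive, got {m.total_protein_mg_per_ml}")
    return m.raw_pg_per_ml * m.dilution / m.total_protein_mg_per_ml


def ab_ratio(ab42: float | AssayMeasurement, ab40: float | AssayMeasurement) -> float:
    """A-beta 42/40 ratio; unit-free provided both inputs share a unit.

    Censored measurements are excluded with a warning (returns NaN) rather
    than imputed as zero.
    """
    for name, v in (("ab42", ab42), ("ab40", ab40)):
        if isinstance(v, AssayMeasurement) and v.below_detection:
            warnings.warn(f"{name} ({v.analyte}) below detection; ratio undefined", UserWarning)
            return math.nan
    a42 = ab42.raw_pg_per_ml if isinstance(ab42, AssayMeasurement) else float(ab42)
    a40 = ab40.raw_pg_per_ml if isinstance(ab40, AssayMeasurement) else float(ab40)
    if a40 <= 0:
        raise ValueError(f"A-beta 1-40 denominator must be positive, got {a40}")
    return a42 / a40


def ddct_fold_change(treated: CtRecord, control: CtRecord) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_gene - Ct_housekeeping per condition; ddCt = dCt_treated -
    dCt_control; fold change = 2^-ddCt.
    """
    if treated.gene != control.gene:
        raise ValueError(f"gene mismatch: {treated.gene!r} vs {control.gene!r}")
    if treated.housekeeping_gene != control.housekeeping_gene:
        raise ValueError("housekeeping gene mismatch between conditions")
    ddct = treated.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def ldh_cytotoxicity(sample_ldh: float, max_ldh: float) -> float:
    """% cytotoxicity = (sample LDH / maximum LDH on the assay) x 100."""
    if max_ldh <= 0:
        raise ValueError(f"maximum LDH must be positive, got {max_ldh}")
    return 100.0 * sample_ldh / max_ldh


def pm_to_pg_per_ml(concentration_pm: float, molecular_weight_da: float) -> float:
    """Convert pM to pg/ml given the peptide's molecular weight in Da.

    1 pM = 1e-12 mol/l; pg/ml = pM * MW(g/mol) * 1e-3.  The molecular
    weight is caller-supplied because A-beta isoform masses differ.
    """
    if molecular_weight_da <= 0:
        raise ValueError("molecular weight must be positive")
    return concentration_pm * molecular_weight_da * 1e-3


def normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized normalization of a long-format assay table.

    Expects columns ``case_id, analyte, raw, dilution, protein`` and
    appends ``normalized`` (pg/mg); censored rows (column ``censored``
    truthy, if present) get NaN.
    """
    out = df.copy()
    if (out["protein"] <= 0).any():
        raise ValueError("total protein must be positive in every row")
    out["normalized"] = out["raw"] * out["dilution"] / out["protein"]
    if "censored" in out.columns:
        n = int(out["censored"].astype(bool).sum())
        if n:
            warnings.warn(f"{n} below-detection rows left unnormalized (NaN)", UserWarning)
        out.loc[out["censored"].astype(bool), "normalized"] = math.nan
    return out
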
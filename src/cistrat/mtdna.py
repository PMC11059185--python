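"""Single-neuron mtDNA quantification from duplex MTND1/MTND4 qPCR.

MTND1 lies outside the mitochondrial major arc and MTND4 inside it, so in
a duplex assay the MTND1 signal estimates total mtDNA copy number and the
MTND4 signal the non-deleted copy number.  Absolute copies come from a
standard curve (Ct linear in log10 copies, serial dilution 1e2-1e6) and
the major-arc deletion fraction is ``1 - ND4/ND1`` clamped to [0, 1].
Group comparisons run on per-subject centers of 8-16 neurons, never on
pooled neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestReport, welch_anova

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify_neurons",
    "subject_deletion_summary",
]

TARGETS = ("MTND1", "MTND4")


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration Ct = intercept + slope * log10(copies)."""

    target: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def copies(self, ct: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)


def fit_standard_curve(standards: pd.DataFrame, target: str | None = None) -> StandardCurve:
    """Fit a standard curve by OLS of Ct on log10(known copies).

    ``standards`` needs columns ``copies`` and ``ct`` (optionally
    ``target``; pass ``target`` to subset).  Requires >= 3 points across
    >= 2 distinct copy levels; a single level is a singular fit.
    """
    df = standards
    if target is not None and "target" in df.columns:
        df = df[df["target"] == target]
    if len(df) < 3:
        raise ValueError("need >= 3 standard points")
    copies = df["copies"].to_numpy(dtype=float)
    ct = df["ct"].to_numpy(dtype=float)
    if (copies <= 0).any():
        raise ValueError("standard copies must be positive")
    if np.unique(copies).size < 2:
        raise ValueError("standards cover a single copy level; fit is singular")
    res = sps.linregress(np.log10(copies), ct)
    curve = StandardCurve(
        target=target or (df["target"].iloc[0] if "target" in df.columns else "?"),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
    if curve.slope >= 0:
        warnings.warn(f"standard curve for {curve.target} has non-negative slope")
    return curve


def quantify_neurons(
    plate: pd.DataFrame,
    curves: dict[str, StandardCurve],
    nd1: str = "MTND1",
    nd4: str = "MTND4",
) -> pd.DataFrame:
    """Convert well Cts to per-neuron copy numbers and deletion fractions.

    ``plate`` holds unknown wells with columns ``sample_id, target, ct``
    (replicates as repeated rows).  Replicate Cts are averaged per
    sample x target on the Ct scale before conversion through the
    target's standard curve.  Samples missing either target are excluded
    with a warning and returned flagged in ``.attrs['excluded']``.

    Returns a frame with ``sample_id, nd1_copies, nd4_copies,
    deletion_fraction, n_wells_nd1, n_wells_nd4``.
    """
    for t in (nd1, nd4):
        if t not in curves:
            raise ValueError(f"missing fitted standard curve for target {t!r}")
    wells = plate
    if "is_standard" in wells.columns:
        wells = wells[~wells["is_standard"].astype(bool)]
    mean_ct = (
        wells.groupby(["sample_id", "target"])["ct"].agg(["mean", "count"]).unstack("target")
    )
    excluded = []
    rows = []
    for sample_id, row in mean_ct.iterrows():
        ct1 = row.get(("mean", nd1), np.nan)
        ct4 = row.get(("mean", nd4), np.nan)
        if np.isnan(ct1) or np.isnan(ct4):
            excluded.append(sample_id)
            continue
        c1 = float(curves[nd1].copies(ct1))
        c4 = float(curves[nd4].copies(ct4))
        rows.append(
            {
                "sample_id": sample_id,
                "nd1_copies": c1,
                "nd4_copies": c4,
                "deletion_fraction": float(np.clip(1.0 - c4 / c1, 0.0, 1.0)),
                "n_wells_nd1": int(row.get(("count", nd1), 0)),
                "n_wells_nd4": int(row.get(("count", nd4), 0)),
            }
        )
    if excluded:
        warnings.warn(f"samples missing one target excluded: {excluded}")
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def subject_deletion_summary(
    results: pd.DataFrame,
    value: str = "deletion_fraction",
    center: str = "median",
    group_col: str = "group",
    subject_col: str = "subject_id",
) -> tuple[pd.DataFrame, TestReport | None]:
    """Per-subject centers of neuron values plus the three-group comparison.

    ``results`` is the neuron-level table joined with subject and group
    columns.  The per-subject center defaults to the median (mean is the
    documented alternative); the omnibus test is Welch's ANOVA with
    eta-squared and Games-Howell post-hoc, run on subject-level centers.
    Groups with a single subject are excluded from the test with a
    warning.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    per_subject = (
        results.groupby([subject_col, group_col])[value].agg(center).reset_index()
    )
    per_subject = per_subject.rename(columns={value: f"{center}_{value}"})

    counts = per_subject[group_col].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"groups with a single subject excluded from the test: {small}")
    usable = per_subject[~per_subject[group_col].isin(small)]
    report = None
    if usable[group_col].nunique() >= 2:
        groups = {
            g: sub[f"{center}_{value}"].to_numpy()
            for g, sub in usable.groupby(group_col)
        }
        report = welch_anova(groups)
    return per_subject, report
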
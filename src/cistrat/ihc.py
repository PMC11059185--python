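"""Neuronal complex-I profiles and k-means stratification.

Immunohistochemistry yields, per subject, region (and sampling sub-region)
and rater, counts of neurons staining positive/negative for a complex-I
subunit.  This module pools those counts into per-subject percent-positive
profiles, applies the substantia-nigra section-size exclusion, stratifies
subjects into CI subtypes by k-means on the prefrontal-cortex values, and
summarizes regional group medians with Ward hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

__all__ = [
    "compute_ci_profiles",
    "rater_percentages",
    "stratify_kmeans",
    "regional_summary",
    "StratificationResult",
    "CLUSTER_LABELS",
]

REQUIRED_COLUMNS = ["subject_id", "region", "rater_id", "n_positive", "n_total"]

#: cluster labels in descending-center order for k = 3
CLUSTER_LABELS = ("nCI", "CI-mild", "CI-severe")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"neuron count table missing columns: {missing}")
    rec = records.copy()
    if "subregion" not in rec.columns:
        rec["subregion"] = "R1"
    bad = rec[(rec["n_positive"] < 0) | (rec["n_total"] < 0) | (rec["n_positive"] > rec["n_total"])]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            "invalid neuron counts (n_positive > n_total or negative) for "
            f"subject={first['subject_id']!r} region={first['region']!r} "
            f"rater={first['rater_id']!r}: {int(first['n_positive'])}/{int(first['n_total'])}"
        )
    return rec


def rater_percentages(records: pd.DataFrame) -> pd.DataFrame:
    """Per subject x region x rater percent positive, sub-regions pooled first.

    Counts are summed over sub-regions before dividing, so three PFC
    sampling regions contribute by neuron, not by average of averages.
    """
    rec = _validate_records(records)
    keys = ["subject_id", "region", "rater_id"]
    pooled = rec.groupby(keys, sort=False)[["n_positive", "n_total"]].sum().reset_index()
    pooled["percent_positive"] = np.where(
        pooled["n_total"] > 0, 100.0 * pooled["n_positive"] / pooled["n_total"], np.nan
    )
    return pooled


def compute_ci_profiles(
    records: pd.DataFrame,
    min_snpc_neurons: int = 25,
    snpc_region: str = "SNpc",
) -> pd.DataFrame:
    """Pool neuron counts into per-subject, per-region CI profiles.

    For each subject x region, sub-region counts are pooled per rater and
    the primary ``percent_positive`` is the arithmetic mean of the rater
    percentages.  SNpc measurements based on fewer than
    ``min_snpc_neurons`` pooled neurons carry too much per-neuron
    uncertainty (one misclassified neuron >= 4% at n < 25) and are flagged
    ``qc_pass=False``; a subject-region passes QC if at least one rater's
    section passes.

    Returns a tidy frame with columns ``subject_id, region,
    percent_positive, qc_pass, n_total, n_raters`` (plus ``group`` when
    present in the input).
    """
    per_rater = rater_percentages(records)
    per_rater["qc_pass"] = ~(
        (per_rater["region"] == snpc_region) & (per_rater["n_total"] < min_snpc_neurons)
    )

    rows = []
    for (subj, region), g in per_rater.groupby(["subject_id", "region"], sort=False):
        ok = g[g["qc_pass"]]
        use = ok if len(ok) else g
        rows.append(
            {
                "subject_id": subj,
                "region": region,
                "percent_positive": float(use["percent_positive"].mean()),
                "qc_pass": bool(len(ok)),
                "n_total": int(use["n_total"].sum()),
                "n_raters": int(len(use)),
            }
        )
    profiles = pd.DataFrame(rows)
    if "group" in records.columns:
        groups = records.drop_duplicates("subject_id").set_index("subject_id")["group"]
        profiles.insert(1, "group", profiles["subject_id"].map(groups))
    return profiles


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@dataclass
class StratificationResult:
    """K-means stratification of subjects on one CI percentage axis.

    ``assignments`` has one row per subject with the cluster index (0 =
    highest center), the subtype label, and for iPD subjects the merged
    nCI-PD / CI-PD label.  ``centers`` are in descending order.
    """

    assignments: pd.DataFrame
    centers: np.ndarray
    wss: float
    n_restarts: int
    control_top_fraction: float | None = None
    extra: dict = field(default_factory=dict)

    def cluster_shares(self, group: str = "iPD") -> pd.Series:
        sub = self.assignments[self.assignments["group"] == group]
        return sub["label"].value_counts(normalize=True)


def stratify_kmeans(
    values: pd.DataFrame,
    k: int = 3,
    n_restarts: int = 20,
    max_iter: int = 100,
    seed: int | None = 0,
    ipd_group: str = "iPD",
) -> StratificationResult:
    """Stratify subjects by k-means on a single CI-percentage axis.

    ``values`` needs columns ``subject_id``, ``group`` and
    ``percent_positive``; cases and controls are clustered jointly but
    only iPD subjects receive the nCI / CI-mild / CI-severe labels
    (merged_label nCI-PD for the top cluster, CI-PD for the two lower
    clusters).  The best of ``n_restarts`` Lloyd runs by total
    within-cluster sum of squares is kept; after fitting, every point is
    assigned to the nearest center with ties going to the higher center,
    which makes the labelling deterministic.
    """
    req = {"subject_id", "group", "percent_positive"}
    if not req.issubset(values.columns):
        raise ValueError(f"values must have columns {sorted(req)}")
    vals = values.dropna(subset=["percent_positive"]).reset_index(drop=True)
    x = vals["percent_positive"].to_numpy(dtype=float)
    if np.unique(x).size < k:
        raise ValueError(f"need >= {k} distinct values for k={k} clustering")

    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=None if seed is None else int(seed) % (2**31),
        algorithm="lloyd",
    ).fit(x.reshape(-1, 1))

    centers = np.sort(km.cluster_centers_.ravel())[::-1]  # descending
    dist = np.abs(x[:, None] - centers[None, :])
    labels_idx = dist.argmin(axis=1)  # argmin ties -> lower index = higher center
    wss = float(((x - centers[labels_idx]) ** 2).sum())

    if k == 3:
        names = list(CLUSTER_LABELS)
    else:
        names = [f"cluster_{i}" for i in range(k)]

    assignments = vals[["subject_id", "group", "percent_positive"]].copy()
    assignments["cluster"] = labels_idx
    assignments["label"] = [names[i] for i in labels_idx]
    assignments["merged_label"] = [
        ("nCI-PD" if i == 0 else "CI-PD") if g == ipd_group else None
        for i, g in zip(labels_idx, assignments["group"])
    ]

    controls = assignments[assignments["group"] != ipd_group]
    control_top = float((controls["cluster"] == 0).mean()) if len(controls) else None

    return StratificationResult(
        assignments=assignments,
        centers=centers,
        wss=wss,
        n_restarts=n_restarts,
        control_top_fraction=control_top,
    )


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------


def _linkage_to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def regional_summary(
    profiles: pd.DataFrame,
    group_col: str = "group",
) -> dict:
    """Group x region median matrix plus Ward clustering of the regions.

    QC-failing entries are excluded from the medians.  Regions with no
    values in any group are dropped with a warning.  Clustering uses
    Ward linkage on Euclidean distances between region columns (the
    ward.D2 criterion on raw observations), returning merge heights and
    a Newick rendering of the dendrogram.
    """
    needed = {"subject_id", group_col, "region", "percent_positive"}
    if not needed.issubset(profiles.columns):
        raise ValueError(f"profiles must have columns {sorted(needed)}")
    use = profiles
    if "qc_pass" in profiles.columns:
        use = profiles[profiles["qc_pass"]]
    medians = use.pivot_table(
        index=group_col, columns="region", values="percent_positive", aggfunc="median"
    )
    empty = medians.columns[medians.isna().all(axis=0)]
    if len(empty):
        warnings.warn(f"regions with all-missing values dropped: {list(empty)}")
        medians = medians.drop(columns=empty)
    medians = medians.dropna(axis=1)
    if medians.shape[0] < 2 or medians.shape[1] < 2:
        raise ValueError("need >= 2 groups and >= 2 regions with complete medians")

    link = hierarchy.linkage(medians.T.to_numpy(), method="ward")
    return {
        "medians": medians,
        "linkage": link,
        "merge_heights": link[:, 2].copy(),
        "newick": _linkage_to_newick(link, list(medians.columns)),
    }
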
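"""Droplet-level QC cascade for single-nucleus RNA-seq.

The cascade turns a raw barcode x gene UMI matrix into a high-confidence
set of annotated nuclei in four strict stages:

1. threshold filter — keep droplets with >= 500 detected genes, >= 1000
   UMIs and below 3% mitochondrially-encoded UMIs; then drop genes seen
   in fewer than 10 kept droplets;
2. clustering + annotation — normalize, reduce to principal components,
   cluster (pluggable backend, default k-means) and annotate each
   cluster with the cortical major type whose marker panel dominates;
3. centroid purification — remove barcodes whose nearest cluster
   centroid in the first 5 PCs is not their own cluster;
4. MGP-ratio score — per droplet, the marker-gene-profile of the
   annotated type divided by the sum of the other types' MGPs (each
   min-max scaled across droplets); droplets scoring below 0.4 are out.

Keep-sets are nested: a barcode removed at one stage never reappears,
and each removed barcode records the first stage that failed it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from scipy import stats as sps
from sklearn.cluster import KMeans

from .bulk import _first_pc
from .stats import TestReport, bh_adjust, one_way_anova

__all__ = [
    "DEFAULT_MARKER_PANEL",
    "droplet_threshold_filter",
    "cluster_and_annotate",
    "centroid_purify",
    "mgp_score_filter",
    "run_qc_cascade",
    "cluster_overrepresentation",
    "nuclei_count_compare",
    "QCCascadeResult",
]

#: cortical major-type marker panels (no marker shared between types)
DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "excitatory_neuron": ["SATB2", "SLC17A7"],
    "inhibitory_neuron": ["GAD1", "SLC6A1"],
    "oligodendrocyte": ["MOG", "MOBP"],
    "astrocyte": ["GFAP", "AQP4"],
    "microglia": ["CSF1R", "CSF3R"],
    "OPC": ["OLIG1", "VCAN"],
    "endothelial": ["CLDN5", "SLC2A1"],
}


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


# ---------------------------------------------------------------------------
# stage 1: thresholds
# ---------------------------------------------------------------------------

def droplet_threshold_filter(
    adata: ad.AnnData,
    min_genes: int = 500,
    min_umi: int = 1000,
    max_mito: float = 0.03,
    gene_min_cells: int = 10,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Keep droplets with enough genes/UMIs and low mitochondrial fraction.

    A droplet passes iff genes_detected >= ``min_genes`` AND UMIs >=
    ``min_umi`` AND mito fraction strictly below ``max_mito``.  Genes
    present in fewer than ``gene_min_cells`` *kept* droplets are then
    removed (droplets first, then genes).  Returns the filtered AnnData
    and a per-barcode QC frame with the failure reason.
    """
    if adata.n_obs == 0:
        raise ValueError("empty droplet matrix")
    X = adata.X
    umis = np.asarray(X.sum(axis=1)).ravel()
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(umis)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, mito / umis, 0.0)

    reason = np.array([""] * adata.n_obs, dtype=object)
    reason[mito_frac >= max_mito] = "mito_fraction"
    reason[umis < min_umi] = "min_umi"
    reason[genes_detected < min_genes] = "min_genes"
    passed = reason == ""

    qc = pd.DataFrame(
        {
            "n_umi": umis,
            "n_genes": genes_detected,
            "mito_fraction": mito_frac,
            "passed_thresholds": passed,
            "failure_reason": reason,
        },
        index=adata.obs_names,
    )
    if not passed.any():
        raise ValueError(
            "no droplet passed the threshold stage "
            f"(median UMIs {np.median(umis):.0f}, genes {np.median(genes_detected):.0f})"
        )
    kept = adata[passed].copy()
    cells_per_gene = np.asarray((kept.X > 0).sum(axis=0)).ravel()
    kept = kept[:, cells_per_gene >= gene_min_cells].copy()
    return kept, qc


# ---------------------------------------------------------------------------
# stage 2: clustering + marker annotation
# ---------------------------------------------------------------------------

ClusterBackend = Callable[[np.ndarray, int | None], np.ndarray]


def _kmeans_backend(n_clusters: int) -> ClusterBackend:
    def run(pcs: np.ndarray, seed: int | None) -> np.ndarray:
        km = KMeans(
            n_clusters=min(n_clusters, len(pcs)),
            n_init=10,
            random_state=None if seed is None else int(seed) % (2**31),
        )
        return km.fit_predict(pcs)

    return run


def cluster_and_annotate(
    adata: ad.AnnData,
    panel: Mapping[str, Sequence[str]] = DEFAULT_MARKER_PANEL,
    n_pcs: int = 50,
    n_clusters: int = 28,
    backend: ClusterBackend | None = None,
    seed: int | None = 0,
    ambiguity_margin: float = 0.05,
) -> ad.AnnData:
    """Normalize, embed, cluster and annotate droplets with major types.

    Normalization is UMIs-per-10k + log1p; high-variance genes feed a
    PCA with ``n_pcs`` components, clustered by the pluggable
    ``backend`` (default k-means with ``n_clusters``).  Each cluster's
    annotation is the marker panel with the highest mean z-scored
    expression; when the runner-up panel comes within
    ``ambiguity_margin`` of the winner's lead over the weakest panel the
    cluster is flagged ambiguous and left unassigned.

    Adds ``obs['cluster']``, ``obs['major_type']``, ``obsm['X_pca']``,
    ``uns['annotation']`` (per-cluster table) and ``uns['dot_matrix']``
    (mean scaled expression and fraction expressing per cluster/marker).
    """
    adata = adata.copy()
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    adata.layers["lognorm"] = adata.X.copy()
    n_hvg = min(2000, adata.n_vars)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg)
    n_comps = int(min(n_pcs, adata.n_obs - 1, adata.n_vars - 1))
    sc.pp.scale(adata, max_value=10)
    sc.pp.pca(adata, n_comps=n_comps, use_highly_variable=True, random_state=0)

    backend = backend or _kmeans_backend(n_clusters)
    labels = np.asarray(backend(adata.obsm["X_pca"], seed))
    adata.obs["cluster"] = pd.Categorical(labels)

    # z-scored log-normal expression of panel markers, per cluster
    lognorm = adata.layers["lognorm"]
    marker_genes = [g for genes in panel.values() for g in genes if g in adata.var_names]
    gidx = [adata.var_names.get_loc(g) for g in marker_genes]
    expr = _dense(lognorm[:, gidx])
    mu, sd = expr.mean(axis=0), expr.std(axis=0)
    z = (expr - mu) / np.where(sd > 0, sd, 1.0)
    zdf = pd.DataFrame(z, columns=marker_genes, index=adata.obs_names)
    raw = pd.DataFrame(_dense(adata.layers["counts"][:, gidx]) > 0,
                       columns=marker_genes, index=adata.obs_names)

    ann_rows = []
    dot_rows = []
    type_of_cluster: dict[int, str | None] = {}
    for cl in sorted(set(labels)):
        in_cl = labels == cl
        panel_scores = {}
        for t, genes in panel.items():
            present = [g for g in genes if g in zdf.columns]
            panel_scores[t] = float(zdf.loc[in_cl, present].to_numpy().mean()) if present else -np.inf
        ordered = sorted(panel_scores.items(), key=lambda kv: kv[1], reverse=True)
        top_t, top_s = ordered[0]
        second_s = ordered[1][1] if len(ordered) > 1 else -np.inf
        span = top_s - min(s for _, s in ordered if np.isfinite(s))
        ambiguous = span > 0 and (top_s - second_s) <= ambiguity_margin * span
        assigned = None if ambiguous else top_t
        type_of_cluster[cl] = assigned
        ann_rows.append(
            {
                "cluster": cl,
                "n_barcodes": int(in_cl.sum()),
                "major_type": assigned,
                "ambiguous": ambiguous,
                **{f"score_{t}": s for t, s in panel_scores.items()},
            }
        )
        for g in marker_genes:
            dot_rows.append(
                {
                    "cluster": cl,
                    "marker": g,
                    "mean_scaled_expression": float(zdf.loc[in_cl, g].mean()),
                    "fraction_expressing": float(raw.loc[in_cl, g].mean()),
                }
            )

    adata.obs["major_type"] = [type_of_cluster[c] for c in labels]
    adata.uns["annotation"] = pd.DataFrame(ann_rows).set_index("cluster")
    adata.uns["dot_matrix"] = pd.DataFrame(dot_rows)
    # restore raw counts as X; analysis layers stay available
    adata.X = adata.layers["counts"].copy()
    return adata


# ---------------------------------------------------------------------------
# stage 3: centroid purification
# ---------------------------------------------------------------------------

def centroid_purify(
    pc_scores: np.ndarray,
    labels: Sequence[int],
    n_pcs_used: int = 5,
) -> np.ndarray:
    """Keep barcodes whose nearest cluster centroid is their own cluster.

    Distances are Euclidean in the first ``n_pcs_used`` principal
    components to each cluster's mean.  A barcode is removed iff the
    strict argmin over centroids differs from its cluster; exact
    distance ties keep the barcode.  Singleton clusters trivially keep
    their barcode (with a warning).
    """
    pcs = np.asarray(pc_scores, dtype=float)[:, :n_pcs_used]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    singletons = [c for c, n in sizes.items() if n == 1]
    if singletons:
        warnings.warn(f"singleton clusters kept trivially: {singletons}")
    centroids = np.vstack([pcs[labels == c].mean(axis=0) for c in uniq])
    d = np.linalg.norm(pcs[:, None, :] - centroids[None, :, :], axis=2)
    own = np.searchsorted(uniq, labels)
    own_d = d[np.arange(len(labels)), own]
    min_d = d.min(axis=1)
    return own_d <= min_d  # ties keep


# ---------------------------------------------------------------------------
# stage 4: MGP-ratio score
# ---------------------------------------------------------------------------

def droplet_mgps(
    lognorm: pd.DataFrame,
    panel: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-droplet MGP of every major type, min-max scaled to [0, 1].

    For each type, the markers present in the matrix are z-scored across
    droplets and the first principal component taken, sign-aligned with
    the mean marker z-score.  Because raw first-PC scores are signed,
    each type's score is min-max scaled across droplets so the ratio
    below is well defined.
    """
    out = {}
    for t, genes in panel.items():
        present = [g for g in genes if g in lognorm.columns]
        sub = lognorm[present].to_numpy(dtype=float)
        sd = sub.std(axis=0)
        usable = sd > 0
        if usable.sum() == 0:
            out[t] = np.full(len(lognorm), 0.5)
            continue
        z = (sub[:, usable] - sub[:, usable].mean(axis=0)) / sd[usable]
        if z.shape[1] == 1:
            pc = z[:, 0]
        else:
            pc, _ = _first_pc(z)
            if np.corrcoef(pc, z.mean(axis=1))[0, 1] < 0:
                pc = -pc
        rng_ = pc.max() - pc.min()
        out[t] = (pc - pc.min()) / rng_ if rng_ > 0 else np.full(len(lognorm), 0.5)
    return pd.DataFrame(out, index=lognorm.index)


def mgp_score_filter(
    lognorm: pd.DataFrame,
    annotations: pd.Series,
    panel: Mapping[str, Sequence[str]] = DEFAULT_MARKER_PANEL,
    threshold: float = 0.4,
    eps: float = 1e-8,
) -> pd.DataFrame:
    """Score droplets by annotated-type MGP over the sum of the others.

    ``score = scaled MGP(annotated type) / sum(scaled MGPs of other
    types)``; droplets scoring strictly below ``threshold`` are dropped.
    A denominator below ``eps`` means no competing signal: the score is
    +inf and the droplet kept.  Unannotated droplets are dropped with
    reason ``unannotated``.

    Returns a frame with ``mgp_ratio_score``, ``keep`` and ``reason``.
    """
    mgps = droplet_mgps(lognorm, panel)
    annotations = annotations.reindex(mgps.index)
    scores = np.full(len(mgps), np.nan)
    keep = np.zeros(len(mgps), dtype=bool)
    reason = np.array([""] * len(mgps), dtype=object)
    total = mgps.sum(axis=1).to_numpy()
    for i, (bc, t) in enumerate(annotations.items()):
        if t is None or (isinstance(t, float) and np.isnan(t)) or t not in mgps.columns:
            reason[i] = "unannotated"
            continue
        own = mgps.at[bc, t]
        denom = total[i] - own
        if denom < eps:
            scores[i] = np.inf
            keep[i] = True
            continue
        scores[i] = own / denom
        if scores[i] >= threshold:
            keep[i] = True
        else:
            reason[i] = "mgp_score"
    return pd.DataFrame(
        {"mgp_ratio_score": scores, "keep": keep, "reason": reason}, index=mgps.index
    )


# ---------------------------------------------------------------------------
# cascade orchestration
# ---------------------------------------------------------------------------


@dataclass
class QCCascadeResult:
    """Outcome of the full droplet QC cascade.

    ``records`` has one row per input barcode with the stage outcomes,
    the final ``final_keep`` flag and the first ``failure_reason``;
    ``adata`` is the surviving annotated AnnData; ``stage_stats`` counts
    barcodes entering/surviving each stage.
    """

    records: pd.DataFrame
    adata: ad.AnnData
    stage_stats: dict = field(default_factory=dict)


def run_qc_cascade(
    adata: ad.AnnData,
    panel: Mapping[str, Sequence[str]] = DEFAULT_MARKER_PANEL,
    min_genes: int = 500,
    min_umi: int = 1000,
    max_mito: float = 0.03,
    gene_min_cells: int = 10,
    n_pcs: int = 50,
    n_clusters: int = 28,
    n_pcs_purify: int = 5,
    mgp_threshold: float = 0.4,
    backend: ClusterBackend | None = None,
    seed: int | None = 0,
) -> QCCascadeResult:
    """Run thresholds -> cluster/annotate -> purify -> MGP score, in order."""
    records = pd.DataFrame(index=adata.obs_names)

    kept, qc = droplet_threshold_filter(
        adata, min_genes=min_genes, min_umi=min_umi, max_mito=max_mito,
        gene_min_cells=gene_min_cells,
    )
    records = records.join(qc)

    clustered = cluster_and_annotate(
        kept, panel=panel, n_pcs=n_pcs, n_clusters=n_clusters,
        backend=backend, seed=seed,
    )
    records["cluster"] = clustered.obs["cluster"].reindex(records.index)
    records["major_type"] = clustered.obs["major_type"].reindex(records.index)

    pure_keep = centroid_purify(
        clustered.obsm["X_pca"], clustered.obs["cluster"].to_numpy(), n_pcs_used=n_pcs_purify
    )
    records["centroid_keep"] = pd.Series(pure_keep, index=clustered.obs_names).reindex(records.index)
    purified = clustered[pure_keep].copy()

    lognorm = pd.DataFrame(
        _dense(purified.layers["lognorm"]), index=purified.obs_names,
        columns=purified.var_names,
    )
    mgp = mgp_score_filter(
        lognorm, purified.obs["major_type"], panel=panel, threshold=mgp_threshold
    )
    records["mgp_ratio_score"] = mgp["mgp_ratio_score"].reindex(records.index)
    records["mgp_keep"] = mgp["keep"].reindex(records.index)

    final_names = purified.obs_names[mgp["keep"].to_numpy()]
    records["final_keep"] = records.index.isin(final_names)

    # first failing stage
    def first_reason(row) -> str:
        if not row["passed_thresholds"]:
            return row["failure_reason"]
        if row.get("centroid_keep") is False:
            return "centroid_purify"
        if row.get("mgp_keep") is False:
            return "unannotated" if row.get("major_type") is None else "mgp_score"
        return ""

    records["failure_reason"] = records.apply(first_reason, axis=1)
    assert ((records["failure_reason"] == "") == records["final_keep"]).all()

    final = purified[mgp["keep"].to_numpy()].copy()
    stats = {
        "input": int(adata.n_obs),
        "after_thresholds": int(qc["passed_thresholds"].sum()),
        "after_centroid": int(pure_keep.sum()),
        "after_mgp": int(final.n_obs),
        "genes_kept": int(final.n_vars),
    }
    return QCCascadeResult(records=records, adata=final, stage_stats=stats)


# ---------------------------------------------------------------------------
# downstream statistics
# ---------------------------------------------------------------------------

def cluster_overrepresentation(
    de_genes: Mapping[str, Sequence[str]],
    gene_sets: Mapping[str, Sequence[str]],
    universes: Mapping[str, Sequence[str]],
) -> dict[str, pd.DataFrame]:
    """Hypergeometric overrepresentation per cluster, BH within cluster.

    The universe for each cluster is its own expressed-gene set (never
    the whole genome).  For a universe of M genes, a set covering n of
    them and a DE list of N, the p-value is P(X >= k) with k the
    overlap.  Empty DE lists yield an all-NA row, logged.
    """
    out = {}
    for cluster, de in de_genes.items():
        uni = set(universes[cluster])
        de_set = set(de) & uni
        rows = []
        if not de_set:
            warnings.warn(f"cluster {cluster!r}: empty DE list")
        for name, members in gene_sets.items():
            inset = set(members) & uni
            if not inset:
                continue
            if not de_set:
                rows.append({"set": name, "overlap": np.nan, "p_value": np.nan})
                continue
            k = len(de_set & inset)
            p = float(sps.hypergeom.sf(k - 1, len(uni), len(inset), len(de_set)))
            rows.append({"set": name, "overlap": k, "p_value": p})
        df = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
            columns=["overlap", "p_value"]
        )
        if len(df) and df["p_value"].notna().all():
            df["p_bh"] = bh_adjust(df["p_value"].to_numpy())
        else:
            df["p_bh"] = np.nan
        out[cluster] = df
    return out


def nuclei_count_compare(counts: pd.DataFrame, group_col: str = "group",
                         value_col: str = "n_nuclei") -> TestReport:
    """Classical one-way ANOVA on per-subject kept-nuclei counts."""
    groups = {
        g: sub[value_col].to_numpy(dtype=float)
        for g, sub in counts.groupby(group_col)
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    return one_way_anova(groups)
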
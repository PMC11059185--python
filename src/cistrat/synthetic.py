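"""Synthetic cohorts with known ground truth for every pipeline stage.

The study's raw tissue data are controlled-access, so the pipeline is
exercised end to end on simulated inputs that reproduce its structure:

* a cohort of controls and iPD subjects, the iPD split into nCI /
  CI-mild / CI-severe subtypes with region-wise true complex-I-positive
  proportions drawn from Beta distributions calibrated (by quantile
  matching) to the published group medians and IQRs;
* two-rater neuron classification counts with rater noise on the logit
  scale and binomial sampling per section;
* duplex qPCR plates with a known standard curve, true per-neuron copy
  numbers and deletion fractions;
* bulk RNA-seq counts as negative-binomial mixtures of cell-type
  signatures with sex-specific genes and a configurable leak;
* droplet matrices with planted cell types, ambient contamination,
  ambient-only empty droplets and doublets.

Every generator takes an explicit seed and is byte-reproducible; truth
is returned through a separate channel, never mixed into the pipeline
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import anndata as ad
from scipy import optimize, sparse
from scipy import stats as sps

from .snrna import DEFAULT_MARKER_PANEL

__all__ = [
    "CohortSpec",
    "beta_from_quantiles",
    "gen_cohort",
    "gen_ihc_counts",
    "gen_neuron_truth",
    "gen_qpcr",
    "default_signature",
    "default_proportions",
    "gen_bulk",
    "default_droplet_profiles",
    "gen_droplets",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20240429

# ---------------------------------------------------------------------------
# calibration: Beta parameters from published medians / IQRs
# ---------------------------------------------------------------------------

#: per region and group, (median, q25, q75) of % CI-positive neurons.
#: PFC and SNpc control / combined-iPD anchors follow the published group
#: summaries; subtype-level and additional-region values are realistic
#: interpolations consistent with the reported widespread cortical
#: deficiency in CI-PD and the control-like profile of nCI-PD outside
#: the SNpc (cerebellum and inferior olive stay control-like in all
#: groups).
REGION_QUANTILES: dict[str, dict[str, tuple[float, float, float]]] = {
    "PFC": {
        "control": (98.6, 97.8, 99.2),
        "nCI": (97.5, 96.2, 98.5),
        "CI-mild": (84.0, 80.0, 88.0),
        "CI-severe": (55.0, 45.0, 65.0),
    },
    "SNpc": {
        "control": (87.1, 77.1, 94.7),
        "nCI": (79.0, 70.0, 86.0),
        "CI-mild": (68.0, 58.0, 77.0),
        "CI-severe": (52.0, 42.0, 62.0),
    },
    "OC": {
        "control": (98.4, 97.5, 99.1),
        "nCI": (97.8, 96.5, 98.8),
        "CI-mild": (88.0, 83.0, 92.0),
        "CI-severe": (70.0, 60.0, 80.0),
    },
    "TC": {
        "control": (98.0, 97.0, 99.0),
        "nCI": (97.5, 96.0, 98.6),
        "CI-mild": (87.0, 82.0, 91.0),
        "CI-severe": (68.0, 58.0, 78.0),
    },
    "CG": {
        "control": (97.8, 96.8, 98.8),
        "nCI": (97.2, 95.8, 98.4),
        "CI-mild": (88.0, 83.0, 92.0),
        "CI-severe": (72.0, 62.0, 81.0),
    },
    "CC": {
        "control": (88.0, 80.0, 94.0),
        "nCI": (87.0, 79.0, 93.0),
        "CI-mild": (87.5, 79.5, 93.5),
        "CI-severe": (86.0, 78.0, 93.0),
    },
    "ION": {
        "control": (85.0, 75.0, 92.0),
        "nCI": (84.0, 74.0, 91.0),
        "CI-mild": (84.5, 74.5, 91.5),
        "CI-severe": (83.0, 73.0, 90.0),
    },
}

SUBTYPES = ("nCI", "CI-mild", "CI-severe")


def beta_from_quantiles(
    median: float, q25: float, q75: float, scale: float = 100.0
) -> tuple[float, float]:
    """Beta(a, b) whose median and quartiles best match the given ones.

    Quantiles are on the 0-``scale`` axis (percent by default).  Fitted
    by least squares on the three quantiles over log-parameters, which
    keeps a, b > 0.
    """
    targets = np.array([q25, median, q75], dtype=float) / scale
    if not (0 < targets[0] <= targets[1] <= targets[2] < 1):
        raise ValueError("quantiles must be ordered and inside (0, scale)")
    qs = np.array([0.25, 0.5, 0.75])

    def loss(logab: np.ndarray) -> float:
        a, b = np.exp(logab)
        return float(((sps.beta.ppf(qs, a, b) - targets) ** 2).sum())

    # moment-based start from a rough mean/sd guess
    m = targets[1]
    s = max((targets[2] - targets[0]) / 1.35, 1e-3)
    v = min(s**2, m * (1 - m) * 0.95)
    k = m * (1 - m) / v - 1
    x0 = np.log([max(m * k, 0.2), max((1 - m) * k, 0.2)])
    res = optimize.minimize(loss, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    a, b = np.exp(res.x)
    return float(a), float(b)


def _default_region_params() -> dict[str, dict[str, tuple[float, float]]]:
    return {
        region: {grp: beta_from_quantiles(*q) for grp, q in groups.items()}
        for region, groups in REGION_QUANTILES.items()
    }


@dataclass
class CohortSpec:
    """Configuration of a synthetic cohort.

    Defaults follow the combined published cohort: 22 controls and 89
    iPD subjects at subtype fractions 0.73 / 0.20 / 0.07 (nCI, CI-mild,
    CI-severe), demographic summaries from the cohort table (age of
    death, PMI, sex), and clinical phenotype probabilities from the
    reported akinetic-rigid and PIGD shares (88% AR and 75% PIGD in
    CI-PD vs 60% and 29% in nCI-PD; the severe subtype is exclusively
    non-tremor-dominant).  ``cross_region_rho`` sets the within-subject
    correlation of regional CI state via a Gaussian copula.
    """

    n_controls: int = 22
    n_ipd: int = 89
    subtype_fractions: dict[str, float] = field(
        default_factory=lambda: {"nCI": 0.73, "CI-mild": 0.20, "CI-severe": 0.07}
    )
    region_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_region_params
    )
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (83.1, 9.6), "iPD": (78.8, 7.4)}
    )
    pmi_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (27.0, 0.8), "iPD": (16.0, 0.8)}
    )  # lognormal (median hours, sigma)
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"control": 0.458, "nCI": 0.738, "CI-mild": 0.458,
                                 "CI-severe": 0.458}
    )
    ar_probability: dict[str, float] = field(
        default_factory=lambda: {"nCI": 0.60, "CI-mild": 0.88, "CI-severe": 1.0}
    )
    pigd_probability: dict[str, float] = field(
        default_factory=lambda: {"nCI": 0.29, "CI-mild": 0.75, "CI-severe": 1.0}
    )
    cross_region_rho: float = 0.7
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        total = sum(self.subtype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_fractions must sum to 1 (got {total})")
        if self.n_controls < 0 or self.n_ipd < 0:
            raise ValueError("cohort sizes must be non-negative")
        for region, groups in self.region_params.items():
            for grp, (a, b) in groups.items():
                if a <= 0 or b <= 0:
                    raise ValueError(f"non-positive Beta parameter for {region}/{grp}")
        for d in (self.ar_probability, self.pigd_probability, self.male_fraction):
            for k, p in d.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability out of [0,1] for {k}")
        if not 0 <= self.cross_region_rho < 1:
            raise ValueError("cross_region_rho must be in [0, 1)")

    def with_sizes(self, n_controls: int, n_ipd: int) -> "CohortSpec":
        return replace(self, n_controls=n_controls, n_ipd=n_ipd)


def _largest_remainder(fractions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: f * n for k, f in fractions.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)
    for k in order[:short]:
        base[k] += 1
    return base


def gen_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a subject table and its ground truth.

    Returns ``(subjects, truth)``.  ``subjects`` carries subject_id,
    group (control/iPD), cohort (NOR/ESP split evenly), demographics and
    clinical phenotype; ``truth`` carries the true subtype and the true
    % CI-positive per region (columns ``true_pct_<region>``).  Subtype
    counts follow the configured fractions by largest-remainder
    allocation, so the planted composition is exact.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    counts = _largest_remainder(spec.subtype_fractions, spec.n_ipd)
    subtypes = ["control"] * spec.n_controls + [
        s for s in SUBTYPES for _ in range(counts.get(s, 0))
    ]
    n = len(subtypes)
    order = rng.permutation(n)
    subtypes = [subtypes[i] for i in order]

    regions = list(spec.region_params)
    rho = spec.cross_region_rho
    shared = rng.standard_normal(n)
    z = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, len(regions)))
    u = sps.norm.cdf(z)

    rows = []
    truth_rows = []
    for i, subtype in enumerate(subtypes):
        group = "control" if subtype == "control" else "iPD"
        sid = f"S{i + 1:04d}"
        age_mu, age_sd = spec.age_params[group]
        pmi_med, pmi_sig = spec.pmi_params[group]
        male_p = spec.male_fraction["control" if group == "control" else subtype]
        sex = "M" if rng.random() < male_p else "F"
        row = {
            "subject_id": sid,
            "group": group,
            "cohort": "NOR" if i % 2 == 0 else "ESP",
            "age": float(np.clip(rng.normal(age_mu, age_sd), 45, 100)),
            "sex": sex,
            "pmi": float(np.exp(np.log(pmi_med) + pmi_sig * rng.standard_normal())),
        }
        if group == "iPD":
            row["phenotype_ar_td"] = (
                "AR" if rng.random() < spec.ar_probability[subtype] else "TD"
            )
            row["phenotype_pigd_td"] = (
                "PIGD" if rng.random() < spec.pigd_probability[subtype] else "TD"
            )
        else:
            row["phenotype_ar_td"] = None
            row["phenotype_pigd_td"] = None
        rows.append(row)

        tr = {"subject_id": sid, "subtype": subtype}
        grp_key = "control" if subtype == "control" else subtype
        for j, region in enumerate(regions):
            a, b = spec.region_params[region][grp_key]
            tr[f"true_pct_{region}"] = float(100.0 * sps.beta.ppf(u[i, j], a, b))
        truth_rows.append(tr)

    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# IHC neuron counts
# ---------------------------------------------------------------------------

#: per-region section size distribution: (mean neurons, gamma shape).
#: Cortical sampling regions hold on the order of a hundred neurons; the
#: SNpc section count is smaller and overdispersed so that the <25-neuron
#: exclusion rule is exercised.
DEFAULT_SECTION_SIZES: dict[str, tuple[float, float]] = {
    "SNpc": (60.0, 2.5),
}
DEFAULT_SECTION_SIZE = (130.0, 8.0)
DEFAULT_SUBREGIONS: dict[str, int] = {"PFC": 3}


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_ihc_counts(
    subjects: pd.DataFrame,
    truth: pd.DataFrame,
    rater_sd: float = 0.25,
    raters: tuple[str, ...] = ("O1", "O2"),
    section_sizes: dict[str, tuple[float, float]] | None = None,
    subregions: dict[str, int] | None = None,
    regions: list[str] | None = None,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Simulate per-rater neuron classification counts.

    For each subject x region x rater, the subject's true proportion is
    perturbed on the logit scale by Normal(0, ``rater_sd``) — a
    multiplicative error model that keeps proportions in (0, 1), apt for
    the mostly >90% values observed — and each sub-region's positives
    are Binomial(section size, perturbed p).  Section sizes are
    gamma-Poisson draws per region.
    """
    rng = np.random.default_rng(seed)
    sizes = {**DEFAULT_SECTION_SIZES, **(section_sizes or {})}
    subs = {**DEFAULT_SUBREGIONS, **(subregions or {})}
    truth = truth.set_index("subject_id")
    avail = [c.removeprefix("true_pct_") for c in truth.columns if c.startswith("true_pct_")]
    use_regions = regions or avail
    unknown = set(use_regions) - set(avail)
    if unknown:
        raise ValueError(f"regions without truth values: {sorted(unknown)}")

    groups = subjects.set_index("subject_id")["group"]
    rows = []
    for sid in subjects["subject_id"]:
        for region in use_regions:
            p_true = truth.at[sid, f"true_pct_{region}"] / 100.0
            p_true = float(np.clip(p_true, 1e-6, 1 - 1e-6))
            for rater in raters:
                p_obs = float(_expit(_logit(np.array(p_true)) + rng.normal(0, rater_sd))) \
                    if rater_sd > 0 else p_true
                mean, shape = sizes.get(region, DEFAULT_SECTION_SIZE)
                for r in range(subs.get(region, 1)):
                    lam = rng.gamma(shape, mean / shape)
                    n_total = max(int(rng.poisson(lam)), 1)
                    n_pos = int(rng.binomial(n_total, p_obs))
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": groups[sid],
                            "region": region,
                            "subregion": f"R{r + 1}",
                            "rater_id": rater,
                            "n_positive": n_pos,
                            "n_total": n_total,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# single-neuron qPCR
# ---------------------------------------------------------------------------

#: group-level mean neuronal deletion fractions: the CI-deficient group
#: carries a higher major-arc deletion load, all groups below the ~60%
#: biochemical threshold.
DELETION_MEANS = {"control": 0.20, "nCI-PD": 0.18, "CI-PD": 0.30}


def gen_neuron_truth(
    subjects: pd.DataFrame,
    group_col: str = "mtdna_group",
    n_neurons: tuple[int, int] = (8, 16),
    nd1_lognormal: tuple[float, float] = (np.log(1000.0), 0.4),
    deletion_means: dict[str, float] | None = None,
    subject_kappa: float = 30.0,
    neuron_kappa: float = 12.0,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """True per-neuron ND1 copies and deletion fractions for qPCR plates.

    Each subject contributes 8-16 neurons.  The subject-level mean
    deletion fraction is Beta-distributed around the group mean
    (concentration ``subject_kappa``) and per-neuron fractions are Beta
    around the subject mean (concentration ``neuron_kappa``); ND1 copies
    are lognormal.
    """
    rng = np.random.default_rng(seed)
    means = deletion_means or DELETION_MEANS
    rows = []
    for _, subj in subjects.iterrows():
        grp = subj[group_col]
        mu_g = means[grp]
        mu_s = rng.beta(mu_g * subject_kappa, (1 - mu_g) * subject_kappa)
        k = rng.integers(n_neurons[0], n_neurons[1] + 1)
        for j in range(k):
            d = rng.beta(mu_s * neuron_kappa, (1 - mu_s) * neuron_kappa)
            nd1 = float(np.exp(rng.normal(*nd1_lognormal)))
            rows.append(
                {
                    "sample_id": f"{subj['subject_id']}_n{j + 1:02d}",
                    "subject_id": subj["subject_id"],
                    "group": grp,
                    "true_nd1_copies": nd1,
                    "true_deletion_fraction": float(d),
                }
            )
    return pd.DataFrame(rows)


def gen_qpcr(
    neurons: pd.DataFrame,
    curve: tuple[float, float] = (38.0, -3.3219),
    ct_sd: float = 0.15,
    well_correlation: float = 0.5,
    standard_levels: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5, 1e6),
    n_replicates: int = 3,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Simulate a duplex MTND1/MTND4 plate with standards.

    ``neurons`` needs ``sample_id``, ``true_nd1_copies`` and
    ``true_deletion_fraction``.  Ct = intercept + slope*log10(copies) +
    Normal(0, ``ct_sd``); ND4 copies are ND1 x (1 - deletion).  In a
    duplex reaction both targets amplify in the same physical well, so
    pipetting, template-amount and thermal effects are common to the two
    dye channels: ``well_correlation`` is the fraction of the Ct noise
    variance shared per well (each channel's marginal noise sd stays
    ``ct_sd``; the shared part cancels in the ND4/ND1 ratio).  The
    standard dilution series — the same template mix read in both
    channels — spans 1e2-1e6 copies.
    """
    intercept, slope = curve
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    if not 0 <= well_correlation <= 1:
        raise ValueError("well_correlation must lie in [0, 1]")
    nd1 = neurons["true_nd1_copies"].to_numpy(dtype=float)
    dele = neurons["true_deletion_fraction"].to_numpy(dtype=float)
    if (nd1 <= 0).any():
        raise ValueError("non-positive true ND1 copies")
    if ((dele < 0) | (dele >= 1)).any():
        raise ValueError("deletion fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sd_shared = ct_sd * np.sqrt(well_correlation)
    sd_dye = ct_sd * np.sqrt(1.0 - well_correlation)

    rows = []
    well = 0
    for sid, c1, d in zip(neurons["sample_id"], nd1, dele):
        for _ in range(n_replicates):
            well += 1
            shared = rng.normal(0, sd_shared) if ct_sd > 0 else 0.0
            for target, copies in (("MTND1", c1), ("MTND4", c1 * (1 - d))):
                ct = intercept + slope * np.log10(copies)
                if ct_sd > 0:
                    ct += shared + rng.normal(0, sd_dye)
                rows.append(
                    {
                        "well": f"W{well:04d}",
                        "sample_id": sid,
                        "target": target,
                        "ct": float(ct),
                        "is_standard": False,
                        "standard_copies": np.nan,
                    }
                )
    for copies in standard_levels:
        for _ in range(n_replicates):
            well += 1
            shared = rng.normal(0, sd_shared) if ct_sd > 0 else 0.0
            for target in ("MTND1", "MTND4"):
                ct = intercept + slope * np.log10(copies)
                if ct_sd > 0:
                    ct += shared + rng.normal(0, sd_dye)
                rows.append(
                    {
                        "well": f"W{well:04d}",
                        "sample_id": f"STD_{copies:g}",
                        "target": target,
                        "ct": float(ct),
                        "is_standard": True,
                        "standard_copies": float(copies),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bulk RNA-seq mixtures
# ---------------------------------------------------------------------------

DEFAULT_CELL_TYPES = (
    "GabaVIPReln", "GabaPV", "Pyramidal", "Astrocyte", "Oligo", "Microglia"
)
DEFAULT_BASE_PROPORTIONS = {
    "GabaVIPReln": 0.10, "GabaPV": 0.08, "Pyramidal": 0.42,
    "Astrocyte": 0.18, "Oligo": 0.16, "Microglia": 0.06,
}


def default_signature(
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    markers_per_type: int = 12,
    n_background: int = 800,
    marker_fold: float = 30.0,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """A gene x cell-type mean-expression signature plus its marker table.

    Marker genes are expressed ``marker_fold`` times higher in their own
    type than elsewhere; background genes share lognormal means across
    types with mild type-to-type wobble.
    """
    rng = np.random.default_rng(seed)
    genes = []
    marker_table: dict[str, list[str]] = {t: [] for t in cell_types}
    rows = []
    for t in cell_types:
        for m in range(markers_per_type):
            g = f"{t}_MK{m + 1:02d}"
            genes.append(g)
            marker_table[t].append(g)
            base = np.exp(rng.normal(3.0, 0.5))
            rows.append([base * marker_fold if u == t else base for u in cell_types])
    for b in range(n_background):
        g = f"BG{b + 1:04d}"
        genes.append(g)
        base = np.exp(rng.normal(4.0, 1.0))
        rows.append([base * np.exp(rng.normal(0, 0.1)) for _ in cell_types])
    sig = pd.DataFrame(rows, index=genes, columns=list(cell_types))
    return sig, marker_table


def default_proportions(
    subjects: pd.DataFrame,
    base: dict[str, float] | None = None,
    shifts: dict[str, float] | None = None,
    shifted_group: str = "CI-PD",
    group_col: str = "bulk_group",
    severity_beta: tuple[float, float] = (5.0, 2.0),
    concentration: float = 40.0,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Per-sample true cell-type proportions with a planted driver shift.

    Each sample in ``shifted_group`` carries a latent severity
    ``s ~ Beta(severity_beta)`` (controls: s = 0); type ``t``'s base
    proportion is multiplied by ``shifts[t] ** s`` before renormalizing,
    so all shifted types co-vary through the same latent severity.  The
    default mirrors the CI-deficient profile: a strong decrease of the
    VIP/reelin GABAergic interneurons (factor 0.4), the single truly
    shifted type; every other type's share then co-varies with it
    through compositional closure, the structure in which one cell
    type's profile drives the other types' apparent group effects.
    Sample-to-sample variation is Dirichlet with the given
    concentration.
    """
    rng = np.random.default_rng(seed)
    base = base or DEFAULT_BASE_PROPORTIONS
    shifts = shifts if shifts is not None else {"GabaVIPReln": 0.4}
    types = list(base)
    rows = []
    for _, subj in subjects.iterrows():
        p = np.array([base[t] for t in types], dtype=float)
        if subj[group_col] == shifted_group:
            s = rng.beta(*severity_beta)
            for t, f in shifts.items():
                p[types.index(t)] *= f**s
        p = p / p.sum()
        rows.append(rng.dirichlet(p * concentration))
    return pd.DataFrame(rows, index=subjects["subject_id"].to_numpy(), columns=types)


SEX_GENE_SPECIFICITY = {"XIST": "F", "KDM5D": "M", "RPS4Y1": "M"}


def gen_bulk(
    subjects: pd.DataFrame,
    signature: pd.DataFrame,
    proportions: pd.DataFrame,
    library_size: float = 2e5,
    dispersion: float = 0.05,
    sex_gene_level: float = 500.0,
    sex_leak: float = 0.01,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk counts as negative-binomial mixtures of cell-type signatures.

    Per sample, gene means are ``library_size * sum_t proportion_t *
    signature_norm[g, t]`` (signature columns normalized to unit mass),
    with gamma-Poisson dispersion.  Sex-specific genes XIST (female) and
    KDM5D/RPS4Y1 (male) are added at ``sex_gene_level`` counts in the
    concordant sex and ``sex_leak`` of that in the discordant sex.
    Returns (counts genes x samples, metadata).
    """
    if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1 per sample")
    if (signature < 0).to_numpy().any():
        raise ValueError("signature means must be non-negative")
    rng = np.random.default_rng(seed)
    sig = signature / signature.sum(axis=0)
    samples = list(proportions.index)
    meta = subjects.set_index("subject_id").loc[samples].reset_index()

    mean = (sig.to_numpy() @ proportions.to_numpy().T) * library_size
    genes = list(signature.index)
    sex = meta.set_index("subject_id")["sex"]
    sex_rows = []
    for g, conc in SEX_GENE_SPECIFICITY.items():
        level = np.where(sex.loc[samples].to_numpy() == conc,
                         sex_gene_level, sex_gene_level * sex_leak)
        sex_rows.append(level.astype(float))
    mean = np.vstack([mean, np.array(sex_rows)])
    genes = genes + list(SEX_GENE_SPECIFICITY)

    if dispersion < 1e-8:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=samples), meta


# ---------------------------------------------------------------------------
# droplet matrices
# ---------------------------------------------------------------------------

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)


def default_droplet_profiles(
    panel: dict[str, list[str]] | None = None,
    n_extra_markers: int = 30,
    n_background: int = 1500,
    marker_fold: float = 10.0,
    mito_fraction: float = 0.01,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Gene-probability profiles (genes x types) for droplet simulation.

    Each major type expresses its panel markers and ``n_extra_markers``
    synthetic type-specific genes at ``marker_fold`` times background;
    ``n_background`` housekeeping genes are shared, and mitochondrial
    genes carry ``mito_fraction`` of each profile's mass.
    """
    rng = np.random.default_rng(seed)
    panel = panel or DEFAULT_MARKER_PANEL
    types = list(panel)
    genes: list[str] = []
    marker_of: dict[str, str] = {}
    for t in types:
        for g in panel[t]:
            genes.append(g)
            marker_of[g] = t
        for m in range(n_extra_markers):
            g = f"{t}_SMK{m + 1:02d}"
            genes.append(g)
            marker_of[g] = t
    bg = [f"GENE{i + 1:05d}" for i in range(n_background)]
    genes += bg
    genes += list(MITO_GENES)

    bg_w = np.exp(rng.normal(0.0, 1.0, size=n_background))
    cols = {}
    for t in types:
        w = np.zeros(len(genes))
        for i, g in enumerate(genes):
            if g in marker_of:
                w[i] = marker_fold if marker_of[g] == t else 0.02
        w[len(genes) - n_background - len(MITO_GENES):len(genes) - len(MITO_GENES)] = (
            bg_w / bg_w.mean() * 0.5
        )
        non_mito = w.sum()
        mito_w = mito_fraction / (1 - mito_fraction) * non_mito / len(MITO_GENES)
        w[-len(MITO_GENES):] = mito_w
        cols[t] = w / w.sum()
    return pd.DataFrame(cols, index=genes)


def gen_droplets(
    n_cells: int = 2000,
    type_proportions: dict[str, float] | None = None,
    profiles: pd.DataFrame | None = None,
    n_empty: int = 500,
    ambient_profile: np.ndarray | None = None,
    ambient_fraction: float = 0.05,
    doublet_rate: float = 0.07,
    cell_umi_lognormal: tuple[float, float] = (np.log(3500.0), 0.25),
    empty_umi_mean: float = 100.0,
    doublet_umi_factor: float = 1.8,
    seed: int = DEFAULT_SEED,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a droplet UMI matrix with planted truth.

    Of the ``n_cells`` cell-containing droplets, ``doublet_rate`` are
    doublets mixing two independently drawn types.  Cells sample UMIs
    multinomially from ``(1 - a) * type profile + a * ambient`` with
    ``a = ambient_fraction``; empty droplets sample ~``empty_umi_mean``
    UMIs from the ambient profile alone (the mean expression soup,
    weighted by type abundance).  Returns an AnnData of integer counts
    and a truth table (kind, type, second type for doublets, ambient
    fraction) indexed by barcode; barcodes are emitted in shuffled
    order so droplet kind is not positional.
    """
    if not 0 <= doublet_rate < 1:
        raise ValueError("doublet_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    profiles = profiles if profiles is not None else default_droplet_profiles(seed=seed)
    types = list(profiles.columns)
    props = type_proportions or {t: 1.0 / len(types) for t in types}
    p_types = np.array([props[t] for t in types], dtype=float)
    p_types = p_types / p_types.sum()
    P = profiles.to_numpy()  # genes x types
    if ambient_profile is None:
        ambient = P @ p_types
    else:
        ambient = np.asarray(ambient_profile, dtype=float)
        if ambient.shape[0] != P.shape[0]:
            raise ValueError("ambient profile length mismatch")
        ambient = ambient / ambient.sum()

    n_doublet = int(round(n_cells * doublet_rate))
    n_singlet = n_cells - n_doublet

    rows = []
    counts = []
    for i in range(n_singlet):
        t = rng.choice(len(types), p=p_types)
        n_umi = int(np.exp(rng.normal(*cell_umi_lognormal)))
        mix = (1 - ambient_fraction) * P[:, t] + ambient_fraction * ambient
        counts.append(rng.multinomial(n_umi, mix))
        rows.append({"kind": "cell", "type": types[t], "type_b": None,
                     "ambient_fraction": ambient_fraction})
    for i in range(n_doublet):
        ta, tb = rng.choice(len(types), p=p_types), rng.choice(len(types), p=p_types)
        n_umi = int(np.exp(rng.normal(*cell_umi_lognormal)) * doublet_umi_factor)
        mix = (1 - ambient_fraction) * 0.5 * (P[:, ta] + P[:, tb]) + ambient_fraction * ambient
        counts.append(rng.multinomial(n_umi, mix))
        rows.append({"kind": "doublet", "type": types[ta], "type_b": types[tb],
                     "ambient_fraction": ambient_fraction})
    for i in range(n_empty):
        n_umi = max(int(rng.poisson(empty_umi_mean)), 1)
        counts.append(rng.multinomial(n_umi, ambient))
        rows.append({"kind": "empty", "type": None, "type_b": None,
                     "ambient_fraction": 1.0})

    order = rng.permutation(len(rows))
    X = sparse.csr_matrix(np.vstack(counts)[order])
    truth = pd.DataFrame([rows[i] for i in order])
    barcodes = [f"BC{i + 1:06d}" for i in range(len(rows))]
    truth.index = pd.Index(barcodes, name="barcode")
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=profiles.index),
    )
    return adata, truth
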
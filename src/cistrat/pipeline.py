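"""End-to-end orchestration of the stratification pipeline.

``run_pipeline`` executes the stages in dependency order on synthetic
data (or on user-supplied files via the CLI stage commands): cohort
synthesis -> IHC profiling and k-means stratification -> single-neuron
mtDNA quantification -> bulk MGP analysis -> droplet QC cascade ->
association reports.  Every output is written atomically under the run
directory and a deterministic RunReport (per-stage record counts, test
reports, config hash) is serialized as JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import bulk as bulk_mod
from . import ihc as ihc_mod
from . import io as io_mod
from . import mtdna as mtdna_mod
from . import snrna as snrna_mod
from . import stats as stats_mod
from . import synthetic as synth_mod

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's parameter values."""

    outdir: str = "cistrat_run"
    seed: int = synth_mod.DEFAULT_SEED
    # cohort synthesis
    n_controls: int = 22
    n_ipd: int = 89
    rater_sd: float = 0.25
    # stratification
    k: int = 3
    n_restarts: int = 20
    max_iter: int = 100
    min_snpc_neurons: int = 25
    # mtDNA
    ct_sd: float = 0.15
    mtdna_subjects_per_group: int = 8
    # bulk
    n_bulk_samples: int = 60
    dominant_frac: float = 0.006
    dominant_sample_frac: float = 0.5
    low_count: int = 5
    low_sample_frac: float = 0.8
    gsr_resamples: int = 2000
    gene_set_min: int = 20
    gene_set_max: int = 500
    # snRNA
    n_droplet_cells: int = 2000
    n_empty_droplets: int = 500
    doublet_rate: float = 0.07
    min_genes: int = 500
    min_umi: int = 1000
    max_mito: float = 0.03
    gene_min_cells: int = 10
    n_pcs: int = 50
    n_clusters: int = 10
    n_pcs_purify: int = 5
    mgp_threshold: float = 0.4
    # stage toggles
    run_ihc: bool = True
    run_mtdna: bool = True
    run_bulk: bool = True
    run_snrna: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run the synthetic end-to-end pipeline and return the RunReport."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed, 8)
    report: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "tests": {},
    }

    # ---- synthesize cohort ------------------------------------------------
    spec = synth_mod.CohortSpec(
        n_controls=config.n_controls, n_ipd=config.n_ipd, seed=seeds[0]
    )
    subjects, truth = synth_mod.gen_cohort(spec)
    records = synth_mod.gen_ihc_counts(
        subjects, truth, rater_sd=config.rater_sd, seed=seeds[1]
    )
    io_mod.write_tsv(subjects, out / "subjects.tsv")
    io_mod.write_tsv(records, out / "neuron_counts.tsv")
    io_mod.write_tsv(truth, out / "truth" / "cohort_truth.tsv")
    report["stages"]["synth"] = {
        "n_subjects": len(subjects), "n_count_records": len(records)
    }

    merged = pd.Series("control", index=subjects["subject_id"])

    if config.run_ihc:
        profiles = ihc_mod.compute_ci_profiles(
            records, min_snpc_neurons=config.min_snpc_neurons
        )
        pfc = profiles[(profiles["region"] == "PFC") & profiles["qc_pass"]]
        strat = ihc_mod.stratify_kmeans(
            pfc, k=config.k, n_restarts=config.n_restarts,
            max_iter=config.max_iter, seed=seeds[2],
        )
        assign = strat.assignments.set_index("subject_id")
        ipd = assign["group"] == "iPD"
        merged.loc[assign.index[ipd]] = assign.loc[ipd, "merged_label"]

        io_mod.write_tsv(profiles, out / "ci_profiles.tsv")
        io_mod.write_tsv(strat.assignments, out / "stratification.tsv")

        prof_merged = profiles.copy()
        prof_merged["group"] = prof_merged["subject_id"].map(merged)
        regional = ihc_mod.regional_summary(prof_merged)
        (out / "regional_dendrogram.nwk").write_text(regional["newick"] + "\n")
        io_mod.write_tsv(regional["medians"].reset_index(), out / "regional_medians.tsv")

        per_rater = ihc_mod.rater_percentages(records)
        pfc_rater = per_rater[per_rater["region"] == "PFC"].pivot_table(
            index="subject_id", columns="rater_id", values="percent_positive"
        )
        icc = stats_mod.icc_agreement(pfc_rater)
        ba = stats_mod.bland_altman(pfc_rater.to_numpy())
        mwu = stats_mod.mann_whitney(
            pfc.loc[pfc["group"] == "iPD", "percent_positive"],
            pfc.loc[pfc["group"] == "control", "percent_positive"],
        )
        shares = (
            assign.loc[ipd, "label"].value_counts(normalize=True).to_dict()
        )
        report["stages"]["ihc"] = {
            "n_profiles": len(profiles),
            "centers": strat.centers.tolist(),
            "wss": strat.wss,
            "control_top_fraction": strat.control_top_fraction,
            "ipd_cluster_shares": shares,
        }
        report["tests"]["icc_pfc"] = icc.to_dict()
        report["tests"]["bland_altman_pfc"] = {
            "bias": ba["bias"], "loa_low": ba["loa_low"], "loa_high": ba["loa_high"]
        }
        report["tests"]["mwu_pfc_ipd_vs_control"] = mwu.to_dict()
        io_mod.write_json(
            {
                "centers": strat.centers.tolist(),
                "wss": strat.wss,
                "control_top_fraction": strat.control_top_fraction,
                "ipd_cluster_shares": shares,
            },
            out / "stratification_summary.json",
        )

    if config.run_mtdna:
        rng = np.random.default_rng(seeds[3])
        chosen = []
        for grp, label in (("control", "control"), ("nCI-PD", "nCI-PD"), ("CI-PD", "CI-PD")):
            ids = merged.index[merged == grp]
            take = min(config.mtdna_subjects_per_group, len(ids))
            chosen += list(rng.choice(ids, size=take, replace=False))
        mt_subjects = subjects[subjects["subject_id"].isin(chosen)].copy()
        mt_subjects["mtdna_group"] = mt_subjects["subject_id"].map(merged)
        neuron_truth = synth_mod.gen_neuron_truth(mt_subjects, seed=seeds[3])
        plate = synth_mod.gen_qpcr(neuron_truth, ct_sd=config.ct_sd, seed=seeds[4])
        io_mod.write_tsv(plate, out / "qpcr_plate.tsv")
        io_mod.write_tsv(
            neuron_truth, out / "truth" / "neuron_truth.tsv"
        )

        standards = plate[plate["is_standard"]].rename(columns={"standard_copies": "copies"})
        curves = {
            t: mtdna_mod.fit_standard_curve(standards, target=t)
            for t in ("MTND1", "MTND4")
        }
        results = mtdna_mod.quantify_neurons(plate, curves)
        results = results.merge(
            neuron_truth[["sample_id", "subject_id", "group"]], on="sample_id"
        )
        io_mod.write_tsv(results, out / "mtdna_results.tsv")
        per_subject, welch = mtdna_mod.subject_deletion_summary(results)
        io_mod.write_tsv(per_subject, out / "mtdna_subject_summary.tsv")
        report["stages"]["mtdna"] = {
            "n_neurons": len(results),
            "n_subjects": len(per_subject),
            "curves": {t: {"slope": c.slope, "intercept": c.intercept,
                           "r_squared": c.r_squared, "efficiency": c.efficiency}
                       for t, c in curves.items()},
        }
        if welch is not None:
            gh = welch.extra.pop("games_howell")
            report["tests"]["mtdna_deletion_welch"] = welch.to_dict()
            io_mod.write_json(
                {**welch.to_dict(), "games_howell": gh.to_dict(orient="records")},
                out / "mtdna_group_comparison.json",
            )

    if config.run_bulk:
        rng = np.random.default_rng(seeds[5])
        ids = list(merged.index)
        take = min(config.n_bulk_samples, len(ids))
        chosen = list(rng.choice(ids, size=take, replace=False))
        bs = subjects[subjects["subject_id"].isin(chosen)].copy()
        bs["bulk_group"] = bs["subject_id"].map(merged)
        signature, markers = synth_mod.default_signature(seed=seeds[5])
        proportions = synth_mod.default_proportions(bs, seed=seeds[5])
        counts, meta = synth_mod.gen_bulk(bs, signature, proportions, seed=seeds[5])
        io_mod.write_tsv(counts.reset_index(names="gene"), out / "bulk_counts.tsv")
        io_mod.write_tsv(meta, out / "bulk_metadata.tsv")
        io_mod.write_tsv(proportions.reset_index(names="subject_id"),
                         out / "truth" / "bulk_proportions.tsv")

        filtered, removal = bulk_mod.filter_genes(
            counts,
            dominant_frac=config.dominant_frac,
            dominant_sample_frac=config.dominant_sample_frac,
            low_count=config.low_count,
            low_sample_frac=config.low_sample_frac,
        )
        lc = bulk_mod.logcpm(filtered)
        threshold, _ = bulk_mod.sex_noise_threshold(
            lc, meta.set_index("subject_id")["sex"]
        )
        mgp = bulk_mod.mgp_estimate(lc, markers)
        analysis = bulk_mod.mgp_group_analysis(
            mgp, meta.set_index("subject_id"), group_col="bulk_group",
            reference="control", covariates=("age", "sex", "pmi", "cohort"),
        )
        io_mod.write_tsv(mgp.scores.reset_index(names="subject_id"), out / "mgp_scores.tsv")
        io_mod.write_tsv(analysis["effects"], out / "mgp_effects.tsv")

        scores = bulk_mod.rank_sum_gene_scores(
            lc, meta.set_index("subject_id")["bulk_group"], "CI-PD", "control"
        )
        rng_sets = np.random.default_rng(seeds[6])
        gene_sets = {"GABA_VIPRELN_SET": markers["GabaVIPReln"]
                     + list(rng_sets.choice(lc.index, 10, replace=False))}
        for i in range(8):
            gene_sets[f"RANDOM_SET_{i + 1}"] = list(
                rng_sets.choice(lc.index, 25, replace=False)
            )
        enrich = bulk_mod.gsr_enrichment(
            scores, gene_sets, n_resample=config.gsr_resamples, seed=seeds[6],
            min_size=config.gene_set_min, max_size=config.gene_set_max,
        )
        io_mod.write_tsv(enrich.reset_index(), out / "gsr_enrichment.tsv")
        report["stages"]["bulk"] = {
            "n_samples": take,
            "n_genes_in": len(counts),
            "n_genes_kept": len(filtered),
            "n_removed": len(removal),
            "sex_noise_threshold": threshold,
            "mgp_variance_explained": mgp.variance_explained,
            "driver": analysis["driver"],
        }

    if config.run_snrna:
        adata, droplet_truth = synth_mod.gen_droplets(
            n_cells=config.n_droplet_cells,
            n_empty=config.n_empty_droplets,
            doublet_rate=config.doublet_rate,
            seed=seeds[7],
        )
        io_mod.write_droplets(adata, out / "droplets")
        io_mod.write_tsv(
            droplet_truth.reset_index(), out / "truth" / "droplet_truth.tsv"
        )
        cascade = snrna_mod.run_qc_cascade(
            adata,
            min_genes=config.min_genes,
            min_umi=config.min_umi,
            max_mito=config.max_mito,
            gene_min_cells=config.gene_min_cells,
            n_pcs=config.n_pcs,
            n_clusters=config.n_clusters,
            n_pcs_purify=config.n_pcs_purify,
            mgp_threshold=config.mgp_threshold,
            seed=seeds[7],
        )
        io_mod.write_tsv(
            cascade.records.reset_index(names="barcode"), out / "droplet_qc.tsv"
        )
        io_mod.write_tsv(
            cascade.adata.uns["annotation"].reset_index(), out / "cluster_annotation.tsv"
        )
        report["stages"]["snrna"] = dict(cascade.stage_stats)

        # per-subject nuclei counts: kept nuclei spread over the mtDNA-style
        # subject design (synthetic plumbing for the group ANOVA report)
        rng = np.random.default_rng(seeds[7])
        groups3 = merged.map(lambda g: g if g != "control" else "control")
        subj_ids = list(groups3.index)
        weights = rng.dirichlet(np.full(len(subj_ids), 50.0))
        assign_counts = rng.multinomial(cascade.adata.n_obs, weights)
        nuclei = pd.DataFrame(
            {"subject_id": subj_ids, "group": groups3.to_numpy(), "n_nuclei": assign_counts}
        )
        anova = snrna_mod.nuclei_count_compare(nuclei)
        report["tests"]["nuclei_count_anova"] = anova.to_dict()

    io_mod.write_json(report, out / "run_report.json")
    return report
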
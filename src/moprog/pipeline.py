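"""End-to-end orchestration: simulate -> prep -> cluster (methylation,
mRNA) + integrate -> survival labeling and pooling -> downstream
characterization (differential expression, ORA, immune/stromal scores,
differential methylation, region analyses, mutation burden, spectra,
signature fits).

Each stage reads and writes TSV files under one output directory and is
recorded in a JSON run manifest with SHA-256 hashes of its inputs and
outputs. Re-running with an unchanged configuration skips stages whose
recorded hashes still match; corrupting an intermediate file invalidates
that stage and everything downstream of it.

One global seed fans out to per-stage seeds as
``(seed * 1009 + stage_index) % 2**31`` so any stage can be reproduced
in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .consensus import consensus_cluster
from .core_stats import t_test_two_sided
from .data_io import (
    get_logger,
    read_clinical,
    read_gmt,
    read_matrix,
    read_mutations,
    read_regions,
    read_signatures,
)
from .expression import nb_wald_test, ora, score_table
from .feature_prep import log2_transform, select_top_mad
from .integrate import block_scale, consensus_pca, gap_statistic_cluster
from .methylation import call_dm_genes, region_enrichment, region_means, sam_test
from .mutation import build_catalog, burden_by_sample, fit_signatures, gene_mutation_test
from .survival import SurvivalLabeling, km_estimate, label_clusters, pool_groups
from .synthetic import CohortConfig, generate_cohort, write_cohort

logger = get_logger()

__all__ = ["PipelineConfig", "run_all"]

_GROUP_PAIRS = (("better", "poorer"), ("better", "intermediate"), ("poorer", "intermediate"))


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable settings of the orchestrated run.

    Resampling and permutation counts default to desk-scale values
    (50 consensus resamples, 100 SAM permutations) rather than the
    1000-resample production setting, which is available by raising
    them here.
    """

    seed: int = 0
    n_samples: int = 447
    meth_fraction: float = 0.10
    expr_fraction: float = 0.20
    n_resamples: int = 50
    p_item: float = 0.9
    p_feature: float = 0.9
    k_min: int = 2
    k_max: int = 6
    n_factors: int = 10
    gap_k_max: int = 8
    gap_references: int = 30
    sam_permutations: int = 100
    alpha_label: float = 0.01
    force_k_methylation: int | None = None
    force_k_mrna: int | None = None
    force_k_integrated: int | None = None
    cohort_overrides: dict | None = None

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.cohort_overrides or {})
        overrides.setdefault("n_samples", self.n_samples)
        overrides.setdefault("seed", self._stage_seed(0))
        return CohortConfig(**overrides)

    def _stage_seed(self, index: int) -> int:
        return (self.seed * 1009 + index) % 2**31


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: str, config: PipelineConfig):
        self.path = path
        # JSON round-trip so the snapshot compares equal to a reloaded one
        snapshot = json.loads(json.dumps(dataclasses.asdict(config)))
        self.data = {"version": __version__, "config": snapshot, "stages": {}}
        if os.path.exists(path):
            with open(path) as fh:
                previous = json.load(fh)
            if previous.get("config") == self.data["config"] and previous.get(
                "version"
            ) == __version__:
                self.data["stages"] = previous.get("stages", {})

    def up_to_date(self, stage: str, inputs: list[str], outputs: list[str]) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None:
            return False
        try:
            current_in = {p: _sha256(p) for p in inputs}
        except FileNotFoundError:
            return False
        if entry["inputs"] != current_in:
            return False
        for p, digest in entry["outputs"].items():
            if not os.path.exists(p) or _sha256(p) != digest:
                return False
        return set(entry["outputs"]) == set(outputs)

    def record(self, stage: str, inputs: list[str], outputs: list[str], seed: int) -> None:
        self.data["stages"][stage] = {
            "inputs": {p: _sha256(p) for p in inputs},
            "outputs": {p: _sha256(p) for p in outputs},
            "seed": seed,
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def _write(frame: pd.DataFrame, path: str, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _plot_km(grouping: pd.Series, clinical, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name in sorted(grouping.unique()):
        ids = grouping.index[grouping == name]
        times, events = clinical.survival_arrays(ids)
        curve = km_estimate(times, events)
        ax.step(
            np.concatenate([[0.0], curve.times]),
            np.concatenate([[1.0], curve.survival]),
            where="post",
            label=f"{name} (n={len(ids)})",
        )
    ax.set_xlabel("days")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(config: PipelineConfig | dict | None = None, out_dir: str = "moprog_run") -> dict:
    """Execute every stage in dependency order under ``out_dir``.

    Returns the mapping of logical output names to paths. Stages whose
    recorded input and output hashes are unchanged are skipped.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    os.makedirs(out_dir, exist_ok=True)
    manifest = _Manifest(os.path.join(out_dir, "manifest.json"), config)
    data_dir = os.path.join(out_dir, "data")
    res_dir = os.path.join(out_dir, "results")
    os.makedirs(res_dir, exist_ok=True)
    paths: dict[str, str] = {"manifest": manifest.path}

    # ---- stage 0: simulate ------------------------------------------------
    cohort_cfg = config.cohort_config()
    data_paths = {
        name: os.path.join(data_dir, fname)
        for name, fname in [
            ("methylation", "methylation_beta.tsv"),
            ("mrna_counts", "mrna_counts.tsv"),
            ("mirna_counts", "mirna_counts.tsv"),
            ("clinical", "clinical.tsv"),
            ("mutations", "mutations.tsv"),
            ("gene_sets", "gene_sets.gmt"),
            ("signatures", "signatures.tsv"),
            ("regions_bed", "regions.bed"),
            ("tss", "tss.tsv"),
            ("probes", "probes.tsv"),
            ("groups", "latent_groups.tsv"),
        ]
    }
    paths.update(data_paths)
    if not manifest.up_to_date("simulate", [], list(data_paths.values())):
        logger.info("stage simulate: generating cohort (n=%d)", cohort_cfg.n_samples)
        write_cohort(generate_cohort(cohort_cfg), data_dir)
        manifest.record("simulate", [], list(data_paths.values()), cohort_cfg.seed)
    else:
        logger.info("stage simulate: up to date, skipped")

    meth = read_matrix(data_paths["methylation"], "methylation_beta")
    clinical = read_clinical(data_paths["clinical"])

    # ---- stage 1: prep ----------------------------------------------------
    prep_paths = {
        "meth_top": os.path.join(out_dir, "prep", "methylation_top.tsv"),
        "mrna_top": os.path.join(out_dir, "prep", "mrna_log_top.tsv"),
        "mirna_top": os.path.join(out_dir, "prep", "mirna_log_top.tsv"),
    }
    os.makedirs(os.path.join(out_dir, "prep"), exist_ok=True)
    paths.update(prep_paths)
    prep_inputs = [data_paths[k] for k in ("methylation", "mrna_counts", "mirna_counts")]
    if not manifest.up_to_date("prep", prep_inputs, list(prep_paths.values())):
        logger.info("stage prep: MAD selection")
        from .data_io import write_matrix

        write_matrix(select_top_mad(meth, config.meth_fraction), prep_paths["meth_top"])
        mrna = read_matrix(data_paths["mrna_counts"], "expression_counts")
        write_matrix(
            select_top_mad(log2_transform(mrna), config.expr_fraction),
            prep_paths["mrna_top"],
        )
        mirna = read_matrix(data_paths["mirna_counts"], "expression_counts")
        write_matrix(
            select_top_mad(log2_transform(mirna), config.expr_fraction),
            prep_paths["mirna_top"],
        )
        manifest.record("prep", prep_inputs, list(prep_paths.values()), config.seed)
    else:
        logger.info("stage prep: up to date, skipped")

    # ---- stages 2-3: single-block consensus clustering --------------------
    cluster_dir = os.path.join(out_dir, "clusters")
    os.makedirs(cluster_dir, exist_ok=True)
    assignments: dict[str, pd.Series] = {}
    for stage_idx, (name, prep_key, kind, force_k) in enumerate(
        [
            ("methylation", "meth_top", "methylation_beta", config.force_k_methylation),
            ("mrna", "mrna_top", "expression_log", config.force_k_mrna),
        ],
        start=2,
    ):
        out_path = os.path.join(cluster_dir, f"{name}_assignment.tsv")
        cons_path = os.path.join(cluster_dir, f"{name}_consensus.tsv")
        paths[f"{name}_assignment"] = out_path
        stage = f"cluster_{name}"
        seed = config._stage_seed(stage_idx)
        if not manifest.up_to_date(stage, [prep_paths[prep_key]], [out_path, cons_path]):
            logger.info("stage %s: consensus clustering", stage)
            block = read_matrix(prep_paths[prep_key], kind)
            result = consensus_cluster(
                block,
                k_range=range(config.k_min, config.k_max + 1),
                base_method="ward",
                n_resamples=config.n_resamples,
                p_item=config.p_item,
                p_feature=config.p_feature,
                seed=seed,
                force_k=force_k,
            )
            series = result.assignment_series()
            _write(series.rename_axis("sample_id").reset_index(), out_path)
            _write(
                pd.DataFrame(
                    result.consensus[result.selected_k],
                    index=result.sample_ids,
                    columns=result.sample_ids,
                ),
                cons_path,
                index=True,
            )
            manifest.record(stage, [prep_paths[prep_key]], [out_path, cons_path], seed)
        else:
            logger.info("stage %s: up to date, skipped", stage)
        assignments[name] = pd.read_csv(out_path, sep="\t", index_col=0)["cluster"]

    # ---- stage 4: integrative clustering -----------------------------------
    integrated_path = os.path.join(cluster_dir, "integrated_assignment.tsv")
    paths["integrated_assignment"] = integrated_path
    seed = config._stage_seed(4)
    if not manifest.up_to_date("integrate", list(prep_paths.values()), [integrated_path]):
        logger.info("stage integrate: consensus PCA + gap statistic")
        blocks = [
            read_matrix(prep_paths["meth_top"], "methylation_beta"),
            read_matrix(prep_paths["mrna_top"], "expression_log"),
            read_matrix(prep_paths["mirna_top"], "expression_log"),
        ]
        scaled = block_scale(blocks)
        factors = consensus_pca(
            scaled,
            n_factors=min(config.n_factors, len(scaled[0].sample_ids) - 1),
            block_names=["methylation", "mrna", "mirna"],
        )
        gap = gap_statistic_cluster(
            factors.scores,
            k_range=range(1, config.gap_k_max + 1),
            n_references=config.gap_references,
            seed=seed,
            override=config.force_k_integrated,
        )
        series = pd.Series(gap.labels, index=factors.sample_ids, name="cluster")
        _write(series.rename_axis("sample_id").reset_index(), integrated_path)
        manifest.record("integrate", list(prep_paths.values()), [integrated_path], seed)
    else:
        logger.info("stage integrate: up to date, skipped")
    assignments["integrated"] = pd.read_csv(integrated_path, sep="\t", index_col=0)["cluster"]

    # ---- stage 5: survival labeling + pooling ------------------------------
    grouping_path = os.path.join(res_dir, "prognostic_grouping.tsv")
    labeling_path = os.path.join(res_dir, "cluster_labeling.tsv")
    km_path = os.path.join(res_dir, "km_pooled.png")
    paths["grouping"] = grouping_path
    pool_inputs = [
        integrated_path,
        os.path.join(cluster_dir, "methylation_assignment.tsv"),
        os.path.join(cluster_dir, "mrna_assignment.tsv"),
        data_paths["clinical"],
    ]
    if not manifest.up_to_date("pool", pool_inputs, [grouping_path, labeling_path, km_path]):
        logger.info("stage pool: survival labeling and pooling")
        def _labeling_for(name: str) -> SurvivalLabeling:
            assign = assignments[name].astype(str)
            if assign.nunique() < 2:
                # a single-cluster solution carries no survival contrast
                labels = pd.Series("neutral", index=assign.index, name="label")
                return SurvivalLabeling(
                    name,
                    labels,
                    {c: "neutral" for c in assign.unique()},
                    pd.DataFrame(),
                    pd.DataFrame(),
                )
            return label_clusters(
                assign, clinical, alpha=config.alpha_label, approach=name
            )

        labelings = [
            _labeling_for(name) for name in ("integrated", "methylation", "mrna")
        ]
        grouping = pool_groups(labelings)
        out = grouping.provenance.copy()
        out["prognostic_group"] = grouping.groups
        _write(out.rename_axis("sample_id").reset_index(), grouping_path)
        rows = []
        for lab in labelings:
            for cluster, label in sorted(lab.cluster_labels.items()):
                rows.append({"approach": lab.approach, "cluster": cluster, "label": label})
        _write(pd.DataFrame(rows), labeling_path)
        _plot_km(grouping.groups, clinical, km_path)
        manifest.record("pool", pool_inputs, [grouping_path, labeling_path, km_path], config.seed)
    else:
        logger.info("stage pool: up to date, skipped")
    grouping = pd.read_csv(grouping_path, sep="\t", index_col=0)["prognostic_group"]

    def _group_ids(name: str) -> list[str]:
        return list(grouping.index[grouping == name].astype(str))

    def _pairs_with_samples(minimum: int = 2):
        for a, b in _GROUP_PAIRS:
            if len(_group_ids(a)) >= minimum and len(_group_ids(b)) >= minimum:
                yield a, b

    # ---- stage 6: differential expression + ORA ----------------------------
    dge_path = os.path.join(res_dir, "differential_expression.tsv")
    ora_path = os.path.join(res_dir, "ora.tsv")
    seed = config._stage_seed(6)
    dge_inputs = [data_paths["mrna_counts"], grouping_path, data_paths["gene_sets"]]
    if not manifest.up_to_date("dge", dge_inputs, [dge_path, ora_path]):
        logger.info("stage dge: NB Wald tests per group pair")
        counts = read_matrix(data_paths["mrna_counts"], "expression_counts")
        gene_sets = read_gmt(data_paths["gene_sets"])
        tables, ora_tables = [], []
        for a, b in _pairs_with_samples():
            # "up" means upregulated in group a relative to group b
            res = nb_wald_test(counts, _group_ids(b), _group_ids(a))
            t = res.table.assign(comparison=f"{a}_vs_{b}")
            tables.append(t)
            up = res.calls("up")
            if up:
                enriched = ora(up, counts.feature_ids, gene_sets, alpha_adj=0.01)
                ora_tables.append(enriched.assign(comparison=f"{a}_vs_{b}_up"))
        _write(pd.concat(tables, ignore_index=True), dge_path)
        _write(
            pd.concat(ora_tables, ignore_index=True)
            if ora_tables
            else pd.DataFrame(columns=["set", "comparison"]),
            ora_path,
        )
        manifest.record("dge", dge_inputs, [dge_path, ora_path], seed)
    else:
        logger.info("stage dge: up to date, skipped")
    paths["dge"] = dge_path
    paths["ora"] = ora_path

    # ---- stage 7: immune / stromal scores ----------------------------------
    scores_path = os.path.join(res_dir, "immune_stromal_scores.tsv")
    score_tests_path = os.path.join(res_dir, "score_group_tests.tsv")
    score_inputs = [data_paths["mrna_counts"], data_paths["gene_sets"], grouping_path]
    if not manifest.up_to_date("score", score_inputs, [scores_path, score_tests_path]):
        logger.info("stage score: ssGSEA immune/stromal scores")
        counts = read_matrix(data_paths["mrna_counts"], "expression_counts")
        gene_sets = read_gmt(data_paths["gene_sets"])
        expr = log2_transform(counts)
        scores = score_table(expr, gene_sets)
        _write(scores.rename_axis("sample_id").reset_index(), scores_path)
        rows = []
        for col in scores.columns:
            for a, b in _pairs_with_samples():
                res = t_test_two_sided(
                    scores.loc[_group_ids(a), col], scores.loc[_group_ids(b), col]
                )
                rows.append(
                    {
                        "score": col,
                        "group_a": a,
                        "group_b": b,
                        "statistic": res.statistic,
                        "p": res.p_value,
                    }
                )
        _write(pd.DataFrame(rows), score_tests_path)
        manifest.record("score", score_inputs, [scores_path, score_tests_path], config.seed)
    else:
        logger.info("stage score: up to date, skipped")
    paths["scores"] = scores_path

    # ---- stage 8: differential methylation ---------------------------------
    dmp_path = os.path.join(res_dir, "differential_methylation.tsv")
    dm_genes_path = os.path.join(res_dir, "dm_genes.tsv")
    seed = config._stage_seed(8)
    region_files = [data_paths["regions_bed"], data_paths["tss"], data_paths["probes"]]
    dmp_inputs = [data_paths["methylation"], grouping_path] + region_files
    if not manifest.up_to_date("dmp", dmp_inputs, [dmp_path, dm_genes_path]):
        logger.info("stage dmp: SAM differential methylation")
        regions = read_regions(*region_files)
        dm = sam_test(
            meth,
            _group_ids("better"),
            _group_ids("poorer"),
            n_permutations=config.sam_permutations,
            seed=seed,
        )
        _write(dm.table, dmp_path)
        _write(call_dm_genes(dm, regions), dm_genes_path)
        manifest.record("dmp", dmp_inputs, [dmp_path, dm_genes_path], seed)
    else:
        logger.info("stage dmp: up to date, skipped")
    paths["dmp"] = dmp_path

    # ---- stage 9: region means + enrichment --------------------------------
    region_means_path = os.path.join(res_dir, "region_means.tsv")
    region_tests_path = os.path.join(res_dir, "region_tests.tsv")
    region_enrich_path = os.path.join(res_dir, "region_enrichment.tsv")
    reg_outputs = [region_means_path, region_tests_path, region_enrich_path]
    reg_inputs = [data_paths["methylation"], grouping_path, dmp_path] + region_files
    if not manifest.up_to_date("regions", reg_inputs, reg_outputs):
        logger.info("stage regions: genomic-region summaries")
        regions = read_regions(*region_files)
        summary = region_means(meth, grouping, regions)
        _write(summary.means.reset_index(), region_means_path)
        _write(summary.tests, region_tests_path)
        from .methylation import DiffMethResult

        dm = DiffMethResult(pd.read_csv(dmp_path, sep="\t"))
        tables = []
        for direction in ("hyper", "hypo"):
            enr = region_enrichment(dm, regions, direction)
            tables.append(enr.enrichment.assign(direction=direction))
        _write(pd.concat(tables, ignore_index=True), region_enrich_path)
        manifest.record("regions", reg_inputs, reg_outputs, config.seed)
    else:
        logger.info("stage regions: up to date, skipped")
    paths["region_means"] = region_means_path
    paths["region_enrichment"] = region_enrich_path

    # ---- stage 10: mutation burden -----------------------------------------
    burden_path = os.path.join(res_dir, "mutation_burden.tsv")
    burden_tests_path = os.path.join(res_dir, "burden_tests.tsv")
    braf_path = os.path.join(res_dir, "braf_fisher.tsv")
    burden_inputs = [data_paths["mutations"], grouping_path]
    burden_outputs = [burden_path, burden_tests_path, braf_path]
    if not manifest.up_to_date("burden", burden_inputs, burden_outputs):
        logger.info("stage burden: nonsynonymous mutation counts")
        muts = read_mutations(data_paths["mutations"])
        burden = burden_by_sample(muts, list(grouping.index.astype(str)))
        out = burden.rename_axis("sample_id").reset_index()
        out["prognostic_group"] = grouping.reindex(out["sample_id"]).to_numpy()
        _write(out, burden_path)
        rows = []
        for a, b in _pairs_with_samples():
            res = t_test_two_sided(
                burden.loc[_group_ids(a)], burden.loc[_group_ids(b)]
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": float(burden.loc[_group_ids(a)].mean()),
                    "mean_b": float(burden.loc[_group_ids(b)].mean()),
                    "statistic": res.statistic,
                    "p": res.p_value,
                }
            )
        _write(pd.DataFrame(rows), burden_tests_path)
        braf_rows = []
        for a, b in _pairs_with_samples():
            sub = grouping[grouping.isin([a, b])]
            res = gene_mutation_test(muts, sub, "BRAF")
            braf_rows.append(
                {
                    "gene": "BRAF",
                    "group_a": a,
                    "group_b": b,
                    "odds_ratio": res.estimate,
                    "p": res.p_value,
                }
            )
        _write(pd.DataFrame(braf_rows), braf_path)
        manifest.record("burden", burden_inputs, burden_outputs, config.seed)
    else:
        logger.info("stage burden: up to date, skipped")
    paths["burden"] = burden_path

    # ---- stages 11-12: spectra + signature fits ----------------------------
    spectra_path = os.path.join(res_dir, "group_spectra.tsv")
    sigfit_path = os.path.join(res_dir, "signature_weights.tsv")
    spec_inputs = [data_paths["mutations"], grouping_path, data_paths["signatures"]]
    if not manifest.up_to_date("spectra", spec_inputs, [spectra_path, sigfit_path]):
        logger.info("stage spectra: 96-channel catalogs and signature fits")
        muts = read_mutations(data_paths["mutations"])
        signatures = read_signatures(data_paths["signatures"])
        spectra = {}
        fit_rows = []
        for name in sorted(grouping.unique()):
            members = set(_group_ids(name))
            from .data_io import MutationSet

            sub = MutationSet(
                muts.records[muts.records["sample_id"].isin(members)].reset_index(
                    drop=True
                )
            )
            if len(sub) == 0:
                continue
            catalog = build_catalog(sub, label=name)
            spectra[name] = catalog.fractions()
            fit = fit_signatures(catalog, signatures)
            for sig_name, w in fit.weights.items():
                fit_rows.append(
                    {
                        "group": name,
                        "signature": sig_name,
                        "weight": w,
                        "residual": fit.residual,
                    }
                )
        _write(
            pd.DataFrame(spectra).rename_axis("channel").reset_index(), spectra_path
        )
        _write(pd.DataFrame(fit_rows), sigfit_path)
        manifest.record("spectra", spec_inputs, [spectra_path, sigfit_path], config.seed)
    else:
        logger.info("stage spectra: up to date, skipped")
    paths["spectra"] = spectra_path
    paths["signature_weights"] = sigfit_path
    return paths
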
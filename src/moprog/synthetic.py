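"""Synthetic multi-omics melanoma-like cohorts.

Generates cohorts with the statistical structure the downstream analysis
assumes: three latent prognostic groups (better / poorer / intermediate)
that differ in

* methylation level (beta values; the better group is globally the least
  methylated, the poorer group the most),
* expression of an immune (and, more weakly, a stromal) gene module,
  upregulated in the better group and downregulated in the poorer group,
* overall-survival hazard (exponential by default, the poorer group's
  hazard a configurable multiple of the better group's),
* nonsynonymous mutation burden (Poisson; the better group carries the
  most mutations), and
* mutational-signature composition (each group's catalog is drawn from a
  two-signature mixture with group-specific weights; one UV-like and one
  clock-like synthetic signature).

Every draw is governed by a single seed, so a cohort is reproducible
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import (
    CHANNELS_96,
    ClinicalTable,
    GeneSetCollection,
    MutationSet,
    OmicsMatrix,
    RegionAnnotation,
    SignatureMatrix,
    reverse_complement,
    write_clinical,
    write_gmt,
    write_matrix,
    write_mutations,
    write_regions,
    write_signatures,
)

__all__ = [
    "GROUPS",
    "CohortConfig",
    "CohortBundle",
    "ValidationCohort",
    "default_signatures",
    "generate_cohort",
    "generate_validation_cohorts",
    "write_cohort",
]

#: Latent group order used for all per-group parameter tuples.
GROUPS = ("better", "poorer", "intermediate")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; per-group tuples follow :data:`GROUPS` order."""

    n_samples: int = 447
    group_proportions: tuple[float, float, float] = (0.67, 0.12, 0.21)
    n_meth_probes: int = 2000
    n_genes: int = 1500
    n_mirnas: int = 200
    n_immune_genes: int = 100
    n_stromal_genes: int = 60
    #: beta-mean offset of the poorer group above the better group;
    #: the intermediate group sits halfway.
    meth_beta_shift: float = 0.08
    #: log2 fold-change of the immune module in the better group; the
    #: poorer group is shifted by half as much in the other direction.
    immune_set_log2fc: float = 1.5
    nb_dispersion: float = 0.15
    #: events per day for the better group (median OS ~ 4.7 years).
    baseline_hazard: float = 1.0 / 2500.0
    hazard_multipliers: tuple[float, float, float] = (1.0, 2.0, 1.4)
    #: target fraction of administratively censored patients.
    censoring_rate: float = 0.45
    weibull_shape: float = 1.0
    #: mean nonsynonymous mutations per patient, per group.
    mutation_burden_means: tuple[float, float, float] = (300.0, 80.0, 150.0)
    #: weight of the UV-like signature in each group's mixture.
    signature_weights: tuple[float, float, float] = (0.8, 0.4, 0.6)
    #: probability a patient carries a nonsynonymous BRAF mutation.
    braf_mut_probs: tuple[float, float, float] = (0.54, 0.29, 0.40)
    #: non-nonsynonymous mutations per nonsynonymous one.
    other_consequence_rate: float = 0.15
    mean_ages: tuple[float, float, float] = (57.67, 60.55, 57.96)
    #: validation-cohort sizes (first k are used) and planted effects.
    validation_sizes: tuple[int, ...] = (44, 79, 45)
    validation_log2fc: float = 1.0
    validation_loghr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        for name in (
            "baseline_hazard",
            "censoring_rate",
            "nb_dispersion",
            "weibull_shape",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(m <= 0 for m in self.hazard_multipliers):
            raise ValueError("hazard multipliers must be positive")
        if any(m <= 0 for m in self.mutation_burden_means):
            raise ValueError("mutation burden means must be positive")
        if not all(0.0 <= w <= 1.0 for w in self.signature_weights):
            raise ValueError("signature weights must be in [0, 1]")


@dataclass
class CohortBundle:
    """Everything one synthetic cohort comprises."""

    methylation: OmicsMatrix
    mrna_counts: OmicsMatrix
    mirna_counts: OmicsMatrix
    clinical: ClinicalTable
    mutations: MutationSet
    gene_sets: GeneSetCollection
    signatures: SignatureMatrix
    regions: RegionAnnotation
    groups: pd.Series  # latent truth, index = sample_id


@dataclass
class ValidationCohort:
    expression: OmicsMatrix  # log-scale microarray-like values
    clinical: ClinicalTable


def default_signatures() -> SignatureMatrix:
    """Two synthetic reference signatures.

    ``Signature_UV`` puts all its mass on C>T changes (double weight at
    dipyrimidine contexts), loosely imitating the shape of an
    ultraviolet-exposure signature; ``Signature_Age`` is uniform over
    the T>C channels, a clock-like stand-in. Both are synthetic
    constructs, not COSMIC signatures; their supports are disjoint,
    which makes mixture weights maximally identifiable from a catalog.
    """
    channels = list(CHANNELS_96)
    uv = np.zeros(96)
    for i, ch in enumerate(channels):
        if "[C>T]" in ch:
            uv[i] = 2.0 if ch[0] in "CT" else 1.0
    uv /= uv.sum()
    age = np.zeros(96)
    for i, ch in enumerate(channels):
        if "[T>C]" in ch:
            age[i] = 1.0
    age /= age.sum()
    frame = pd.DataFrame(
        {"Signature_UV": uv, "Signature_Age": age}, index=channels
    )
    return SignatureMatrix(frame)


def _gene_ids(config: CohortConfig) -> tuple[list[str], list[str], list[str]]:
    """Gene universe: immune module, stromal module, background (+BRAF)."""
    immune = [f"IMM{i:04d}" for i in range(config.n_immune_genes)]
    stromal = [f"STR{i:04d}" for i in range(config.n_stromal_genes)]
    n_bg = config.n_genes - len(immune) - len(stromal) - 1
    if n_bg < 1:
        raise ValueError("n_genes too small for the immune/stromal modules")
    background = [f"G{i:05d}" for i in range(n_bg)] + ["BRAF"]
    return immune, stromal, background


def _synthetic_regions(config: CohortConfig) -> RegionAnnotation:
    """A deterministic toy genome on chr1.

    One gene every 10 kb with 5'UTR/exon/intron/3'UTR intervals; every
    third gene gets an upstream enhancer. Methylation probes cycle
    through characteristic offsets relative to their gene's TSS, so every
    region class (and the promoter window) is populated.
    """
    immune, stromal, background = _gene_ids(config)
    genes = immune + stromal + background
    spacing = 10_000
    rows, tss_rows = [], []
    for g_idx, gene in enumerate(genes):
        tss = 20_000 + g_idx * spacing
        tss_rows.append((gene, "chr1", "+", tss))
        rows.append(("chr1", tss, tss + 200, "5'UTR"))
        rows.append(("chr1", tss, tss + 300, "exon"))
        rows.append(("chr1", tss + 300, tss + 1000, "intron"))
        rows.append(("chr1", tss + 1000, tss + 1300, "exon"))
        rows.append(("chr1", tss + 1300, tss + 1500, "3'UTR"))
        if g_idx % 3 == 0:
            rows.append(("chr1", tss - 5000, tss - 4500, "enhancer"))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_class"])
    tss_table = pd.DataFrame(
        tss_rows, columns=["gene", "chrom", "strand", "tss_position"]
    )
    # probe placement: cycle through promoter / exonic / intronic /
    # 3'UTR / enhancer / intergenic offsets
    offsets = (-1200, 100, 500, 1100, 1400, -4750, -3000)
    probe_rows = []
    for p in range(config.n_meth_probes):
        gene_idx = p % len(genes)
        tss = 20_000 + gene_idx * spacing
        off = offsets[(p // len(genes)) % len(offsets)]
        probe_rows.append((f"cg{p:07d}", "chr1", tss + off))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "position"])
    return RegionAnnotation(intervals, tss_table, probes)


def _censoring_horizon(mean_hazard: float, censoring_rate: float) -> float:
    """Accrual horizon tau so that staggered entry with a fixed study end
    (censoring times ~ Uniform(0, tau)) censors about the target fraction
    of exponential(mean_hazard) event times."""

    def censored_frac(tau: float) -> float:
        return (1.0 - np.exp(-mean_hazard * tau)) / (mean_hazard * tau)

    lo, hi = 1e-6, 1e9
    target = min(max(censoring_rate, censored_frac(hi) + 1e-9), 1.0 - 1e-9)
    return brentq(lambda t: censored_frac(t) - target, lo, hi, xtol=1e-6)


def _draw_survival(
    rng: np.random.Generator, hazards: np.ndarray, config: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    shape = config.weibull_shape
    scale = 1.0 / hazards
    if shape == 1.0:
        event_t = rng.exponential(scale)
    else:
        event_t = scale * rng.weibull(shape, size=hazards.size)
    tau = _censoring_horizon(float(hazards.mean()), config.censoring_rate)
    censor_t = rng.uniform(0.0, tau, size=hazards.size)
    os_days = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    os_days = np.maximum(os_days, 1.0)  # avoid zero-day follow-up
    return os_days, event


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial via gamma-Poisson; var = mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam).astype(float)


# precomputed per-channel decomposition of the 96 labels
_CH_REF = np.array([ch[2] for ch in CHANNELS_96])
_CH_ALT = np.array([ch[4] for ch in CHANNELS_96])
_CH_CTX = np.array([ch[0] + ch[2] + ch[6] for ch in CHANNELS_96])
_CH_CTX_RC = np.array([reverse_complement(c) for c in _CH_CTX])
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CH_REF_RC = np.array([_COMP[b] for b in _CH_REF])
_CH_ALT_RC = np.array([_COMP[b] for b in _CH_ALT])


def _draw_mutations(
    rng: np.random.Generator,
    sample_ids: list[str],
    group_idx: np.ndarray,
    gene_pool: np.ndarray,
    signatures: SignatureMatrix,
    config: CohortConfig,
) -> MutationSet:
    sig = signatures.weights.to_numpy()  # 96 x 2
    rows: list[pd.DataFrame] = []
    burdens = np.asarray(config.mutation_burden_means)
    for s_idx, sample in enumerate(sample_ids):
        g = group_idx[s_idx]
        w = config.signature_weights[g]
        mix = w * sig[:, 0] + (1.0 - w) * sig[:, 1]
        mix = mix / mix.sum()
        n_nonsyn = rng.poisson(burdens[g])
        n_other = rng.poisson(burdens[g] * config.other_consequence_rate)
        n_braf = int(rng.random() < config.braf_mut_probs[g])
        n_total = n_nonsyn + n_other + n_braf
        if n_total == 0:
            continue
        ch = rng.choice(96, size=n_total, p=mix)
        flip = rng.random(n_total) < 0.5  # store purine-strand representation
        ref = np.where(flip, _CH_REF_RC[ch], _CH_REF[ch])
        alt = np.where(flip, _CH_ALT_RC[ch], _CH_ALT[ch])
        ctx = np.where(flip, _CH_CTX_RC[ch], _CH_CTX[ch])
        genes = rng.choice(gene_pool, size=n_total)
        consequence = np.array(
            ["nonsynonymous"] * n_nonsyn + ["other"] * n_other + ["nonsynonymous"] * n_braf
        )
        if n_braf:
            genes[-1] = "BRAF"
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "gene": genes,
                    "ref_allele": ref,
                    "alt_allele": alt,
                    "context3": ctx,
                    "consequence": consequence,
                }
            )
        )
    if not rows:
        records = pd.DataFrame(columns=list(MutationSet.REQUIRED))
    else:
        records = pd.concat(rows, ignore_index=True)
    return MutationSet(records)


def generate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Draw one full synthetic cohort from ``config`` (seeded)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"P{i:04d}" for i in range(n)]
    group_idx = rng.choice(3, size=n, p=np.asarray(config.group_proportions))
    groups = pd.Series(
        [GROUPS[g] for g in group_idx], index=sample_ids, name="group"
    )

    # methylation: per-probe baseline mean, group offsets (better lowest).
    # Each probe has its own susceptibility to the group effect (gamma,
    # mean 1), so groups differ in methylation *pattern*, not by a flat
    # offset a correlation-based distance could never see; all
    # susceptibilities are positive, so the better < intermediate <
    # poorer ordering holds probe-wise and region-wise.
    base = rng.uniform(0.15, 0.65, size=config.n_meth_probes)
    susceptibility = rng.gamma(shape=2.0, scale=0.5, size=config.n_meth_probes)
    offsets = np.array([0.0, config.meth_beta_shift, config.meth_beta_shift / 2.0])
    mean = np.clip(
        base[:, None] + susceptibility[:, None] * offsets[group_idx][None, :],
        0.02,
        0.98,
    )
    conc = 60.0
    beta = rng.beta(mean * conc, (1.0 - mean) * conc)
    beta = np.clip(beta, 0.0, 1.0)
    methylation = OmicsMatrix(
        beta,
        [f"cg{p:07d}" for p in range(config.n_meth_probes)],
        sample_ids,
        "methylation_beta",
    )

    # expression: NB counts; immune module up in better, down in poorer
    immune, stromal, background = _gene_ids(config)
    gene_list = immune + stromal + background
    base_mu = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=len(gene_list))
    lfc = config.immune_set_log2fc
    mult = np.ones((len(gene_list), 3))
    n_imm, n_str = len(immune), len(stromal)
    mult[:n_imm, 0] = 2.0 ** lfc
    mult[:n_imm, 1] = 2.0 ** (-lfc / 2.0)
    mult[n_imm : n_imm + n_str, 0] = 2.0 ** (lfc / 2.0)
    mult[n_imm : n_imm + n_str, 1] = 2.0 ** (-lfc / 4.0)
    mu = base_mu[:, None] * mult[:, group_idx]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    mrna_counts = OmicsMatrix(counts, gene_list, sample_ids, "expression_counts")

    # miRNA: pure NB noise (no planted structure)
    mirna_ids = [f"mir{m:04d}" for m in range(config.n_mirnas)]
    mir_mu = rng.lognormal(mean=np.log(30.0), sigma=1.0, size=config.n_mirnas)
    mirna = _nb_draw(rng, np.repeat(mir_mu[:, None], n, axis=1), config.nb_dispersion)
    mirna_counts = OmicsMatrix(mirna, mirna_ids, sample_ids, "expression_counts")

    # survival + clinical covariates
    hazards = config.baseline_hazard * np.asarray(config.hazard_multipliers)[group_idx]
    os_days, event = _draw_survival(rng, hazards, config)
    ages = np.clip(
        rng.normal(np.asarray(config.mean_ages)[group_idx], 12.0), 18.0, 95.0
    )
    sex = rng.choice(["female", "male"], size=n, p=[0.383, 0.617])
    stage = rng.choice(
        ["0", "I", "II", "III", "IV", "unknown"],
        size=n,
        p=[0.016, 0.163, 0.286, 0.367, 0.051, 0.117],
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "os_days": np.round(os_days, 1),
                "event": event,
                "age_years": np.round(ages, 1),
                "sex": sex,
                "stage": stage,
            }
        )
    )

    signatures = default_signatures()
    mutations = _draw_mutations(
        rng,
        sample_ids,
        group_idx,
        np.asarray(background[:-1]),  # BRAF handled separately
        signatures,
        config,
    )

    gene_sets = GeneSetCollection(
        {"IMMUNE": frozenset(immune), "STROMAL": frozenset(stromal)},
        {
            "IMMUNE": "planted immune infiltration module",
            "STROMAL": "planted stromal module",
        },
    )
    regions = _synthetic_regions(config)
    return CohortBundle(
        methylation=methylation,
        mrna_counts=mrna_counts,
        mirna_counts=mirna_counts,
        clinical=clinical,
        mutations=mutations,
        gene_sets=gene_sets,
        signatures=signatures,
        regions=regions,
        groups=groups,
    )


def generate_validation_cohorts(
    config: CohortConfig | None = None, k_cohorts: int = 3
) -> list[ValidationCohort]:
    """Independent expression+survival cohorts with a planted association
    between immune-module expression and survival.

    Each patient carries a latent immune activity ``a ~ N(0, 1)`` that
    shifts the immune module by ``validation_log2fc * a / 2`` log2 units
    and multiplies the hazard by ``exp(-validation_loghr * a)``. Setting
    ``validation_loghr = 0`` severs the association (null cohorts).
    """
    config = config or CohortConfig()
    if k_cohorts < 1:
        raise ValueError("k_cohorts must be >= 1")
    immune, stromal, background = _gene_ids(config)
    gene_list = immune + stromal + background
    n_imm = len(immune)
    cohorts = []
    for c in range(k_cohorts):
        rng = np.random.default_rng(config.seed + 10_000 + c)
        n = config.validation_sizes[c % len(config.validation_sizes)]
        sample_ids = [f"V{c}_{i:03d}" for i in range(n)]
        activity = rng.normal(0.0, 1.0, size=n)
        base = rng.normal(6.0, 1.5, size=len(gene_list))
        values = base[:, None] + rng.normal(0.0, 1.0, size=(len(gene_list), n))
        values[:n_imm, :] += config.validation_log2fc * activity[None, :] / 2.0
        expr = OmicsMatrix(values, gene_list, sample_ids, "expression_log")
        hazards = config.baseline_hazard * np.exp(-config.validation_loghr * activity)
        os_days, event = _draw_survival(rng, hazards, config)
        ages = np.clip(rng.normal(58.0, 12.0, size=n), 18.0, 95.0)
        clinical = ClinicalTable(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "os_days": np.round(os_days, 1),
                    "event": event,
                    "age_years": np.round(ages, 1),
                    "sex": rng.choice(["female", "male"], size=n),
                    "stage": ["III"] * n,
                }
            )
        )
        cohorts.append(ValidationCohort(expr, clinical))
    return cohorts


def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Write the full fixture set in the on-disk formats; returns the
    mapping of logical names to paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "methylation": os.path.join(out_dir, "methylation_beta.tsv"),
        "mrna_counts": os.path.join(out_dir, "mrna_counts.tsv"),
        "mirna_counts": os.path.join(out_dir, "mirna_counts.tsv"),
        "clinical": os.path.join(out_dir, "clinical.tsv"),
        "mutations": os.path.join(out_dir, "mutations.tsv"),
        "gene_sets": os.path.join(out_dir, "gene_sets.gmt"),
        "signatures": os.path.join(out_dir, "signatures.tsv"),
        "regions_bed": os.path.join(out_dir, "regions.bed"),
        "tss": os.path.join(out_dir, "tss.tsv"),
        "probes": os.path.join(out_dir, "probes.tsv"),
        "groups": os.path.join(out_dir, "latent_groups.tsv"),
    }
    write_matrix(bundle.methylation, paths["methylation"])
    write_matrix(bundle.mrna_counts, paths["mrna_counts"])
    write_matrix(bundle.mirna_counts, paths["mirna_counts"])
    write_clinical(bundle.clinical, paths["clinical"])
    write_mutations(bundle.mutations, paths["mutations"])
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    write_signatures(bundle.signatures, paths["signatures"])
    write_regions(bundle.regions, paths["regions_bed"], paths["tss"], paths["probes"])
    bundle.groups.rename_axis("sample_id").to_frame().to_csv(
        paths["groups"], sep="\t"
    )
    return paths
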
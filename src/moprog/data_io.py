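"""Typed containers and readers/writers for every on-disk format the
pipeline touches.

All tabular formats are plain TSV. Genomic coordinates are 0-based
half-open throughout (BED is consumed natively; the TSS table is
documented as 0-based). Sample alignment across omics blocks is by
intersection of sample identifiers, with the number of dropped samples
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "MATRIX_KINDS",
    "CHANNELS_96",
    "OmicsMatrix",
    "ClinicalTable",
    "MutationSet",
    "GeneSetCollection",
    "RegionAnnotation",
    "SignatureMatrix",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_mutations",
    "write_mutations",
    "read_gmt",
    "write_gmt",
    "read_regions",
    "write_regions",
    "read_signatures",
    "write_signatures",
    "read_config",
    "align_samples",
    "get_logger",
]

logger = logging.getLogger("moprog")


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger with plain-text output and a configurable level."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger


class FormatError(ValueError):
    """A file violated the documented dialect or a container invariant."""


MATRIX_KINDS = (
    "methylation_beta",
    "expression_log",
    "expression_counts",
    "mirna_log",
)

#: The 96 canonical single-base-substitution channels, in fixed
#: lexicographic order of (pyrimidine substitution, 5' base, 3' base),
#: labelled like ``A[C>A]A``.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class OmicsMatrix:
    """One omics block: a features x samples numeric matrix.

    ``kind`` controls the invariant checked on the values: beta values in
    [0, 1] for ``methylation_beta``, nonnegative integers for
    ``expression_counts``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.kind not in MATRIX_KINDS:
            raise FormatError(f"unknown matrix kind {self.kind!r}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at feature {self.feature_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if self.kind == "methylation_beta":
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            if bad.size:
                r, c = bad[0]
                raise FormatError(
                    f"beta value {self.values[r, c]} outside [0, 1] at feature "
                    f"{self.feature_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )
        if self.kind == "expression_counts":
            bad = np.argwhere(
                (self.values < 0) | (self.values != np.round(self.values))
            )
            if bad.size:
                r, c = bad[0]
                raise FormatError(
                    f"count {self.values[r, c]} is not a nonnegative integer at "
                    f"feature {self.feature_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str) -> "OmicsMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            list(frame.index),
            list(frame.columns),
            kind,
        )

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return OmicsMatrix(
            self.values[:, cols], self.feature_ids, list(sample_ids), self.kind
        )

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return OmicsMatrix(
            self.values[rows, :], list(feature_ids), self.sample_ids, self.kind
        )


@dataclass
class ClinicalTable:
    """Per-sample overall-survival follow-up and covariates."""

    table: pd.DataFrame  # sample_id, os_days, event, age_years, sex, stage

    REQUIRED = ("sample_id", "os_days", "event", "age_years", "sex", "stage")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        t = self.table
        _check_unique(t["sample_id"], "clinical sample_id")
        if (t["os_days"].astype(float) < 0).any():
            raise FormatError("negative os_days in clinical table")
        if not set(t["event"].astype(int)) <= {0, 1}:
            raise FormatError("event must be 0 (censored) or 1 (death)")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"].astype(str))

    def subset(self, sample_ids) -> "ClinicalTable":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)]
        return ClinicalTable(sub.reset_index())

    def survival_arrays(self, sample_ids=None):
        t = self.table.set_index("sample_id")
        if sample_ids is not None:
            t = t.loc[list(sample_ids)]
        return (
            t["os_days"].to_numpy(dtype=float),
            t["event"].to_numpy(dtype=int),
        )


@dataclass
class MutationSet:
    """Per-patient single-nucleotide variant records.

    ``context3`` is the reference trinucleotide with the mutated base
    central; its middle base must equal ``ref_allele``.
    """

    records: pd.DataFrame  # sample_id, gene, ref_allele, alt_allele,
    #                        context3, consequence

    REQUIRED = (
        "sample_id",
        "gene",
        "ref_allele",
        "alt_allele",
        "context3",
        "consequence",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"mutation table missing columns: {missing}")
        r = self.records
        ctx = r["context3"].astype(str)
        bad_len = ctx[ctx.str.len() != 3]
        if len(bad_len):
            raise FormatError(
                f"context3 must be a 3-mer; offending value {bad_len.iloc[0]!r}"
            )
        if not ctx.str.fullmatch("[ACGT]{3}").all():
            raise FormatError("context3 must be over the alphabet ACGT")
        central = ctx.str[1]
        mism = central != r["ref_allele"].astype(str)
        if mism.any():
            i = int(np.flatnonzero(mism)[0])
            raise FormatError(
                f"context3 central base {central.iloc[i]!r} does not equal "
                f"ref_allele {r['ref_allele'].iloc[i]!r} (record {i})"
            )
        self.records = r.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions (GMT)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(str(g) for g in members)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RegionAnnotation:
    """Genomic intervals by class, gene TSS table and probe positions.

    All coordinates 0-based; intervals are half-open ``[start, end)``.
    """

    intervals: pd.DataFrame  # chrom, start, end, region_class
    tss_table: pd.DataFrame  # gene, chrom, strand, tss_position
    probe_positions: pd.DataFrame  # probe_id, chrom, position

    REGION_CLASSES = ("5'UTR", "exon", "intron", "3'UTR", "enhancer")

    def __post_init__(self) -> None:
        iv = self.intervals
        for col in ("chrom", "start", "end", "region_class"):
            if col not in iv.columns:
                raise FormatError(f"intervals missing column {col!r}")
        if (iv["start"].astype(int) >= iv["end"].astype(int)).any():
            raise FormatError("interval with start >= end")
        if (iv["start"].astype(int) < 0).any():
            raise FormatError("negative interval coordinate")
        unknown = set(iv["region_class"]) - set(self.REGION_CLASSES)
        if unknown:
            raise FormatError(f"unknown region classes: {sorted(unknown)}")
        for col in ("gene", "chrom", "strand", "tss_position"):
            if col not in self.tss_table.columns:
                raise FormatError(f"tss table missing column {col!r}")
        if (self.tss_table["tss_position"].astype(int) < 0).any():
            raise FormatError("negative TSS position")
        for col in ("probe_id", "chrom", "position"):
            if col not in self.probe_positions.columns:
                raise FormatError(f"probe table missing column {col!r}")
        _check_unique(self.probe_positions["probe_id"], "probe_id")


@dataclass
class SignatureMatrix:
    """Reference mutational signatures: 96 channels x S signatures.

    Rows follow :data:`CHANNELS_96` order; each column is a probability
    vector over the channels.
    """

    weights: pd.DataFrame  # index CHANNELS_96, columns signature names

    def __post_init__(self) -> None:
        w = self.weights
        if list(w.index) != list(CHANNELS_96):
            raise FormatError(
                "signature matrix rows must be the 96 canonical channels "
                "in lexicographic (substitution, 5' base, 3' base) order"
            )
        _check_unique(w.columns, "signature names")
        if (w.to_numpy() < 0).any():
            raise FormatError("negative signature entry")
        sums = w.sum(axis=0)
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            raise FormatError(
                f"signature column {off.index[0]!r} sums to {off.iloc[0]:.6f}, "
                "expected 1"
            )

    @property
    def signature_names(self) -> list[str]:
        return list(self.weights.columns)


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(path, kind: str) -> OmicsMatrix:
    """Read a features x samples TSV (header = sample ids, first column =
    feature ids) into a validated :class:`OmicsMatrix`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[int(np.flatnonzero(bad)[0])]
            raise FormatError(
                f"non-numeric cell at feature {row!r}, sample {col!r} in {path}"
            )
        frame[col] = coerced
    if frame.isna().any().any():
        raise FormatError(f"missing values in matrix {path}")
    return OmicsMatrix.from_frame(frame, kind)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str, "stage": str})
    missing = [c for c in ClinicalTable.REQUIRED if c not in t.columns]
    if missing:
        raise FormatError(f"clinical file {path} missing columns: {missing}")
    return ClinicalTable(t)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


#: MAF-like column names accepted on disk, mapped to internal names.
_MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Reference_Allele": "ref_allele",
    "Tumor_Seq_Allele2": "alt_allele",
    "Context3": "context3",
    "Consequence": "consequence",
}


def read_mutations(path) -> MutationSet:
    t = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MAF_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"mutation file {path} missing columns: {missing}")
    return MutationSet(t.rename(columns=_MAF_COLUMNS)[list(_MAF_COLUMNS.values())])


def write_mutations(muts: MutationSet, path) -> None:
    inv = {v: k for k, v in _MAF_COLUMNS.items()}
    muts.records.rename(columns=inv).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset] = {}
    descs: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{line_no}: GMT line needs name, description "
                    "and at least one gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{line_no}: duplicate set name {name!r}")
            if not genes:
                raise FormatError(f"{path}:{line_no}: empty gene set {name!r}")
            sets[name] = frozenset(genes)
            descs[name] = desc
    return GeneSetCollection(sets, descs)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_regions(bed_path, tss_path, probe_path) -> RegionAnnotation:
    """Read interval BED (0-based half-open; name column = region class),
    TSS TSV and probe-position TSV into a :class:`RegionAnnotation`."""
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "region_class"],
        dtype={"chrom": str, "region_class": str},
    )
    tss = pd.read_csv(tss_path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    probes = pd.read_csv(probe_path, sep="\t", dtype={"probe_id": str, "chrom": str})
    return RegionAnnotation(bed, tss, probes)


def write_regions(annotation: RegionAnnotation, bed_path, tss_path, probe_path) -> None:
    annotation.intervals.to_csv(bed_path, sep="\t", index=False, header=False)
    annotation.tss_table.to_csv(tss_path, sep="\t", index=False)
    annotation.probe_positions.to_csv(probe_path, sep="\t", index=False)


def read_signatures(path) -> SignatureMatrix:
    w = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(w)


def write_signatures(signatures: SignatureMatrix, path) -> None:
    signatures.weights.to_csv(path, sep="\t", float_format="%.17g")


def read_config(path) -> dict:
    """Run configuration as a flat YAML key-value file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a mapping")
    return cfg


def align_samples(*blocks: OmicsMatrix, clinical: ClinicalTable | None = None):
    """Restrict omics blocks (and optionally the clinical table) to their
    common samples, preserving the first block's sample order.

    Logs how many samples each input loses, mirroring the cohort-
    intersection step of multi-platform studies.
    """
    common = set(blocks[0].sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if clinical is not None:
        common &= set(clinical.sample_ids)
    order = [s for s in blocks[0].sample_ids if s in common]
    if len(order) < 2:
        raise FormatError("fewer than 2 samples shared across blocks")
    for b in blocks:
        dropped = b.n_samples - len(order)
        if dropped:
            logger.info("align_samples: dropping %d samples from %s block", dropped, b.kind)
    out = [b.subset_samples(order) for b in blocks]
    if clinical is not None:
        dropped = len(clinical.sample_ids) - len(order)
        if dropped:
            logger.info("align_samples: dropping %d samples from clinical table", dropped)
        return out, clinical.subset(order)
    return out


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))
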
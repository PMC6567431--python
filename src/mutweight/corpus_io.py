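"""Reading annotated variant tables and building sample x gene mutation-count matrices.

Variants arrive as gene-annotated rows (one row per called mutation) from
one of three dialects:

``simple_tsv``
    Tab-separated, UTF-8, header columns ``sample_id``, ``gene``,
    ``func_class`` and optionally ``score`` (a per-variant deleteriousness
    score such as a CADD C-score).
``annovar_multianno``
    An ANNOVAR ``*_multianno``-style table with ``Func.refGene`` and
    ``Gene.refGene`` columns (and optionally a score column, by default
    ``CADD_phred``).  One file describes one sample, so the sample id is
    supplied by the caller.
``vcf_info``
    A VCF 4.x file whose INFO field carries gene / functional-class
    annotations under configurable tag names (defaults ``Gene.refGene`` and
    ``Func.refGene``).  Multi-allelic sites yield one record per ALT allele.

Genomic coordinates are never interpreted: aggregation is purely at the
gene level, so 0/1-based and strand conventions are out of play.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "FuncClass",
    "VariantRecord",
    "VariantTable",
    "MutationMatrix",
    "FormatError",
    "read_variant_table",
    "filter_by_location",
    "build_matrix",
    "serialize_matrix",
    "deserialize_matrix",
]

_SERIAL_FORMAT = "mutweight-matrix"
_SERIAL_VERSION = 1


class FuncClass(str, Enum):
    """Functional location of a variant relative to its gene."""

    EXONIC = "exonic"
    INTRONIC = "intronic"
    OTHER = "other"


#: Functional-class labels recognised as exonic / intronic.  Anything else
#: (splicing, UTR, ncRNA_intronic, upstream, ...) maps to OTHER: the
#: weighting models only ever distinguish exonic from intronic mutations.
_FUNC_SYNONYMS: dict[str, FuncClass] = {
    "exonic": FuncClass.EXONIC,
    "intronic": FuncClass.INTRONIC,
    "intron": FuncClass.INTRONIC,
}


def normalize_func_class(raw: str) -> FuncClass:
    """Map a raw annotation string to exonic / intronic / other."""
    return _FUNC_SYNONYMS.get(str(raw).strip().lower(), FuncClass.OTHER)


class FormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


@dataclass(frozen=True)
class VariantRecord:
    """One gene-annotated mutation.

    ``score`` is an optional per-variant deleteriousness score (C-score
    units); when present it must be finite and non-negative.
    """

    sample_id: str
    gene: str
    func_class: FuncClass = FuncClass.OTHER
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.score is not None:
            if not np.isfinite(self.score) or self.score < 0:
                raise ValueError(f"score must be finite and >= 0, got {self.score}")


@dataclass
class VariantTable:
    """A materialised stream of :class:`VariantRecord` plus a skip count.

    Rows whose gene field could not be parsed are dropped, not errored:
    ``n_skipped`` reports how many.
    """

    records: list[VariantRecord]
    n_skipped: int = 0

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _split_genes(raw: str) -> list[str]:
    # ANNOVAR joins multiple overlapping genes with ';' (sometimes ','):
    # the mutation is credited to every annotated gene.
    parts = [g.strip() for g in str(raw).replace(",", ";").split(";")]
    return [g for g in parts if g and g not in (".", "NONE", "nan")]


def _parse_score(raw) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if s in ("", ".", "nan", "NA", "None"):
        return None
    return float(s)


def _read_simple_tsv(path: str) -> VariantTable:
    import pandas as pd

    if os.path.getsize(path) == 0:
        return VariantTable([], 0)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "gene", "func_class"):
        if col not in df.columns:
            raise FormatError(f"simple_tsv is missing mandatory column {col!r}")
    has_score = "score" in df.columns
    records: list[VariantRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        genes = _split_genes(getattr(row, "gene"))
        if not genes:
            skipped += 1
            continue
        func = normalize_func_class(getattr(row, "func_class"))
        score = _parse_score(getattr(row, "score")) if has_score else None
        for g in genes:
            records.append(VariantRecord(str(getattr(row, "sample_id")), g, func, score))
    return VariantTable(records, skipped)


def _read_annovar(path: str, sample_id: str, score_column: str = "CADD_phred") -> VariantTable:
    import pandas as pd

    if sample_id is None:
        raise ValueError("annovar_multianno dialect requires sample_id (one file = one sample)")
    if os.path.getsize(path) == 0:
        return VariantTable([], 0)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Func.refGene", "Gene.refGene"):
        if col not in df.columns:
            raise FormatError(f"annovar_multianno is missing mandatory column {col!r}")
    has_score = score_column in df.columns
    records: list[VariantRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        genes = _split_genes(row["Gene.refGene"])
        if not genes:
            skipped += 1
            continue
        func = normalize_func_class(row["Func.refGene"])
        score = _parse_score(row[score_column]) if has_score else None
        for g in genes:
            records.append(VariantRecord(sample_id, g, func, score))
    return VariantTable(records, skipped)


def _read_vcf(
    path: str,
    sample_id: str | None,
    gene_tag: str = "Gene.refGene",
    func_tag: str = "Func.refGene",
    score_tag: str | None = None,
) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else os.path.basename(path)
    records: list[VariantRecord] = []
    skipped = 0
    for variant in vcf:
        raw_gene = variant.INFO.get(gene_tag)
        if raw_gene is None:
            skipped += 1
            continue
        genes = _split_genes(raw_gene)
        if not genes:
            skipped += 1
            continue
        raw_func = variant.INFO.get(func_tag)
        func = normalize_func_class(raw_func) if raw_func is not None else FuncClass.OTHER
        score = None
        if score_tag is not None:
            raw_score = variant.INFO.get(score_tag)
            if raw_score is not None:
                score = float(raw_score)
        n_alt = max(1, len(variant.ALT))  # one record per ALT allele
        for _ in range(n_alt):
            for g in genes:
                records.append(VariantRecord(sample_id, g, func, score))
    return VariantTable(records, skipped)


def read_variant_table(
    path: str,
    dialect: str = "simple_tsv",
    *,
    sample_id: str | None = None,
    gene_tag: str = "Gene.refGene",
    func_tag: str = "Func.refGene",
    score_tag: str | None = None,
    score_column: str = "CADD_phred",
) -> VariantTable:
    """Read an annotated variant file into a :class:`VariantTable`.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``simple_tsv``, ``annovar_multianno`` or ``vcf_info`` (see module
        docstring for the column / tag contracts).
    sample_id:
        Sample identifier for per-sample files (mandatory for
        ``annovar_multianno``; for ``vcf_info`` defaults to the first VCF
        sample name, else the file name).
    gene_tag, func_tag, score_tag:
        INFO tag names for the ``vcf_info`` dialect.
    score_column:
        Per-variant score column for ``annovar_multianno``.

    Raises
    ------
    FormatError
        If a mandatory column is missing.  An empty file yields an empty
        table, not an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "simple_tsv":
        return _read_simple_tsv(path)
    if dialect == "annovar_multianno":
        return _read_annovar(path, sample_id, score_column)
    if dialect == "vcf_info":
        return _read_vcf(path, sample_id, gene_tag, func_tag, score_tag)
    raise ValueError(
        f"unknown dialect {dialect!r}; expected simple_tsv, annovar_multianno or vcf_info"
    )


def filter_by_location(
    records: Iterable[VariantRecord], mode: str = "all"
) -> list[VariantRecord]:
    """Keep variants by functional location.

    ``mode='exonic'`` / ``'intronic'`` keep only that class; ``mode='all'``
    keeps the union of exonic and intronic.  Variants annotated to any other
    location are always dropped — only exonic and intronic mutations carry a
    usable gene label for the weighting models.
    """
    if mode not in ("exonic", "intronic", "all"):
        raise ValueError(f"unknown location mode {mode!r}; expected exonic, intronic or all")
    if mode == "all":
        keep = (FuncClass.EXONIC, FuncClass.INTRONIC)
    else:
        keep = (FuncClass(mode),)
    return [r for r in records if r.func_class in keep]


@dataclass
class MutationMatrix:
    """Samples x genes mutation counts, with optional per-cell score sums.

    ``counts[s, g]`` is the number of retained variant records for sample
    ``s`` and gene ``g`` — the "term frequency" of the gene in the sample.
    ``score_sums``, when present, holds the per-cell sum of per-variant
    scores and is zero exactly where ``counts`` is zero.
    """

    counts: np.ndarray
    genes: list[str]
    sample_ids: list[str]
    labels: list[str] | None = None
    score_sums: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.genes)):
            raise ValueError("counts shape does not match sample_ids x genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene vocabulary contains duplicates")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length does not match sample_ids")
        if self.score_sums is not None:
            self.score_sums = np.asarray(self.score_sums, dtype=np.float64)
            if self.score_sums.shape != self.counts.shape:
                raise ValueError("score_sums shape does not match counts")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


def build_matrix(
    records: Iterable[VariantRecord],
    vocabulary: Sequence[str] | None = None,
    labels: Mapping[str, str] | None = None,
) -> MutationMatrix:
    """Aggregate variant records into a :class:`MutationMatrix`.

    Without a vocabulary, the gene axis is the sorted set of distinct gene
    symbols observed.  With a vocabulary (e.g. an externally curated causal
    gene list) the columns are exactly that list, in order, and records for
    out-of-vocabulary genes are dropped.  Samples are ordered by sorted id.

    Raises
    ------
    ValueError
        If ``labels`` is supplied but misses samples present in the records,
        or if ``vocabulary`` contains duplicates.
    """
    records = list(records)
    if vocabulary is not None:
        vocabulary = list(vocabulary)
        if len(set(vocabulary)) != len(vocabulary):
            raise ValueError("vocabulary contains duplicate gene symbols")
        vocab_set = set(vocabulary)
        records = [r for r in records if r.gene in vocab_set]
        genes = vocabulary
    else:
        genes = sorted({r.gene for r in records})

    sample_ids = sorted({r.sample_id for r in records})
    if labels is not None:
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise ValueError(f"labels map is missing samples: {missing}")

    g_idx = {g: j for j, g in enumerate(genes)}
    s_idx = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), len(genes)), dtype=np.int64)
    any_score = any(r.score is not None for r in records)
    score_sums = np.zeros_like(counts, dtype=np.float64) if any_score else None
    for r in records:
        i, j = s_idx[r.sample_id], g_idx[r.gene]
        counts[i, j] += 1
        if score_sums is not None and r.score is not None:
            score_sums[i, j] += r.score

    label_list = [labels[s] for s in sample_ids] if labels is not None else None
    return MutationMatrix(counts, genes, sample_ids, label_list, score_sums)


def _dense_to_triplets(a: np.ndarray) -> list[list]:
    ii, jj = np.nonzero(a)
    return [[int(i), int(j), a[i, j].item()] for i, j in zip(ii, jj)]


def serialize_matrix(m: MutationMatrix, path: str) -> None:
    """Write a matrix as a versioned, sparse-triplet JSON container."""
    payload = {
        "format": _SERIAL_FORMAT,
        "version": _SERIAL_VERSION,
        "n_samples": m.n_samples,
        "n_genes": m.n_genes,
        "genes": m.genes,
        "sample_ids": m.sample_ids,
        "labels": m.labels,
        "counts": _dense_to_triplets(m.counts),
        "score_sums": None if m.score_sums is None else _dense_to_triplets(m.score_sums),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def deserialize_matrix(path: str) -> MutationMatrix:
    """Inverse of :func:`serialize_matrix`; round-trips all fields exactly."""
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt or truncated matrix container {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _SERIAL_FORMAT:
        raise FormatError(f"{path!r} is not a mutweight matrix container")
    if payload.get("version") != _SERIAL_VERSION:
        raise FormatError(
            f"matrix container version {payload.get('version')!r} not supported "
            f"(expected {_SERIAL_VERSION})"
        )
    shape = (payload["n_samples"], payload["n_genes"])
    counts = np.zeros(shape, dtype=np.int64)
    for i, j, v in payload["counts"]:
        counts[i, j] = v
    score_sums = None
    if payload["score_sums"] is not None:
        score_sums = np.zeros(shape, dtype=np.float64)
        for i, j, v in payload["score_sums"]:
            score_sums[i, j] = v
    return MutationMatrix(
        counts, payload["genes"], payload["sample_ids"], payload["labels"], score_sums
    )
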
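"""Gene-weighting schemes for mutation-count matrices.

Six representation schemes, all operating on a samples x genes mutation
count matrix (``tf[s, g]`` = number of mutations of gene ``g`` in sample
``s``):

``binary``
    1 if the gene carries at least one mutation in the sample, else 0.
``cscore``
    Sum of per-variant deleteriousness scores (CADD C-scores) for the
    gene's mutations in the sample.
``tf_idf``
    ``tf * idf`` with ``idf_g = log(N / df_g)``, where ``df_g`` is the
    number of samples carrying at least one mutation of gene ``g`` and
    ``N`` the corpus size.  Down-weights commonly mutated genes.
``tf_rf``
    ``tf * rf`` with the supervised relevance frequency
    ``rf_{g,c} = log(2 + a / max(1, b))``: ``a`` = mutated samples of class
    ``c``, ``b`` = mutated samples of the other classes.  Up-weights genes
    whose mutations concentrate in one class.
``bm25_tf_idf`` / ``bm25_tf_rf``
    As above but with the saturating Okapi BM25 term frequency
    ``bm25_tf = (k+1) * tf / (k + tf)``; since every sample is modelled
    over the same gene feature set, the document-length correction drops
    out and only the smoothing parameter ``k`` remains (default 0.8).
    ``bm25_tf`` dampens large mutation counts: a gene with n mutations is
    not n times more important than a gene with one.

The logarithm base is configurable (natural log by default); it rescales
idf/rf monotonically and is pinned only for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import MutationMatrix

__all__ = [
    "SCHEMES",
    "SUPERVISED_SCHEMES",
    "WeightingConfig",
    "FittedWeighter",
    "RepresentationMatrix",
    "idf",
    "rf",
    "bm25_tf",
    "binary_weight",
    "cscore_weight",
    "fit",
    "transform",
    "fit_transform",
]

SCHEMES = ("binary", "cscore", "tf_idf", "tf_rf", "bm25_tf_idf", "bm25_tf_rf")
SUPERVISED_SCHEMES = ("tf_rf", "bm25_tf_rf")
_BM25_SCHEMES = ("bm25_tf_idf", "bm25_tf_rf")
_LOG_BASE = {"e": np.e, "2": 2.0, "10": 10.0, 2: 2.0, 10: 10.0}


def _log(x, base="e"):
    x = np.asarray(x, dtype=np.float64)
    if base in ("e", np.e):
        return np.log(x)
    try:
        b = _LOG_BASE[base]
    except KeyError:
        raise ValueError(f"unsupported log base {base!r}; expected 'e', 2 or 10") from None
    return np.log(x) / np.log(b)


@dataclass(frozen=True)
class WeightingConfig:
    """Configuration of one weighting scheme.

    Parameters
    ----------
    scheme:
        One of :data:`SCHEMES`.
    k:
        BM25 term-frequency smoothing parameter; must be > 0.  Default 0.8
        (the value that tunes best for mutation data).
    log_base:
        Base for the idf / rf logarithms: ``'e'`` (default), 2 or 10.
    rf_test_policy:
        How the supervised rf factor is resolved for samples without a
        class label.  ``'true_label'`` requires labels (transductive use);
        ``'max_over_classes'`` (default) scores each gene by its most
        favourable class, which is safe for unlabeled deployment but is a
        different quantity from the label-resolved weight.
    statistics_source:
        ``'fit_corpus'`` (default): df / rf statistics come from the
        training corpus the weighter was fitted on.  ``'transductive'``:
        the caller fits on the full corpus before splitting.  The flag is
        carried here so pipelines can declare which they did.
    """

    scheme: str = "bm25_tf_rf"
    k: float = 0.8
    log_base: str | int = "e"
    rf_test_policy: str = "max_over_classes"
    statistics_source: str = "fit_corpus"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        if not self.k > 0:
            raise ValueError(f"BM25 smoothing parameter k must be > 0, got {self.k}")
        if self.rf_test_policy not in ("true_label", "max_over_classes"):
            raise ValueError(f"unknown rf_test_policy {self.rf_test_policy!r}")
        if self.statistics_source not in ("fit_corpus", "transductive"):
            raise ValueError(f"unknown statistics_source {self.statistics_source!r}")

    @property
    def supervised(self) -> bool:
        return self.scheme in SUPERVISED_SCHEMES


@dataclass(frozen=True)
class RepresentationMatrix:
    """Samples x genes real-valued features under one scheme."""

    values: np.ndarray
    genes: list[str]
    sample_ids: list[str]
    scheme: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (len(self.sample_ids), len(self.genes)):
            raise ValueError("values shape does not match sample_ids x genes")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.genes)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def idf(df_g: int, n_samples: int, base="e") -> float:
    """Inverse document frequency ``log(N / df)`` of a gene.

    Requires ``1 <= df_g <= N``; a gene never seen mutated (df = 0) has no
    defined idf and is assigned weight zero by :func:`transform` instead.
    """
    if not 1 <= df_g <= n_samples:
        raise ValueError(f"df must satisfy 1 <= df <= N, got df={df_g}, N={n_samples}")
    return float(_log(n_samples / df_g, base))


def rf(a: int, b: int, base="e") -> float:
    """Relevance frequency ``log(2 + a / max(1, b))`` of a gene for a class.

    ``a`` counts mutated samples inside the class, ``b`` outside it; the
    ``max(1, b)`` guard keeps the ratio finite when no other class carries
    the mutation.  Always at least ``log 2``.
    """
    if a < 0 or b < 0:
        raise ValueError("a and b must be non-negative sample counts")
    return float(_log(2.0 + a / max(1, b), base))


def bm25_tf(tf, k: float = 0.8):
    """Saturating BM25 term frequency ``(k+1) * tf / (k + tf)``.

    Equals 0 at tf = 0, 1 at tf = 1 for every k, and approaches k + 1 as
    the mutation count grows, damping the influence of heavily mutated
    genes.  Accepts scalars or arrays.
    """
    if not k > 0:
        raise ValueError(f"BM25 smoothing parameter k must be > 0, got {k}")
    tf = np.asarray(tf, dtype=np.float64)
    out = (k + 1.0) * tf / (k + tf)
    return float(out) if out.ndim == 0 else out


def binary_weight(m: MutationMatrix) -> RepresentationMatrix:
    """Presence/absence representation: 1 wherever the count is >= 1."""
    return RepresentationMatrix(
        (m.counts > 0).astype(np.float64), list(m.genes), list(m.sample_ids), "binary"
    )


def cscore_weight(m: MutationMatrix) -> RepresentationMatrix:
    """Per-gene sums of per-variant deleteriousness scores."""
    if m.score_sums is None:
        raise ValueError(
            "the cscore scheme needs per-variant scores: supply a 'score' column "
            "(or score tag) in the variant table"
        )
    return RepresentationMatrix(
        m.score_sums.copy(), list(m.genes), list(m.sample_ids), "cscore"
    )


@dataclass(frozen=True)
class FittedWeighter:
    """A scheme plus all corpus statistics learned at fit time.

    ``df`` is per-gene document frequency over the fit corpus of size
    ``N``; ``rf_table`` (genes x classes) holds the relevance frequencies
    and is present exactly for supervised schemes.
    """

    config: WeightingConfig
    genes: list[str]
    n_samples: int
    df: np.ndarray
    rf_table: np.ndarray | None = None
    classes: list[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", np.asarray(self.df, dtype=np.int64))
        if np.any(self.df < 0) or np.any(self.df > self.n_samples):
            raise ValueError("df must satisfy 0 <= df <= N")
        if self.config.supervised and self.rf_table is None:
            raise ValueError("supervised scheme requires an rf_table")


def fit(m: MutationMatrix, config: WeightingConfig) -> FittedWeighter:
    """Learn corpus statistics (N, df, and rf per class if supervised).

    Supervised schemes (tf_rf, bm25_tf_rf) require ``m.labels``.
    """
    presence = m.counts > 0
    df = presence.sum(axis=0).astype(np.int64)
    rf_table = None
    classes = None
    if config.supervised:
        if m.labels is None:
            raise ValueError(
                f"scheme {config.scheme!r} is supervised and requires sample labels at fit time"
            )
        classes = sorted(set(m.labels))
        y = np.asarray(m.labels)
        rf_table = np.empty((m.n_genes, len(classes)), dtype=np.float64)
        for ci, c in enumerate(classes):
            in_c = y == c
            a = presence[in_c].sum(axis=0)  # mutated samples inside class c
            b = df - a  # mutated samples outside class c
            rf_table[:, ci] = _log(2.0 + a / np.maximum(1, b), config.log_base)
    return FittedWeighter(config, list(m.genes), m.n_samples, df, rf_table, classes)


def _tf_part(counts: np.ndarray, config: WeightingConfig) -> np.ndarray:
    tf = counts.astype(np.float64)
    if config.scheme in _BM25_SCHEMES:
        return bm25_tf(tf, config.k)
    return tf


def _resolve_rf_rows(
    w: FittedWeighter, labels: Sequence[str] | None, n_samples: int
) -> np.ndarray:
    """Per-sample rf vector (n_samples x n_genes) under the test policy."""
    assert w.rf_table is not None and w.classes is not None
    if labels is not None:
        class_idx = {c: i for i, c in enumerate(w.classes)}
        unknown = sorted(set(labels) - set(w.classes))
        if unknown:
            raise ValueError(f"labels contain classes unseen at fit time: {unknown}")
        rows = np.array([class_idx[c] for c in labels])
        return w.rf_table.T[rows]
    if w.config.rf_test_policy == "true_label":
        raise ValueError(
            "rf_test_policy='true_label' requires labels for the samples being transformed"
        )
    # max_over_classes: each gene scored by its most favourable class
    best = w.rf_table.max(axis=1)
    return np.broadcast_to(best, (n_samples, best.size))


def transform(
    w: FittedWeighter,
    m: MutationMatrix,
    labels: Sequence[str] | None = None,
) -> RepresentationMatrix:
    """Apply a fitted scheme to a mutation matrix.

    The matrix vocabulary must equal the fit vocabulary.  For supervised
    schemes the rf factor is resolved with, in order: the ``labels``
    argument, ``m.labels``, or the configured ``rf_test_policy``.  Genes
    with df = 0 in the fit corpus receive weight 0 under the idf/rf
    schemes (a never-mutated gene carries no corpus signal).
    """
    if list(m.genes) != list(w.genes):
        extra = sorted(set(m.genes) ^ set(w.genes))
        raise ValueError(
            f"vocabulary mismatch between matrix and fitted weighter; "
            f"symmetric difference: {extra[:20]}{'...' if len(extra) > 20 else ''}"
        )
    scheme = w.config.scheme
    if scheme == "binary":
        return binary_weight(m)
    if scheme == "cscore":
        return cscore_weight(m)

    tf_part = _tf_part(m.counts, w.config)
    seen = w.df > 0
    if scheme in ("tf_idf", "bm25_tf_idf"):
        idf_vec = np.zeros(len(w.genes))
        idf_vec[seen] = _log(w.n_samples / w.df[seen], w.config.log_base)
        values = tf_part * idf_vec
    else:  # tf_rf / bm25_tf_rf
        if labels is None:
            labels = m.labels
        rf_rows = _resolve_rf_rows(w, labels, m.n_samples)
        values = tf_part * rf_rows
        values[:, ~seen] = 0.0
    return RepresentationMatrix(values, list(m.genes), list(m.sample_ids), scheme)


def fit_transform(
    m: MutationMatrix, config: WeightingConfig
) -> tuple[FittedWeighter, RepresentationMatrix]:
    """Fit on ``m`` and transform it (the transductive path)."""
    w = fit(m, config)
    return w, transform(w, m)
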
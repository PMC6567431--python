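"""Synthetic labeled mutation cohorts with planted class-specific genes.

The generator emulates the statistical structure the weighting schemes
assume: a multi-class cohort in which each class has a small disjoint set
of "planted" genes mutated at an elevated rate, against a uniform
background mutation rate.  Per-cell mutation counts are drawn Poisson, so
multiplicity >= 2 occurs naturally and the term-frequency schemes are
exercised beyond presence/absence.  Each individual mutation event gets a
functional-class draw (exonic with probability ``exonic_fraction``,
default 0.15 — the minority share typical of whole-genome variant sets —
else intronic) and a per-variant deleteriousness score drawn from a
right-skewed gamma distribution on a CADD-like scale.

Everything is a deterministic function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import FuncClass, VariantRecord

__all__ = ["CohortSpec", "Cohort", "generate", "make_fixture", "expected_distinct_genes"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``samples_per_class`` may be a single int (balanced) or one count per
    class (imbalanced).  ``background_rate`` is the expected mutation
    count per gene per sample (Poisson mean); planted genes of a class
    mutate at ``background_rate * planted_rate_multiplier`` in samples of
    that class.  ``planted_score_shift`` is added to the scores of
    variants in planted genes, to optionally give the C-score model its
    own signal.
    """

    n_classes: int = 2
    samples_per_class: int | Sequence[int] = 100
    n_genes: int = 200
    background_rate: float = 0.5
    planted_genes_per_class: int = 5
    planted_rate_multiplier: float = 5.0
    exonic_fraction: float = 0.15
    score_shape: float = 2.0
    score_scale: float = 5.0
    planted_score_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.planted_rate_multiplier < 1:
            raise ValueError("planted_rate_multiplier must be >= 1")
        if not 0 <= self.exonic_fraction <= 1:
            raise ValueError("exonic_fraction must be in [0, 1]")
        if self.planted_genes_per_class * self.n_classes > self.n_genes:
            raise ValueError(
                f"{self.planted_genes_per_class} planted genes x {self.n_classes} classes "
                f"exceed the {self.n_genes}-gene vocabulary"
            )

    def class_sizes(self) -> list[int]:
        if isinstance(self.samples_per_class, int):
            return [self.samples_per_class] * self.n_classes
        sizes = list(self.samples_per_class)
        if len(sizes) != self.n_classes:
            raise ValueError("samples_per_class must give one count per class")
        return sizes


@dataclass
class Cohort:
    """A generated cohort: variant records, labels, and the planted truth."""

    records: list[VariantRecord]
    labels: dict[str, str]
    planted: dict[str, str]  # gene -> class it was planted for
    genes: list[str]
    classes: list[str]

    def planted_for(self, class_name: str) -> list[str]:
        return sorted(g for g, c in self.planted.items() if c == class_name)

    def write_variants_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tgene\tfunc_class\tscore\n")
            for r in self.records:
                score = "" if r.score is None else f"{r.score:.6g}"
                fh.write(f"{r.sample_id}\t{r.gene}\t{r.func_class.value}\t{score}\n")

    def write_labels_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tlabel\n")
            for s in sorted(self.labels):
                fh.write(f"{s}\t{self.labels[s]}\n")

    def write_truth_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene\tclass\n")
            for g in sorted(self.planted):
                fh.write(f"{g}\t{self.planted[g]}\n")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw one cohort; ``seed`` overrides ``spec.seed`` when given."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sizes = spec.class_sizes()
    classes = [f"class{c}" for c in range(spec.n_classes)]
    genes = _gene_names(spec.n_genes)

    planted: dict[str, str] = {}
    for ci, c in enumerate(classes):
        start = ci * spec.planted_genes_per_class
        for g in genes[start : start + spec.planted_genes_per_class]:
            planted[g] = c

    records: list[VariantRecord] = []
    labels: dict[str, str] = {}
    for ci, c in enumerate(classes):
        rates = np.full(spec.n_genes, spec.background_rate)
        start = ci * spec.planted_genes_per_class
        rates[start : start + spec.planted_genes_per_class] *= spec.planted_rate_multiplier
        counts = rng.poisson(rates, size=(sizes[ci], spec.n_genes))
        for si in range(sizes[ci]):
            sample = f"{c}_s{si:04d}"
            labels[sample] = c
            mutated = np.nonzero(counts[si])[0]
            for gi in mutated:
                n_events = counts[si, gi]
                exonic = rng.random(n_events) < spec.exonic_fraction
                scores = rng.gamma(spec.score_shape, spec.score_scale, size=n_events)
                if genes[gi] in planted:
                    scores = scores + spec.planted_score_shift
                for ev in range(n_events):
                    records.append(
                        VariantRecord(
                            sample,
                            genes[gi],
                            FuncClass.EXONIC if exonic[ev] else FuncClass.INTRONIC,
                            float(scores[ev]),
                        )
                    )
    return Cohort(records, labels, planted, genes, classes)


def expected_distinct_genes(spec: CohortSpec, class_name: str | None = None) -> float:
    """Analytic expected number of distinct mutated genes per sample.

    Under Poisson counts a gene is mutated with probability
    ``1 - exp(-rate)``; the expectation is the sum over genes.  If
    ``class_name`` is given, planted-gene rates for that class are boosted.
    """
    base = spec.background_rate
    boosted = base * spec.planted_rate_multiplier
    n_planted_own = spec.planted_genes_per_class if class_name is not None else 0
    n_rest = spec.n_genes - n_planted_own
    return n_planted_own * (1 - np.exp(-boosted)) + n_rest * (1 - np.exp(-base))


# --- bundled deterministic fixtures ----------------------------------------

#: Hand-written 4-sample x 5-gene count table backing the "tiny" fixture
#: (used as the ground truth for exact weighting oracles in the test suite).
TINY_COUNTS: dict[tuple[str, str], tuple[int, float]] = {
    # (sample, gene) -> (count, per-variant score; every event shares it)
    ("s1", "BRCA1"): (1, 12.5),
    ("s1", "KRAS"): (2, 5.0),
    ("s1", "TP53"): (1, 30.0),
    ("s2", "APC"): (1, 8.0),
    ("s2", "KRAS"): (1, 4.0),
    ("s3", "EGFR"): (3, 10.0),
    ("s3", "TP53"): (1, 22.0),
    ("s4", "APC"): (2, 6.5),
    ("s4", "EGFR"): (1, 15.0),
}

TINY_GENES = ["APC", "BRCA1", "EGFR", "KRAS", "TP53"]
TINY_LABELS = {"s1": "classA", "s2": "classA", "s3": "classB", "s4": "classB"}


def _tiny_cohort() -> Cohort:
    records = []
    alternating = [FuncClass.EXONIC, FuncClass.INTRONIC]
    for i, ((sample, gene), (count, score)) in enumerate(sorted(TINY_COUNTS.items())):
        for ev in range(count):
            records.append(VariantRecord(sample, gene, alternating[(i + ev) % 2], score))
    return Cohort(records, dict(TINY_LABELS), {}, list(TINY_GENES), ["classA", "classB"])


_FIXTURE_SPECS = {
    "separable": CohortSpec(
        n_classes=2,
        samples_per_class=100,
        n_genes=200,
        background_rate=0.5,
        planted_genes_per_class=5,
        planted_rate_multiplier=5.0,
        seed=20190613,
    ),
    # ten classes with sample counts shaped like a frequency-ranked cancer
    # cohort, scaled to ~700 samples
    "imbalanced10": CohortSpec(
        n_classes=10,
        samples_per_class=(123, 108, 103, 73, 66, 50, 50, 47, 44, 38),
        n_genes=300,
        background_rate=0.5,
        planted_genes_per_class=5,
        planted_rate_multiplier=5.0,
        seed=20190613,
    ),
}


def make_fixture(name: str) -> Cohort:
    """Named deterministic fixtures: ``tiny``, ``separable``, ``imbalanced10``."""
    if name == "tiny":
        return _tiny_cohort()
    try:
        spec = _FIXTURE_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; expected tiny, separable or imbalanced10"
        ) from None
    return generate(spec)
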
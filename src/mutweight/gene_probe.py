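"""One-hot probing of trained classifiers for class-effective genes.

A probe feeds the classifier a vector that sets a single gene feature to
1.0 and every other feature to 0.  Because all other inputs cancel, the
softmax output reads off how strongly that one gene pushes the model
toward each class.  Probing every gene against the fold-trained models
and averaging over folds yields a genes x classes heat map; sorting a
class column descending gives the genes most effective for predicting
that class.

The probe value is exactly 1.0 on the representation scale regardless of
the weighting scheme (real features can exceed 1 under e.g. bm25_tf_rf;
the probe deliberately uses the unit vector so maps are comparable across
schemes).  Models are probed in inference mode — dropout off — so two
probe runs of the same models give identical maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["HeatMap", "probe", "top_genes"]


@dataclass(frozen=True)
class HeatMap:
    """Genes x classes mean probe probabilities, averaged over folds."""

    values: np.ndarray
    genes: list[str]
    classes: list[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (len(self.genes), len(self.classes)):
            raise ValueError("heat map shape does not match genes x classes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.classes)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")


def probe(models: Sequence, genes: Sequence[str], batch_size: int = 1024) -> HeatMap:
    """Build the heat map from fold-trained probabilistic classifiers.

    Every model must expose ``predict_proba`` and ``classes_`` over the
    same classes; cell [g, c] is the mean over models of the predicted
    probability of class c for the one-hot input of gene g.
    """
    if not models:
        raise ValueError("need at least one trained model to probe")
    for m in models:
        if not hasattr(m, "predict_proba"):
            raise ValueError(
                f"{type(m).__name__} exposes no class-probability output and cannot be probed"
            )
    classes = list(np.asarray(models[0].classes_))
    for m in models[1:]:
        if list(np.asarray(m.classes_)) != classes:
            raise ValueError("models disagree on the class set")

    genes = list(genes)
    n_genes = len(genes)
    total = np.zeros((n_genes, len(classes)))
    for start in range(0, n_genes, batch_size):
        stop = min(start + batch_size, n_genes)
        block = np.zeros((stop - start, n_genes))
        block[np.arange(stop - start), np.arange(start, stop)] = 1.0
        for m in models:
            total[start:stop] += np.asarray(m.predict_proba(block))
    values = total / len(models)
    return HeatMap(values, genes, [str(c) for c in classes])


def top_genes(h: HeatMap, class_name: str, k: int = 20) -> list[str]:
    """The k genes with the highest probe probability for one class.

    Sorted descending by the class column; ties broken lexicographically
    by gene symbol.  A k beyond the vocabulary returns the full ordering
    with a warning.
    """
    if class_name not in h.classes:
        raise ValueError(f"unknown class {class_name!r}; heat map classes: {h.classes}")
    if k > len(h.genes):
        warnings.warn(
            f"k={k} exceeds the vocabulary size {len(h.genes)}; returning all genes",
            stacklevel=2,
        )
        k = len(h.genes)
    col = h.values[:, h.classes.index(class_name)]
    order = sorted(range(len(h.genes)), key=lambda i: (-col[i], h.genes[i]))
    return [h.genes[i] for i in order[:k]]
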
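"""Independent brute-force oracles used by the tests.

These deliberately mirror the weighting definitions one cell at a time
with plain Python loops and ``math`` — no numpy vectorisation and no
imports from the implementation — so they can arbitrate its output.
"""

import math


def brute_force_weights(counts, scheme, labels=None, k=0.8, base=math.e, score_sums=None):
    """Per-cell literal evaluation of one weighting scheme.

    ``counts`` is a list of rows (samples) of ints; ``labels`` a list of
    class names (needed for the rf schemes).  Genes never seen mutated get
    weight 0 under the idf/rf schemes.
    """
    n = len(counts)
    n_genes = len(counts[0]) if n else 0
    df = [sum(1 for s in range(n) if counts[s][g] > 0) for g in range(n_genes)]

    def idf(g):
        return math.log(n / df[g], base) if df[g] > 0 else None

    def rf(g, c):
        a = sum(1 for s in range(n) if labels[s] == c and counts[s][g] > 0)
        b = df[g] - a
        return math.log(2 + a / max(1, b), base)

    out = [[0.0] * n_genes for _ in range(n)]
    for s in range(n):
        for g in range(n_genes):
            tf = counts[s][g]
            if scheme == "binary":
                out[s][g] = 1.0 if tf > 0 else 0.0
                continue
            if scheme == "cscore":
                out[s][g] = float(score_sums[s][g])
                continue
            if df[g] == 0:
                out[s][g] = 0.0
                continue
            tf_part = float(tf) if scheme in ("tf_idf", "tf_rf") else (k + 1) * tf / (k + tf)
            if scheme in ("tf_idf", "bm25_tf_idf"):
                out[s][g] = tf_part * idf(g)
            else:
                out[s][g] = tf_part * rf(g, labels[s])
    return out


def confusion_metrics(y_true, y_pred, classes):
    """Hand confusion-matrix metrics: per-class precision/recall/F1/FPR
    plus pooled (micro) precision/recall and accuracy."""
    per_class = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t != c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        per_class[c] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                        "precision": prec, "recall": rec, "f_score": f1, "fpr": fpr}
    tp_all = sum(v["tp"] for v in per_class.values())
    fp_all = sum(v["fp"] for v in per_class.values())
    fn_all = sum(v["fn"] for v in per_class.values())
    micro_p = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    micro_r = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    accuracy = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    return {"per_class": per_class, "micro_precision": micro_p,
            "micro_recall": micro_r, "accuracy": accuracy}
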
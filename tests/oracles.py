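"""Independent brute-force oracles used to pin expected metric values.

Everything here is written directly from the defining formulas —
contingency-table AMI with the exact hypergeometric expected mutual
information, and extended B-cubed by full enumeration of item pairs — and
deliberately shares no code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import lgamma, log

import numpy as np


def ami_direct(truth: list, pred: list) -> float:
    """AMI from its definition: (MI - E[MI]) / (max(Ht, Hp) - E[MI]).

    MI and entropies in nats from the contingency table; E[MI] under the
    permutation (hypergeometric) model, summed exactly.
    """
    n = len(truth)
    t_counts = Counter(truth)
    p_counts = Counter(pred)
    joint = Counter(zip(truth, pred))

    mi = 0.0
    for (t, p), nij in joint.items():
        mi += (nij / n) * log(n * nij / (t_counts[t] * p_counts[p]))

    def entropy(counts: Counter) -> float:
        return -sum((c / n) * log(c / n) for c in counts.values())

    h_t, h_p = entropy(t_counts), entropy(p_counts)

    emi = 0.0
    for a in t_counts.values():
        for b in p_counts.values():
            lo = max(1, a + b - n)
            hi = min(a, b)
            for nij in range(lo, hi + 1):
                term = (nij / n) * log(n * nij / (a * b))
                lp = (
                    lgamma(a + 1)
                    + lgamma(b + 1)
                    + lgamma(n - a + 1)
                    + lgamma(n - b + 1)
                    - lgamma(n + 1)
                    - lgamma(nij + 1)
                    - lgamma(a - nij + 1)
                    - lgamma(b - nij + 1)
                    - lgamma(n - a - b + nij + 1)
                )
                emi += term * np.exp(lp)

    denom = max(h_t, h_p) - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom


def b3_enumerate(
    truth_labels: dict[str, frozenset],
    pred_labels: dict[str, frozenset],
    weight: dict[str, float],
    recall_items: list[str] | None = None,
) -> tuple[float, float, float]:
    """Extended B-cubed by explicit enumeration of all ordered item pairs.

    Pair precision = min(|C∩C'|, |T∩T'|)/|C∩C'| over pairs sharing a
    predicted cluster (self pair included); recall swaps C and T.  Item
    and pair contributions are weighted.
    """
    pred_items = [e for e in pred_labels if pred_labels[e]]
    prec_num = prec_den = 0.0
    for e in pred_items:
        num = den = 0.0
        for o in pred_items:
            c_olap = len(pred_labels[e] & pred_labels[o])
            if c_olap == 0:
                continue
            t_olap = len(truth_labels[e] & truth_labels[o])
            den += weight[o]
            num += weight[o] * min(c_olap, t_olap) / c_olap
        prec_num += weight[e] * num / den
        prec_den += weight[e]

    items_r = recall_items if recall_items is not None else pred_items
    rec_num = rec_den = 0.0
    for e in items_r:
        num = den = 0.0
        for o in items_r:
            t_olap = len(truth_labels[e] & truth_labels[o])
            if t_olap == 0:
                continue
            c_olap = len(pred_labels.get(e, frozenset()) & pred_labels.get(o, frozenset()))
            den += weight[o]
            num += weight[o] * min(c_olap, t_olap) / t_olap
        rec_num += weight[e] * num / den
        rec_den += weight[e]

    p = prec_num / prec_den if prec_den else 0.0
    r = rec_num / rec_den if rec_den else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def all_partitions(items: list):
    """Every set partition of ``items`` as a list of blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def random_soft_instance(rng: np.random.Generator, n: int, n_truth: int, n_bins: int):
    """A random weighted soft-truth / hard-prediction pair for metric checks."""
    items = [f"i{k}" for k in range(n)]
    truth = {}
    for it in items:
        k = 1 + (rng.random() < 0.3)
        truth[it] = frozenset(rng.choice(n_truth, size=min(k, n_truth), replace=False).tolist())
    pred = {it: frozenset([int(rng.integers(n_bins))]) for it in items}
    weight = {it: float(rng.integers(1, 10_000)) for it in items}
    return items, truth, pred, weight
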
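"""Clustering-quality metrics against curated taxon labels.

Three scores compare a computed partition with ground-truth classes,
each in [0, 1] with 1 meaning perfect agreement:

* rand index  R = (a + b) / (a + b + c + d), counting element pairs
  that are co-clustered in both assignments (a), separated in both
  (b), or split between them (c, d);
* homogeneity  h = 1 - H(C|K) / H(C): every cluster contains members
  of a single class when h = 1;
* completeness c = 1 - H(K|C) / H(K): members of a class end up in a
  single cluster when c = 1.

Entropies use the natural logarithm (the scores are base-invariant)
with the conventions 0*log 0 = 0 and h = 1 (resp. c = 1) when the
class (resp. cluster) entropy is zero.  Completeness is the exact dual
of homogeneity with the two label lists swapped.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Hashable, Sequence, Tuple


@dataclass(frozen=True)
class ContingencyCounts:
    """Pair counts and joint class-by-cluster counts for two labelings."""

    n: int
    n_c: Dict[Hashable, int]
    n_k: Dict[Hashable, int]
    n_ck: Dict[Tuple[Hashable, Hashable], int]
    a: int  # same class, same cluster
    b: int  # different class, different cluster
    c: int  # same class, different cluster
    d: int  # different class, same cluster


def _check(true_labels: Sequence, pred_labels: Sequence) -> None:
    if len(true_labels) != len(pred_labels):
        raise ValueError(
            f"label lists differ in length: {len(true_labels)} vs {len(pred_labels)}"
        )
    if len(true_labels) == 0:
        raise ValueError("empty label lists")


def contingency(true_labels: Sequence, pred_labels: Sequence) -> ContingencyCounts:
    """Joint counts and the four pair counts a, b, c, d.

    Pair counts come from the contingency table:
    a = sum C(n_ck, 2); a + c = sum C(n_c, 2); a + d = sum C(n_k, 2);
    the remainder of the C(n, 2) pairs is b.
    """
    _check(true_labels, pred_labels)
    n = len(true_labels)
    n_c = Counter(true_labels)
    n_k = Counter(pred_labels)
    n_ck = Counter(zip(true_labels, pred_labels))
    comb2 = lambda m: m * (m - 1) // 2
    a = sum(comb2(v) for v in n_ck.values())
    c = sum(comb2(v) for v in n_c.values()) - a
    d = sum(comb2(v) for v in n_k.values()) - a
    b = comb2(n) - a - c - d
    return ContingencyCounts(n=n, n_c=dict(n_c), n_k=dict(n_k),
                             n_ck=dict(n_ck), a=a, b=b, c=c, d=d)


def rand_index(true_labels: Sequence, pred_labels: Sequence) -> float:
    """R = (a + b) / (a + b + c + d); requires at least two samples."""
    counts = contingency(true_labels, pred_labels)
    total = counts.a + counts.b + counts.c + counts.d
    if total == 0:
        raise ValueError("rand index needs at least 2 samples")
    return (counts.a + counts.b) / total


def _entropy(counts: Dict[Hashable, int], n: int) -> float:
    return -sum(v / n * math.log(v / n) for v in counts.values() if v > 0)


def _conditional_entropy(
    joint: Dict[Tuple[Hashable, Hashable], int],
    cond: Dict[Hashable, int],
    n: int,
) -> float:
    # H(C|K) = -sum_{c,k} n_ck/n * log(n_ck / n_k)
    return -sum(
        v / n * math.log(v / cond[k])
        for (_, k), v in joint.items()
        if v > 0
    )


def homogeneity(true_labels: Sequence, pred_labels: Sequence) -> float:
    """h = 1 - H(C|K)/H(C), with h = 1 when H(C) = 0."""
    counts = contingency(true_labels, pred_labels)
    h_c = _entropy(counts.n_c, counts.n)
    if h_c == 0.0:
        return 1.0
    h_ck = _conditional_entropy(counts.n_ck, counts.n_k, counts.n)
    return 1.0 - h_ck / h_c


def completeness(true_labels: Sequence, pred_labels: Sequence) -> float:
    """c = 1 - H(K|C)/H(K): homogeneity with the label roles swapped."""
    return homogeneity(pred_labels, true_labels)


@dataclass(frozen=True)
class MetricReport:
    rand_index: float
    homogeneity: float
    completeness: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "rand_index": self.rand_index,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
        }


def score_partition(true_labels: Sequence, pred_labels: Sequence) -> MetricReport:
    """All three metrics for one (truth, prediction) pair."""
    return MetricReport(
        rand_index=rand_index(true_labels, pred_labels),
        homogeneity=homogeneity(true_labels, pred_labels),
        completeness=completeness(true_labels, pred_labels),
    )
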
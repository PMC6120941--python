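"""Sequence-complexity metrics of modal reads, aggregated by cluster size.

Reads prone to mapping shifts tend to contain homopolymer runs and short
tandem repeats — the substrates of repeat-stabilised PCR stutter.  Two
information-theoretic statistics capture this:

Shannon entropy (bits) over the base composition of one read,

    H = -sum_x p(x) log2 p(x),   x in {G, A, T, C},

where p(x) is the fraction of the read consisting of base x.  Homopolymers
score 0, perfect dinucleotide repeats 1, uniform composition 2.

Mutual information (bits) between the odd- and even-numbered positions of a
read: the read is made even-length by dropping its first base, cut into
consecutive non-overlapping 2-mers (x, y), and

    I = sum_{x,y} p(x,y) log2( p(x,y) / (p(x) p(y)) ),

with p(x,y) the fraction of 2-mers and the marginals p(.) taken as base
fractions of the whole evened read.  With whole-string marginals a perfect
dinucleotide repeat scores 2.0 — each base fully predicts its successor —
while a homopolymer scores 0.  (Per-position marginals would send the
dinucleotide-repeat value to 0 instead; the whole-string definition is the
one whose reference values these are.)

Both metrics are computed for the single most frequent read at each
cluster's modal coordinate, and the association with cluster size is tested
by one-way fixed-effects ANOVA with cluster size as the factor.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy import stats as scipy_stats

from .umicluster import UmiReadCluster

_BASES = "GATC"


@dataclass(frozen=True)
class ComplexityRecord:
    sequence: str
    H: Optional[float]  # Shannon entropy, bits; None if undefined
    I: Optional[float]  # mutual information, bits; None if undefined
    cluster_size: int


def _acgt_only(sequence: str) -> str:
    # N carries no base identity; excluded from fractions
    return "".join(b for b in sequence.upper() if b in "ACGT")


def shannon_entropy(sequence: str) -> Optional[float]:
    """Base-composition entropy in bits; None for empty/all-N input."""
    seq = _acgt_only(sequence)
    if not seq:
        return None
    n = len(seq)
    h = 0.0
    for count in Counter(seq).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def mutual_information(sequence: str) -> Optional[float]:
    """Mutual information between odd and even positions, in bits.

    Odd-length input is evened by dropping the first base; marginals are
    whole-string base fractions; unobserved pairs contribute 0.  None if
    fewer than 2 informative bases remain.
    """
    seq = _acgt_only(sequence)
    if len(seq) % 2 == 1:
        seq = seq[1:]
    if len(seq) < 2:
        return None
    pairs = Counter(seq[i : i + 2] for i in range(0, len(seq), 2))
    n_pairs = sum(pairs.values())
    marg = Counter(seq)
    n = len(seq)
    info = 0.0
    for pair, count in pairs.items():
        pxy = count / n_pairs
        px = marg[pair[0]] / n
        py = marg[pair[1]] / n
        info += pxy * math.log2(pxy / (px * py))
    return info


def modal_read_complexity(
    clusters: Iterable[UmiReadCluster],
) -> tuple[list[ComplexityRecord], int]:
    """One (H, I, cluster_size) record per cluster, computed on the read at
    the mode.  Returns (records, number of clusters skipped for lack of a
    stored modal sequence)."""
    records: list[ComplexityRecord] = []
    skipped = 0
    for cluster in clusters:
        seq = cluster.modal_sequence
        if not seq:
            skipped += 1
            continue
        records.append(
            ComplexityRecord(
                sequence=seq,
                H=shannon_entropy(seq),
                I=mutual_information(seq),
                cluster_size=cluster.size,
            )
        )
    return records, skipped


@dataclass
class AnovaResult:
    metric: str
    F: float
    p_value: float
    df_between: int
    df_within: int
    group_sizes: dict[int, int]


def anova_by_cluster_size(
    records: Sequence[ComplexityRecord],
    metric: str = "H",
    min_group_size: int = 2,
) -> Optional[AnovaResult]:
    """One-way fixed-effects ANOVA of a complexity metric across cluster sizes.

    Size groups with fewer than ``min_group_size`` records are dropped
    (within-group variance undefined otherwise).  F = MS_between/MS_within
    from explicit sums of squares, so the degenerate case of zero
    within-group variance with differing means reports F = inf, p = 0
    rather than NaN.  Returns None when fewer than two eligible groups
    remain.
    """
    groups: dict[int, list[float]] = defaultdict(list)
    for rec in records:
        value = getattr(rec, metric)
        if value is not None:
            groups[rec.cluster_size].append(value)
    eligible = {s: v for s, v in groups.items() if len(v) >= min_group_size}
    if len(eligible) < 2:
        return None

    arrays = [np.asarray(v, dtype=float) for v in eligible.values()]
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    ms_between = ss_between / df_between
    if ss_within == 0.0:
        f_stat = math.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = ms_between / (ss_within / df_within)
        p = float(scipy_stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        metric=metric,
        F=float(f_stat),
        p_value=p,
        df_between=df_between,
        df_within=df_within,
        group_sizes={s: len(v) for s, v in sorted(eligible.items())},
    )
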
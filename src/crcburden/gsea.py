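"""Pre-ranked gene-set enrichment over gene-burden P-values.

Genes are ranked by ``-log10`` of their burden P-value and a weighted
Kolmogorov–Smirnov running sum is evaluated for each set: hits increment the
sum by ``score / sum(set scores)`` (weight exponent 1), misses decrement it by
``1 / (N - set size)``.  The enrichment score (ES) is the running-sum value at
the point of maximal absolute deviation.  Significance comes from set-based
permutation: null ES distributions are built from random same-size gene draws,
the normalised score NES divides ES by the mean same-sign null ES, and
Q-values follow the standard NES-based FDR construction.  Because the ranking
metric is a significance score with no sign, only positive (enrichment) ES is
reported for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd

DEFAULT_N_PERM = 10_000
MIN_SET_SIZE = 5
MAX_SET_SIZE = 500
LEADING_EDGE_Q = 0.25


@dataclass
class RankedList:
    """Genes in non-increasing score order with their ranking scores."""
    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def positions(self, members: Sequence[str]) -> np.ndarray:
        """Sorted rank indices of the set members present in the list."""
        pos = [self._index[g] for g in members if g in self._index]
        return np.array(sorted(pos), dtype=np.int64)


@dataclass
class GeneSetResult:
    name: str
    size: int                      # members present in the ranked universe
    es: float
    peak_index: int                # rank index of the running-sum peak
    nes: float = np.nan
    p_nominal: float = np.nan
    q_value: float = np.nan
    leading_edge: list = field(default_factory=list)
    testable: bool = True


def rank_genes(p_values: Mapping[str, float],
               n_perm: int = DEFAULT_N_PERM) -> RankedList:
    """Rank genes by ``-log10 P`` descending; ties break lexicographically.

    P-values of 0 (below permutation resolution) are clamped to
    ``0.5 / n_perm`` before the log.
    """
    genes = list(p_values)
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate genes in ranking input")
    floor = 0.5 / n_perm
    score = {g: -np.log10(max(p_values[g], floor)) for g in genes}
    ordered = sorted(genes, key=lambda g: (-score[g], g))
    return RankedList(np.array(ordered, dtype=object),
                      np.array([score[g] for g in ordered]))


def _es_from_positions(scores: np.ndarray, pos: np.ndarray):
    """ES and peak rank index for hit positions ``pos`` (sorted) in a ranked
    list with the given scores."""
    n = len(scores)
    m = len(pos)
    hit = scores[pos]
    total = hit.sum()
    if total > 0:
        inc = hit / total
    else:                       # all hit scores zero: equal weights
        inc = np.full(m, 1.0 / m)
    miss_dec = 1.0 / (n - m) if n > m else 0.0
    cum_hit = np.cumsum(inc)
    j = np.arange(m)
    # running sum immediately after each hit, and just before each hit
    at_hit = cum_hit - (pos - j) * miss_dec
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - (pos - j) * miss_dec
    i_max = int(np.argmax(at_hit))
    i_min = int(np.argmin(before_hit))
    if at_hit[i_max] >= -before_hit[i_min]:
        return float(at_hit[i_max]), int(pos[i_max])
    # negative deviation peaks just before the hit at i_min
    peak = int(pos[i_min]) - 1
    return float(before_hit[i_min]), max(peak, 0)


def enrichment_score(ranked: RankedList, gene_set: Sequence[str]):
    """Weighted running-sum enrichment score of one gene set.

    Returns ``(es, peak_index)``; raises on an empty intersection with the
    ranked universe.
    """
    pos = ranked.positions(gene_set)
    if pos.size == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if pos.size == len(ranked.genes):
        # degenerate: every gene is a hit; ES is max prefix of normalised scores
        inc = ranked.scores / ranked.scores.sum() if ranked.scores.sum() > 0 \
            else np.full(len(ranked.genes), 1.0 / len(ranked.genes))
        cum = np.cumsum(inc)
        return float(cum.max()), int(np.argmax(cum))
    return _es_from_positions(ranked.scores, pos)


def leading_edge(ranked: RankedList, gene_set: Sequence[str],
                 peak_index: int) -> list:
    """Set members at or before the running-sum peak, in rank order."""
    pos = ranked.positions(gene_set)
    return [str(ranked.genes[i]) for i in pos if i <= peak_index]


def set_permutation_significance(
        ranked: RankedList, gene_sets: Mapping[str, Sequence[str]],
        n_perm: int = DEFAULT_N_PERM, seed=0,
        min_size: int = MIN_SET_SIZE, max_size: int = MAX_SET_SIZE,
        leading_edge_q: float = LEADING_EDGE_Q) -> pd.DataFrame:
    """Set-permutation significance, NES and FDR Q-values for many gene sets.

    Null ES values are drawn from random same-size subsets of the ranked
    universe; one null distribution per distinct set size is shared across
    sets of that size.  Nominal P uses the null tail with a mid-P tie rule.
    Leading edges are reported for sets with Q below ``leading_edge_q``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for permutation FDR")
    n = len(ranked.genes)
    rng = np.random.default_rng(seed)

    sizes_needed = {}
    observed = []
    for name, members in gene_sets.items():
        pos = ranked.positions(members)
        m = len(pos)
        if m > n:
            raise ValueError(f"set {name} larger than ranked universe")
        if m == 0:
            observed.append(GeneSetResult(name, 0, np.nan, -1, testable=False))
            continue
        if not (min_size <= m <= max_size):
            observed.append(GeneSetResult(name, m, np.nan, -1, testable=False))
            continue
        es, peak = _es_from_positions(ranked.scores, pos)
        observed.append(GeneSetResult(name, m, es, peak))
        sizes_needed[m] = True

    null_by_size: Dict[int, np.ndarray] = {}
    for m in sizes_needed:
        null = np.empty(n_perm)
        for b in range(n_perm):
            pos = np.sort(rng.choice(n, size=m, replace=False))
            null[b], _ = _es_from_positions(ranked.scores, pos)
        null_by_size[m] = null

    # NES for observed and null (positive side)
    all_null_nes = []
    for m, null in null_by_size.items():
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = -null[null < 0].mean() if (null < 0).any() else np.nan
        nes_null = np.where(null > 0, null / pos_mean,
                            np.where(null < 0, null / neg_mean, 0.0))
        all_null_nes.append(nes_null)
        null_by_size[m] = (null, pos_mean, neg_mean, nes_null)
    pooled_null_nes = np.concatenate(all_null_nes) if all_null_nes else np.array([])

    for r in observed:
        if not r.testable:
            continue
        null, pos_mean, neg_mean, _ = null_by_size[r.size]
        if r.es >= 0:
            gt = (null > r.es).sum()
            eq = (null == r.es).sum()
            r.p_nominal = max((gt + 0.5 * eq) / n_perm, 0.5 / n_perm)
            r.nes = r.es / pos_mean if np.isfinite(pos_mean) else np.nan
        else:
            lt = (null < r.es).sum()
            eq = (null == r.es).sum()
            r.p_nominal = max((lt + 0.5 * eq) / n_perm, 0.5 / n_perm)
            r.nes = r.es / neg_mean if np.isfinite(neg_mean) else np.nan

    # NES-based FDR (positive/enrichment side)
    obs_nes = np.array([r.nes for r in observed if r.testable])
    for r in observed:
        if not r.testable or not np.isfinite(r.nes):
            continue
        if r.nes >= 0:
            null_frac = (pooled_null_nes >= r.nes).mean() if pooled_null_nes.size else 1.0
            obs_frac = (obs_nes >= r.nes).mean()
        else:
            null_frac = (pooled_null_nes <= r.nes).mean() if pooled_null_nes.size else 1.0
            obs_frac = (obs_nes <= r.nes).mean()
        r.q_value = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else 1.0
        if r.q_value < leading_edge_q and r.es >= 0:
            members = gene_sets[r.name]
            r.leading_edge = leading_edge(ranked, members, r.peak_index)

    rows = [(r.name, r.size, r.es, r.nes, r.p_nominal, r.q_value,
             ",".join(r.leading_edge), r.testable) for r in observed]
    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_nominal",
                                      "q_value", "leading_edge", "testable"])
    return out.sort_values(["q_value", "p_nominal", "set"],
                           kind="stable").reset_index(drop=True)
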
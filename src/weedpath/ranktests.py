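"""Exact all-pairs comparisons of Friedman-type ranked data.

Responses are ranked within blocks (experimental fields); each
unordered pair of treatments is compared through the difference of
their rank sums, D.  Under the null hypothesis every within-block
ranking is equally likely, so the single-block distribution of the
rank difference between two fixed treatments can be enumerated over
the k! permutations and the n-block distribution obtained by
convolution.  The two-sided p-value is P(|D*| >= |D|).  P-values are
reported without multiplicity adjustment; homogeneous subgroups are
summarised as a compact letter display.

The exact null assumes tie-free rankings.  When ties occur within a
block, mid-ranks are used and the p-value falls back to a seeded
Monte-Carlo permutation estimate (method tag ``"approximate"``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class PairwiseRankTest:
    """One pairwise comparison: rank-sum difference and its p-value."""

    i: str
    j: str
    D: float
    p: float
    n: int
    k: int
    method: str  # "exact" | "approximate"


def friedman_ranks(m) -> pd.DataFrame:
    """Rank responses 1..k within each block (row); ties get mid-ranks.

    ``m`` is a blocks x treatments table (DataFrame or 2-D array).
    """
    df = pd.DataFrame(m)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(f"need >= 2 blocks and >= 2 treatments, got {df.shape}")
    if df.isna().any(axis=None):
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing cells in blocks {bad}; the exact test needs a complete matrix")
    ranks = rankdata(df.to_numpy(dtype=float), axis=1)
    return pd.DataFrame(ranks, index=df.index, columns=df.columns)


@lru_cache(maxsize=32)
def _single_block_pmf(k: int) -> np.ndarray:
    """Pmf of the rank difference of two fixed treatments in one block.

    Enumerates the k! equally likely tie-free rankings; returns an
    array over support offsets -(k-1)..(k-1) (index d + k - 1).
    """
    counts = np.zeros(2 * k - 1, dtype=float)
    for perm in itertools.permutations(range(1, k + 1)):
        d = perm[0] - perm[1]
        counts[d + k - 1] += 1
    return counts / counts.sum()


@lru_cache(maxsize=256)
def _nfold_pmf(n: int, k: int) -> np.ndarray:
    """Pmf of the n-block rank-sum difference, support -n(k-1)..n(k-1)."""
    single = _single_block_pmf(k)
    pmf = single
    for _ in range(n - 1):
        pmf = np.convolve(pmf, single)
    return pmf


def exact_pair_pvalue(D: float, n: int, k: int) -> float:
    """Two-sided exact p-value P(|D*| >= |D|) for tie-free ranks.

    ``D`` is the rank-sum difference between two treatments over ``n``
    blocks of ``k`` treatments; it must be an integer (tie-free ranks
    always give integer D) with |D| <= n(k-1).
    """
    if n < 1 or k < 2:
        raise ValueError(f"need n >= 1 blocks and k >= 2 treatments, got n={n}, k={k}")
    if abs(D - round(D)) > 1e-9:
        raise ValueError(f"tie-free rank-sum difference must be an integer, got D={D}")
    D = int(round(D))
    dmax = n * (k - 1)
    if abs(D) > dmax:
        raise ValueError(f"|D|={abs(D)} exceeds the maximum n(k-1)={dmax}")
    pmf = _nfold_pmf(n, k)
    offsets = np.arange(-dmax, dmax + 1)
    return float(pmf[np.abs(offsets) >= abs(D)].sum())


def _mc_pair_pvalue(block_values: np.ndarray, i: int, j: int,
                    n_resamples: int, rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo permutation p-value for a pair when ties are present.

    Permutes responses within each block, re-ranks with mid-ranks, and
    compares |D*| of the permuted data with the observed |D|.  Uses the
    add-one estimator so p stays in (0, 1].
    """
    n, k = block_values.shape
    ranks = rankdata(block_values, axis=1)
    d_obs = abs(ranks[:, i].sum() - ranks[:, j].sum())
    # permuting columns independently per block is equivalent to permuting
    # the mid-ranks themselves; drawing two distinct positions per block is
    # enough to resample the (i, j) rank pair
    batch = 20_000
    exceed = 0
    done = 0
    while done < n_resamples:
        b = min(batch, n_resamples - done)
        u = rng.random((b, n, k)).argsort(axis=2)  # random permutations
        ri = np.take_along_axis(ranks[None, :, :], u[:, :, :1], axis=2)[:, :, 0]
        rj = np.take_along_axis(ranks[None, :, :], u[:, :, 1:2], axis=2)[:, :, 0]
        d = np.abs((ri - rj).sum(axis=1))
        exceed += int(np.sum(d >= d_obs - 1e-12))
        done += b
    p = (exceed + 1) / (n_resamples + 1)
    return float(ranks[:, i].sum() - ranks[:, j].sum()), float(p)


def compact_letters(treatments: list[str], pvalues: dict[tuple[str, str], float],
                    alpha: float, order: list[str] | None = None) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two treatments share a letter if and only if their pairwise
    p-value exceeds ``alpha``.  ``order`` fixes the letter sequence
    (first treatment in ``order`` tends to get 'a'); defaults to the
    given treatment order.
    """
    if order is None:
        order = list(treatments)
    idx = {t: order.index(t) for t in treatments}
    sets: list[set[str]] = [set(treatments)]
    for (i, j), p in sorted(pvalues.items(), key=lambda kv: (idx[kv[0][0]], idx[kv[0][1]])):
        if p > alpha:
            continue
        new_sets: list[set[str]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb: deduplicate, then drop sets strictly contained in another
        uniq: list[set[str]] = []
        for s in new_sets:
            if s and s not in uniq:
                uniq.append(s)
        sets = [s for s in uniq if not any(s < t for t in uniq)]
    # repair pass: every non-significant pair must share at least one set
    for (i, j), p in pvalues.items():
        if p > alpha and not any(i in s and j in s for s in sets):
            sets.append({i, j})
    sets = [s for s in sets if not any(s < t for t in sets)]
    sets.sort(key=lambda s: min(idx[t] for t in s))
    letters = {t: "" for t in treatments}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for t in s:
            letters[t] += letter
    return letters


def all_pairs_test(m, alpha: float = 0.05, n_resamples: int = 100_000,
                   seed: int | None = None) -> tuple[list[PairwiseRankTest], dict[str, str]]:
    """Exact all-pairs comparisons with a compact letter display.

    ``m`` is a blocks x treatments response table.  Returns one
    unadjusted two-sided test per unordered treatment pair plus the
    letter coding of homogeneous subgroups at level ``alpha``.
    """
    df = pd.DataFrame(m)
    ranks = friedman_ranks(df)
    values = df.to_numpy(dtype=float)
    n, k = values.shape
    ties = any(len(np.unique(row)) < k for row in values)
    treatments = [str(c) for c in df.columns]
    rank_sums = ranks.sum(axis=0).to_numpy()
    rng = np.random.default_rng(seed)

    tests: list[PairwiseRankTest] = []
    pvals: dict[tuple[str, str], float] = {}
    for a_idx, b_idx in itertools.combinations(range(k), 2):
        if ties:
            D, p = _mc_pair_pvalue(values, a_idx, b_idx, n_resamples, rng)
            method = "approximate"
        else:
            D = float(rank_sums[a_idx] - rank_sums[b_idx])
            p = exact_pair_pvalue(D, n, k)
            method = "exact"
        ti, tj = treatments[a_idx], treatments[b_idx]
        tests.append(PairwiseRankTest(ti, tj, D, p, n, k, method))
        pvals[(ti, tj)] = pvals[(tj, ti)] = p

    mean_ranks = ranks.mean(axis=0)
    order = [str(t) for t in mean_ranks.sort_values(ascending=False).index]
    letters = compact_letters(treatments, pvals, alpha, order=order)
    return tests, letters


def pairs_table(tests: list[PairwiseRankTest]) -> pd.DataFrame:
    """Tidy table of pairwise results."""
    return pd.DataFrame([t.__dict__ for t in tests])
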
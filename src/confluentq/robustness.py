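"""Sensitivity of method rankings: spamming, single-swap bounds, subsets.

Spamming asks what happens when a dataset is flooded with k trivial variants
of one method (each correlating 1.0 with the target and inheriting its
correlations to everyone else).  Closed forms follow immediately: the
spammed method's summed correlation S grows by exactly k, any other method's
by k times its correlation to the target, and threshold counts grow by k
only for methods already above the threshold against the target.  Spamming
therefore cannot promote a method past a leader it is highly correlated
with under the count criterion, and it betrays itself through a ranking
abnormality (different winners under the S and count criteria).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import confluence
from .confluence import ConfluenceScores, RankingTable, _ranked, threshold_counts
from .dataset_io import NACTable
from .errors import ValidationError
from .regression import CorrelationSummary, correlation_matrix, standardized_matrix


def spam_updated_sum(s_old: float, k: int, omega_to_target: float) -> float:
    """Summed correlation after k perfect variants of the target are added.

    For the target itself ``omega_to_target`` is 1, giving S_old + k.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    return s_old + k * omega_to_target


def spammed_correlation_matrix(omega: np.ndarray, target_index: int,
                               k: int) -> np.ndarray:
    """Explicit (V+k) x (V+k) correlation matrix with k duplicates of one row.

    Each variant correlates 1.0 with the target and with every other variant
    and inherits the target's correlations to the original methods.  The
    result is a valid (singular) correlation matrix.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    m = np.asarray(omega, dtype=float)
    v = m.shape[0]
    big = np.ones((v + k, v + k))
    big[:v, :v] = m
    row = m[target_index]
    big[v:, :v] = row
    big[:v, v:] = row[:, None]
    return big


@dataclass
class SpamResult:
    """Outcome of adding k trivial variants of one method."""

    spammed_method: str
    k: int
    method_names: list[str]
    new_s: np.ndarray                          # per original method
    new_counts: dict[float, np.ndarray]        # threshold -> per-method counts
    rankings: RankingTable
    ranking_abnormality: bool                  # S-top differs from a count-top
    explicit_verified: bool                    # closed form matched brute force


def spam_analysis(summary: CorrelationSummary,
                  scores: ConfluenceScores,
                  target: str,
                  k: int,
                  thresholds: Sequence[float] = (0.8, 0.9),
                  strict: bool = True,
                  explicit_limit: int = 1000) -> SpamResult:
    """Closed-form spam update of S and counts, verified against the
    explicitly enlarged correlation matrix when k <= ``explicit_limit``.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    if target not in summary.method_names:
        raise ValidationError(f"unknown method {target!r}")
    names = summary.method_names
    t = names.index(target)
    omega = summary.correlation
    omega_to_target = omega[:, t]

    new_s = scores.s_alpha + k * omega_to_target
    new_counts: dict[float, np.ndarray] = {}
    for cut in thresholds:
        base = threshold_counts(omega, cut, strict=strict)
        above = omega_to_target > cut if strict else omega_to_target >= cut
        new_counts[cut] = base + k * above.astype(int)

    explicit_verified = False
    if k <= explicit_limit:
        big = spammed_correlation_matrix(omega, t, k)
        brute_s = big.sum(axis=1)[: len(names)]
        if not np.allclose(brute_s, new_s, rtol=0, atol=1e-9):
            raise AssertionError("closed-form spam update disagrees with "
                                 "explicit matrix construction")
        for cut in thresholds:
            brute_counts = threshold_counts(big, cut, strict=strict)[: len(names)]
            if not np.array_equal(brute_counts, new_counts[cut]):
                raise AssertionError("closed-form count update disagrees with "
                                     "explicit matrix construction")
        explicit_verified = True

    rankings: dict[str, list[tuple[int, str, float]]] = {}
    ties: dict[str, list[list[str]]] = {}
    rankings["S_alpha"], ties["S_alpha"] = _ranked(names, new_s)
    for cut, counts in new_counts.items():
        key = f"count_gt_{cut}"
        rankings[key], ties[key] = _ranked(names, counts.astype(float))
    table = RankingTable(rankings, ties)

    s_top = table.top("S_alpha")
    abnormality = any(table.top(f"count_gt_{cut}") != s_top
                      for cut in thresholds)
    return SpamResult(target, k, list(names), new_s, new_counts, table,
                      abnormality, explicit_verified)


@dataclass
class SwapSensitivity:
    """Best/worst ranks under a single arbitrary method swap (+-1 counts)."""

    method_names: list[str]
    counts: np.ndarray
    best_rank: dict[str, int]
    worst_rank: dict[str, int]
    #: informational: one swap changes any S_alpha by at most 2 in magnitude
    s_alpha_swap_bound: float = 2.0

    def stable_top(self, n: int) -> bool:
        """True if no single +-1 perturbation can change the top-n set."""
        order = sorted(self.method_names,
                       key=lambda m: -self.counts[self.method_names.index(m)])
        top = set(order[:n])
        inside_ok = all(self.worst_rank[m] <= n for m in top)
        outside_ok = all(self.best_rank[m] > n
                         for m in self.method_names if m not in top)
        return inside_ok and outside_ok


def swap_sensitivity(counts: Mapping[str, int] | Sequence[int]) -> SwapSensitivity:
    """Rank bounds when each method's count moves +-1 adversarially.

    Swapping one method B for an arbitrary new B' changes every other
    method's threshold count by at most +-1, so each method's best case is
    its own count +1 with all rivals at count -1, and vice versa for the
    worst case.  Rank is 1 + (number of strictly larger counts).
    """
    if isinstance(counts, Mapping):
        names = list(counts.keys())
        vals = np.asarray([counts[n] for n in names], dtype=int)
    else:
        vals = np.asarray(counts, dtype=int)
        names = [f"m{i + 1}" for i in range(len(vals))]
    if np.any(vals < 1):
        raise ValidationError("counts must be >= 1 (self correlation)")

    best: dict[str, int] = {}
    worst: dict[str, int] = {}
    for i, name in enumerate(names):
        others = np.delete(vals, i)
        best[name] = 1 + int(np.sum(others - 1 > vals[i] + 1))
        worst[name] = 1 + int(np.sum(others + 1 > vals[i] - 1))
    return SwapSensitivity(names, vals, best, worst)


def subset_rerank(table: NACTable, keep: Sequence[str],
                  thresholds: Sequence[float] = (0.8, 0.9),
                  strict: bool = True) -> RankingTable:
    """Re-run the full confluence ranking on a column subset of the table."""
    if len(keep) < 2:
        raise ValidationError("need at least 2 methods")
    sub = table.subset_methods(keep)
    summary = correlation_matrix(sub)
    w = standardized_matrix(sub)
    report = confluence.analyze(summary, w, thresholds=thresholds, strict=strict)
    return report.ranking
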
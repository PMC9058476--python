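"""Confluence metrics: summed correlations, the average standardized variable,
correlation-matrix PCA, threshold counts, block detection, and method ranking.

A group of descriptors is mutually positively correlated (confluent) when
every entry of its correlation matrix Omega is positive.  For such a group:

* S_alpha = sum_beta Omega_alpha_beta (self term included) measures how well
  method alpha correlates with the whole group; its maximizer is the group's
  "superdelegate".
* phi_i, the mean of all standardized columns at datapoint i, is the linear
  combination with the largest possible summed correlation
  S_phi = sqrt(sum_ab Omega_ab), and Omega(alpha, phi) = S_alpha / S_phi.
* The main principal component (MPC) of Omega maximizes the sum of *squared*
  correlations; a variable's correlation to component k is v_alpha^(k) *
  sqrt(lambda^(k)).  One step of power iteration from the all-ones vector
  already lands near the MPC: v_MPC ~ S / ||S||_2.

These identities make several seemingly different ranking criteria coincide
exactly (S_alpha vs Omega(alpha, phi); MPC coefficient vs Omega(alpha, MPC))
or nearly so (phi- vs MPC-based correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .errors import (DegenerateEigenvalueError, MissingDataError,
                     ValidationError)
from .regression import CorrelationSummary

#: Eigenvalue gaps below this are treated as degenerate (rotation freedom).
DEGENERACY_TOL = 1e-9


# ---------------------------------------------------------------------------
# charge-transfer magnitudes

def charge_transfer_magnitudes(summary: CorrelationSummary,
                               reference: str) -> pd.DataFrame:
    """Per-method sigma, mean charge, and sigma relative to a reference method.

    Returns a DataFrame sorted ascending by sigma with columns
    ``sigma``, ``q_avg``, ``relative`` (= sigma / sigma_reference).
    """
    if reference not in summary.method_names:
        raise ValidationError(f"unknown reference method {reference!r}")
    ref_sigma = summary.sigma[summary.method_names.index(reference)]
    df = pd.DataFrame({
        "sigma": summary.sigma,
        "q_avg": summary.q_avg,
        "relative": summary.sigma / ref_sigma,
    }, index=summary.method_names)
    df.loc[reference, "relative"] = 1.0
    return df.sort_values("sigma")


# ---------------------------------------------------------------------------
# PCA of the correlation (or covariance) matrix

@dataclass
class PCAResult:
    """Eigendecomposition of a correlation or covariance matrix.

    Components are sorted by descending eigenvalue; eigenvector k is column
    k of ``eigenvectors``.  For a correlation matrix the eigenvalues sum to
    the number of variables, so lambda/V*100 is the percent of correlation
    the component explains.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # columns are unit-norm components
    n_variables: int
    kind: str                     # "correlation" | "covariance"
    degenerate: np.ndarray        # per-component: shares its eigenvalue

    @property
    def percent_explained(self) -> np.ndarray:
        if self.kind == "correlation":
            return self.eigenvalues / self.n_variables * 100.0
        return self.eigenvalues / self.eigenvalues.sum() * 100.0

    @property
    def mpc(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def lambda_mpc(self) -> float:
        return float(self.eigenvalues[0])


def pca(matrix: np.ndarray, kind: str = "correlation") -> PCAResult:
    """Full symmetric eigendecomposition with a reproducible sign convention.

    The first component is flipped so its coefficients sum positive (for a
    confluent group the MPC is then all-positive); every other component is
    flipped so its largest-magnitude coefficient is positive.  Components
    whose eigenvalues are equal within ``DEGENERACY_TOL`` are flagged: any
    rotation of their subspace is an equally valid decomposition.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("matrix must be square")
    if np.max(np.abs(m - m.T)) > 1e-9:
        raise ValidationError("matrix is not symmetric within 1e-9")
    if kind not in ("correlation", "covariance"):
        raise ValidationError("kind must be 'correlation' or 'covariance'")
    eigvals, eigvecs = np.linalg.eigh((m + m.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    v = m.shape[0]
    for k in range(v):
        if k == 0:
            if eigvecs[:, 0].sum() < 0:
                eigvecs[:, 0] = -eigvecs[:, 0]
        else:
            j = int(np.argmax(np.abs(eigvecs[:, k])))
            if eigvecs[j, k] < 0:
                eigvecs[:, k] = -eigvecs[:, k]

    degenerate = np.zeros(v, dtype=bool)
    for k in range(v - 1):
        if abs(eigvals[k] - eigvals[k + 1]) < DEGENERACY_TOL:
            degenerate[k] = degenerate[k + 1] = True
    return PCAResult(eigvals, eigvecs, v, kind, degenerate)


def pc_correlation(coefficient: float | np.ndarray,
                   eigenvalue: float) -> float | np.ndarray:
    """Correlation of a variable to component k: v_alpha^(k) * sqrt(lambda^(k))."""
    if eigenvalue < 0:
        raise ValidationError("eigenvalue must be >= 0")
    return coefficient * np.sqrt(eigenvalue)


def component_scores(w: np.ndarray, result: PCAResult, k: int = 0) -> np.ndarray:
    """Datapoint scores P_i^(k) = sum_alpha v_alpha^(k) * w_i^(alpha)."""
    return np.asarray(w, dtype=float) @ result.eigenvectors[:, k]


def power_iteration_mpc(omega: np.ndarray,
                        trial: np.ndarray | None = None,
                        p: int = 1,
                        tol: float = 1e-12) -> tuple[float, np.ndarray]:
    """Estimate the main eigenpair of Omega by p steps of power iteration.

    For a mutually positive matrix the all-ones trial (default) is never
    orthogonal to the MPC; one step then gives S / ||S||_2, which is already
    very close to the exact MPC for confluent groups.  A trial vector whose
    image collapses toward zero norm (orthogonal to the dominant eigenvector)
    raises.
    """
    m = np.asarray(omega, dtype=float)
    v = m.shape[0]
    vec = np.ones(v) if trial is None else np.asarray(trial, dtype=float)
    if vec.shape != (v,):
        raise ValidationError("trial vector has wrong shape")
    norm0 = np.linalg.norm(vec)
    if norm0 == 0:
        raise ValidationError("trial vector is zero")
    vec = vec / norm0
    if p < 1:
        raise ValidationError("need p >= 1 iterations")
    for _ in range(p):
        nxt = m @ vec
        norm = np.linalg.norm(nxt)
        if norm < tol * max(1.0, np.linalg.norm(m)):
            raise ValidationError(
                "trial vector appears orthogonal to the main eigenvector")
        vec = nxt / norm
    lam = float(vec @ m @ vec)
    if vec.sum() < 0:
        vec = -vec
    return lam, vec


# ---------------------------------------------------------------------------
# confluence scores

@dataclass
class ConfluenceScores:
    """phi-based and summed-correlation quantities for one descriptor group."""

    method_names: list[str]
    s_alpha: np.ndarray                   # summed correlations, self included
    s_phi: float                          # max possible summed correlation
    omega_alpha_phi: np.ndarray           # = s_alpha / s_phi
    superdelegate: str                    # argmax of s_alpha
    confluent: bool                       # all Omega entries > 0
    phi: np.ndarray | None = None         # per-datapoint average standardized var
    sigma_phi: float | None = None
    phi_hat: np.ndarray | None = None     # standardized phi

    def as_series(self) -> pd.Series:
        return pd.Series(self.s_alpha, index=self.method_names, name="S_alpha")


def confluence_scores(summary: CorrelationSummary,
                      w: np.ndarray | None = None) -> ConfluenceScores:
    """Compute S_alpha, S_phi, Omega(alpha, phi), and (optionally) phi itself.

    The phi-based quantities assume mutual positive correlation; when some
    Omega entry is <= 0 they are still computed from the same formulas but
    the result is flagged as outside that premise (``confluent=False``).

    Parameters
    ----------
    w:
        Optional standardized data matrix (rows = datapoints, columns =
        methods, each column zero mean / unit sigma).  When given, phi_i is
        its row mean and sigma_phi is computed from the data; S_phi always
        comes from the correlation matrix.
    """
    omega = summary.correlation
    if np.isnan(omega).any():
        raise MissingDataError("correlation matrix contains NaN")
    s_alpha = omega.sum(axis=1)
    total = float(omega.sum())
    s_phi = float(np.sqrt(total)) if total > 0 else float("nan")
    omega_alpha_phi = s_alpha / s_phi
    # name-stable argmax: ties broken alphabetically
    best = max(range(len(s_alpha)),
               key=lambda i: (s_alpha[i], ), default=0)
    top = [i for i in range(len(s_alpha)) if s_alpha[i] == s_alpha[best]]
    superdelegate = min((summary.method_names[i] for i in top))

    phi = sigma_phi = phi_hat = None
    if w is not None:
        w = np.asarray(w, dtype=float)
        if w.shape[1] != summary.n_methods:
            raise ValidationError("W column count != number of methods")
        phi = w.mean(axis=1)
        sigma_phi = float(np.sqrt(np.mean(phi ** 2)))  # phi has zero mean
        phi_hat = phi / sigma_phi if sigma_phi > 0 else phi
    return ConfluenceScores(list(summary.method_names), s_alpha, s_phi,
                            omega_alpha_phi, superdelegate,
                            summary.mutually_positive, phi, sigma_phi, phi_hat)


def mpc_summary(scores: ConfluenceScores, result: PCAResult
                ) -> tuple[float, float]:
    """(S_MPC, Omega(phi, MPC)) from the correlation-matrix MPC.

    S_MPC = sum_alpha Omega(alpha, MPC) = sqrt(lambda_MPC) * sum_alpha
    v_alpha, and Omega(phi, MPC) = S_MPC / S_phi.  The identity is validated
    against a brute-force correlation of phi with MPC component scores in the
    test suite.  A degenerate top eigenvalue makes the MPC non-unique.
    """
    if result.kind != "correlation":
        raise ValidationError("mpc_summary requires correlation-kind PCA")
    if result.degenerate[0]:
        raise DegenerateEigenvalueError("top eigenvalue is degenerate")
    s_mpc = float(np.sqrt(result.lambda_mpc) * result.mpc.sum())
    return s_mpc, s_mpc / scores.s_phi


# ---------------------------------------------------------------------------
# counts, blocks, rankings

def threshold_counts(omega: np.ndarray, cut: float,
                     strict: bool = True) -> np.ndarray:
    """Per method: number of methods (self included) with Omega above ``cut``."""
    if not 0 < cut < 1:
        raise ValidationError("cut must lie in (0, 1)")
    m = np.asarray(omega, dtype=float)
    return (m > cut).sum(axis=1) if strict else (m >= cut).sum(axis=1)


@dataclass
class BlockStructure:
    """Connected components of the thresholded correlation graph."""

    groups: list[list[str]]               # components, largest first
    adjacency: dict[str, list[str]]       # neighbors at Omega >= cut (no self)
    ordering: list[str]                   # display order, components contiguous


def find_blocks(omega: np.ndarray, cut: float,
                method_names: Sequence[str] | None = None) -> BlockStructure:
    """Group methods into blocks of mutual correlation >= cut.

    Blocks are connected components of the graph with edges where
    Omega_alpha_beta >= cut.  The display ordering keeps components
    contiguous and puts highly connected methods first within each.
    """
    if not 0 < cut < 1:
        raise ValidationError("cut must lie in (0, 1)")
    m = np.asarray(omega, dtype=float)
    v = m.shape[0]
    names = list(method_names) if method_names is not None else [
        f"m{i + 1}" for i in range(v)]
    adj = (m >= cut) & ~np.eye(v, dtype=bool)
    n_comp, labels = connected_components(adj.astype(int), directed=False)
    degree = adj.sum(axis=1)

    groups: list[list[str]] = []
    for comp in range(n_comp):
        members = [i for i in range(v) if labels[i] == comp]
        members.sort(key=lambda i: (-degree[i], names[i]))
        groups.append([names[i] for i in members])
    groups.sort(key=lambda g: (-len(g), g[0]))
    adjacency = {
        names[i]: sorted((names[j] for j in range(v) if adj[i, j]))
        for i in range(v)
    }
    ordering = [name for g in groups for name in g]
    return BlockStructure(groups, adjacency, ordering)


@dataclass
class RankingTable:
    """Per-criterion ordered rankings with tie annotations."""

    rankings: dict[str, list[tuple[int, str, float]]]
    ties: dict[str, list[list[str]]] = field(default_factory=dict)

    def order(self, criterion: str) -> list[str]:
        return [name for _, name, _ in self.rankings[criterion]]

    def top(self, criterion: str) -> str:
        return self.rankings[criterion][0][1]


def _ranked(names: Sequence[str], scores: np.ndarray
            ) -> tuple[list[tuple[int, str, float]], list[list[str]]]:
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    ranking = [(r + 1, names[i], float(scores[i])) for r, i in enumerate(order)]
    ties: list[list[str]] = []
    by_score: dict[float, list[str]] = {}
    for _, name, score in ranking:
        by_score.setdefault(score, []).append(name)
    for score, group in by_score.items():
        if len(group) > 1:
            ties.append(group)
    return ranking, ties


def rank_methods(summary: CorrelationSummary,
                 scores: ConfluenceScores,
                 result: PCAResult,
                 thresholds: Sequence[float] = (0.8, 0.9),
                 strict: bool = True) -> RankingTable:
    """Rank methods under every criterion; ties broken by method name.

    The S_alpha and Omega(alpha, phi) orderings are identical by the
    S_alpha = S_phi * Omega(alpha, phi) identity, as are the MPC-coefficient
    and Omega(alpha, MPC) orderings; both identities are asserted.
    """
    names = summary.method_names
    omega_mpc = pc_correlation(result.mpc, result.lambda_mpc)
    criteria: dict[str, np.ndarray] = {
        "S_alpha": scores.s_alpha,
        "omega_phi": scores.omega_alpha_phi,
        "mpc_coefficient": result.mpc,
        "omega_mpc": np.asarray(omega_mpc),
    }
    for cut in thresholds:
        criteria[f"count_gt_{cut}"] = threshold_counts(
            summary.correlation, cut, strict=strict).astype(float)

    rankings: dict[str, list[tuple[int, str, float]]] = {}
    ties: dict[str, list[list[str]]] = {}
    for crit, vals in criteria.items():
        rankings[crit], ties[crit] = _ranked(names, np.asarray(vals, float))

    table = RankingTable(rankings, ties)
    assert table.order("S_alpha") == table.order("omega_phi")
    assert table.order("mpc_coefficient") == table.order("omega_mpc")
    return table


# ---------------------------------------------------------------------------
# one-call pipeline

@dataclass
class ConfluenceReport:
    summary: CorrelationSummary
    scores: ConfluenceScores
    pca: PCAResult
    ranking: RankingTable
    s_mpc: float | None
    omega_phi_mpc: float | None
    blocks: BlockStructure


def analyze(summary: CorrelationSummary,
            w: np.ndarray | None = None,
            thresholds: Sequence[float] = (0.8, 0.9),
            strict: bool = True,
            block_cut: float = 0.9) -> ConfluenceReport:
    """Run the full confluence pipeline on one correlation summary."""
    scores = confluence_scores(summary, w)
    result = pca(summary.correlation, kind="correlation")
    ranking = rank_methods(summary, scores, result, thresholds, strict)
    try:
        s_mpc, omega_phi_mpc = mpc_summary(scores, result)
    except DegenerateEigenvalueError:
        s_mpc = omega_phi_mpc = None
    blocks = find_blocks(summary.correlation, block_cut, summary.method_names)
    return ConfluenceReport(summary, scores, result, ranking,
                            s_mpc, omega_phi_mpc, blocks)
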
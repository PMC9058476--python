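"""Standardization, correlation, and reversible (instant) least squares fitting.

Ordinary least squares of y on x and of x on y give two different lines,
which is awkward when neither variable is privileged — as when comparing two
charge-assignment methods.  Standardizing both variables (zero mean, unit
standard deviation, with the second variable sign-flipped if the covariance
is negative) makes total least squares, orthogonal distance regression, and
PCA regression coincide on the single universal line w = z.  This "instant
least squares fit" (ILSF) is reversible, its optimum (zeta, eta) = (1, 0)
requires no numerical optimization, and its fit quality equals the
correlation magnitude |Omega|.

Loss conventions for the standardized pair (w, z) and a candidate line
z = zeta*w + eta, with Dz_i = zeta*w_i + eta - z_i and Dw_i = -Dz_i/zeta:

* total least squares:       L1 = sum(Dw^2 + Dz^2)
* orthogonal distance:       L2 = sum(Dz^2) / (1 + zeta^2)

At the optimum L1 = 4*M*(1 - Omega) and L2 = M*(1 - Omega), so L1 = 4*L2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateVarianceError, MissingDataError, ValidationError

#: Covariances below this relative level are treated as exactly zero, in
#: which case the standardized model collapses to a point at the means.
ZERO_COVARIANCE_RTOL = 1e-12


def _divisor(n: int, population: bool) -> int:
    return n if population else n - 1


@dataclass
class StandardizedVariable:
    """A variable shifted to zero mean and scaled to unit standard deviation."""

    values: np.ndarray
    mean: float
    sigma: float
    sign: int
    M: int  # divisor used (N for population, N-1 for sample)

    def inverse(self, w: np.ndarray) -> np.ndarray:
        """Map standardized values back to original units."""
        return np.asarray(w) * self.sigma * self.sign + self.mean


@dataclass
class CorrelationSummary:
    """Per-method spread, mean, covariance and correlation matrices."""

    method_names: list[str]
    sigma: np.ndarray          # per-method standard deviation (e)
    q_avg: np.ndarray          # per-method mean charge (e)
    covariance: np.ndarray     # Lambda (e^2)
    correlation: np.ndarray    # Omega (dimensionless)
    population: bool = True    # divisor convention: M = N (True) or N-1

    @property
    def n_methods(self) -> int:
        return len(self.method_names)

    def omega(self, a: str, b: str) -> float:
        i, j = self.method_names.index(a), self.method_names.index(b)
        return float(self.correlation[i, j])

    @property
    def mutually_positive(self) -> bool:
        return bool(np.all(self.correlation > 0))

    @classmethod
    def from_correlation(cls, correlation: np.ndarray,
                         method_names: Sequence[str] | None = None,
                         sigma: np.ndarray | None = None,
                         q_avg: np.ndarray | None = None,
                         population: bool = True) -> "CorrelationSummary":
        """Build a summary from a correlation matrix alone.

        Useful when only the matrix is known (e.g. printed in a report);
        sigma defaults to ones, making covariance equal correlation.
        """
        omega = np.asarray(correlation, dtype=float)
        v = omega.shape[0]
        if method_names is None:
            method_names = [f"m{i + 1}" for i in range(v)]
        if sigma is None:
            sigma = np.ones(v)
        sigma = np.asarray(sigma, dtype=float)
        if q_avg is None:
            q_avg = np.zeros(v)
        cov = omega * np.outer(sigma, sigma)
        return cls(list(method_names), sigma, np.asarray(q_avg, dtype=float),
                   cov, omega, population)


@dataclass
class SLSFModel:
    """Forward and reverse simple (irreversible) least-squares lines."""

    slope: float
    intercept: float
    reverse_slope: float
    reverse_intercept: float
    omega: float

    @property
    def reversibility_defect(self) -> float:
        """|m * m' - 1|; zero iff |Omega| = 1, i.e. the fit is reversible."""
        return abs(self.slope * self.reverse_slope - 1.0)


@dataclass
class ILSFModel:
    """The reversible standardized fit: zeta, eta, losses, and quality."""

    zeta: float
    eta: float
    omega_wz: float            # correlation of the standardized pair (>= 0)
    loss_tls: float            # L1 at the optimum
    loss_odr: float            # L2 at the optimum
    fit_quality: float         # equals omega_wz
    slope_original: float      # line mapped back to input units
    intercept_original: float
    sign_y: int
    degenerate: bool = False   # zero covariance: model collapses to a point
    x_mean: float = 0.0
    y_mean: float = 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.full_like(np.asarray(x, dtype=float), self.y_mean)
        return self.slope_original * np.asarray(x) + self.intercept_original


def standardize(values: Sequence[float], sign: int = 1,
                *, population: bool = True) -> StandardizedVariable:
    """Standardize a variable: w_i = (x_i - mean) * sign / sigma.

    Parameters
    ----------
    sign:
        +1 or -1; a -1 flips the variable so that a negatively correlated
        partner becomes positively correlated after standardization.
    population:
        Use the population divisor M = N (default) or the sample divisor
        N - 1.  The same convention must be used for every variable entering
        a joint analysis.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need a 1-D sequence of length >= 2")
    if np.isnan(x).any():
        raise MissingDataError("cannot standardize values containing NaN")
    if sign not in (-1, 1):
        raise ValidationError("sign must be +1 or -1")
    m = _divisor(len(x), population)
    mean = float(x.mean())
    sigma = float(np.sqrt(np.sum((x - mean) ** 2) / m))
    if sigma == 0.0:
        raise DegenerateVarianceError("constant input has zero sigma")
    return StandardizedVariable((x - mean) * sign / sigma, mean, sigma, sign, m)


def correlation_matrix(table_or_values, *, population: bool = True
                       ) -> CorrelationSummary:
    """Per-method sigma, mean, covariance Lambda and correlation Omega.

    Accepts a :class:`~confluentq.dataset_io.NACTable`, a DataFrame, or a
    2-D array (rows = atoms, columns = methods).  Missing cells are
    rejected: rows must be dropped explicitly upstream.
    """
    if hasattr(table_or_values, "values") and hasattr(table_or_values, "method_names"):
        frame = table_or_values.values
    elif isinstance(table_or_values, pd.DataFrame):
        frame = table_or_values
    else:
        frame = pd.DataFrame(np.asarray(table_or_values, dtype=float))
        frame.columns = [f"m{i + 1}" for i in range(frame.shape[1])]
    if frame.isna().to_numpy().any():
        raise MissingDataError("table has missing cells; drop rows explicitly")
    x = frame.to_numpy(dtype=float)
    n, v = x.shape
    if n < 2:
        raise ValidationError("need at least 2 rows")
    m = _divisor(n, population)
    q_avg = x.mean(axis=0)
    centered = x - q_avg
    cov = centered.T @ centered / m
    sigma = np.sqrt(np.diag(cov))
    zero = np.where(sigma == 0)[0]
    if zero.size:
        raise DegenerateVarianceError(
            f"zero-variance column(s): {[frame.columns[i] for i in zero]}")
    omega = cov / np.outer(sigma, sigma)
    np.fill_diagonal(omega, 1.0)
    return CorrelationSummary(list(frame.columns), sigma, q_avg, cov, omega,
                              population)


def standardized_matrix(table_or_values, *, population: bool = True) -> np.ndarray:
    """Column-wise standardized data matrix W (all signs +1)."""
    summary = correlation_matrix(table_or_values, population=population)
    if hasattr(table_or_values, "method_names"):
        x = table_or_values.values.to_numpy(dtype=float)
    elif isinstance(table_or_values, pd.DataFrame):
        x = table_or_values.to_numpy(dtype=float)
    else:
        x = np.asarray(table_or_values, dtype=float)
    return (x - summary.q_avg) / summary.sigma


def slsf_fit(x: Sequence[float], y: Sequence[float],
             *, population: bool = True) -> SLSFModel:
    """Ordinary least squares both ways: y ~ m*x + c and x ~ m'*y + c'.

    The two lines agree (reversibility defect 0) only when |Omega| = 1;
    in general m * m' = Omega^2.
    """
    summary = correlation_matrix(np.column_stack([x, y]), population=population)
    cov = summary.covariance[0, 1]
    sx, sy = summary.sigma
    mx, my = summary.q_avg
    m = cov / sx ** 2
    c = my - m * mx
    m_rev = cov / sy ** 2
    c_rev = mx - m_rev * my
    return SLSFModel(m, c, m_rev, c_rev, float(summary.correlation[0, 1]))


def ilsf_fit(x: Sequence[float], y: Sequence[float],
             *, population: bool = True) -> ILSFModel:
    """Instant least squares fit of two variables.

    Standardizes x with sign +1 and y with sign(covariance); the
    standardized pair is then positively correlated and the optimum is the
    universal line (zeta, eta) = (1, 0).  Losses come from the closed forms
    L1 = 4*M*(1 - Omega_wz) and L2 = M*(1 - Omega_wz); the line is also
    mapped back to original units.  A zero covariance collapses the model to
    the point of the means.
    """
    summary = correlation_matrix(np.column_stack([x, y]), population=population)
    cov = summary.covariance[0, 1]
    sx, sy = summary.sigma
    mx, my = summary.q_avg
    m = _divisor(len(np.asarray(x)), population)

    if abs(cov) <= ZERO_COVARIANCE_RTOL * sx * sy:
        return ILSFModel(zeta=np.nan, eta=np.nan, omega_wz=0.0,
                         loss_tls=np.nan, loss_odr=np.nan, fit_quality=0.0,
                         slope_original=np.nan, intercept_original=np.nan,
                         sign_y=1, degenerate=True, x_mean=mx, y_mean=my)

    sign_y = 1 if cov > 0 else -1
    omega_wz = abs(cov) / (sx * sy)
    slope = sign_y * sy / sx
    intercept = my - slope * mx
    return ILSFModel(zeta=1.0, eta=0.0, omega_wz=omega_wz,
                     loss_tls=4.0 * m * (1.0 - omega_wz),
                     loss_odr=float(m * (1.0 - omega_wz)),
                     fit_quality=omega_wz,
                     slope_original=slope, intercept_original=intercept,
                     sign_y=sign_y, x_mean=mx, y_mean=my)


def evaluate_losses(zeta: float, eta: float,
                    w: StandardizedVariable | np.ndarray,
                    z: StandardizedVariable | np.ndarray
                    ) -> tuple[float, float]:
    """TLS and ODR losses of an arbitrary candidate line on standardized data.

    Returns (L1, L2) with L1 = sum(Dw^2 + Dz^2) and L2 = sum(Dz^2)/(1+zeta^2)
    where Dz_i = zeta*w_i + eta - z_i and Dw_i = -Dz_i/zeta.
    """
    if zeta == 0:
        raise ValidationError("zeta = 0 is outside the TLS parameterization")
    wv = w.values if isinstance(w, StandardizedVariable) else np.asarray(w, float)
    zv = z.values if isinstance(z, StandardizedVariable) else np.asarray(z, float)
    if wv.shape != zv.shape:
        raise ValidationError("w and z must have equal length")
    dz = zeta * wv + eta - zv
    sum_dz2 = float(np.sum(dz ** 2))
    l1 = sum_dz2 * (1.0 + zeta ** -2)
    l2 = sum_dz2 / (1.0 + zeta ** 2)
    return l1, l2
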
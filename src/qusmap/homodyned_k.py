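"""Homodyned-K (HK) envelope model: theory, lookup table, XU inversion.

The HK law models the envelope A of backscatter as a coherent amplitude
``epsilon`` plus diffuse scatter whose power is modulated by a Gamma(alpha)
mixing variable: conditionally on w ~ Gamma(alpha, 1) the intensity
I = A^2 is noncentral-exponential with scale 2 sigma^2 w and noncentrality
gamma / w, where gamma = epsilon^2 / (2 sigma^2).  alpha is the scatterer
clustering parameter (effective scatterers per resolution cell), and the
mean intensity is mu = epsilon^2 + 2 alpha sigma^2.

Estimation uses the mean intensity together with two scale-invariant
intensity log-moments,

    X = E[I ln I]/E[I] - E[ln I],      U = ln E[I] - E[ln I],

matched against their theoretical values X_HK(alpha, gamma) and
U_HK(alpha, gamma).  The theoretical moments reduce to closed forms in the
conditional law -- with lam = gamma/w and Ein the complementary exponential
integral,

    E[ln W]   = Ein(lam) - euler_gamma,
    E[W ln W] = (1+lam)(1 + ln lam + E1(lam)) + 1 - lam - exp(-lam),

for the unit-scale noncentral-exponential W -- leaving one smooth outer
expectation over w that is evaluated by generalized Gauss-Laguerre
quadrature.  All remaining log-singular terms cancel analytically, and the
K-distribution limit gamma = 0 is evaluated exactly:

    X_HK(alpha, 0) = 1 + 1/alpha,
    U_HK(alpha, 0) = euler_gamma + ln(alpha) - psi(alpha).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import exp1, psi, roots_genlaguerre

from .config import ParameterError

EULER_GAMMA = np.euler_gamma

DEFAULT_ALPHA_MAX = 40.5
_N_QUAD = 256


class EstimationError(ValueError):
    """Raised when an estimator cannot produce a value for a sample set."""


# ---------------------------------------------------------------------------
# Sample statistics (Eqs. of the XU estimator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class XUStatistics:
    """Mean intensity and the two intensity log-moment statistics."""

    mu: float
    X: float
    U: float


def xu_sample_statistics(
    envelope_samples, max_zero_fraction: float = 0.01
) -> XUStatistics:
    """Compute mu, X, U from envelope amplitudes (natural logarithms).

    Zero samples are undefined under the log-moments; a small fraction
    (<= ``max_zero_fraction``) is dropped, more is an error.
    """
    a = np.asarray(envelope_samples, dtype=float).ravel()
    if a.size < 2:
        raise EstimationError("need at least 2 envelope samples")
    if np.any(a < 0):
        raise EstimationError("envelope samples must be nonnegative")
    zeros = a == 0
    if zeros.any():
        if zeros.mean() > max_zero_fraction:
            raise EstimationError(
                f"{zeros.mean():.1%} zero samples exceeds the "
                f"{max_zero_fraction:.0%} threshold"
            )
        a = a[~zeros]
        if a.size < 2:
            raise EstimationError("all samples are zero")
    intensity = a * a
    log_i = np.log(intensity)
    mu = intensity.mean()
    mean_log = log_i.mean()
    x_stat = np.mean(intensity * log_i) / mu - mean_log
    u_stat = np.log(mu) - mean_log
    return XUStatistics(mu=float(mu), X=float(x_stat), U=float(u_stat))


# ---------------------------------------------------------------------------
# Theoretical log-moments
# ---------------------------------------------------------------------------

def _xu_theory_row(alpha: float, gammas: np.ndarray, n_quad: int = _N_QUAD):
    """X_HK, U_HK at one alpha for an array of gamma values (gamma > 0)."""
    nodes, weights = roots_genlaguerre(n_quad, alpha - 1.0)
    weights = weights / weights.sum()  # expectation under Gamma(alpha, 1)
    g = np.asarray(gammas, dtype=float)[:, None]
    lam = g / nodes[None, :]
    e1 = exp1(lam)
    s_e1 = e1 @ weights
    s_we1 = ((nodes[None, :] + g) * e1) @ weights
    s_damp = (nodes[None, :] * np.exp(-lam)) @ weights
    g = g[:, 0]
    mu = alpha + g
    mean_log_i = np.log(g) + s_e1
    mean_i_log_i = mu * (1.0 + np.log(g)) + s_we1 + alpha - g - s_damp
    return mean_i_log_i / mu - mean_log_i, np.log(mu) - mean_log_i


def hk_theoretical_log_moments(
    alpha: float, gamma: float, n_quad: int = _N_QUAD
) -> tuple[float, float]:
    """Theoretical (X_HK, U_HK) for HK parameters (alpha, gamma).

    Scale-invariant: independent of the mean-intensity scale.  gamma = 0 is
    the K-distribution limit, returned in closed form.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    if gamma < 0:
        raise ParameterError("gamma must be nonnegative")
    if gamma == 0.0:
        return 1.0 + 1.0 / alpha, EULER_GAMMA + np.log(alpha) - psi(alpha)
    x, u = _xu_theory_row(alpha, np.array([gamma]), n_quad)
    x, u = float(x[0]), float(u[0])
    if not (np.isfinite(x) and np.isfinite(u)):
        raise ArithmeticError(
            f"HK log-moment quadrature failed at alpha={alpha}, gamma={gamma}"
        )
    return x, u


# ---------------------------------------------------------------------------
# Lookup table
# ---------------------------------------------------------------------------

@dataclass
class HKTheoryTable:
    """Tabulated X_HK/U_HK on an (alpha, gamma) grid with interpolation.

    Interpolation is bilinear in (ln alpha, gamma); rows at grid nodes
    reproduce the direct computation exactly.
    """

    alpha_grid: np.ndarray
    gamma_grid: np.ndarray
    X: np.ndarray  # (n_alpha, n_gamma)
    U: np.ndarray
    n_quad: int = _N_QUAD
    _log_alpha: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._log_alpha = np.log(self.alpha_grid)

    @property
    def x_min(self) -> float:
        return float(self.X.min())

    def rows_at(self, alpha: float) -> tuple[np.ndarray, np.ndarray]:
        """X and U as functions of gamma at ``alpha`` (ln-alpha row blend)."""
        la = np.log(np.clip(alpha, self.alpha_grid[0], self.alpha_grid[-1]))
        j = np.searchsorted(self._log_alpha, la)
        if j <= 0:
            return self.X[0], self.U[0]
        if j >= len(self.alpha_grid):
            return self.X[-1], self.U[-1]
        t = (la - self._log_alpha[j - 1]) / (self._log_alpha[j] - self._log_alpha[j - 1])
        return (
            (1 - t) * self.X[j - 1] + t * self.X[j],
            (1 - t) * self.U[j - 1] + t * self.U[j],
        )

    def xu_at(self, alpha: float, gamma: float) -> tuple[float, float]:
        x_row, u_row = self.rows_at(alpha)
        g = np.clip(gamma, self.gamma_grid[0], self.gamma_grid[-1])
        return (
            float(np.interp(g, self.gamma_grid, x_row)),
            float(np.interp(g, self.gamma_grid, u_row)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            alpha_grid=self.alpha_grid,
            gamma_grid=self.gamma_grid,
            X=self.X,
            U=self.U,
        )
        meta = {
            "n_alpha": len(self.alpha_grid),
            "n_gamma": len(self.gamma_grid),
            "alpha_range": [float(self.alpha_grid[0]), float(self.alpha_grid[-1])],
            "gamma_range": [float(self.gamma_grid[0]), float(self.gamma_grid[-1])],
            "n_quad": self.n_quad,
            "version": 1,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "HKTheoryTable":
        path = Path(path)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            data = {k: z[k] for k in ("alpha_grid", "gamma_grid", "X", "U")}
        meta_path = path.with_suffix(".json")
        n_quad = _N_QUAD
        if meta_path.exists():
            n_quad = json.loads(meta_path.read_text()).get("n_quad", _N_QUAD)
        return cls(**data, n_quad=n_quad)


def build_hk_lookup_table(
    alpha_grid=None,
    gamma_grid=None,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    n_alpha: int = 200,
    n_gamma: int = 200,
    gamma_max: float = 20.0,
    n_quad: int = _N_QUAD,
) -> HKTheoryTable:
    """Tabulate the theoretical log-moments on an (alpha, gamma) grid.

    Defaults: alpha log-spaced on [0.1, alpha_max] (200 points), gamma
    linear on [0, gamma_max] (200 points, gamma = 0 as the exact K-limit).
    """
    if alpha_grid is None:
        alpha_grid = np.geomspace(0.1, alpha_max, n_alpha)
    else:
        alpha_grid = np.asarray(alpha_grid, dtype=float)
    if gamma_grid is None:
        gamma_grid = np.linspace(0.0, gamma_max, n_gamma)
    else:
        gamma_grid = np.asarray(gamma_grid, dtype=float)
    if np.any(np.diff(alpha_grid) <= 0) or np.any(np.diff(gamma_grid) <= 0):
        raise ParameterError("grids must be strictly increasing")
    if alpha_grid[0] <= 0 or alpha_grid[-1] > alpha_max + 1e-12:
        raise ParameterError(f"alpha grid must lie in (0, {alpha_max}]")
    if gamma_grid[0] < 0:
        raise ParameterError("gamma grid must be nonnegative")

    X = np.empty((len(alpha_grid), len(gamma_grid)))
    U = np.empty_like(X)
    positive = gamma_grid > 0
    for i, a in enumerate(alpha_grid):
        if (~positive).any():
            X[i, ~positive] = 1.0 + 1.0 / a
            U[i, ~positive] = EULER_GAMMA + np.log(a) - psi(a)
        if positive.any():
            X[i, positive], U[i, positive] = _xu_theory_row(
                a, gamma_grid[positive], n_quad
            )
    return HKTheoryTable(alpha_grid=alpha_grid, gamma_grid=gamma_grid, X=X, U=U,
                         n_quad=n_quad)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HKParams:
    """Estimated HK parameters and derived quantities.

    The mean-intensity identity mu = epsilon^2 + 2 alpha sigma^2 is enforced
    exactly by construction (sigma^2 = mu / (2 (alpha + gamma))).
    """

    epsilon: float
    sigma2: float
    alpha: float
    gamma: float
    k: float
    mu: float
    log10_alpha: float
    clamped: bool = False


def _gamma_matching_x(table: HKTheoryTable, x_row: np.ndarray, x_stat: float) -> float:
    """gamma solving X_HK(alpha, gamma) = X on one table row.

    X is strictly decreasing in gamma, so invert by interpolation on the
    reversed row; saturates at the grid ends.
    """
    if x_stat >= x_row[0]:
        return float(table.gamma_grid[0])
    if x_stat <= x_row[-1]:
        return float(table.gamma_grid[-1])
    return float(np.interp(x_stat, x_row[::-1], table.gamma_grid[::-1]))


def hk_xu_estimate(
    envelope_samples=None,
    table: HKTheoryTable = None,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    stats: XUStatistics = None,
    alpha_tol: float = 1e-3,
    max_iter: int = 60,
) -> HKParams:
    """Invert the XU system for (epsilon, sigma^2, alpha) from envelope samples.

    Nested solve for argmin_alpha |U_HK(alpha, gamma(alpha)) - U|, where the
    inner step picks gamma(alpha) satisfying X_HK(alpha, gamma) = X (X is
    monotone in gamma).  The residual is scanned over the table's alpha grid;
    a sign change near the optimum is refined by bisection, otherwise (data
    off the HK manifold, where no alpha zeroes the residual) the interior
    minimum of |residual| is refined by golden-section search.  ``clamped``
    is set when the solution saturates at the bracket ends — at the Rayleigh
    limit the estimate saturates at ``alpha_max``.
    """
    if table is None:
        raise ParameterError("an HKTheoryTable is required")
    if stats is None:
        stats = xu_sample_statistics(envelope_samples)
    if stats.mu <= 0 or not np.isfinite(stats.X) or not np.isfinite(stats.U):
        raise EstimationError("degenerate sample statistics")
    if stats.X < table.x_min:
        raise EstimationError(
            f"X={stats.X:.4g} below the theoretical minimum "
            f"{table.x_min:.4g} of the table (U={stats.U:.4g}); no HK solution"
        )

    def residual(a: float) -> tuple[float, float]:
        x_row, u_row = table.rows_at(a)
        g = _gamma_matching_x(table, x_row, stats.X)
        u_theory = float(np.interp(g, table.gamma_grid, u_row))
        return u_theory - stats.U, g

    # residual on the alpha grid nodes (exact table rows, no blending)
    usable = table.alpha_grid <= alpha_max * (1 + 1e-12)
    alphas = table.alpha_grid[usable]
    res_grid = np.empty(len(alphas))
    for i in range(len(alphas)):
        g_i = _gamma_matching_x(table, table.X[i], stats.X)
        res_grid[i] = np.interp(g_i, table.gamma_grid, table.U[i]) - stats.U

    k = int(np.argmin(np.abs(res_grid)))
    clamped = False
    # prefer a genuine root adjacent to the minimum
    bracket = None
    if k > 0 and np.sign(res_grid[k - 1]) != np.sign(res_grid[k]):
        bracket = (alphas[k - 1], alphas[k], res_grid[k - 1])
    elif k + 1 < len(alphas) and np.sign(res_grid[k]) != np.sign(res_grid[k + 1]):
        bracket = (alphas[k], alphas[k + 1], res_grid[k])
    if bracket is not None:
        lo, hi, r_lo = bracket
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            r_mid, _ = residual(mid)
            if np.sign(r_mid) == np.sign(r_lo):
                lo, r_lo = mid, r_mid
            else:
                hi = mid
            if hi - lo < alpha_tol:
                break
        alpha = 0.5 * (lo + hi)
        _, gamma = residual(alpha)
    elif 0 < k < len(alphas) - 1:
        # off-manifold data: refine the interior minimum of |residual|
        lo, hi = alphas[k - 1], alphas[k + 1]
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        c = hi - invphi * (hi - lo)
        d = lo + invphi * (hi - lo)
        fc, fd = abs(residual(c)[0]), abs(residual(d)[0])
        for _ in range(max_iter):
            if fc < fd:
                hi, d, fd = d, c, fc
                c = hi - invphi * (hi - lo)
                fc = abs(residual(c)[0])
            else:
                lo, c, fc = c, d, fd
                d = lo + invphi * (hi - lo)
                fd = abs(residual(d)[0])
            if hi - lo < alpha_tol:
                break
        alpha = 0.5 * (lo + hi)
        _, gamma = residual(alpha)
    else:
        clamped = True
        alpha = float(alphas[k])
        _, gamma = residual(alpha)

    sigma2 = stats.mu / (2.0 * (alpha + gamma))
    epsilon = np.sqrt(2.0 * sigma2 * gamma)
    k = epsilon / np.sqrt(sigma2 * alpha)
    return HKParams(
        epsilon=float(epsilon),
        sigma2=float(sigma2),
        alpha=float(alpha),
        gamma=float(gamma),
        k=float(k),
        mu=stats.mu,
        log10_alpha=float(np.log10(alpha)),
        clamped=clamped,
    )
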
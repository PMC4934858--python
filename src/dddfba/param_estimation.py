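"""Transcription-rate estimation from RPKM time courses.

The estimation model is the mRNA balance with a Heaviside activation: the
gene transcribes at a basal rate s_b throughout, and an additional
activated rate s_a switches on after a dead time T_d following the
environmental shift at t = 0:

    d[mRNA]/dt = s_b + H(t - T_d) * s_a - (mu + gamma) * [mRNA]

Starting from the pre-shift steady state [mRNA](0) = s_b / (mu + gamma)
this has the closed form implemented by :func:`mrna_solution`.  s_b comes
directly from the anaerobic steady-state RPKM (:func:`estimate_basal`);
(s_a, T_d) are fitted to the post-shift time course by least squares
(:func:`fit_activation`), with bootstrap confidence intervals for s_a.

The degradation rate gamma is taken from literature half-life compilations
and the growth rate mu is measured, so neither is estimated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FitResult", "mrna_solution", "estimate_basal", "fit_activation",
    "normalize_counts",
]


@dataclass
class FitResult:
    """Least-squares estimate of the activated transcription parameters."""

    s_b: float                 #: basal rate (fixed input), RPKM/min
    s_a: float                 #: activated rate, RPKM/min
    t_d: float                 #: dead time, min
    rss: float                 #: residual sum of squares
    s_a_ci: tuple[float, float]          #: bootstrap 95% CI for s_a
    s_a_ci_linear: tuple[float, float]   #: linearized (Jacobian) 95% CI
    degenerate: bool = False   #: flat series; T_d not identifiable


def mrna_solution(t, s_b: float, s_a: float, t_d: float, gamma: float,
                  mu_per_min: float):
    """Closed-form mRNA level of the Heaviside-activated balance ODE.

    Parameters are per minute; ``t`` (min, scalar or array) is measured
    from the shift, with the activated term switching on at ``t_d``.
    Before activation the level sits at the basal steady state
    s_b/(mu+gamma); afterwards it relaxes exponentially toward
    (s_b+s_a)/(mu+gamma).  The function is continuous at t = t_d.
    """
    k = mu_per_min + gamma
    if k <= 0:
        raise ValueError("mu + gamma must be positive")
    t = np.asarray(t, dtype=float)
    base = s_b / k
    rise = np.where(t >= t_d,
                    (s_a / k) * -np.expm1(-k * np.clip(t - t_d, 0.0, None)),
                    0.0)
    out = base + rise
    return float(out) if out.ndim == 0 else out


def estimate_basal(rpkm_ss: float, mu_per_min: float, gamma: float) -> float:
    """Basal transcription rate from a steady-state RPKM level.

    Inverts the pre-shift equilibrium [mRNA] = s_b/(mu+gamma):
    s_b = rpkm_ss * (mu + gamma).  ``mu_per_min`` is the growth rate in
    min^-1 (divide an hourly rate by 60).
    """
    if rpkm_ss < 0:
        raise ValueError("steady-state RPKM must be non-negative")
    k = mu_per_min + gamma
    if k <= 0:
        raise ValueError("mu + gamma must be positive")
    return rpkm_ss * k


def _profile_fit(times: np.ndarray, values: np.ndarray, weights: np.ndarray,
                 s_b: float, gamma: float, mu: float,
                 td_grid: np.ndarray) -> tuple[float, float, float]:
    """Global search: profile the 1-D dead time on a grid.

    For fixed T_d the model is linear in s_a, so the conditionally optimal
    s_a has the closed form of a weighted one-parameter regression; the
    grid search over T_d plus this profile is an effectively global
    minimizer of the 2-D problem.  Ties in RSS break toward smaller T_d
    (np.argmin returns the first minimum on the ascending grid).
    """
    k = mu + gamma
    resid0 = values - s_b / k
    dt = times[None, :] - td_grid[:, None]
    basis = np.where(dt >= 0.0, -np.expm1(-k * np.clip(dt, 0.0, None)) / k, 0.0)
    wb = weights[None, :] * basis
    denom = np.sum(wb * basis, axis=1)
    numer = np.sum(wb * resid0[None, :], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_a = np.where(denom > 0, numer / denom, 0.0)
    s_a = np.clip(s_a, 0.0, None)
    rss = np.sum(weights[None, :] * (resid0[None, :] - s_a[:, None] * basis) ** 2,
                 axis=1)
    i = int(np.argmin(rss))
    return float(s_a[i]), float(td_grid[i]), float(rss[i])


def _fit_once(times: np.ndarray, values: np.ndarray, weights: np.ndarray,
              s_b: float, gamma: float, mu: float, t_max: float,
              n_grid: int, refine: bool) -> tuple[float, float, float]:
    td_grid = np.linspace(0.0, t_max, n_grid)
    s_a, t_d, rss = _profile_fit(times, values, weights, s_b, gamma, mu, td_grid)
    if refine:
        sw = np.sqrt(weights)

        def residuals(x):
            return sw * (mrna_solution(times, s_b, x[0], x[1], gamma, mu) - values)

        res = optimize.least_squares(
            residuals, x0=[max(s_a, 1e-9), t_d],
            bounds=([0.0, 0.0], [np.inf, t_max]), xtol=1e-12, ftol=1e-12)
        rss_ref = float(np.sum(res.fun ** 2))
        if rss_ref <= rss:
            s_a, t_d, rss = float(res.x[0]), float(res.x[1]), rss_ref
    return s_a, t_d, rss


def fit_activation(times, values, s_b: float, gamma: float, mu_per_min: float,
                   sd=None, n_boot: int = 1000, seed: int | None = None,
                   n_grid: int = 241) -> FitResult:
    """Estimate (s_a, T_d) from an RPKM time course by least squares.

    Parameters
    ----------
    times, values:
        Sample times (min, shift at 0; pre-shift points allowed) and RPKM
        values.  At least three post-shift points are required.
    s_b, gamma, mu_per_min:
        Fixed basal rate, degradation rate and growth rate (all per min).
    sd:
        Optional per-point replicate standard deviations; when given, the
        fit is weighted by 1/sd^2.
    n_boot:
        Residual-bootstrap replicates for the 95% CI of s_a (percentile
        interval); 0 disables the bootstrap.
    seed:
        Seed for the bootstrap resampling.
    n_grid:
        Size of the dead-time profile grid spanning [0, max(times)].

    The search profiles T_d on a grid with the conditionally optimal s_a
    in closed form, then polishes with a bounded local least-squares step.
    A flat series (no information above the basal level) is returned as
    ``s_a = 0`` with the ``degenerate`` flag set.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if np.sum(times > 0) < 3:
        raise ValueError("need at least three post-shift time points")
    if sd is None:
        weights = np.ones_like(values)
    else:
        sd = np.asarray(sd, dtype=float)
        if np.any(sd <= 0):
            raise ValueError("replicate SDs must be positive")
        weights = 1.0 / sd ** 2

    t_max = float(times.max())
    if np.allclose(values, values[0]):
        return FitResult(s_b=s_b, s_a=0.0, t_d=0.0, rss=0.0,
                         s_a_ci=(0.0, 0.0), s_a_ci_linear=(0.0, 0.0),
                         degenerate=True)

    s_a, t_d, rss = _fit_once(times, values, weights, s_b, gamma, mu_per_min,
                              t_max, n_grid, refine=True)

    fitted = mrna_solution(times, s_b, s_a, t_d, gamma, mu_per_min)
    residuals = values - fitted

    # Linearized CI: t-interval from the Gauss-Newton covariance.
    s_a_ci_linear = _linearized_ci(times, weights, residuals, s_b, s_a, t_d,
                                   gamma, mu_per_min)

    if n_boot > 0:
        # Residual bootstrap.  Residuals are standardized by the fit weights
        # (so heteroscedastic data keep their per-point noise scale) and
        # leverage-adjusted by 1/sqrt(1 - h_ii) — raw fitted residuals are
        # shrunk by the fit and undercover at small n.  The interval is the
        # t-quantile times the bootstrap standard error, centred on the
        # estimate; percentile intervals of a handful of points are too
        # narrow at n ~ 8.
        from scipy import stats as _stats

        rng = np.random.default_rng(seed)
        n = len(values)
        sw = np.sqrt(weights)
        standardized = residuals * sw / np.sqrt(
            np.clip(1.0 - _leverages(times, weights, s_a, t_d, gamma,
                                     mu_per_min), 1e-3, None))
        boot = np.empty(n_boot)
        for b in range(n_boot):
            draw = rng.choice(standardized, size=n, replace=True)
            resampled = fitted + draw / sw
            boot[b], _, _ = _fit_once(times, resampled, weights, s_b, gamma,
                                      mu_per_min, t_max, n_grid, refine=False)
        half = _stats.t.ppf(0.975, max(n - 2, 1)) * float(np.std(boot, ddof=1))
        s_a_ci = (s_a - half, s_a + half)
    else:
        s_a_ci = s_a_ci_linear

    return FitResult(s_b=s_b, s_a=s_a, t_d=t_d, rss=rss, s_a_ci=s_a_ci,
                     s_a_ci_linear=s_a_ci_linear)


def _jacobian(times, weights, s_a, t_d, gamma, mu):
    k = mu + gamma
    dt = np.clip(times - t_d, 0.0, None)
    active = times >= t_d
    d_sa = np.where(active, -np.expm1(-k * dt) / k, 0.0)
    d_td = np.where(active, -s_a * np.exp(-k * dt), 0.0)
    return np.column_stack([d_sa, d_td]) * np.sqrt(weights)[:, None]


def _leverages(times, weights, s_a, t_d, gamma, mu):
    """Diagonal of the hat matrix of the linearized (weighted) fit."""
    J = _jacobian(times, weights, s_a, t_d, gamma, mu)
    JtJ = J.T @ J
    try:
        H = J @ np.linalg.solve(JtJ, J.T)
    except np.linalg.LinAlgError:
        return np.zeros(len(times))
    return np.clip(np.diag(H), 0.0, 0.999)


def _linearized_ci(times, weights, residuals, s_b, s_a, t_d, gamma, mu,
                   alpha: float = 0.05) -> tuple[float, float]:
    from scipy import stats

    J = _jacobian(times, weights, s_a, t_d, gamma, mu)
    dof = max(len(times) - 2, 1)
    sigma2 = float(np.sum(weights * residuals ** 2)) / dof
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ) * sigma2
        se = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        return (float("nan"), float("nan"))
    half = stats.t.ppf(1 - alpha / 2, dof) * se
    return (s_a - half, s_a + half)


def normalize_counts(counts, library_size: float, gene_length: float):
    """Convert raw read counts to (CPM, RPKM).

    CPM = counts * 1e6 / library_size; RPKM = CPM * 1e3 / gene_length.
    ``counts`` may be scalar or array-like.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if gene_length <= 0:
        raise ValueError("gene length must be positive")
    counts = np.asarray(counts, dtype=float)
    cpm = counts * 1e6 / library_size
    rpkm = cpm * 1e3 / gene_length
    if cpm.ndim == 0:
        return float(cpm), float(rpkm)
    return cpm, rpkm
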
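"""Worm-like-chain inference: persistence length and bending rigidity.

The worm-like chain (Kratky–Porod) model predicts, for a semiflexible
polymer of contour length L and persistence length P, a mean squared
end-to-end distance

    <R^2> = 2 P L (1 - (P/L) (1 - exp(-L/P))).

Fitting this expectation to measured (L, R^2) pairs by unweighted
nonlinear least squares yields the persistence length P of a fibril
population; the bending rigidity then follows as B = k_B T P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .traces import InvalidParameterError

__all__ = [
    "BOLTZMANN_J_PER_K",
    "WLCFitResult",
    "RigidityResult",
    "wlc_expected_r2",
    "fit_persistence_length",
    "bending_rigidity",
]

#: Exact SI Boltzmann constant (J/K).
BOLTZMANN_J_PER_K = 1.380649e-23

# Below this L/P the closed form loses precision to cancellation; switch
# to the series L^2 (1 - L/(3P) + ...).
_SERIES_CUTOFF = 1e-4


def wlc_expected_r2(p_um, l_um):
    """WLC mean squared end-to-end distance, um^2.

    Evaluates 2PL(1 - (P/L)(1 - e^{-L/P})). For L/P < 1e-4 the direct
    expression suffers catastrophic cancellation and the series
    L^2 (1 - L/(3P)) is used instead. Accepts scalars or arrays.

    Raises
    ------
    InvalidParameterError
        If any persistence length or contour length is non-positive.
    """
    p = np.asarray(p_um, dtype=float)
    l = np.asarray(l_um, dtype=float)
    if np.any(p <= 0) or np.any(l <= 0):
        raise InvalidParameterError("p_um and l_um must be positive")
    x = l / p
    with np.errstate(over="ignore"):
        direct = 2.0 * p * l * (1.0 + (p / l) * np.expm1(-x))
    series = l * l * (1.0 - x / 3.0)
    out = np.where(x < _SERIES_CUTOFF, series, direct)
    if np.isscalar(p_um) and np.isscalar(l_um):
        return float(out)
    return out


@dataclass
class WLCFitResult:
    """Persistence-length fit with uncertainty and diagnostics.

    ``se_um`` and the CI come either from the linearized (Jacobian)
    approximation with a t(n-1) quantile, or from a percentile bootstrap
    over fibrils, according to ``ci_method``.
    """

    p_hat_um: float
    se_um: float
    ci95_lo_um: float
    ci95_hi_um: float
    n_fibrils: int
    rss_um4: float
    converged: bool
    ci_method: str
    at_bound: bool = False
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged and not (self.ci95_lo_um <= self.p_hat_um <= self.ci95_hi_um):
            raise ValueError("confidence interval does not bracket the estimate")


def _fit_once(L: np.ndarray, R2: np.ndarray, p0: float, bounds: tuple[float, float]):
    res = optimize.least_squares(
        lambda p: wlc_expected_r2(p[0], L) - R2,
        x0=[p0],
        bounds=([bounds[0]], [bounds[1]]),
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-10,
        max_nfev=500,
    )
    return res


def _wlc_dr2_dp(p: float, l: np.ndarray) -> np.ndarray:
    # d/dP of 2PL + 2P^2 (e^{-L/P} - 1)
    em = np.exp(-l / p)
    return 2.0 * l + 4.0 * p * (em - 1.0) + 2.0 * l * em


def _fit_once_fast(
    L: np.ndarray, R2: np.ndarray, p0: float, bounds: tuple[float, float]
) -> float:
    """Damped Gauss-Newton for the 1-parameter WLC objective.

    Same objective and tolerance as :func:`_fit_once`; used for bootstrap
    refits where the per-call overhead of the general optimizer dominates.
    """
    p = float(np.clip(p0, bounds[0], bounds[1]))
    rss = float(np.sum((wlc_expected_r2(p, L) - R2) ** 2))
    for _ in range(200):
        r = wlc_expected_r2(p, L) - R2
        j = _wlc_dr2_dp(p, L)
        denom = float(j @ j)
        if denom <= 0:
            break
        step = -float(j @ r) / denom
        # backtracking keeps the step inside the bounds and downhill
        lam = 1.0
        for _ in range(40):
            cand = float(np.clip(p + lam * step, bounds[0], bounds[1]))
            rss_new = float(np.sum((wlc_expected_r2(cand, L) - R2) ** 2))
            if rss_new <= rss:
                break
            lam *= 0.5
        else:
            break
        if abs(rss - rss_new) <= 1e-10 * max(rss, 1e-300) and abs(cand - p) <= 1e-12 * p:
            p = cand
            break
        p, rss = cand, rss_new
    return p


def fit_persistence_length(
    geometry,
    init: float | None = None,
    bounds: tuple[float, float] = (1e-3, 1e3),
    ci_method: str = "linearized",
    bootstrap_B: int = 1000,
    seed: int | None = None,
) -> WLCFitResult:
    """Fit the WLC expectation to (L, R^2) pairs by unweighted least squares.

    Parameters
    ----------
    geometry : pandas.DataFrame
        Must have columns ``contour_length_um`` and ``r2_um2`` (the output
        of :func:`fibriltools.geometry.measure_all`); at least 3 rows.
    init : float, optional
        Starting value for P in um. Defaults to the freely-jointed-chain
        moment estimate mean(R^2) / (2 mean(L)), clipped to ``bounds``.
    bounds : (lo, hi)
        Positivity box for P in um.
    ci_method : {"linearized", "bootstrap"}
        Linearized: SE from the Jacobian at the optimum with a t(n-1)
        quantile (what Matlab-style ``confint`` reports). Bootstrap:
        percentile interval over ``bootstrap_B`` fibril resamples.
    bootstrap_B : int
        Number of bootstrap refits (bootstrap method only).
    seed : int, optional
        Seed for the bootstrap resampling.

    Raises
    ------
    ValueError
        Fewer than 3 fibrils, rows violating R <= L, or unknown ci_method.
    """
    if ci_method not in ("linearized", "bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    L = np.asarray(geometry["contour_length_um"], dtype=float)
    R2 = np.asarray(geometry["r2_um2"], dtype=float)
    n = len(L)
    if n < 3:
        raise ValueError(f"need >=3 fibrils to fit, got {n}")
    if np.any(R2 > L * L * (1.0 + 1e-9)):
        raise ValueError("geometry contains rows with R > L")

    p0 = init if init is not None else float(np.mean(R2) / (2.0 * np.mean(L)))
    p0 = float(np.clip(p0, bounds[0], bounds[1]))
    res = _fit_once(L, R2, p0, bounds)
    p_hat = float(res.x[0])
    rss = float(2.0 * res.cost)
    at_bound = bool(
        p_hat <= bounds[0] * (1 + 1e-6) or p_hat >= bounds[1] * (1 - 1e-6)
    )

    tq = stats.t.ppf(0.975, n - 1)
    jtj = float((res.jac.T @ res.jac).reshape(()))
    if jtj > 0 and n > 1:
        se = float(np.sqrt(rss / (n - 1) / jtj))
    else:
        se = float("nan")

    if ci_method == "linearized":
        lo, hi = p_hat - tq * se, p_hat + tq * se
    else:
        rng = np.random.default_rng(seed)
        boot = np.empty(bootstrap_B)
        for b in range(bootstrap_B):
            idx = rng.integers(0, n, size=n)
            boot[b] = _fit_once_fast(L[idx], R2[idx], p_hat, bounds)
        lo, hi = (float(q) for q in np.percentile(boot, [2.5, 97.5]))

    return WLCFitResult(
        p_hat_um=p_hat,
        se_um=se,
        ci95_lo_um=min(lo, p_hat),
        ci95_hi_um=max(hi, p_hat),
        n_fibrils=n,
        rss_um4=rss,
        converged=bool(res.success),
        ci_method=ci_method,
        at_bound=at_bound,
        options={
            "init": p0,
            "bounds": list(bounds),
            "bootstrap_B": bootstrap_B if ci_method == "bootstrap" else None,
            "seed": seed,
        },
    )


def plot_fit(geometry, result: WLCFitResult, path) -> None:
    """Scatter of (L, R^2) with the fitted WLC expectation curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = np.asarray(geometry["contour_length_um"], dtype=float)
    R2 = np.asarray(geometry["r2_um2"], dtype=float)
    grid = np.linspace(L.min(), L.max(), 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(L, R2, "o", ms=3, alpha=0.6, label=f"fibrils (n = {result.n_fibrils})")
    ax.plot(grid, wlc_expected_r2(result.p_hat_um, grid), "r-",
            label=f"WLC fit, P = {result.p_hat_um:.2f} um")
    ax.set_xlabel("contour length L (um)")
    ax.set_ylabel("squared end-to-end distance R$^2$ (um$^2$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class RigidityResult:
    """Bending rigidity B = k_B T P with provenance of the inputs."""

    b_Nm2: float
    temperature_K: float
    boltzmann_JperK: float
    p_um: float
    se_b_Nm2: float | None = None


def bending_rigidity(
    p_um: float, temperature_K: float = 300.0, se_p_um: float | None = None
) -> RigidityResult:
    """Bending rigidity B = k_B T P (N m^2) from a persistence length in um.

    The standard error, when a persistence-length SE is given, propagates
    linearly: SE(B) = k_B T SE(P).
    """
    if p_um < 0:
        raise InvalidParameterError("persistence length must be non-negative")
    if temperature_K <= 0:
        raise InvalidParameterError("temperature must be positive")
    b = BOLTZMANN_J_PER_K * temperature_K * p_um * 1e-6
    se_b = None
    if se_p_um is not None:
        if se_p_um < 0:
            raise InvalidParameterError("se_p_um must be non-negative")
        se_b = BOLTZMANN_J_PER_K * temperature_K * se_p_um * 1e-6
    return RigidityResult(
        b_Nm2=b,
        temperature_K=temperature_K,
        boltzmann_JperK=BOLTZMANN_J_PER_K,
        p_um=p_um,
        se_b_Nm2=se_b,
    )
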
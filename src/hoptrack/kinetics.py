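"""Survival-curve and displacement-distribution mixture analysis.

Membrane dissociation kinetics are summarised by the survival curve
``S(t) = fraction of molecules still bound at time t after association``,
fitted with a sum of exponentials

    S(t) = sum_i A_i * exp(-k_i * t),        sum_i A_i ~ 1,

whose components define kinetic states occupied with relative frequency
``(A_i/k_i) / sum_j(A_j/k_j)``.  Lateral mobility is summarised by the
one-frame displacement distribution, fitted with a mixture of Rayleigh
components broadened by the localization error epsilon:

    p(r) = sum_i a_i * r/(2*(D_i*dt + eps^2)) * exp(-r^2 / (4*(D_i*dt + eps^2))).

Note the D <-> epsilon degeneracy of this model: the data constrain only
the combined variances ``D_i*dt + eps^2``, so the error term must be
supplied externally (the standard route is the intercept of the
mean-square displacement, see :func:`localization_error_from_msd`); the
observable floor on D is ``eps^2/dt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import TrackSet

__all__ = [
    "SurvivalCurve",
    "ExpMixtureFit",
    "DiffusionMixtureFit",
    "survival_curve",
    "survival_from_lifetimes",
    "sample_exp_mixture_lifetimes",
    "fit_exp_mixture",
    "compare_exp_models",
    "state_frequencies",
    "displacement_distribution",
    "sample_displacements",
    "fit_diffusion_mixture",
    "localization_error_from_msd",
    "tail_probability",
    "fit_hopping_lifetime",
]


@dataclass
class SurvivalCurve:
    """Fraction of molecules surviving to each multiple of the frame time."""

    times: np.ndarray  # seconds, m * dt for m = 0, 1, ...
    fraction: np.ndarray  # S(t), monotone non-increasing, S(0) = 1
    counts: np.ndarray  # number of molecules with lifetime >= t

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.counts = np.asarray(self.counts)


def survival_from_lifetimes(lifetimes: np.ndarray, dt: float) -> SurvivalCurve:
    """Survival curve ``S(m*dt) = #(lifetime >= m*dt) / N`` from lifetimes (s)."""
    lifetimes = np.asarray(lifetimes, dtype=float)
    if lifetimes.size == 0:
        raise ValueError("no lifetimes given")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m = np.round(lifetimes / dt).astype(int)
    m_max = int(m.max())
    grid = np.arange(m_max + 1)
    counts = np.array([(m >= g).sum() for g in grid])
    return SurvivalCurve(grid * dt, counts / len(m), counts)


def survival_curve(trackset: TrackSet) -> SurvivalCurve:
    """Survival curve of the observed trajectory lifetimes."""
    if trackset.N0 == 0:
        raise ValueError("empty track set")
    return survival_from_lifetimes(trackset.lifetimes(), trackset.frame_interval)


def sample_exp_mixture_lifetimes(
    amplitudes, rates, n: int, dt: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw frame-quantized lifetimes from a multi-exponential mixture.

    Continuous dwell times are drawn from ``sum A_i Exp(k_i)`` (amplitudes
    are normalized to probabilities) and quantized downward to multiples of
    ``dt``, so that the resulting survival curve satisfies
    ``S(m*dt) = sum_i A_i exp(-k_i * m * dt)`` exactly in expectation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = np.asarray(amplitudes, dtype=float)
    k = np.asarray(rates, dtype=float)
    comp = rng.choice(len(A), size=n, p=A / A.sum())
    t = rng.exponential(1.0 / k[comp])
    return np.floor(t / dt) * dt


def _exp_model(t: np.ndarray, A: np.ndarray, k: np.ndarray) -> np.ndarray:
    return np.exp(-np.outer(t, k)) @ A


def fit_exp_mixture(
    curve: SurvivalCurve, n: int, n_starts: int = 6
) -> "ExpMixtureFit":
    """Least-squares multi-exponential fit of a survival curve.

    Uses multi-start nonlinear least squares with log-spaced rate
    initializations; for each rate guess the amplitudes are seeded by
    non-negative linear least squares.  Components are returned sorted by
    ascending rate.  Amplitudes are free (not constrained to sum to 1);
    on a curve anchored at S(0)=1 they sum to ~1 by construction.
    """
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    t = curve.times
    S = curve.fraction
    if len(t) <= 3 * n:
        raise ValueError(f"need more than {3 * n} curve points to fit n={n}")
    dt = t[1] - t[0] if len(t) > 1 else 0.033
    k_slow = max(0.5 / t[-1], 1e-4)
    k_fast = 1.0 / dt

    def residual(params):
        A = params[:n]
        k = np.exp(params[n:])
        return _exp_model(t, A, k) - S

    best = None
    for factor in np.geomspace(0.2, 5.0, n_starts):
        k0 = np.geomspace(k_slow, k_fast * 0.5, n) * factor if n > 1 else np.array(
            [np.sqrt(k_slow * k_fast) * factor]
        )
        basis = np.exp(-np.outer(t, k0))
        A0, _ = optimize.nnls(basis, S)
        A0 = np.where(A0 > 1e-6, A0, 1.0 / n)
        x0 = np.concatenate([A0, np.log(k0)])
        try:
            res = optimize.least_squares(
                residual,
                x0,
                bounds=(
                    np.concatenate([np.zeros(n), np.full(n, np.log(1e-4))]),
                    np.concatenate([np.full(n, 2.0), np.full(n, np.log(1e4))]),
                ),
                max_nfev=2000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x)
    if best is None:
        raise RuntimeError(
            f"multi-exponential fit (n={n}) failed to converge from any of "
            f"{n_starts} log-spaced starts"
        )
    rss, x = best
    A = x[:n]
    k = np.exp(x[n:])
    order = np.argsort(k)
    A, k = A[order], k[order]
    degenerate = bool(
        np.any(A < 1e-3) or (n > 1 and np.any(k[1:] / np.maximum(k[:-1], 1e-12) < 1.2))
    )
    return ExpMixtureFit(n=n, amplitudes=A, rates=k, rss=rss, degenerate=degenerate)


@dataclass
class ExpMixtureFit:
    """Fitted multi-exponential survival model, components sorted by rate.

    ``degenerate`` flags fits where a component's amplitude collapsed to
    ~0 or two rates nearly merged (typical when n exceeds the number of
    resolvable states).
    """

    n: int
    amplitudes: np.ndarray
    rates: np.ndarray
    rss: float
    degenerate: bool = False

    def __call__(self, t) -> np.ndarray:
        return _exp_model(np.atleast_1d(np.asarray(t, dtype=float)),
                          self.amplitudes, self.rates)


def compare_exp_models(curve: SurvivalCurve, ns=(1, 2, 3)) -> dict[int, float]:
    """Residual sum of squares per component count (model-choice metric)."""
    out = {}
    for n in ns:
        try:
            out[n] = fit_exp_mixture(curve, n).rss
        except (ValueError, RuntimeError):
            out[n] = np.nan
    return out


def state_frequencies(fit: ExpMixtureFit) -> np.ndarray:
    """Relative state occupancies ``A_i/k_i`` as integer percentages."""
    if np.any(fit.rates == 0):
        raise ValueError("state frequencies undefined for a zero rate constant")
    w = fit.amplitudes / fit.rates
    return np.round(100.0 * w / w.sum()).astype(int)


def displacement_distribution(trackset: TrackSet, lag: int = 1) -> np.ndarray:
    """All per-trajectory scalar displacements at the given frame lag (µm).

    Honours the track set's geometry (minimum-image distances on a
    periodic simulation domain).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    geom = trackset.geometry
    parts = []
    for t in trackset:
        if t.n_frames <= lag:
            continue
        if geom is not None:
            dx, dy = geom.separation(t.x[:-lag], t.y[:-lag], t.x[lag:], t.y[lag:])
            parts.append(np.hypot(dx, dy))
        else:
            parts.append(t.displacements(lag))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def sample_displacements(
    weights, diffusion_coeffs, n: int, dt: float, epsilon: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw 2D scalar displacements from a diffusion mixture.

    Per-axis displacement variance for component i is
    ``2*D_i*dt + 2*eps^2`` (diffusion plus localization error at both
    endpoints), matching the fitted density's combined variance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(weights, dtype=float)
    D = np.asarray(diffusion_coeffs, dtype=float)
    comp = rng.choice(len(a), size=n, p=a / a.sum())
    sd = np.sqrt(2.0 * D[comp] * dt + 2.0 * epsilon**2)
    dx = rng.normal(0.0, sd)
    dy = rng.normal(0.0, sd)
    return np.hypot(dx, dy)


@dataclass
class DiffusionMixtureFit:
    """Fitted displacement-distribution mixture, sorted by ascending D."""

    n: int
    weights: np.ndarray  # a_i, sum to 1
    diffusion_coeffs: np.ndarray  # µm²/s
    epsilon: float  # µm
    dt: float
    rss: float

    @property
    def observable_floor(self) -> float:
        """Smallest resolvable diffusion coefficient, eps^2/dt."""
        return self.epsilon**2 / self.dt

    def pdf(self, r) -> np.ndarray:
        r = np.atleast_1d(np.asarray(r, dtype=float))
        s = self.diffusion_coeffs * self.dt + self.epsilon**2
        return (self.weights[None, :] * r[:, None] / (2 * s[None, :])
                * np.exp(-r[:, None] ** 2 / (4 * s[None, :]))).sum(axis=1)


def fit_diffusion_mixture(
    displacements: np.ndarray,
    n: int,
    dt: float,
    epsilon: float | None = 0.0,
    bin_width: float = 0.001,
    n_starts: int = 6,
) -> DiffusionMixtureFit:
    """Least-squares mixture fit of the displacement distribution.

    The empirical distribution is binned at ``bin_width`` (µm) and the
    density fitted with the n-component model, with residuals weighted by
    the Poisson uncertainty of each bin (a plain chi-square histogram
    fit); without the weighting the dense small-r bins drown out the far
    tail and the smallest component becomes unidentifiable.  ``epsilon``
    is the localization error in µm; pass the externally measured value
    (or 0).  ``epsilon=None`` co-fits a shared error term, but note that
    it is degenerate with a common shift of all D_i and therefore only
    weakly identified.
    """
    r = np.asarray(displacements, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 10 * n:
        raise ValueError("too few displacements for a mixture fit")
    if np.all(r == 0):
        raise ValueError("degenerate displacement distribution (all zero)")
    if dt <= 0 or bin_width <= 0:
        raise ValueError("dt and bin_width must be > 0")
    edges = np.arange(0.0, r.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(r, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (r.size * bin_width)
    # Poisson uncertainty per bin (+1 regularizes empty tail bins)
    sigma = np.sqrt(counts + 1.0) / (r.size * bin_width)
    fit_eps = epsilon is None
    eps_fixed = 0.0 if fit_eps else float(epsilon)

    def unpack(params):
        w = params[:n] ** 2
        D = np.exp(params[n:2 * n])
        eps = params[-1] if fit_eps else eps_fixed
        return w, D, eps

    def residual(params):
        w, D, eps = unpack(params)
        s = D * dt + eps**2
        model = (w[None, :] * centers[:, None] / (2 * s[None, :])
                 * np.exp(-centers[:, None] ** 2 / (4 * s[None, :]))).sum(axis=1)
        return (model - density) / sigma

    mean_sq = float(np.mean(r**2))
    s_typ = mean_sq / 4.0  # single-component scale
    D_typ = max((s_typ - eps_fixed**2) / dt, 1e-5)
    best = None
    for factor in np.geomspace(0.2, 5.0, n_starts):
        D0 = (np.geomspace(D_typ / 10, D_typ * 10, n) * factor
              if n > 1 else np.array([D_typ * factor]))
        x0 = np.concatenate([
            np.full(n, np.sqrt(1.0 / n)),
            np.log(D0),
            [0.02] if fit_eps else [],
        ])
        lo = np.concatenate([np.zeros(n), np.full(n, np.log(1e-7)),
                             [0.0] if fit_eps else []])
        hi = np.concatenate([np.full(n, 2.0), np.full(n, np.log(1e3)),
                             [0.2] if fit_eps else []])
        try:
            res = optimize.least_squares(residual, x0, bounds=(lo, hi), max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x)
    if best is None:
        raise RuntimeError(f"diffusion mixture fit (n={n}) failed to converge")
    rss, x = best
    w, D, eps = unpack(x)
    a = w / w.sum()
    order = np.argsort(D)
    return DiffusionMixtureFit(
        n=n, weights=a[order], diffusion_coeffs=D[order],
        epsilon=float(eps), dt=dt, rss=rss,
    )


def localization_error_from_msd(trackset: TrackSet, max_lag: int = 4) -> float:
    """Localization error (µm) from the MSD intercept.

    Fits ``MSD(lag) = 4*D*lag*dt + 4*eps^2`` to the ensemble mean-square
    displacement at lags 1..max_lag and returns eps.
    """
    lags = np.arange(1, max_lag + 1)
    msd = []
    for lag in lags:
        disp = displacement_distribution(trackset, lag=int(lag))
        if disp.size == 0:
            raise ValueError(f"no displacements at lag {lag}")
        msd.append(np.mean(disp**2))
    slope, intercept = np.polyfit(lags * trackset.frame_interval, msd, 1)
    return float(np.sqrt(max(intercept, 0.0) / 4.0))


def tail_probability(fit: DiffusionMixtureFit, r0: float) -> float:
    """Probability of a one-frame displacement larger than ``r0`` (µm).

    Closed-form tail of the fitted mixture:
    ``sum_i a_i exp(-r0^2 / (4*(D_i*dt + eps^2)))``.
    """
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    s = fit.diffusion_coeffs * fit.dt + fit.epsilon**2
    return float(np.sum(fit.weights * np.exp(-(r0**2) / (4 * s))))


def fit_hopping_lifetime(
    lifetimes: np.ndarray, dt: float = 0.033
) -> tuple[float, float]:
    """Single-exponential fit ``A*exp(-k*t)`` of the chain-lifetime survival.

    ``lifetimes`` are hop-chain durations in seconds (multiples of the
    frame interval).  Returns (A, k) from a least-squares fit of the
    normalized cumulative survival plot.
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    if lifetimes.size < 2 or np.all(lifetimes == lifetimes[0]):
        raise ValueError("need at least two distinct chain lifetimes")
    curve = survival_from_lifetimes(lifetimes, dt)

    def residual(params):
        A, logk = params
        return A * np.exp(-np.exp(logk) * curve.times) - curve.fraction

    mean_lt = max(float(lifetimes.mean()), dt / 10)
    best = None
    for k0 in (0.5 / mean_lt, 1.0 / mean_lt, 2.0 / mean_lt):
        res = optimize.least_squares(residual, x0=[1.0, np.log(k0)], max_nfev=1000)
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x)
    if best is None:
        raise RuntimeError("hopping-lifetime fit failed to converge")
    A, logk = best[1]
    return float(A), float(np.exp(logk))
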
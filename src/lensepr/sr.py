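"""Saturation-recovery (SR) EPR kinetics: simulation and exponential fitting.

After a saturating microwave pulse, the EPR signal of a nitroxide spin label
recovers with the spin-lattice relaxation time T1.  In a homogeneous lipid
environment the recorded recovery is single-exponential,

    I(t) = baseline + I_o * exp(-t / T1),

and in a sample where the label distributes over two coexisting lipid
environments (e.g. the bulk phospholipid bilayer and a pure-cholesterol
bilayer domain) it is double-exponential,

    I(t) = baseline + I_o1 * exp(-t / T11) + I_o2 * exp(-t / T12),

with T11 > T12 by convention.  This module provides a seeded forward
simulator for such decays, least-squares fits for both models with
covariance-based standard errors, and model selection between them by the
corrected Akaike information criterion (AICc).

Signals are stored as decays toward a baseline.  Rising recovery curves
must be inverted on import (I <- I(inf) - I(t)).  Times are in microseconds
(us) throughout; rates in 1/us.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SRDecay",
    "SRFitResult",
    "FitError",
    "default_time_grid",
    "simulate_sr_decay",
    "fit_single",
    "fit_double",
    "select_model",
    "relaxation_rate",
    "aicc",
]

#: minimum ratio of recovered time constants below which a two-component
#: fit is flagged degenerate
DEGENERACY_RATIO = 1.05
#: minimum amplitude fraction of either component in a non-degenerate fit
MIN_AMP_FRACTION = 0.02
#: AICc improvement required to accept the two-component model
AICC_THRESHOLD = 10.0


class FitError(RuntimeError):
    """Raised when a fit does not converge; carries the best iterate."""

    def __init__(self, message: str, best: "SRFitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SRDecay:
    """One saturation-recovery record: time grid (us) and signal amplitude."""

    t: np.ndarray
    intensity: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("t and intensity must be 1-D arrays of equal length")
        if t.size < 16:
            raise ValueError(f"decay too short: {t.size} points (need >= 16)")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("t must be non-negative and strictly increasing")


@dataclass(frozen=True)
class SRFitResult:
    """Fitted exponential recovery model.

    ``params``/``se`` map parameter names to estimates and covariance-based
    standard errors.  Single-component names: I_o, T1, baseline.
    Two-component names: I_o1, T11, I_o2, T12, baseline, ordered so that
    T11 > T12.
    """

    n_components: int
    params: Mapping[str, float]
    se: Mapping[str, float]
    rss: float
    aicc: float
    n_points: int
    converged: bool = True
    degenerate: bool = False
    cov: np.ndarray | None = None

    @property
    def T1(self) -> float:
        return self.params["T1" if self.n_components == 1 else "T11"]

    def times(self) -> tuple[float, ...]:
        if self.n_components == 1:
            return (self.params["T1"],)
        return (self.params["T11"], self.params["T12"])

    def amplitudes(self) -> tuple[float, ...]:
        if self.n_components == 1:
            return (self.params["I_o"],)
        return (self.params["I_o1"], self.params["I_o2"])


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for Gaussian least squares.

    ``k`` counts the fitted mean parameters; the noise variance adds one.
    """
    k_eff = k + 1
    if n - k_eff - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k_eff + (
        2 * k_eff * (k_eff + 1) / (n - k_eff - 1)
    )


def default_time_grid(longest_T1: float, n_points: int = 2048) -> np.ndarray:
    """Uniform acquisition grid spanning five times the longest T1."""
    if longest_T1 <= 0:
        raise ValueError("longest_T1 must be positive")
    return np.linspace(0.0, 5.0 * longest_T1, n_points)


def simulate_sr_decay(
    components: Sequence[tuple[float, float]],
    baseline: float = 0.0,
    t_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    meta: Mapping[str, object] | None = None,
) -> SRDecay:
    """Simulate a (multi)exponential SR decay with additive Gaussian noise.

    Parameters
    ----------
    components
        Sequence of ``(I_o, T1)`` pairs, amplitudes in arbitrary units and
        time constants in us; all must be positive.
    baseline
        Constant offset the signal decays toward.
    t_grid
        Time grid in us; defaults to 2048 uniform points over five times
        the longest T1.
    noise_sd
        SD of i.i.d. additive Gaussian noise, in amplitude units.
    seed
        Seed or ``numpy.random.Generator``; fixed seed gives a bitwise
        reproducible series.
    """
    if not components:
        raise ValueError("need at least one component")
    for i_o, t1 in components:
        if t1 <= 0:
            raise ValueError(f"non-positive T1: {t1}")
        if i_o <= 0:
            raise ValueError(f"non-positive amplitude: {i_o}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if t_grid is None:
        t_grid = default_time_grid(max(t1 for _, t1 in components))
    t = np.asarray(t_grid, dtype=float)
    y = np.full_like(t, float(baseline))
    for i_o, t1 in components:
        y += i_o * np.exp(-t / t1)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return SRDecay(t=t, intensity=y, meta=dict(meta or {}))


def _model_single(t, i_o, t1, baseline):
    return baseline + i_o * np.exp(-t / t1)


def _model_double(t, i_o1, t11, i_o2, t12, baseline):
    return baseline + i_o1 * np.exp(-t / t11) + i_o2 * np.exp(-t / t12)


def _init_single(decay: SRDecay, fix_baseline: float | None):
    """Log-linear initial guess on the baseline-subtracted tail."""
    t, y = decay.t, decay.intensity
    base0 = float(np.mean(y[-max(4, len(y) // 20):])) if fix_baseline is None else fix_baseline
    z = y - base0
    pos = z > max(1e-12, 1e-3 * max(z.max(), 1e-12))
    if pos.sum() >= 4:
        # weighted by z so early (high-SNR) points dominate
        slope, intercept = np.polyfit(t[pos], np.log(z[pos]), 1, w=z[pos])
        t1_0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3
        i_o0 = float(np.exp(intercept))
    else:
        t1_0 = (t[-1] - t[0]) / 3
        i_o0 = max(float(z[0]), 1e-6)
    t1_0 = float(np.clip(t1_0, 1e-4 * (t[-1] - t[0] + 1e-12), 100 * (t[-1] - t[0])))
    return max(i_o0, 1e-9), t1_0, base0


def _finish(
    popt, pcov, names, n_components, rss, n, converged, degenerate=False
) -> SRFitResult:
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    params = dict(zip(names, (float(p) for p in popt)))
    se = dict(zip(names, (float(s) for s in perr)))
    return SRFitResult(
        n_components=n_components,
        params=params,
        se=se,
        rss=float(rss),
        aicc=aicc(rss, n, len(names)),
        n_points=n,
        converged=converged,
        degenerate=degenerate,
        cov=pcov,
    )


def fit_single(decay: SRDecay, fix_baseline: float | None = None) -> SRFitResult:
    """Least-squares single-exponential fit: I(t) = baseline + I_o exp(-t/T1).

    The baseline is free by default; pass ``fix_baseline=0`` for the strict
    offset-free model.  Standard errors come from the residual-scaled fit
    covariance.
    """
    t, y = decay.t, decay.intensity
    i_o0, t1_0, base0 = _init_single(decay, fix_baseline)
    if fix_baseline is None:
        def f(tt, i_o, t1, b):
            return _model_single(tt, i_o, t1, b)
        p0 = [i_o0, t1_0, base0]
        bounds = ([0, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
        names = ["I_o", "T1", "baseline"]
    else:
        def f(tt, i_o, t1):
            return _model_single(tt, i_o, t1, fix_baseline)
        p0 = [i_o0, t1_0]
        bounds = ([0, 1e-12], [np.inf, np.inf])
        names = ["I_o", "T1"]
    try:
        popt, pcov = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"single-exponential fit did not converge: {exc}") from exc
    resid = y - f(t, *popt)
    rss = float(resid @ resid)
    res = _finish(popt, pcov, names, 1, rss, len(t), True)
    if fix_baseline is not None:
        params = dict(res.params, baseline=fix_baseline)
        se = dict(res.se, baseline=0.0)
        res = SRFitResult(
            n_components=1, params=params, se=se, rss=res.rss, aicc=res.aicc,
            n_points=res.n_points, converged=True, cov=res.cov,
        )
    return res


#: time-constant ratios explored by the two-component multi-start
MULTISTART_RATIOS = (2.0, 3.0, 5.0, 8.0, 12.0)


def fit_double(decay: SRDecay, fix_baseline: float | None = None) -> SRFitResult:
    """Least-squares double-exponential fit with multi-start initialization.

    Starting points place the two time constants at ratios 2, 3, 5, 8 and 12
    around the single-exponential estimate; the best converged start (lowest
    residual sum of squares) wins.  Components are relabelled so T11 > T12.
    A fit whose time constants collapse (T11/T12 < 1.05) or whose minor
    amplitude fraction falls below 2% is flagged ``degenerate``.
    """
    t, y = decay.t, decay.intensity
    single = fit_single(decay, fix_baseline=fix_baseline)
    i_tot = single.params["I_o"]
    t1_s = single.params["T1"]
    base0 = single.params["baseline"]

    if fix_baseline is None:
        def f(tt, i1, t11, i2, t12, b):
            return _model_double(tt, i1, t11, i2, t12, b)
        bounds = ([0, 1e-12, 0, 1e-12, -np.inf], [np.inf] * 5)
        names = ["I_o1", "T11", "I_o2", "T12", "baseline"]
    else:
        def f(tt, i1, t11, i2, t12):
            return _model_double(tt, i1, t11, i2, t12, fix_baseline)
        bounds = ([0, 1e-12, 0, 1e-12], [np.inf] * 4)
        names = ["I_o1", "T11", "I_o2", "T12"]

    best = None
    last_err: Exception | None = None
    for ratio in MULTISTART_RATIOS:
        s = np.sqrt(ratio)
        p0 = [i_tot / 2, t1_s * s, i_tot / 2, t1_s / s]
        if fix_baseline is None:
            p0.append(base0)
        try:
            popt, pcov = curve_fit(f, t, y, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError as exc:
            last_err = exc
            continue
        resid = y - f(t, *popt)
        rss = float(resid @ resid)
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError(
            f"double-exponential fit failed from all starts: {last_err}",
            best=single,
        )
    popt, pcov, rss = best

    # relabel so the slower component comes first
    if popt[1] < popt[3]:
        order = [2, 3, 0, 1] + ([4] if fix_baseline is None else [])
        popt = popt[order]
        pcov = pcov[np.ix_(order, order)]

    t11, t12 = popt[1], popt[3]
    a1, a2 = popt[0], popt[2]
    amp_tot = a1 + a2
    degenerate = (
        t12 <= 0
        or t11 / max(t12, 1e-300) < DEGENERACY_RATIO
        or min(a1, a2) / max(amp_tot, 1e-300) < MIN_AMP_FRACTION
    )
    res = _finish(popt, pcov, names, 2, rss, len(t), True, degenerate)
    if fix_baseline is not None:
        params = dict(res.params, baseline=fix_baseline)
        se = dict(res.se, baseline=0.0)
        res = SRFitResult(
            n_components=2, params=params, se=se, rss=res.rss, aicc=res.aicc,
            n_points=res.n_points, converged=True, degenerate=degenerate,
            cov=res.cov,
        )
    return res


def select_model(
    decay: SRDecay,
    fix_baseline: float | None = None,
    aicc_threshold: float = AICC_THRESHOLD,
) -> tuple[int, SRFitResult, SRFitResult | None]:
    """Choose between one and two recovery components.

    The two-component model is accepted only when it improves AICc by more
    than ``aicc_threshold`` over the single-component fit *and* is not
    degenerate.  Returns ``(n_components, single_fit, double_fit)``; the
    double fit is None when it failed outright.
    """
    single = fit_single(decay, fix_baseline=fix_baseline)
    try:
        double = fit_double(decay, fix_baseline=fix_baseline)
    except FitError:
        return 1, single, None
    accept_two = (
        not double.degenerate
        and single.aicc - double.aicc > aicc_threshold
    )
    return (2 if accept_two else 1), single, double


def relaxation_rate(
    fit: SRFitResult, component: int = 1
) -> tuple[float, float]:
    """Spin-lattice relaxation rate 1/T1 (1/us) with propagated error.

    ``component`` selects T1 (single fit) or T11/T12 (two-component fit,
    1 = slower, 2 = faster).  SE(rate) = SE(T1) / T1**2 to first order.
    """
    if fit.n_components == 1:
        if component != 1:
            raise ValueError("single-component fit has only component 1")
        name = "T1"
    else:
        if component not in (1, 2):
            raise ValueError("component must be 1 or 2")
        name = "T11" if component == 1 else "T12"
    t1 = fit.params[name]
    se = fit.se[name]
    return 1.0 / t1, se / t1**2
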
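"""Spin-label oximetry: the oxygen transport parameter and CBD discrimination.

Collisions with paramagnetic molecular oxygen shorten the spin-lattice
relaxation time of a nitroxide.  Comparing T1 measured under air with T1
measured under nitrogen yields the oxygen transport parameter (OTP)

    W = 1/T1(air) - 1/T1(N2)        [1/us],

proportional to the local oxygen diffusion-concentration product at the
nitroxide depth — a probe of membrane fluidity.

When cholesterol exceeds its saturation limit, pure-cholesterol bilayer
domains (CBDs) coexist with the bulk phospholipid bilayer.  An androstane
spin label (ASL) at the membrane center then shows a double-exponential
air recovery — one component per environment ("discrimination by oxygen
transport") — and the component with the smaller W is assigned to the CBD.
A cholestane label (CSL) in the headgroup region cannot discriminate; its
reading is the population-weighted average of the environment OTPs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sr import SRDecay, SRFitResult, fit_single, fit_double, select_model, relaxation_rate

__all__ = [
    "OTPMeasurement",
    "TitrationPoint",
    "TitrationSeries",
    "TitrationResult",
    "compute_otp",
    "otp_from_decays",
    "discriminate_domains",
    "averaged_otp",
    "detect_cbd_onset",
]


@dataclass(frozen=True)
class OTPMeasurement:
    """Oxygen transport parameter at one membrane depth.

    ``environment`` labels which lipid environment the value belongs to:
    the bulk PL bilayer, a CBD, a population average (CSL), or unassigned.
    """

    W: float
    T1_air: float
    T1_n2: float
    se_W: float = 0.0
    depth_position: str | None = None
    spin_label: str | None = None
    environment: str = "unassigned"

    def __post_init__(self) -> None:
        if self.environment not in ("bulk", "CBD", "averaged", "unassigned"):
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.W < 0:
            raise ValueError(f"W must be >= 0, got {self.W}")


def compute_otp(
    T1_air: float,
    T1_n2: float,
    se_air: float = 0.0,
    se_n2: float = 0.0,
    **labels,
) -> OTPMeasurement:
    """W = 1/T1(air) - 1/T1(N2) with first-order error propagation.

    A small negative W (within 3 SE of zero) is clamped to 0 with a warning;
    a clearly negative W is a physical impossibility and raises.
    """
    if T1_air <= 0 or T1_n2 <= 0:
        raise ValueError("T1 values must be positive")
    w = 1.0 / T1_air - 1.0 / T1_n2
    se_w = math.hypot(se_air / T1_air**2, se_n2 / T1_n2**2)
    if w < 0:
        if w < -3 * se_w:
            raise ValueError(
                f"air relaxation slower than nitrogen (W = {w:.4g} 1/us)"
            )
        warnings.warn(
            f"W = {w:.4g} 1/us slightly negative; clamped to 0", stacklevel=2
        )
        w = 0.0
    return OTPMeasurement(W=w, T1_air=T1_air, T1_n2=T1_n2, se_W=se_w, **labels)


def otp_from_decays(
    decay_air: SRDecay,
    decay_n2: SRDecay,
    fix_baseline: float | None = 0.0,
    **labels,
) -> OTPMeasurement:
    """Fit both single-exponential decays and form the OTP.

    The baseline is pinned to 0 by default (the strict decaying-exponential
    model): a free offset trades off strongly against slow components and
    inflates the rate variance.  Pass ``fix_baseline=None`` for data with a
    genuine unknown offset.
    """
    fa = fit_single(decay_air, fix_baseline=fix_baseline)
    fn = fit_single(decay_n2, fix_baseline=fix_baseline)
    return compute_otp(
        fa.params["T1"], fn.params["T1"], fa.se["T1"], fn.se["T1"], **labels
    )


def discriminate_domains(
    fit_air: SRFitResult,
    fit_n2: SRFitResult,
    depth_position: str | None = None,
    spin_label: str = "ASL",
) -> tuple[OTPMeasurement, OTPMeasurement]:
    """Split a two-component air recovery into bulk and CBD OTP values.

    The nitrogen-atmosphere recovery is usually single-exponential (the
    oxygen-free rates of the two environments are taken as equal at the
    membrane center); when it is two-component, air and nitrogen components
    are paired by rank of relaxation rate.  Of the two W values the smaller
    is assigned to the CBD.  If the two W confidence intervals overlap both
    measurements come back ``environment='unassigned'``.

    Returns ``(bulk, cbd)`` ordered by assignment (first element carries the
    larger W even when unassigned).
    """
    if fit_air.n_components != 2:
        raise ValueError("air fit must have two components")
    rates_air = [relaxation_rate(fit_air, c) for c in (1, 2)]  # slow, fast
    if fit_n2.n_components == 1:
        rates_n2 = [relaxation_rate(fit_n2, 1)] * 2
    else:
        rates_n2 = [relaxation_rate(fit_n2, c) for c in (1, 2)]

    # rank pairing: slower air component with slower N2 component
    meas = []
    for (ra, sea), (rn, sen), c in zip(rates_air, rates_n2, (1, 2)):
        t1a = fit_air.params["T11" if c == 1 else "T12"]
        t1n = 1.0 / rn
        w = max(ra - rn, 0.0)
        se_w = math.hypot(sea, sen)
        meas.append((w, se_w, t1a, t1n))

    meas.sort(key=lambda m: m[0], reverse=True)  # larger W first
    (w_hi, se_hi, t1a_hi, t1n_hi), (w_lo, se_lo, t1a_lo, t1n_lo) = meas
    ambiguous = w_hi - se_hi <= w_lo + se_lo
    env_hi, env_lo = ("unassigned", "unassigned") if ambiguous else ("bulk", "CBD")
    bulk = OTPMeasurement(
        W=w_hi, T1_air=t1a_hi, T1_n2=t1n_hi, se_W=se_hi,
        depth_position=depth_position, spin_label=spin_label, environment=env_hi,
    )
    cbd = OTPMeasurement(
        W=w_lo, T1_air=t1a_lo, T1_n2=t1n_lo, se_W=se_lo,
        depth_position=depth_position, spin_label=spin_label, environment=env_lo,
    )
    return bulk, cbd


def averaged_otp(
    weights: Sequence[float], W_components: Sequence[OTPMeasurement | float]
) -> OTPMeasurement:
    """Population-weighted mean OTP, as reported by a non-discriminating label.

    ``W_components`` may be plain W values or OTPMeasurements; weights are
    population fractions and must sum to 1.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()!r}, expected 1")
    vals = np.array(
        [m.W if isinstance(m, OTPMeasurement) else float(m) for m in W_components]
    )
    ses = np.array(
        [m.se_W if isinstance(m, OTPMeasurement) else 0.0 for m in W_components]
    )
    if len(vals) != len(w):
        raise ValueError("weights and components must have equal length")
    wbar = float(w @ vals)
    se = float(np.sqrt(np.sum((w * ses) ** 2)))
    # harmonic bookkeeping values for the averaged rate are not meaningful;
    # store effective T1s consistent with the averaged W against a 1/us ref
    return OTPMeasurement(
        W=wbar, T1_air=1.0 / (wbar + 1.0), T1_n2=1.0, se_W=se,
        environment="averaged",
    )


@dataclass(frozen=True)
class TitrationPoint:
    """One Chol/PL mixing ratio in a titration: paired air/N2 decays."""

    ratio: float
    decay_air: SRDecay
    decay_n2: SRDecay


@dataclass(frozen=True)
class TitrationSeries:
    """Chol/PL titration of one spin label in one species model."""

    points: Sequence[TitrationPoint]
    spin_label: str = "ASL"
    species_label: str = ""

    def __post_init__(self) -> None:
        ratios = [p.ratio for p in self.points]
        if any(r < 0 for r in ratios):
            raise ValueError("mixing ratios must be >= 0")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("mixing ratios must be strictly increasing")


@dataclass(frozen=True)
class TitrationResult:
    onset_ratio: float | None
    n_components: Sequence[int]
    measurements: Mapping[float, tuple[OTPMeasurement, ...]] = field(
        default_factory=dict
    )


def detect_cbd_onset(
    series: TitrationSeries, fix_baseline: float | None = 0.0
) -> TitrationResult:
    """Find the Chol/PL mixing ratio at which CBDs appear.

    Each titration point's air-atmosphere recovery is model-selected; the
    onset is the smallest sampled ratio from which that point *and every
    later point* shows two components (persistence guards against single-
    point false positives).  Returns per-point component counts and OTP
    values for plotting; ``onset_ratio`` is None when the membrane never
    oversaturates.
    """
    if len(series.points) < 4:
        raise ValueError("need at least 4 titration points")
    if series.spin_label != "ASL":
        raise ValueError(
            "only ASL titrations can be domain-discriminated; "
            "model CSL series with averaged_otp"
        )
    ncomp: list[int] = []
    meas: dict[float, tuple[OTPMeasurement, ...]] = {}
    for pt in series.points:
        n, single_fit, double_fit = select_model(
            pt.decay_air, fix_baseline=fix_baseline
        )
        fn = fit_single(pt.decay_n2, fix_baseline=fix_baseline)
        ncomp.append(n)
        if n == 2 and double_fit is not None:
            meas[pt.ratio] = discriminate_domains(double_fit, fn)
        else:
            fa = single_fit
            meas[pt.ratio] = (
                compute_otp(
                    fa.params["T1"], fn.params["T1"], fa.se["T1"], fn.se["T1"],
                    spin_label=series.spin_label, environment="bulk",
                ),
            )
    onset = None
    for i in range(len(ncomp)):
        if all(n == 2 for n in ncomp[i:]):
            onset = series.points[i].ratio
            break
    return TitrationResult(
        onset_ratio=onset, n_components=tuple(ncomp), measurements=meas
    )
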
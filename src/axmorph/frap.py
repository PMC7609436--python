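"""FRAP recovery-curve analysis.

Fluorescence recovery after photobleaching reports molecular turnover at a
bleached membrane spot: mobile molecules exchange into the spot and the
intensity recovers along an exponential time course

    I(t) = plateau * (1 - exp(-k * t)),     t measured from the bleach,

where ``k`` (1/s) is the recovery rate and ``plateau`` (fraction of the
pre-bleach level) absorbs the immobile fraction.  Traces are normalized so
the mean pre-bleach intensity is 1 and the first post-bleach sample is 0,
which makes traces from different spots directly comparable.

The time to recover a given fraction of the plateau follows in closed form:
``t_f = -ln(1 - f) / k`` (e.g. t90 with f = 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FrapTrace",
    "RecoveryFit",
    "normalize_trace",
    "fit_exponential_recovery",
    "time_to_fraction",
    "moving_average",
]


@dataclass
class FrapTrace:
    """Time-stamped fluorescence of one bleached spot.

    ``bleach_index`` is the index of the first post-bleach sample.
    """

    times: np.ndarray  # seconds
    intensities: np.ndarray
    bleach_index: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.bleach_index < len(self.times):
            raise ValueError("bleach index out of range")

    @property
    def post_times(self) -> np.ndarray:
        """Times of the post-bleach samples, measured from the bleach."""
        return self.times[self.bleach_index :] - self.times[self.bleach_index]

    @property
    def post_intensities(self) -> np.ndarray:
        return self.intensities[self.bleach_index :]


@dataclass
class RecoveryFit:
    """Least-squares single-exponential recovery fit."""

    k: float  # 1/s
    plateau: float  # fraction of pre-bleach intensity
    residual_norm: float
    covariance: np.ndarray  # 2x2 covariance of (k, plateau)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.plateau * (1.0 - np.exp(-self.k * t))


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Affine rescale: mean pre-bleach -> 1, first post-bleach sample -> 0."""
    if trace.normalized:
        return trace
    if trace.bleach_index < 1 or len(trace.times) - trace.bleach_index < 2:
        raise ValueError("need >=1 pre-bleach and >=2 post-bleach samples")
    pre = float(trace.intensities[: trace.bleach_index].mean())
    bleach = float(trace.intensities[trace.bleach_index])
    if pre == bleach:
        raise ValueError("pre-bleach mean equals bleach value; cannot normalize")
    scaled = (trace.intensities - bleach) / (pre - bleach)
    return FrapTrace(
        times=trace.times.copy(),
        intensities=scaled,
        bleach_index=trace.bleach_index,
        normalized=True,
    )


def fit_exponential_recovery(trace: FrapTrace) -> RecoveryFit:
    """Fit I(t) = plateau * (1 - exp(-k t)) to the post-bleach samples.

    The rate is initialised from a log-linearisation of the early recovery
    and the plateau from the tail mean; k is bounded to (1e-5, 1) 1/s.
    """
    if not trace.normalized:
        trace = normalize_trace(trace)
    t = trace.post_times
    y = trace.post_intensities
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach samples")
    tail = float(np.mean(y[max(len(y) // 2, 1) :]))
    if np.ptp(y) < 1e-12 or tail <= 0:
        raise ValueError("flat or non-recovering trace: degenerate fit")

    # log-linearised initial rate from the early points: ln(1 - y/plateau) = -k t
    p0 = max(tail, 1e-3)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = 1.0 - y / p0
        ok = (z > 1e-6) & (t > 0)
    k0 = 0.01
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(z[ok]), 1)[0]
        if slope < 0:
            k0 = min(max(-slope, 1e-5), 1.0)

    def resid(p):
        k, plateau = p
        return plateau * (1.0 - np.exp(-k * t)) - y

    sol = least_squares(
        resid,
        x0=[k0, p0],
        bounds=([1e-5, 1e-6], [1.0, 1.2]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"recovery fit failed to converge: {sol.message}")
    # Gauss-Newton covariance estimate from the Jacobian at the solution
    dof = max(len(t) - 2, 1)
    s2 = 2.0 * sol.cost / dof
    JtJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return RecoveryFit(
        k=float(sol.x[0]),
        plateau=float(sol.x[1]),
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        covariance=cov,
    )


def time_to_fraction(
    fit: RecoveryFit, fraction: float = 0.9, reference: str = "plateau"
) -> float:
    """Smallest t with I(t) = fraction x reference level, in seconds.

    With ``reference="plateau"`` (default) this is the closed form
    ``-ln(1 - fraction) / k``.  With ``reference="prebleach"`` the fraction
    refers to the normalized pre-bleach level 1, so recovery to it requires
    ``fraction < plateau`` (otherwise the level is never reached).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if reference == "plateau":
        return float(-np.log1p(-fraction) / fit.k)
    if reference == "prebleach":
        if fraction >= fit.plateau:
            raise ValueError(
                f"recovery never reaches {fraction:.2f} of pre-bleach "
                f"(plateau = {fit.plateau:.3f})"
            )
        return float(-np.log1p(-fraction / fit.plateau) / fit.k)
    raise ValueError("reference must be 'plateau' or 'prebleach'")


def moving_average(series: np.ndarray, period: int = 3) -> np.ndarray:
    """Centred moving average, valid region only (output length n - period + 1).

    Period 3 is the default trendline used for recovery plots.
    """
    series = np.asarray(series, float)
    if series.ndim != 1:
        raise ValueError("expected a 1D series")
    if period < 1 or len(series) < period:
        raise ValueError("series shorter than the averaging period")
    kernel = np.full(period, 1.0 / period)
    return np.convolve(series, kernel, mode="valid")
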
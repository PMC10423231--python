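"""Lifetime-vs-crowding calibration and Trp spectra analysis.

The crowding axis is fractional volume occupancy (FVO, % of solution volume
occupied by crowder).  mCherry's mean fluorescence lifetime stays at its
dilute plateau up to an onset near 30% FVO and declines monotonically above
it; the onset is estimated with a two-segment (flat + linear decline)
changepoint regression.  Trp emission spectra are summarized by area and
lambda-max, and the area-vs-FVO transition is fitted with a logistic whose
midpoint localizes the fluorophore-environment transition (reported near
23.3% FVO for mCherry + PEG).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lmfit_minimize
from scipy import optimize
from sklearn.base import BaseEstimator

from .flim import CROWDING_BOUNDARY_NS

__all__ = [
    "CalibrationCurve",
    "EmissionSpectrum",
    "SigmoidFit",
    "OnsetFit",
    "fvo_from_concentration",
    "concentration_from_fvo",
    "detect_reduction_onset",
    "OnsetChangepointEstimator",
    "spectrum_area_and_lambda_max",
    "fit_sigmoid_transition",
    "SigmoidTransitionFitter",
    "classify_fvo_regime",
    "PEG_PARTIAL_SPECIFIC_VOLUME",
]

PEG_PARTIAL_SPECIFIC_VOLUME = 0.84
"""Partial specific volume of PEG in mL/g, used to convert % w/v to FVO."""


@dataclass
class CalibrationCurve:
    """Mean lifetime (ns) versus FVO (%) for one crowder."""

    fvo: np.ndarray
    mean_lifetime: np.ndarray
    lifetime_ci: np.ndarray | None = None  # (n, 2) per-point interval
    crowder: str = ""

    def __post_init__(self) -> None:
        self.fvo = np.asarray(self.fvo, dtype=float)
        self.mean_lifetime = np.asarray(self.mean_lifetime, dtype=float)
        if np.any(self.fvo < 0) or np.any(self.fvo > 100):
            raise ValueError("fvo must lie in [0, 100]")
        if np.any(np.diff(self.fvo) <= 0):
            raise ValueError("fvo must be strictly increasing")
        if self.fvo.shape != self.mean_lifetime.shape:
            raise ValueError("fvo and mean_lifetime must match")

    @classmethod
    def from_table(cls, table: pd.DataFrame, crowder: str = "") -> "CalibrationCurve":
        return cls(
            table["fvo_percent"].to_numpy(),
            table["mean_lifetime_ns"].to_numpy(),
            crowder=crowder,
        )


@dataclass
class EmissionSpectrum:
    """Fluorescence emission spectrum on a strictly increasing wavelength grid."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class SigmoidFit:
    """Logistic transition fit of area vs FVO."""

    midpoint: float
    steepness: float
    lower: float
    upper: float
    midpoint_stderr: float
    success: bool


@dataclass
class OnsetFit:
    """Two-segment changepoint fit of a calibration curve.

    ``onset`` is NaN (no-onset sentinel) when the curve is flat.
    """

    onset: float
    plateau: float
    slope: float
    ci: tuple[float, float] | None = None

    @property
    def detected(self) -> bool:
        return np.isfinite(self.onset)


def fvo_from_concentration(
    conc_percent_w_v: float | np.ndarray,
    partial_specific_volume: float = PEG_PARTIAL_SPECIFIC_VOLUME,
) -> float | np.ndarray:
    """Convert crowder concentration (% w/v) to fractional volume occupancy (%).

    FVO = concentration (g / 100 mL) * partial specific volume (mL/g),
    expressed in %, clamped to [0, 100].  With a partial specific volume of
    1.0 the FVO equals the % w/v numerically.
    """
    conc = np.asarray(conc_percent_w_v, dtype=float)
    if np.any(conc < 0) or partial_specific_volume <= 0:
        raise ValueError("concentration and partial specific volume must be nonnegative")
    out = np.clip(conc * partial_specific_volume, 0.0, 100.0)
    return float(out) if np.isscalar(conc_percent_w_v) else out


def concentration_from_fvo(
    fvo_percent: float | np.ndarray,
    partial_specific_volume: float = PEG_PARTIAL_SPECIFIC_VOLUME,
) -> float | np.ndarray:
    """Inverse of :func:`fvo_from_concentration`."""
    fvo = np.asarray(fvo_percent, dtype=float)
    if np.any(fvo < 0) or partial_specific_volume <= 0:
        raise ValueError("fvo and partial specific volume must be nonnegative")
    out = fvo / partial_specific_volume
    return float(out) if np.isscalar(fvo_percent) else out


def _piecewise_rss(c: float, x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares plateau and slope for a fixed changepoint c; returns
    (rss, plateau, slope)."""
    h = np.where(x > c, x - c, 0.0)
    # design: y = plateau + slope * h
    a = np.column_stack([np.ones_like(x), h])
    coef, rss, *_ = np.linalg.lstsq(a, y, rcond=None)
    resid = y - a @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


class OnsetChangepointEstimator(BaseEstimator):
    """Flat-plus-linear-decline changepoint regression on a calibration curve.

    The changepoint is profiled on a fine grid over the FVO range (linear
    sub-problems solved exactly), then refined continuously.  A curve whose
    best two-segment fit does not beat the flat model by ``min_f_ratio``
    (variance-ratio) returns the no-onset sentinel NaN.  ``bootstrap``
    residual resamples give a percentile confidence interval.

    Attributes: ``onset_``, ``plateau_``, ``slope_``, ``ci_``.
    """

    def __init__(
        self,
        grid_points: int = 400,
        bootstrap: int = 200,
        min_f_ratio: float = 3.0,
        seed: int = 0,
    ) -> None:
        self.grid_points = grid_points
        self.bootstrap = bootstrap
        self.min_f_ratio = min_f_ratio
        self.seed = seed

    def _point_estimate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        lo, hi = x[1], x[-2]
        grid = np.linspace(lo, hi, self.grid_points)
        rss = np.array([_piecewise_rss(c, x, y)[0] for c in grid])
        c0 = grid[int(np.argmin(rss))]
        span = (hi - lo) / self.grid_points * 2.0
        res = optimize.minimize_scalar(
            lambda c: _piecewise_rss(c, x, y)[0],
            bounds=(max(lo, c0 - span), min(hi, c0 + span)),
            method="bounded",
        )
        c_best = float(res.x) if res.fun <= rss.min() else float(c0)
        _, plateau, slope = _piecewise_rss(c_best, x, y)
        return c_best, plateau, slope

    def fit(self, fvo: np.ndarray, lifetime: np.ndarray) -> "OnsetChangepointEstimator":
        x = np.asarray(fvo, dtype=float)
        y = np.asarray(lifetime, dtype=float)
        if x.size < 5:
            raise ValueError("need at least 5 calibration points")
        c, plateau, slope = self._point_estimate(x, y)
        rss_piece = _piecewise_rss(c, x, y)[0]
        rss_flat = float(np.sum((y - y.mean()) ** 2))
        yscale = max(float(np.max(np.abs(y))), 1e-12)
        decline = -slope * (x[-1] - c)
        if slope >= 0 or decline < 1e-8 * yscale:
            flat = True
        elif rss_piece <= 1e-20 * yscale**2 * x.size:
            flat = False  # numerically perfect two-segment fit, real decline
        else:
            # variance-ratio comparison flat vs two-segment
            improvement = (rss_flat - rss_piece) / 2.0 / (rss_piece / max(x.size - 3, 1))
            flat = improvement < self.min_f_ratio
        if flat:
            self.onset_ = float("nan")
            self.plateau_ = float(y.mean())
            self.slope_ = 0.0
            self.ci_ = None
            return self
        self.onset_ = c
        self.plateau_ = plateau
        self.slope_ = slope
        if self.bootstrap > 0:
            rng = np.random.default_rng(self.seed)
            h = np.where(x > c, x - c, 0.0)
            fitted = plateau + slope * h
            resid = y - fitted
            boots = []
            for _ in range(self.bootstrap):
                yb = fitted + rng.choice(resid, size=resid.size, replace=True)
                cb, _, _ = self._point_estimate(x, yb)
                boots.append(cb)
            self.ci_ = (
                float(np.percentile(boots, 2.5)),
                float(np.percentile(boots, 97.5)),
            )
        else:
            self.ci_ = None
        return self

    def predict(self, fvo: np.ndarray) -> np.ndarray:
        x = np.asarray(fvo, dtype=float)
        if not np.isfinite(self.onset_):
            return np.full_like(x, self.plateau_)
        return self.plateau_ + self.slope_ * np.where(x > self.onset_, x - self.onset_, 0.0)


def detect_reduction_onset(
    curve: CalibrationCurve | pd.DataFrame,
    bootstrap: int = 200,
    seed: int = 0,
) -> OnsetFit:
    """Estimate the FVO at which the lifetime reduction trend begins.

    Two-segment least-squares changepoint fit (flat plateau, then linear
    decline); the onset is the breakpoint, with a residual-bootstrap 95%
    interval.  Returns a NaN onset for curves with no resolvable decline.
    """
    if isinstance(curve, pd.DataFrame):
        curve = CalibrationCurve.from_table(curve)
    est = OnsetChangepointEstimator(bootstrap=bootstrap, seed=seed)
    est.fit(curve.fvo, curve.mean_lifetime)
    return OnsetFit(est.onset_, est.plateau_, est.slope_, est.ci_)


def spectrum_area_and_lambda_max(
    spectrum: EmissionSpectrum, smooth: bool = False
) -> tuple[float, float]:
    """Trapezoidal area under the spectrum and the wavelength of its maximum.

    With ``smooth`` a 3-point moving average is applied before locating the
    maximum.  An all-zero spectrum returns area 0 and NaN lambda-max.
    """
    if spectrum.wavelength.size < 3:
        raise ValueError("need at least 3 spectral points")
    area = float(np.trapezoid(spectrum.intensity, spectrum.wavelength))
    if not np.any(spectrum.intensity > 0):
        return 0.0, float("nan")
    intensity = spectrum.intensity
    if smooth:
        kernel = np.ones(3) / 3.0
        intensity = np.convolve(intensity, kernel, mode="same")
    lam_max = float(spectrum.wavelength[int(np.argmax(intensity))])
    return area, lam_max


class SigmoidTransitionFitter(BaseEstimator):
    """Logistic fit y = lower + (upper - lower) / (1 + exp((x - midpoint) * steepness)).

    Positive steepness describes a decreasing transition (quenching); the
    fit accepts either sign.  Attributes: ``midpoint_``, ``steepness_``,
    ``lower_``, ``upper_``, ``midpoint_stderr_``, ``success_``.
    """

    def __init__(self) -> None:
        pass

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SigmoidTransitionFitter":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 5:
            raise ValueError("need at least 5 points")
        rng_span = max(float(y.max() - y.min()), 1e-12)
        decreasing = y[0] > y[-1]
        params = Parameters()
        params.add("lower", value=float(y.min()))
        params.add("upper", value=float(y.max()))
        params.add("midpoint", value=float(np.median(x)))
        k0 = 4.0 / max(float(x.max() - x.min()), 1e-12) * 4.0
        params.add("steepness", value=k0 if decreasing else -k0)

        def model(p: Parameters) -> np.ndarray:
            return p["lower"].value + (p["upper"].value - p["lower"].value) / (
                1.0 + np.exp((x - p["midpoint"].value) * p["steepness"].value)
            )

        out = lmfit_minimize(lambda p: model(p) - y, params, method="leastsq")
        p = out.params
        self.midpoint_ = float(p["midpoint"].value)
        self.steepness_ = float(p["steepness"].value)
        self.lower_ = float(min(p["lower"].value, p["upper"].value))
        self.upper_ = float(max(p["lower"].value, p["upper"].value))
        stderr = p["midpoint"].stderr
        self.midpoint_stderr_ = float(stderr) if stderr is not None else float("nan")
        self.success_ = bool(out.success)
        self._params = {k: float(v.value) for k, v in p.items()}
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        pr = self._params
        return pr["lower"] + (pr["upper"] - pr["lower"]) / (
            1.0 + np.exp((x - pr["midpoint"]) * pr["steepness"])
        )


def fit_sigmoid_transition(x, y) -> SigmoidFit:
    """Fit the logistic transition of Trp-spectrum area versus FVO."""
    est = SigmoidTransitionFitter()
    est.fit(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return SigmoidFit(
        midpoint=est.midpoint_,
        steepness=est.steepness_,
        lower=est.lower_,
        upper=est.upper_,
        midpoint_stderr=est.midpoint_stderr_,
        success=est.success_,
    )


def classify_fvo_regime(
    mean_lifetime: float, boundary: float = CROWDING_BOUNDARY_NS
) -> str:
    """One-sided crowding call from a mean lifetime.

    Strictly below the boundary reports "crowded_ge_30pct" (local density
    above ~30% FVO); at or above it the sensor cannot resolve the density,
    so "not_resolved" — never "dilute".
    """
    if mean_lifetime <= 0:
        raise ValueError("mean_lifetime must be positive")
    return "crowded_ge_30pct" if mean_lifetime < boundary else "not_resolved"
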
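"""Kinetic curve smoothing and twelve-descriptor fermentation phenotyping.

Each anaerobic fecal culture yields paired OD600 growth and pH kinetic curves.
This module smooths them with a local polynomial (Savitzky-Golay) filter and
extracts a fixed twelve-descriptor phenotype per culture -- six growth
descriptors and six acidification descriptors -- plus the simpler max-growth
and max-gas-production-rate summaries used for pathogen growth and gas
kinetics.  Descriptors are model-free: no parametric growth law is fitted.

The twelve descriptors (units in brackets):

========== =====================================================
od_max     maximum smoothed OD600 [OD]
t_od_max   time of od_max [h]
mu_max     maximum of smoothed dOD/dt [OD/h]
t_mu_max   time of mu_max [h]
lag_time   tangent-intercept lag: where the tangent at the point
           of fastest growth crosses the baseline OD level [h]
od_auc     trapezoid area under smoothed OD [OD*h]
ph_start   smoothed pH at the first timepoint [pH]
ph_min     minimum smoothed pH [pH]
t_ph_min   time of ph_min [h]
acid_rate_max   maximum of -dpH/dt [pH/h]
t_acid_rate_max time of acid_rate_max [h]
delta_ph   ph_start - ph_min [pH]
========== =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "FermentationProfile",
    "DESCRIPTOR_NAMES",
    "smooth_curve",
    "extract_descriptors",
    "max_growth",
    "max_gas_rate",
]


@dataclass(frozen=True)
class FermentationProfile:
    od_max: float
    t_od_max: float
    mu_max: float
    t_mu_max: float
    lag_time: float
    od_auc: float
    ph_start: float
    ph_min: float
    t_ph_min: float
    acid_rate_max: float
    t_acid_rate_max: float
    delta_ph: float
    flat_od: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)


DESCRIPTOR_NAMES = [f.name for f in fields(FermentationProfile)][:12]


def smooth_curve(t, y, window: int = 9, degree: int = 2):
    """Savitzky-Golay smoothing of a kinetic series plus its derivative.

    The derivative comes from the locally fitted polynomial, not raw
    differences, which keeps derivative-based descriptors stable at
    plate-reader noise levels.  Sampling must be (near-)uniform.

    Returns ``(smoothed, derivative)`` arrays aligned with ``t``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if degree >= window:
        raise ValueError("degree must be < window")
    if y.size < window:
        raise ValueError(f"series length {y.size} shorter than window {window}")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("time must be strictly increasing")
    step = float(np.mean(dt))
    if np.max(np.abs(dt - step)) > 0.05 * step:
        raise ValueError("sampling must be uniform or near-uniform")
    smoothed = savgol_filter(y, window, degree)
    deriv = savgol_filter(y, window, degree, deriv=1, delta=step)
    return smoothed, deriv


def extract_descriptors(
    t,
    od,
    ph,
    window: int = 9,
    degree: int = 2,
    flat_tol: float = 1e-9,
    baseline: float | None = None,
) -> FermentationProfile:
    """Extract the twelve-descriptor phenotype from paired OD and pH curves.

    Lag time uses the classical tangent construction: the tangent to the
    smoothed OD curve at the time of maximum growth rate, intersected with the
    baseline OD level, truncated to the observed time range.  ``baseline``
    defaults to the smoothed OD at the first timepoint; pass the known
    pre-growth OD explicitly when it is available.  For a flat OD curve (no
    measurable growth) mu_max is 0, lag_time is set to the final timepoint
    and the profile is flagged.
    """
    t = np.asarray(t, dtype=float)
    od = np.asarray(od, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if not (t.shape == od.shape == ph.shape):
        raise ValueError("time, OD and pH series must share a common grid")
    if t.size < 5:
        raise ValueError("need at least 5 timepoints")

    od_s, od_d = smooth_curve(t, od, window, degree)
    ph_s, ph_d = smooth_curve(t, ph, window, degree)

    i_od = int(np.argmax(od_s))
    od_max = float(od_s[i_od])
    i_mu = int(np.argmax(od_d))
    mu_max = float(od_d[i_mu])
    od0 = float(od_s[0]) if baseline is None else float(baseline)

    flat = float(np.ptp(od_s)) < flat_tol or mu_max <= flat_tol
    if flat:
        mu_max = 0.0
        lag = float(t[-1])
    else:
        # tangent OD(t) = od_s[i_mu] + mu_max*(t - t[i_mu]) meets the baseline
        lag = float(t[i_mu] - (od_s[i_mu] - od0) / mu_max)
        lag = float(np.clip(lag, t[0], t[-1]))

    i_ph = int(np.argmin(ph_s))
    acid = -ph_d
    i_ar = int(np.argmax(acid))

    return FermentationProfile(
        od_max=od_max,
        t_od_max=float(t[i_od]),
        mu_max=mu_max,
        t_mu_max=float(t[i_mu]),
        lag_time=lag,
        od_auc=float(np.trapezoid(od_s, t)),
        ph_start=float(ph_s[0]),
        ph_min=float(ph_s[i_ph]),
        t_ph_min=float(t[i_ph]),
        acid_rate_max=max(0.0, float(acid[i_ar])),
        t_acid_rate_max=float(t[i_ar]),
        delta_ph=float(ph_s[0] - ph_s[i_ph]),
        flat_od=flat,
    )


def max_growth(t, od_replicates, window: int = 9, degree: int = 2) -> float:
    """Mean maximum smoothed OD600 across replicate cultures.

    ``od_replicates`` is a single series or a sequence of replicate series on
    the common grid ``t``; replicate maxima are reduced by the mean.
    """
    arr = np.atleast_2d(np.asarray(od_replicates, dtype=float))
    maxima = []
    for row in arr:
        if row.size < 2:
            raise ValueError("need at least 2 timepoints")
        if row.size >= window:
            row = savgol_filter(row, window, degree)
        maxima.append(float(np.max(row)))
    return float(np.mean(maxima))


def max_gas_rate(t, pressure, window: int = 9, degree: int = 2) -> float:
    """Maximum gas production rate (psi/h): max of smoothed d(pressure)/dt."""
    t = np.asarray(t, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if p.size >= window:
        _, deriv = smooth_curve(t, p, window, degree)
    else:
        deriv = np.gradient(p, t)
    return max(0.0, float(np.max(deriv)))
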
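"""Ratiometric BCECF pH calibration.

Culture pH is read out with the ratiometric dye BCECF: fluorescence at the
pH-sensitive excitation (485 nm ex / 540 nm em) divided by fluorescence at the
pH-insensitive isosbestic excitation (450 nm ex / 540 nm em) gives a ratio that
increases sigmoidally with pH.  A standard curve of growth medium adjusted to
known pH values is fit with a four-parameter logistic (4PL) in pH,

    R(pH) = R_min + (R_max - R_min) / (1 + exp(-s * (pH - pH_mid)))

and sample ratios are converted to pH through the analytic inverse.  The 4PL is
parameterized directly in pH (not the EC50/Hill concentration form) because pH
is the natural abscissa and the inverse is what the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PhCalibrationModel",
    "compute_bcecf_ratio",
    "fit_4pl",
    "ratio_to_ph",
    "ph_to_ratio",
]


@dataclass(frozen=True)
class PhCalibrationModel:
    """Fitted 4PL relation between pH and BCECF fluorescence ratio.

    Parameters are the lower/upper ratio asymptotes ``r_min``/``r_max``, the
    inflection ``ph_mid`` (pH units) and the slope ``s`` (per pH unit).
    ``rss`` and ``n`` are fit diagnostics (residual sum of squares, number of
    standards); both are 0 for a model constructed from known truth.
    """

    r_min: float
    r_max: float
    ph_mid: float
    s: float
    rss: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite([self.r_min, self.r_max, self.ph_mid, self.s]).all():
            raise ValueError("4PL parameters must be finite")
        if self.r_min == self.r_max:
            raise ValueError("degenerate 4PL: r_min == r_max")

    def predict(self, ph):
        """Ratio predicted at the given pH value(s)."""
        ph = np.asarray(ph, dtype=float)
        return self.r_min + (self.r_max - self.r_min) / (
            1.0 + np.exp(-self.s * (ph - self.ph_mid))
        )

    def as_dict(self) -> dict:
        return {
            "r_min": self.r_min,
            "r_max": self.r_max,
            "ph_mid": self.ph_mid,
            "s": self.s,
            "rss": self.rss,
            "n": self.n,
        }


def compute_bcecf_ratio(f_sensitive, f_isosbestic, times=None):
    """Elementwise ratio of pH-sensitive to isosbestic fluorescence.

    ``times`` may carry the timestamps of both series; when two sequences are
    given they must agree exactly (the two channels are read from the same
    well at the same cycle).
    """
    f_s = np.asarray(f_sensitive, dtype=float)
    f_i = np.asarray(f_isosbestic, dtype=float)
    if times is not None:
        t_s, t_i = (np.asarray(t, dtype=float) for t in times)
        if t_s.shape != t_i.shape or not np.array_equal(t_s, t_i):
            raise ValueError("sensitive and isosbestic timestamps do not align")
    if f_s.shape != f_i.shape:
        raise ValueError("fluorescence series have different lengths")
    bad = ~(f_i > 0)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"non-positive isosbestic fluorescence at index {idx} (value {f_i[idx]!r})"
        )
    return f_s / f_i


def _fourpl(params, ph):
    r_min, r_max, ph_mid, s = params
    return r_min + (r_max - r_min) / (1.0 + np.exp(-s * (ph - ph_mid)))


def fit_4pl(
    ph,
    ratio,
    n_restarts: int = 5,
    seed: int = 0,
    flat_tol: float = 1e-12,
) -> PhCalibrationModel:
    """Least-squares 4PL fit of ratio against pH standards.

    Initialization is from data quantiles (asymptotes near the observed
    min/max ratio, midpoint near the pH at half-range) with ``n_restarts``
    jittered restarts; the best residual sum of squares wins.

    Raises ``ValueError`` for fewer than 5 distinct pH levels (the 4PL is
    poorly identified) and for a flat response.
    """
    ph = np.asarray(ph, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if ph.shape != ratio.shape or ph.ndim != 1:
        raise ValueError("ph and ratio must be 1-D arrays of equal length")
    if np.unique(ph).size < 5:
        raise ValueError("need at least 5 distinct pH levels to fit a 4PL")
    if float(np.var(ratio)) < flat_tol:
        raise ValueError("unidentifiable curve: ratio response is flat")

    lo, hi = float(ratio.min()), float(ratio.max())
    span = hi - lo
    half = lo + span / 2.0
    # pH at the observation closest to half-range; slope sign from overall trend
    mid0 = float(ph[np.argmin(np.abs(ratio - half))])
    trend = np.polyfit(ph, ratio, 1)[0]
    s0 = 4.0 * trend / span if span > 0 else 1.0
    base = np.array([lo - 0.05 * span, hi + 0.05 * span, mid0, s0])

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_restarts)):
        x0 = base.copy()
        if k > 0:
            x0 = x0 * (1.0 + 0.1 * rng.standard_normal(4))
            x0[2] = mid0 + 0.5 * rng.standard_normal()
        try:
            res = least_squares(
                lambda p: _fourpl(p, ph) - ratio, x0, method="lm", max_nfev=5000
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from all restarts")
    rss, p = best
    r_min, r_max, ph_mid, s = (float(v) for v in p)
    # canonical orientation: increasing logistic with r_min < r_max
    if r_min > r_max:
        r_min, r_max, s = r_max, r_min, -s
    return PhCalibrationModel(r_min, r_max, ph_mid, s, rss=rss, n=ph.size)


def ph_to_ratio(model: PhCalibrationModel, ph):
    """Forward 4PL: predicted ratio at the given pH value(s)."""
    return model.predict(ph)


def ratio_to_ph(model: PhCalibrationModel, ratio, eps: float = 1e-9):
    """Analytic inverse of the 4PL; out-of-range ratios are clamped and flagged.

    Returns ``(ph, clamped)`` where ``clamped`` is a boolean array marking
    ratios outside ``(r_min + eps, r_max - eps)``: these are clamped to the
    corresponding asymptote-adjacent bound rather than extrapolated, because
    the inverse diverges at the asymptotes.
    """
    ratio = np.atleast_1d(np.asarray(ratio, dtype=float))
    lo = model.r_min + eps
    hi = model.r_max - eps
    clamped = (ratio <= lo) | (ratio >= hi)
    r = np.clip(ratio, lo, hi)
    ph = model.ph_mid - np.log((model.r_max - model.r_min) / (r - model.r_min) - 1.0) / model.s
    return ph, clamped
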
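"""Short-chain fatty acid quantification from peak areas.

Analyte peak areas are normalized by the co-injected internal standard's peak
area, a weighted linear calibration line is fit through the normalized
responses of the calibration standards (default levels 2.5-40 mM), and
sample concentrations are back-calculated from the line.  The 1/x weighting
(x = detector response) gives low-response standards proportionally more
influence, the usual choice when residual variance grows with signal.
Negative back-calculated concentrations are floored at 0 and flagged;
responses above the top standard are flagged as extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibrationModel", "normalize_by_is", "fit_calibration", "quantify",
           "quantify_table"]


@dataclass(frozen=True)
class CalibrationModel:
    analyte: str
    slope: float        # normalized-area per mM
    intercept: float    # normalized-area
    weighting: str      # "none" | "1/x" | "1/conc"
    standards: tuple    # ((conc_mM, response), ...)

    def __post_init__(self) -> None:
        if len({c for c, _ in self.standards}) < 2:
            raise ValueError("need >= 2 distinct standard concentrations")
        if not np.isfinite(self.slope):
            raise ValueError("non-finite slope")

    @property
    def top_standard(self) -> float:
        return max(c for c, _ in self.standards)


def normalize_by_is(analyte_area, is_area, sample_id=None):
    """Internal-standard normalization: analyte area / IS area."""
    analyte_area = np.asarray(analyte_area, dtype=float)
    is_area = np.asarray(is_area, dtype=float)
    bad = ~(is_area > 0)
    if np.any(bad):
        which = sample_id if np.isscalar(is_area) or sample_id is not None else \
            np.flatnonzero(np.atleast_1d(bad))[0]
        raise ValueError(f"non-positive internal-standard area (sample {which!r})")
    return analyte_area / is_area


def fit_calibration(conc, response, weighting: str = "1/x",
                    analyte: str = "analyte") -> CalibrationModel:
    """Weighted least-squares calibration line through the standards.

    ``weighting="1/x"`` uses w_i = 1/response_i (the quoted detector-response
    weighting; responses must be positive); ``"1/conc"`` weights by inverse
    concentration; ``"none"`` is ordinary least squares.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(response, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("conc and response must be 1-D arrays of equal length")
    if np.unique(conc).size < 2:
        raise ValueError("rank-deficient calibration: all standard concentrations identical")
    if weighting == "1/x":
        if (resp <= 0).any():
            raise ValueError("1/x weighting requires positive responses")
        w = 1.0 / resp
    elif weighting == "1/conc":
        if (conc <= 0).any():
            raise ValueError("1/conc weighting requires positive concentrations")
        w = 1.0 / conc
    elif weighting == "none":
        w = np.ones_like(resp)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    # weighted normal equations for y = b0 + b1 x
    sw, swx, swy = w.sum(), (w * conc).sum(), (w * resp).sum()
    swxx, swxy = (w * conc * conc).sum(), (w * conc * resp).sum()
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return CalibrationModel(analyte=analyte, slope=float(slope),
                            intercept=float(intercept), weighting=weighting,
                            standards=tuple(zip(conc.tolist(), resp.tolist())))


def quantify(model: CalibrationModel, response):
    """Back-calculate concentrations (mM) from normalized responses.

    Returns ``(conc, flags)`` where flags marks 'floored' (negative estimate
    clipped to 0) and 'extrapolated' (above the top standard).
    """
    resp = np.atleast_1d(np.asarray(response, dtype=float))
    top_resp = model.intercept + model.slope * model.top_standard
    if abs(model.slope) < 1e-12 * max(1.0, abs(model.intercept)):
        raise ValueError("calibration slope is ~0; cannot invert")
    conc = (resp - model.intercept) / model.slope
    flags = np.where(conc < 0, "floored",
                     np.where(conc > model.top_standard, "extrapolated", ""))
    return np.maximum(conc, 0.0), flags


def quantify_table(samples: pd.DataFrame, standards: pd.DataFrame,
                   weighting: str = "1/x") -> pd.DataFrame:
    """Quantify a peak table against a standards table, one model per analyte.

    Both tables need columns (sample_id, analyte, area, is_area); standards
    additionally ``conc_mm``.  Returns (sample_id, analyte, conc_mm, flag).
    """
    out = []
    for analyte, std in standards.groupby("analyte"):
        resp_std = normalize_by_is(std["area"].to_numpy(), std["is_area"].to_numpy())
        model = fit_calibration(std["conc_mm"].to_numpy(), resp_std,
                                weighting=weighting, analyte=str(analyte))
        sub = samples[samples["analyte"] == analyte]
        resp = normalize_by_is(sub["area"].to_numpy(), sub["is_area"].to_numpy())
        conc, flags = quantify(model, resp)
        out.append(pd.DataFrame({"sample_id": sub["sample_id"].to_numpy(),
                                 "analyte": analyte, "conc_mm": conc,
                                 "flag": flags}))
    return pd.concat(out, ignore_index=True)
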
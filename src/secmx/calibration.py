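"""Molecular-weight calibration of the SEC column and monomer/complex calls.

A protein standard of known molecular weights is run on the column; its
elution fractions give a log-linear relationship log10(MW) = intercept +
slope * fraction (larger assemblies elute earlier, so the slope is
negative).  A peak apex is called *monomeric* when it elutes at or after the
fraction where the calibrated MW equals ``multiplier`` x the protein's
monomer mass; the default multiplier of 1.5 buffers wide or slightly
shifted elution peaks.  Anything eluting earlier — i.e. at an apparent MW
above 1.5x the monomer — is called *complexed*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import ValidationError

__all__ = [
    "CalibrationError",
    "CalibrationStandard",
    "CalibrationModel",
    "fit_mw_calibration",
    "estimate_fraction_mw",
    "monomer_boundary_fraction",
    "classify_apex",
]

MONOMERIC = "monomeric"
COMPLEXED = "complexed"
UNCLASSIFIED = "unclassified"


class CalibrationError(ValueError):
    """The standard cannot produce a valid (negative-slope) calibration."""


@dataclass
class CalibrationStandard:
    """Known (fraction, MW in Da) points of the column calibration standard.

    When the standard is measured more than once (e.g. start and end of an
    experimental day) the pooled points are fitted together; the residual SD
    then exposes drift.
    """

    points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValidationError("calibration standard needs >= 2 points")
        if any(mw <= 0 for _, mw in self.points):
            raise ValidationError("standard MWs must be positive")
        ordered = sorted(self.points)
        # Strictly decreasing MW with fraction (allowing repeated fractions
        # from pooled injections).
        by_fraction: dict[float, list[float]] = {}
        for f, mw in ordered:
            by_fraction.setdefault(f, []).append(mw)
        fr = sorted(by_fraction)
        if len(fr) < 2:
            raise ValidationError("calibration standard needs >= 2 distinct fractions")
        means = [float(np.mean(by_fraction[f])) for f in fr]
        if any(b >= a for a, b in zip(means, means[1:])):
            raise ValidationError("standard MW must decrease with fraction")


@dataclass
class CalibrationModel:
    """Log-linear fraction -> MW map plus the monomer-boundary rule."""

    slope: float            # d log10(MW Da) / d fraction, < 0
    intercept: float        # log10(MW Da) at fraction 0
    residual_sd: float
    n_points: int
    monomer_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(
                f"calibration slope must be negative (got {self.slope:g}); "
                "check the standard's column orientation"
            )


def fit_mw_calibration(
    std: CalibrationStandard, monomer_multiplier: float = 1.5
) -> CalibrationModel:
    """Ordinary least squares of log10(MW) on fraction (exact when n = 2)."""
    fr = np.array([f for f, _ in std.points], dtype=float)
    logmw = np.log10([mw for _, mw in std.points])
    if len(fr) == 2:
        slope = (logmw[1] - logmw[0]) / (fr[1] - fr[0])
        intercept = logmw[0] - slope * fr[0]
        resid_sd = 0.0
    else:
        res = stats.linregress(fr, logmw)
        slope, intercept = float(res.slope), float(res.intercept)
        resid = logmw - (intercept + slope * fr)
        resid_sd = float(np.sqrt(np.sum(resid**2) / (len(fr) - 2)))
    return CalibrationModel(slope, intercept, resid_sd, len(fr), monomer_multiplier)


def estimate_fraction_mw(model: CalibrationModel, fraction: float) -> float:
    """Calibrated molecular weight (Da) at a (possibly fractional) fraction index."""
    return float(10.0 ** (model.intercept + model.slope * fraction))


def monomer_boundary_fraction(model: CalibrationModel, monomer_mw: float) -> float:
    """Fraction where the calibrated MW equals multiplier x the monomer mass."""
    if monomer_mw <= 0:
        raise ValidationError("monomer MW must be positive")
    target = np.log10(model.monomer_multiplier * monomer_mw)
    return float((target - model.intercept) / model.slope)


def classify_apex(
    model: CalibrationModel, monomer_mw: float | None, apex: float
) -> str:
    """Monomeric iff the apex elutes at or after the monomer boundary.

    The boundary itself is inclusive (monomeric): the multiplier already
    buffers shifted peaks, so the boundary lies within that buffer.  Unknown
    monomer mass yields ``unclassified``.
    """
    if monomer_mw is None or (isinstance(monomer_mw, float) and np.isnan(monomer_mw)):
        return UNCLASSIFIED
    return MONOMERIC if apex >= monomer_boundary_fraction(model, monomer_mw) else COMPLEXED


def model_to_dict(model: CalibrationModel) -> dict[str, float]:
    return {
        "slope": model.slope,
        "intercept": model.intercept,
        "residual_sd": model.residual_sd,
        "n_points": model.n_points,
        "monomer_multiplier": model.monomer_multiplier,
    }


def model_from_dict(d: dict) -> CalibrationModel:
    return CalibrationModel(
        float(d["slope"]),
        float(d["intercept"]),
        float(d.get("residual_sd", 0.0)),
        int(float(d.get("n_points", 2))),
        float(d.get("monomer_multiplier", 1.5)),
    )
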
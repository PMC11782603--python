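"""Fit the fraction<->MW calibration and detect elution peaks on a profile.

Builds a two-state protein profile (complex at fraction 18, monomer at 40),
smooths it, detects peaks and classifies each apex against the calibrated
monomer boundary.
"""

import numpy as np

from secmx import (
    CalibrationStandard,
    classify_apex,
    detect_peaks,
    estimate_fraction_mw,
    fit_mw_calibration,
    monomer_boundary_fraction,
    smooth_profile,
)

standard = CalibrationStandard([(f, 10 ** (7.0 - 0.06 * f)) for f in (3, 17, 31, 45)])
model = fit_mw_calibration(standard)
print(f"calibration: slope={model.slope:.3f} log10(Da)/fraction, "
      f"intercept={model.intercept:.2f}")

monomer_mw = estimate_fraction_mw(model, 40)  # protein whose monomer elutes at 40
boundary = monomer_boundary_fraction(model, monomer_mw)
print(f"monomer MW {monomer_mw/1e3:.1f} kDa -> 1.5x boundary at fraction {boundary:.2f}")

fr = np.arange(1, 55)
profile = 30000 * np.exp(-0.5 * ((fr - 18) / 1.5) ** 2) \
        + 20000 * np.exp(-0.5 * ((fr - 40) / 1.4) ** 2)
for p in detect_peaks(smooth_profile(profile)):
    label = classify_apex(model, monomer_mw, p.apex)
    print(f"  peak at fraction {p.apex}: height {p.height:.0f}, "
          f"width {p.width:.1f}, apparent MW "
          f"{estimate_fraction_mw(model, p.apex)/1e3:.0f} kDa -> {label}")
# The early peak elutes at ~20x the monomer mass (complexed); the late peak
# sits at the monomer's own position, inside the 1.5x buffer (monomeric).
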
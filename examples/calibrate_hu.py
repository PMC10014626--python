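"""Slice-wise HU -> BMD calibration against the six-insert phantom.

The phantom's HU law drifts sinusoidally along the scan (tube-current
modulation), so one global line would be biased; each slice is fitted from
the insert discs after a five-slice moving average.  The example prints the
spread of fitted slopes and the accuracy of the recovered densities.
"""

import numpy as np

from femfall import PhantomSpec, calibrate_volume, generate_phantom

case = generate_phantom(PhantomSpec(noise_sd=5.0, seed=3))
bmd, cal = calibrate_volume(case.hu_volume, case.insert_layout)

print(f"slices: {len(cal.slope)}, "
      f"slope range {cal.slope.min():.4f}..{cal.slope.max():.4f} (mg/cm3)/HU")
# The slope spread reflects the simulated current modulation; a constant
# calibration would miss it.

inside = case.mask.values > 0
err = bmd.values[inside] - case.truth_bmd.values[inside]
print(f"in-bone recovery: RMS {np.sqrt((err**2).mean()):.2f} mg/cm3, "
      f"bias {err.mean():+.2f} mg/cm3")
# With 5 HU image noise the density error stays a few mg/cm3 - small against
# the ~650 mg/cm3 cortical/trabecular contrast.
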
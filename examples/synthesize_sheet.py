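"""Synthesize the Bessel-Gaussian-array light sheet and measure it.

Calibrates the axicon slope for a 0.8 um core, multiplexes nine beams by
stripe splitting, focuses the pupil through the Debye integral and reports
the sheet's FWHM dimensions.  Runs in a few seconds on one core.
"""

import numpy as np

from adlsfc import optics as opt
from adlsfc.units import UM

spec = opt.PupilSpec(grid_size=512, envelope_waist=0.6 * 2.5e-3)
z_w = 85 * UM  # working plane of the Bessel zone

tan_alpha = opt.calibrate_axicon(spec, target_fwhm=0.8 * UM, z_working=z_w)
print(f"calibrated axicon slope tan(alpha) = {tan_alpha:.3e}")

variation, gauss_factor, _ = opt.anti_diffraction_ratio(spec, tan_alpha, z_w)
print(f"core FWHM variation over the Gaussian-doubling range: {variation*100:.1f}%")
print(f"(an equal-waist Gaussian focus broadens by {100*(gauss_factor-1):.0f}%)")

beams = opt.sheet_beams(n_beams=9, spacing=1.5 * UM, tan_alpha=tan_alpha)
mask = opt.ssp_multiplex(beams, spec, stripe_width=1)
zs = z_w + np.linspace(-5, 5, 11) * UM
stack = opt.debye_focus(mask, spec, zs).intensity()
d = spec.focal_sampling
metrics = opt.measure_sheet(stack, (1 * UM, d, d), roi_halfwidth=2.5 * UM)
print(
    f"sheet: {metrics.width/UM:.1f} um wide, "
    f"{metrics.thickness_fwhm/UM:.2f} um thick "
    f"(SD {metrics.thickness_sd/UM:.2f} um) across the sampled z-range"
)
# The thin core persists over the measured axial range - the anti-diffraction
# property that lets a single sheet cover the whole jet at submicron thickness.
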
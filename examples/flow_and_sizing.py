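"""Channel flow arithmetic and FWHM-based sizing.

Computes the chamber Reynolds number at the 1 uL/h bench point and inverts
two measured pulse widths to particle diameters.
"""

from adlsfc.microfluidics import (
    ChannelGeometry,
    FlowConfig,
    FluidProps,
    hydraulic_diameter,
    mean_velocity,
    particle_diameter,
    particle_speed,
)
from adlsfc.units import UM

geom = ChannelGeometry()          # 10 um x 50 um chamber, 15 um jet
flow = FlowConfig.from_ul_per_h(1.0, 1.0)   # Qj = Qs = 1 uL/h
fluid = FluidProps()              # water

dh = hydraulic_diameter(geom)
um = mean_velocity(flow, geom)
up = particle_speed(flow, geom)

from adlsfc.microfluidics import reynolds

print(f"hydraulic diameter : {dh/UM:.2f} um")
print(f"mean velocity      : {um*1e3:.3f} mm/s")
print(f"Reynolds number    : {reynolds(fluid, um, dh):.3e}  (laminar)")

for tau_ms in (1.13, 3.46):
    d = particle_diameter(up, tau_ms * 1e-3, 0.8 * UM)
    print(f"pulse FWHM {tau_ms:.2f} ms -> particle diameter {d.diameter/UM:.2f} um")
# A 1.13 ms pulse is a ~1.1 um micropillar; 3.46 ms is a ~5 um microsphere.
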
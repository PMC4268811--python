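"""Kernel-smoothed pale-ommatidium density surface of one retina.

A Gaussian kernel (70 px bandwidth on the 1400 px canvas) turns the
point pattern of pale ommatidia into an intensity surface; the Diggle
edge correction makes the surface integrate to the pale count exactly.
"""

import numpy as np

import retmosaic as rm
from retmosaic.synthetic_data import zom4_like_params

retina = rm.generate_hex_retina(zom4_like_params(seed=7))
pattern = rm.to_point_pattern(retina)
grid = rm.kernel_density(pattern, type_filter="P_OC", sigma=70.0, cell=10.0)

n_pale = rm.count_types(retina).n_p_oc
peak_iy, peak_ix = np.unravel_index(np.nanargmax(grid.values), grid.values.shape)
print(f"pale ommatidia:          {n_pale}")
print(f"surface integral:        {grid.integral():.2f}")
print(f"max intensity:           {np.nanmax(grid.values):.6f} points/px^2")
print(f"peak location (px):      x={10 * (peak_ix + 0.5):.0f}, y={10 * (peak_iy + 0.5):.0f}")
print(f"display range (fixed):   {grid.display_range}")
print()
print(
    "The integral reproduces the pale count (mass conservation); the peak\n"
    "sits in the dorsal-posterior quadrant where this strain's patch lies.\n"
    "Use grid.render('density.png') to draw it with the fixed colour scale."
)
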
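"""Blend two backgrounds in the Fourier domain and cut triangular targets.

The 25/50/75% blends are the specialist-on-B, generalist, and
specialist-on-A target sources of the two-background design.
"""

import numpy as np

from camokit import (
    CategorySpec,
    extract_triangle,
    fourier_blend,
    generate_background,
)

a = generate_background(
    CategorySpec("grass", (55, -30, 35), (0, 0, 0), 1.2, 11.0), 192, 192, seed=1
)
b = generate_background(
    CategorySpec("bark", (35, 8, 18), (0, 0, 0), 1.6, 10.0), 192, 192, seed=2
)

rng = np.random.default_rng(0)
for w in (0.25, 0.50, 0.75):
    blend = fourier_blend(a, b, w)
    target = extract_triangle(blend, rng)
    print(
        f"w={w:.2f}  blend mean RGB={blend.image.pixels.mean():.3f}  "
        f"clipped={blend.clip_fraction:.2%}  target anchor={target.anchor}"
    )
print(
    "\nEach blend mixes the amplitude spectra linearly and the phases "
    "circularly, so its mean brightness interpolates between the parents "
    "and the 150x75 px triangular 'moth' is cut at a random anchor."
)
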
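"""Quantify plaque-associated glial activation and its dependence on plaque size.

Generates a two-channel scene (plaque channel + glial channel) whose glial
halos were painted from the linear model  intensity = 633.8 * area + 276,179
with no noise, then runs the full measurement chain: detect plaques at
threshold 20-255, build each plaque's 8x-Feret neighborhood disk, exclude
overlapping neighborhoods, measure background-corrected halo intensity
(threshold 30-255), and regress intensity on plaque area.  The fitted slope
and intercept recover the generating coefficients.
"""

from gliaquant import simgen
from gliaquant.plaques import (
    default_background,
    detect_plaques,
    exclude_overlaps,
    halo_intensity,
    plaques_to_frame,
    regress_intensity_on_area,
)

spec = simgen.PlaqueSpec(sigma=0.0)  # noiseless halos
plaque_plane, glial_plane, _ = simgen.generate_plaque_scene(spec, seed=3)

records = detect_plaques(plaque_plane, low=20)
exclude_overlaps(records)
background = default_background(glial_plane, records)
for rec in records:
    if not rec.excluded:
        halo_intensity(glial_plane, rec, background, low=30)

print(plaques_to_frame(records).to_string(index=False))
fit = regress_intensity_on_area(records)
print()
print(f"fit: intensity = {fit.slope:.1f} * area + {fit.intercept:.0f}  (R^2 = {fit.r_squared:.3f}, n = {fit.n})")
print(f"generating model: intensity = {spec.beta1} * area + {spec.beta0:.0f}")
print()
print(
    "The regression recovers the painted halo law: glial activation around a "
    "plaque scales linearly with plaque area in this scene."
)
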
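"""Vestibule and channel water counting on a labeled coordinate frame.

Builds a synthetic frame with planted waters (each satisfying all the
membership criteria or violating exactly one) and counts the waters in
the intracellular vestibule and in the release channel near the A198
backbone.
"""

from leutkit.mdgeom import count_waters, hydration_histogram
from leutkit.simulate import FrameFixtureConfig, make_frame_fixture

config = FrameFixtureConfig(n_satisfies_all=6, n_violates_lipid=2,
                            n_violates_z=1, n_violates_A198=3,
                            n_random=20, seed=2)
frame, labels = make_frame_fixture(config)

wc = count_waters(frame)
print(f"vestibule waters: {wc.vestibule}   channel waters: {wc.channel}")
print(f"ground truth:     {sum(l.vestibule for l in labels)}"
      f"                  {sum(l.channel for l in labels)}")

hist = hydration_histogram([[wc.vestibule]] * 3)
print(f"pooled mean vestibule count: {hist.pooled_mean:.1f}")
# A water belongs to the vestibule when its oxygen is within 15 A of the
# substrate center of mass, away from lipids and the exclusion backbones,
# and inside the membrane slab; the channel adds proximity to A198.
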
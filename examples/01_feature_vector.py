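"""Compute the chi feature vector of a single synthetic spotted pattern.

Builds a 50x50 spotted pattern (15% vegetation cover), ranks the
bare-ground pixels by subgraph centrality, and prints the 20 Euler
characteristics of the expanding rank subregions.
"""

from vegmorph import PatternSpec, feature_vector, smoothed_field_pattern

pattern = smoothed_field_pattern(PatternSpec((50, 50), cover_fraction=0.15,
                                             correlation_length_px=3.0, seed=7))
print(f"pattern: 50x50, vegetation cover {pattern.cover_fraction:.2f}")

fv = feature_vector(pattern, polarity="background")
for frac, chi in zip(fv.fractions, fv.chi):
    print(f"  top {frac:4.0%} of pixels by centrality: chi = {chi:6d}")
print(f"steepness (chi_1 - chi_20): {fv.steepness}")

# chi decreases monotonically: the top-ranked pixels already form compact,
# densely edged cores, and every added rank band contributes more edges than
# vertices. The steeper the total drop, the more the background forms a single
# continuous shape — the signature of a spotted vegetation pattern seen from
# its complement.
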
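"""Pearson colocalization between two fluorescence channels.

Builds channel pairs with known correlation and recovers it; +1 means
perfect colocalization, -1 perfect anti-correlation.
"""

from chondrocolumn import generate_coloc_pair, pearson_colocalization

for target in (1.0, 0.5, 0.0, -1.0):
    ch1, ch2 = generate_coloc_pair(target, n_px=50_000, seed=4)
    res = pearson_colocalization(ch1, ch2)
    print(f"target r = {target:+.1f}  ->  measured r = {res.r:+.4f} "
          f"({res.n_px} pixels)")

# The estimate converges to the target as the pixel count grows; the
# residual error at 5e4 pixels is within sampling error (~1/sqrt(n)).
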
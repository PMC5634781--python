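"""Junctional intensity over time: persistent band vs decaying band.

Compares the wild-type preset (junctional adhesion protein persists at
the post-cleavage furrow) against the receptor-overexpression preset
(junction decays with a ~5 h half-life while the sisters separate).
"""

from chondrocolumn import run_preset

for name in ("wild_type", "pcp_gain"):
    report = run_preset(name, n_pairs=3, seed=0)
    mean_f = report.junction.groupby("t_h").f_over_fmax.mean()
    print(f"{name}: junctional F/Fmax by hour")
    print("   " + " ".join(f"{v:4.2f}" for v in mean_f))

# F/Fmax normalizes each pair's junctional intensity by its own maximum
# over the time course. Values near 1 throughout mean the junction
# persists; the overexpression preset drops to about 0.5 by 5 h.
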
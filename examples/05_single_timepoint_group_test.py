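"""Exact Mann-Whitney test for a single-time-point two-group contrast.

Typical use: comparing a marker between two genotypes sampled at one
zeitgeber time with a handful of animals per group, where the exact null
distribution of U is enumerable.
"""

import numpy as np

from rhythmkit import mann_whitney, significance_stars

rng = np.random.default_rng(3)
wild_type = rng.normal(100.0, 15.0, size=8)   # e.g. serum ALT, IU/L
knockout = rng.normal(135.0, 15.0, size=8)

res = mann_whitney(wild_type, knockout)
print(f"n = {res.n1} vs {res.n2}, U = {res.U:.1f}")
print(f"two-sided p = {res.p_two_sided:.4f}  ({res.method})")
print(f"annotation  : {significance_stars(res.p_two_sided)}")
print(f"vs-indicated-group marker: {significance_stars(res.p_two_sided, marker='$')}")
# '*' marks p < 0.05 against the control group; the '$' variant is the
# conventional symbol for a contrast against an indicated (non-control) group.
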
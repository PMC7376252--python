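"""Bootstrap comparison of oscillation parameters between two conditions.

Simulates one gene whose peak is advanced by 3 h under a dietary
challenge, bootstraps the cosinor parameters of each condition
(stratified case resampling within time points), and prints the
between-condition contrasts with 95% confidence intervals and the
resulting rhythm-change classification.
"""

from rhythmkit import bootstrap_params, compare_conditions, generate_dataset
from rhythmkit.studies import two_condition_study

# control peaks at ZT20; challenge at ZT17 (a 3 h advance); same mesor/amplitude
config = two_condition_study(phi_a=20.0, phi_b=17.0, noise=0.8, seed=5)
dataset = generate_dataset(config)

dists = {}
for i, condition in enumerate(("CD", "MCDD")):
    g = dataset[dataset["condition"] == condition]
    dists[condition] = bootstrap_params(
        g["zt"].to_numpy(), g["value"].to_numpy(), B=1000, seed=100 + i
    )

cmp = compare_conditions(dists["CD"], dists["MCDD"])
dm, ar, dp = cmp.delta_mesor, cmp.amplitude_ratio, cmp.delta_phi
print(f"delta MESOR     : {dm.point:+.3f}  [{dm.lower:+.3f}, {dm.upper:+.3f}]")
print(f"amplitude ratio : {ar.point:.3f}  [{ar.lower:.3f}, {ar.upper:.3f}]")
print(f"delta phase (h) : {dp.point:+.3f}  [{dp.lower:+.3f}, {dp.upper:+.3f}]")
print(f"significant     : {cmp.significant}")
print(f"change class    : {cmp.change_class}")
# The phase-difference CI excludes 0 while the mesor and amplitude contrasts
# do not, so the change is classified as a pure phase shift (~3 h).
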
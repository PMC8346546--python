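"""Parameter recovery through the iterative calibration pipeline.

Generates a zero-noise synthetic study (live counts at days 3/6/9 under
3 mM Mg2+) from known ground-truth parameters, then runs one round of
sensitivity screening + rejection ABC and compares posterior medians with
the truth.

Reduced scale to stay interactive (~2-3 min): ABC uses 200 runs / top 10
on a 20 x 20 x 8 world.
"""

from fuzzymsc import CalibrationConfig, CalibrationState, ParameterSet, iterate
from fuzzymsc.fixtures import generate, make_simulator, recovery_priors, study_protocols

truth = ParameterSet(gamma_p0=0.13, alpha_p=1.6, gamma_m0=0.003)
kw = dict(world_shape=(20, 20, 8), seed_count=20, conditions=(3.0,))

study = generate("study3", truth=truth, noise=0.0, seed=42, **kw)
print("synthetic dataset:")
print(study.dataset.table.to_string(index=False))

simulate = make_simulator(study_protocols("study3", **kw))
free = recovery_priors(truth, ("gamma_p0", "alpha_p", "gamma_m0", "alpha_m", "r_d0", "wc"))
config = CalibrationConfig(n_runs=200, n_keep=10, max_iterations=1)
state = iterate(CalibrationState(free=dict(free)), simulate, study.dataset,
                config, seed=42)

rec = state.records[0]
print("\nsensitivity ranking (scaled F):")
print(rec["effects"].round(3).to_string())
print(f"\nkept-run fit: R2 = {rec['r2_mean']:.3f} +/- {rec['r2_sd']:.3f}")
print("\nposterior medians vs truth:")
for name, median in rec["posterior_medians"].items():
    t = getattr(truth, name)
    print(f"  {name:10s} truth {t:8.4f}  median {median:8.4f}  "
          f"({100 * abs(median - t) / t:.0f}% off)")
print("\nThe screen puts the proliferation parameters on top for live-count")
print("data, and their posterior medians land near the generating truth;")
print("weakly identified parameters stay close to their prior centres.")
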
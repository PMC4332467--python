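"""The classical symmetry protocol: CV, symmetry index, and paired t per parameter.

Simulates a cohort whose right side pushes off 5 % harder (Fz1, Fz3) and
builds the six-parameter report: per-side trial-to-trial CV (repeatable when
<= 12.5 %), Robinson's absolute symmetry index (acceptable when < 10 %), and
a paired t-test across subjects (significant when p <= 0.05).
"""

from gaitsym import CohortConfig, build_si_report, discrete_params_frame, simulate_patterns

config = CohortConfig(n_subjects=20, trials_per_side=10, seed=3,
                      asymmetry={"fz1": 0.05, "fz3": 0.05})
dataset, _ = simulate_patterns(config)

frame = discrete_params_frame(dataset)
report = build_si_report(frame)
print(report.render_text())
print()
print("Reading: the SI column stays below the 10 % acceptability line even for the")
print("shifted peaks (a 5 % shift gives SI ~ 5 %), while the paired t-test flags")
print("them (p:sig) - per-parameter SI thresholds are blind to small systematic")
print("asymmetries that paired statistics across subjects pick up.")
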
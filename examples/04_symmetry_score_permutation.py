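"""Permutation-calibrated symmetry score on a subtly asymmetric cohort.

A 3 % multiplicative shift distributed over four parameters is far below
the classical SI > 10 % flag, but the classifier-based permutation test can
still detect it: labels are swapped within subject pairs to simulate the
symmetric null, and the observed cross-validated accuracy is ranked against
the permuted ones.
"""

from gaitsym import CohortConfig, KernelSpec, build_si_report, discrete_params_frame, simulate_patterns, symmetry_score

config = CohortConfig(n_subjects=16, trials_per_side=10, seed=2,
                      asymmetry={p: 0.03 for p in ("fz1", "fz2", "fz3", "tz2")})
dataset, _ = simulate_patterns(config)

score = symmetry_score(dataset, feature_mode="six_params", kernel=KernelSpec("linear"),
                       penalty_c=1.0, k=4, repeats=1, n_permutations=99, seed=0)
print(f"mean CV accuracy       {score.mean_accuracy:.3f}")
print(f"symmetry score         {score.score:.3f}   (1 = chance-level = symmetric)")
print(f"permutation p-value    {score.permutation_p:.3f}   ({score.n_permutations} permutations)")

report = build_si_report(discrete_params_frame(dataset))
worst = max(report.summaries, key=lambda s: s.si_pct)
print(f"largest classical SI   {worst.si_pct:.2f} %  ({worst.parameter_name}) "
      f"- below the 10 % flag, so the SI rule calls this cohort symmetric")
print("A p-value at or below 0.05 while every SI value is 'acceptable' is exactly")
print("the regime where the classifier-based test outperforms the classical index;")
print("at this cohort size detection is not certain, so replicate cohorts (or more")
print("subjects) sharpen the comparison.")
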
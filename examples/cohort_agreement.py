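"""Paired cohort study: reference vs reconstruction-based strengths.

Generates paired phantoms (QCT-like truth + degraded reconstruction-like
counterpart with a -64 mg/cm3 density offset and 7% volume deficit), runs
both arms through the strength pipeline, applies the collective and the
individual BMC corrections, and prints the agreement statistics of each set
against the reference strengths.
"""

from femfall import MaterialLaw, PhantomSpec, make_cohort
from femfall.pipeline import cohort_strength_study

base = PhantomSpec(head_radius=15.0, neck_radius=9.0, neck_length=22.0,
                   shaft_radius=13.0, shaft_length=62.0,
                   cortical_thickness=2.5, seed=0)
cohort = make_cohort(4, base, variability=0.06, seed=11)
study = cohort_strength_study(cohort, law=MaterialLaw(), n_increments=8,
                              bootstrap_reps=500, seed=11,
                              with_difference_map=False)

print(study.table.round(1).to_string(index=False))
for name, s in (("uncorrected", study.stats_uncorrected),
                ("collective", study.stats_collective),
                ("individual", study.stats_individual)):
    print(f"{name:<12s} r2 {s.r2:.3f}  slope {s.slope:.2f} "
          f"[{s.slope_ci[0]:.2f}, {s.slope_ci[1]:.2f}]  "
          f"CCC {s.ccc:.3f}  MAE {s.mae:.0f} N ({100*s.cv_mae:.1f}%)")
# Uncorrected reconstruction-based strengths underestimate the reference
# (slope > 1, CCC < r); rescaling densities to matched mineral content
# moves the regression toward identity and raises the concordance.
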
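"""Harmonize two cohorts: median-normalize, filter, impute, log2.

The missingness report classifies every shared metabolite: 'retained'
(<=20% missing in both cohorts) proceed; 'discrepant' (low in one cohort,
20-80% in the other), 'severe' (>=80% somewhere) and 'both_moderate' are
excluded — mirroring how platform or medication differences between
studies show up as cohort-specific missingness.
"""

from metaboclock import SimulationConfig, generate_cohort_pair, harmonize

cfg = SimulationConfig(n_subjects=(300, 150), n_metabolites=200,
                       n_age_assoc=60, n_obstr_assoc=60, n_shared=30,
                       n_discrepant=12, n_severe=8, seed=2)
(mat_a, _), (mat_b, _), truth = generate_cohort_pair(cfg)

proc_a, proc_b, report = harmonize(mat_a, mat_b)

print("missingness classes:")
print(report["missing_class"].value_counts().to_string())
print(f"\nprocessed cohort A: {proc_a.n_samples} x {proc_a.n_metabolites} "
      f"(complete: {proc_a.data.notna().all().all()}, scale: {proc_a.scale})")
planted = truth.metabolites["planted_missing"]
hit = report.loc[planted == "discrepant", "missing_class"].eq("discrepant").mean()
print(f"planted discrepant metabolites correctly classified: {hit:.0%}")
# After harmonization both matrices are complete log2 tables restricted to
# the retained metabolites — the input the score models expect.
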
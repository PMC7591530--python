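"""Many-to-one inference on a synthetic dose-ranging cohort.

Generates one full cohort (untreated/vehicle knockout controls plus
high/medium/low dose arms at the study group sizes), then runs the
inferential layer on the rotarod outcome: one-way ANOVA, Dunnett's
many-to-one comparisons against the untreated control, and Fisher's
exact test on spontaneous-seizure incidence.
"""

from neurophenopipe import (CohortDesign, anova, default_effect_model,
                            dunnett, fisher_exact, gen_cohort_outcomes,
                            incidence_table)

design = CohortDesign(n_per_group=15)
effects = default_effect_model(design)   # recovery d: H=1.2, M=0.8, L=0.3
cohort = gen_cohort_outcomes(design, effects, seed=6)

rot = cohort.query("outcome == 'rotarod_latency_s'")
per_animal = (rot.groupby(["animal_id", "group"], sort=False)["value"]
              .mean().reset_index())

res = anova(per_animal, dv="value", factors=("group",))
print(f"one-way ANOVA: F = {res.statistic:.2f}, p = {res.p_value:.2e}")

dres = dunnett(per_animal, control="untreated-KO", seed=6)
print(dres.table.round(4).to_string(index=False))

seized = cohort.query("outcome == 'spontaneous_seizure'")[
    ["animal_id", "group", "value"]].rename(columns={"value": "seized"})
inc = incidence_table(seized.assign(seized=seized["seized"].astype(bool)))
t2 = inc.loc[["untreated-KO", "H"]].to_numpy().astype(int)
print(f"\nseizure incidence:\n{inc.to_string()}")
print(f"Fisher exact, H vs untreated-KO: p = "
      f"{fisher_exact(t2).p_value:.4f}")
print()
print("Dunnett adjusted p-values control the family-wise error over the")
print("dose arms; the dose-ordered effects make H and M significant")
print("while L typically is not - the minimum-efficacious-dose pattern.")
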
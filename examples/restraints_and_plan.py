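"""From cross-link evidence to distance restraints and an ensemble plan.

Twelve interpeptide cross-links become twelve Cα–Cα upper-bound restraints
(mean 15 Å, SD 5 Å).  Three sampling strategies feed the refinement
ensemble: all restraints, random subsets of six, and random residue pairs as
a null control.  The default plan enumerates 16,000 models.
"""

from xlrefine.restraints import (CrossLink, Linker, PlanConfig,
                                 build_ensemble_plan,
                                 restraints_from_crosslinks,
                                 sample_random_restraints,
                                 sample_reduced_restraints)

links = [CrossLink("p53", 305 + 3 * i, 370 + i, Linker.BS2G)
         for i in range(12)]
restraints = restraints_from_crosslinks(links)
print(f"{len(links)} cross-links -> {len(restraints)} upper-bound restraints "
      f"(mean {restraints[0].mean} Å, sd {restraints[0].sd} Å)")

reduced = sample_reduced_restraints(links, k=6, seed=0)
print(f"reduced strategy: subset of {len(reduced)} links")

random_rs = sample_random_restraints(region=(301, 393), n=12, seed=0)
print(f"random strategy: {len(random_rs)} restraints, endpoints "
      f"{min(r.res_a for r in random_rs)}–{max(r.res_b for r in random_rs)}")

plan = build_ensemble_plan()
print(f"\nensemble plan: {plan.totals} -> grand total {plan.grand_total}")

scaled = build_ensemble_plan(PlanConfig(scale_down=100))
print(f"desk-scale plan (factor 100): {scaled.totals} -> "
      f"{scaled.grand_total} models")
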
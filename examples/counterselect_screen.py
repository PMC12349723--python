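"""Two-round counter-selective screen on a planted affinity landscape.

Twenty ligands are given a −3 kcal/mol preference for the nucleotide
binding domains (NBDs); everything else binds NBD and DBD boxes equally.
With noise of 0.5 kcal/mol per docking energy, the screen should still
rank the planted NBD-preferrers first: a ΔΔG of −3 kcal/mol at 310 K is a
K_D ratio of exp(3/RT) ≈ 130, far above the noise floor.
"""

from pgpscreen import (PlantedLandscape, example_target_manifest,
                       gen_ligand_library, iterate_screen, kd_from_dg,
                       mock_dock)

print(f"K_D at ΔG = -8 kcal/mol, 310 K: {kd_from_dg(-8.0):.3g} M")
print(f"ratio for ΔΔG = 3 kcal/mol: "
      f"{kd_from_dg(-6.0) / kd_from_dg(-9.0):.1f}\n")

lib, labels = gen_ligand_library(400, 40, within_cluster_similarity=0.9,
                                 seed=42)
firsts = {}
for rec, lab in zip(lib.records, labels):
    firsts.setdefault(lab, rec.ligand_id)
planted = frozenset(firsts[c] for c in range(20))

targets = [t for t in example_target_manifest()
           if t.pair_group in {"open", "transition", "closed"}
           and t.conformation in {"open", "transition", "closed"}]
landscape = PlantedLandscape(planted_ids=planted, planted_offset_nbd=-3.0,
                             noise_sd=0.5, seed=42)

outcome = iterate_screen(lib, targets,
                         lambda sub, tgts: mock_dock(sub, tgts, landscape),
                         cutoff=0.95, band=(0.70, 0.99), n_top=50)

prov = outcome.provenance
print(f"round 1 docked the {prov['subset_size']}-ligand diversity subset; "
      f"round 2 docked {prov['expansion_size']} band-expanded neighbors")
top20 = outcome.merged.ids()[:20]
print(f"planted ligands recovered in top 20: "
      f"{len(set(top20) & planted)}/20")
best = outcome.merged.entries[0]
print(f"best ligand {best.ligand_id}: aggregate ratio {best.aggregate:.1f} "
      f"(min over {len(best.per_pair)} conformation pairs)")
# aggregate ≈ exp(3/RT) ≈ 130 means the ligand is predicted to bind the
# NBDs ~130-fold tighter than the DBDs in its worst conformation
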
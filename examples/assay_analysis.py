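"""Analyze the embedded LC-MS/MS panel and synthetic MTT/fluorescence data.

The LC-MS/MS substrate test: if a compound accumulates intracellularly only
when the efflux pump is blocked by tariquidar, the pump was transporting
it — an undesirable trait for an inhibitor meant to bind the nucleotide
binding domains.
"""

from pgpscreen import (AssayGroundTruth, dau_fold_change, gen_assay_data,
                       hit_rate, mtt_resensitization,
                       reference_accumulation_panel,
                       substrate_calls_from_summary)

# --- published accumulation panel -----------------------------------------
panel = reference_accumulation_panel()
calls = substrate_calls_from_summary(panel[panel.compound_id != "DAU"])
for c in calls:
    ps = [f"{t.p_two_sided:.2g}" for t in c.per_trial if not t.indeterminate]
    tag = ("substrate" if c.substrate
           else "indeterminate" if c.indeterminate else "non-substrate")
    print(f"compound {c.compound_id:>3}: {tag:<13} "
          f"(per-trial p: {', '.join(ps) or 'below quantification'})")
n_sub = sum(c.substrate for c in calls)
print(f"→ {n_sub} likely substrates, {len(calls) - n_sub} non-substrates\n")

# --- synthetic MTT plate ---------------------------------------------------
ids = [f"C{i}" for i in range(6)]
truth = AssayGroundTruth(compound_ids=ids, inhibitor_ids=set(ids[:2]),
                         dau_enhancer_ids={"C0"})
data = gen_assay_data(truth, seed=3)
results = mtt_resensitization(data["plate"])
hits = [r.compound_id for r in results if r.resensitizer]
print(f"MTT: {len(hits)}/{len(results)} compounds re-sensitize "
      f"(decrease ≥ 30 points): {', '.join(hits)}")
print(f"screen-scale hit-rate reporting, 9 hits of 67 tested: "
      f"{hit_rate(67, 9)}%\n")

# --- DAU accumulation ------------------------------------------------------
fluor = data["fluorescence"]
dau_alone = fluor[fluor.compound_id == "DAU-alone"]["fluorescence"]
comp = fluor[fluor.compound_id == "C0"]["fluorescence"]
r = dau_fold_change(comp.to_numpy(), dau_alone.to_numpy(), compound_id="C0")
print(f"DAU fold change for C0: {r.fold_change:.2f} "
      f"(p = {r.p_two_sided:.2g}) — fluorescence above 1.0 means the "
      "compound blocks DAU efflux")
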
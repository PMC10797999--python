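"""Simulate a small overexpression screen with injected phenotype archetypes.

A control strain plus four TF strains with known truth (a global r-Prot
silencer, a global enhancer, a pH-inverted responder and a null TF) are
measured over the full 104-run plan in biological duplicate, with 8%
multiplicative lognormal noise.
"""

import tfscreen as tfs

factors = tfs.default_screen_factors()
variants = tfs.build_fcccd(factors)
plan = tfs.replicate_plan(variants, factors, seed=7)

assign = {
    "control": "control",
    "tf_silencer": "global_silencer",
    "tf_enhancer": "global_enhancer",
    "tf_inverted": "inverted",
    "tf_null": "null_tf",
}
readouts, truth = tfs.simulate_screen(assign, plan, seed=11)

print(f"readout rows: {len(readouts)} "
      f"({len(assign)} strains x {plan.n_runs} runs x {plan.bio_reps} bio reps)")
print("\nfirst readouts (OD600 = growth, FU = reporter fluorescence):")
print(readouts.head(4).to_string(index=False))
print("\nground-truth labels (kept out-of-band, never in the readout table):")
print(truth)
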
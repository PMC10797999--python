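"""Build the face-centered central composite design and its replicated run plan.

Five factors — oxygen availability, carbon source, nitrogen source (binary
categoric) and pH, temperature (numeric, three coded levels) — are crossed
into condition variants; central variants (pH and temperature at the center)
are run in pentaplicate, everything else once, then the schedule is
randomized.
"""

import tfscreen as tfs

factors = tfs.default_screen_factors()
variants = tfs.build_fcccd(factors)
plan = tfs.replicate_plan(variants, factors, central_reps=5, outer_reps=1,
                          bio_reps=2, seed=7)

n_central = sum(v.role == "central" for v in variants)
print(f"condition variants : {len(variants)} ({n_central} central)")
print(f"culture runs/strain: {plan.n_runs}")
print(f"cultures/strain    : {plan.n_cultures} (x{plan.bio_reps} biological replicates)")

df = tfs.design_frame(variants, factors)
print("\nfirst variants (coded and actual levels):")
print(df.head(5).to_string(index=False))
# 72 variants and 104 runs: the 3x3 pH/temperature grid crossed with the 8
# categoric combinations; 8 central variants x 5 + 64 outer x 1 = 104.
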
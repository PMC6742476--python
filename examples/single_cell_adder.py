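"""The adder in action: a lineage adds a fixed length per division cycle.

Division fires when the accumulated division protein reaches P0 = rho*pi*w,
so each cycle adds dL = rho*pi*w*k/kP regardless of birth size.  Even with
5% division-asymmetry noise the *added* length stays constant while birth
lengths fluctuate.
"""

from rodshape import ModelParams, analytic_cycle, make_lineage_table

params = ModelParams(k=0.75, delta_sigma=0.05, evolve_width=False)
T, dL = analytic_cycle(params, L_birth=2.83, w=1.0)
print(f"closed form at w = 1 um: division after {T:.3f} h, added length {dL:.3f} um")

lineage = make_lineage_table(params, n_generations=15, seed=3)
birth_cv = lineage.birth_length_um.std() / lineage.birth_length_um.mean()
dl_cv = lineage.delta_L_um.std() / lineage.delta_L_um.mean()
print(lineage[["generation", "birth_length_um", "division_length_um",
               "delta_L_um", "delta_L_over_w"]].head(6).to_string(index=False))
print(f"birth-length CV = {birth_cv:.3f}  (division noise visible)")
print(f"added-length CV = {dl_cv:.2e}  (the adder: essentially zero)")
print("Interpretation: noise perturbs newborn sizes, but every cycle still")
print("adds the same length -> newborn sizes regress to dL within a few")
print("generations, and dL/w is the invariant that fixes the aspect ratio.")
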
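"""How strongly does a cell's reporter level 3 h after photoconversion
predict its level at 6 h?

Simulates the two-stage expression model with a photoconvertible reporter:
at t = 0 the whole green pool is switched to red, and the regrowing green
pool is sampled at 3 h and 6 h across many cells. Cell-to-cell variability
enters as a random per-cell translation rate. The Pearson correlation
across cells is compared with the closed-form auto-correlation of a simple
birth-death process, which bounds it from below.
"""

from noisetissue import ExtrinsicSpec, TwoStageParams, autocorr_birth_death, autocorr_two_stage_mc

params = TwoStageParams(transcription_rate=2.25, mrna_decay=1.125,
                        translation_rate=45.0, protein_decay=0.09)
bound = autocorr_birth_death(params.protein_decay, 3.0, 6.0)
print(f"birth-death lower bound c0(6h, 3h) = {bound:.3f}")

for var in (0.0, 25.0, 100.0):
    est = autocorr_two_stage_mc(params, ExtrinsicSpec(45.0, var), 3.0, 6.0,
                                n_traj=20_000, seed=1)
    print(f"Var(v1) = {var:5.0f} h^-2:  r(3h, 6h) = {est.r:.3f} +- {est.se:.3f}")

print("\nMore extrinsic noise -> slower decorrelation: cell identity (its")
print("translation capacity) dominates the memory of expression levels,")
print("so the measured auto-correlation sits well above the bound.")
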
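"""Estimate the reporter degradation rate from a pulse-chase cohort.

Generates a synthetic photoconversion time course (true protein decay
0.09/h, 400 nuclei, duplicate measurements with 10% lognormal technical
noise), then recovers the rate from the red-channel intensities at 3 h and
6 h via per-nucleus log-ratios.
"""

from noisetissue import (
    ExtrinsicSpec,
    TwoStageParams,
    average_duplicates,
    estimate_decay_rate,
    generate_kik_timecourse,
)

params = TwoStageParams(2.25, 1.125, 45.0, 0.09)
table, _ = generate_kik_timecourse(params, ExtrinsicSpec(45.0, 100.0),
                                   n_cells=400, noise_sigma=0.1, seed=7)

df = average_duplicates(table).data
red = df[df["channel"] == "KikR"]
background = red["background_mean_grey"].iloc[0]
r3 = red[red["time_h"] == 3.0].set_index("cell_id")["mean_grey"] - background
r6 = red[red["time_h"] == 6.0].set_index("cell_id")["mean_grey"] - background

est = estimate_decay_rate(r3, r6, dt=3.0)
print(f"decay rate d1 = {est.rate:.4f} +- {est.se:.4f} /h   (n = {est.n_used} nuclei)")
print(f"true generating rate: {params.protein_decay} /h")
print("\nThe per-nucleus log-ratio ln(R3/R6)/3h averages out both the")
print("counting noise of the molecules and the technical measurement noise.")
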
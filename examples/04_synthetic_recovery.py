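"""Generate a synthetic experiment and test pipeline parameter recovery.

Simulates the full 200-column design (110 intact 'Field' + 90 re-packed
columns over five matric potentials) with known ground-truth models, then
runs the whole estimation chain — 70/30 stratified split, Busscher fit,
surface fit, validation metrics — once with noise switched off (closure
must be exact) and once at realistic noise.
"""

from dataclasses import replace

from rootstress import SyntheticConfig, generate_experiment, recovery_experiment

cfg = SyntheticConfig(seed=42)
table = generate_experiment(cfg)
print(f"simulated {len(table)} columns; Qp span "
      f"{table.qp_calc.min():.2f}-{table.qp_calc.max():.2f} MPa, "
      f"S span {table.saturation_pct.min():.0f}-{table.saturation_pct.max():.0f}%")

noise_free = recovery_experiment(replace(cfg, noise_re_sd=0.0, noise_qp_sd=0.0), 1)
print("\nnoise-free closure (max |Re_fit - Re_truth| over the data cloud):")
print(noise_free.per_rep[["structure", "surface_max_dev", "val_rmse"]].to_string(index=False))

noisy = recovery_experiment(cfg, 3)
print("\nwith Re noise sd = 0.05 (3 replicates), validation metrics:")
print(noisy.summary()[["val_rmse", "val_r", "val_d", "surface_max_dev"]].round(3).to_string())
print("\nvalidation RMSE tracking the injected noise level indicates the")
print("surface fit explains all recoverable structure in the simulation.")
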
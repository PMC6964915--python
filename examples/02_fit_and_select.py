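"""Fit candidate learning models to a simulated dataset and select by BIC.

Data are simulated from the Kalman RW model under the backward-blocking
design; both RW and KRW are fitted by bounded maximum likelihood and
compared by BIC (lower is better; the penalty is k*ln(n_trials)).
"""

from condesign import build_reference_design, select_model, simulate_dataset

design = build_reference_design("backward_blocking",
                                {"stage1": 20, "stage2": 20, "test": 10})
truth = {"w0_var": 1.0, "q_diffusion": 0.01, "r_noise_var": 0.25,
         "sigma_obs": 0.5}
dataset, _ = simulate_dataset(design, "krw", truth, seed=11)

result = select_model(dataset, ["rw", "krw"], seed=0)
for model_id, fit in result.fits.items():
    pretty = ", ".join(f"{k}={v:.3f}" for k, v in fit.params.items())
    print(f"{model_id:>4}: loglik {fit.loglik:8.2f}  BIC "
          f"{result.bics[model_id]:8.2f}  ({pretty})")
print(f"\nselected: {result.winner} (delta BIC vs runner-up "
      f"{result.delta_bic:+.2f})")
print("With moderate response noise the 50-trial backward-blocking "
      "experiment often cannot justify KRW's two extra parameters — "
      "exactly the misidentification an optimized design should reduce.")
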
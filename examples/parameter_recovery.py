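"""Monte-Carlo check that the fit recovers a known selection coefficient.

Simulates 200 complete competition experiments at s_true = 0.30 (the
strongest single-allele effect measured in the N2 background) and reports
the bias, RMSE and 95% CI coverage of the estimated selection coefficient.
"""

from compfit import CompetitionConfig, parameter_recovery_experiment

config = CompetitionConfig(w_true=1.30, seed=2026)
summary = parameter_recovery_experiment(config, n_experiments=200)

print(f"s_true      = {summary.s_true:.3f}")
print(f"mean s_hat  = {summary.mean_s_hat:.4f}")
print(f"bias        = {summary.bias:+.4f}")
print(f"RMSE        = {summary.rmse:.4f}")
print(f"CI coverage = {summary.ci_coverage:.3f}  (nominal 0.95)")
print("\nBias near zero and coverage near 0.95 mean the logit-linear fit and")
print("its replicate-t interval are calibrated under bottleneck drift and")
print("ddPCR counting noise at the protocol's default settings.")
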
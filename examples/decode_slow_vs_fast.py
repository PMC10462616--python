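"""Decode the slowest vs fastest 10% of speeds from simulated sEEG.

Runs the full analysis chain on one speed-coupled session: detrend,
theta/gamma Hilbert envelopes, 1-s windows with 0.5-s hop, log/z-score,
extreme-decile labels, shrinkage-LDA 10-fold cross-validation, and a
circular-shift permutation test with 500 surrogates.  A shorter session
(300 s) keeps the example quick.
"""

from hipponav import SimConfig, extract_features, generate_session
from hipponav.inference import (
    decile_task_aucs,
    shift_null_distribution,
    significance_report,
)

config = SimConfig(duration_s=300.0, n_channels=8, g_theta=0.5, seed=3)
session, trace = generate_session(config)
table = extract_features(session, trace)
print(f"{table.n_windows} windows x {len(table.feature_names)} features "
      f"(theta+gamma power per hippocampal channel)")

_, observed, datasets = decile_task_aucs(table, cv_seed=7)
null = shift_null_distribution(table, "decile", n_perm=500, seed=7, cv_seed=7)
report = significance_report(observed, null)

n_per_class = datasets[0].n_samples // 2
print(f"\nslow vs fast decile task ({n_per_class} windows per class):")
print(f"  cross-validated AUC = {observed[0]:.3f}")
print(f"  permutation p (maxT) = {report.p_adjusted[0]:.4g} "
      f"-> significant: {bool(report.significant[0])}")
print("\nAUC is the probability a random fast window outscores a random "
      "slow one; the p-value compares it with AUCs obtained after "
      "circularly shifting the speed trace, which preserves autocorrelation "
      "but breaks the neural-behaviour alignment.")
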
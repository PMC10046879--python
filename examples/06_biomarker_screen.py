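"""Screening composite biomarkers against a benchmark predicate device.

Mechanism demonstration on synthetic observations: the null is "on par
with a predicate test of AUC 0.88" (equal-variance binormal calibrated to
that AUC), Bonferroni-corrected for a pair-combinatorial hypothesis count.
"""

from exactroc import (RunConfig, TestSpec, build_distribution,
                      composite_hypothesis_count, screen_aucs)

hypotheses = composite_hypothesis_count(n_features=39, directions_per_pair=8,
                                        cohorts=9)
print(f"composite biomarkers tested simultaneously: {hypotheses}")

# a small cohort: 44 cases vs 120 controls under the benchmark null
cfg = RunConfig(n=44, m=120, benchmark_auc=0.88, i_max=40, reps=300_000,
                seed=13, match_alpha=0.999)
dist, _ = build_distribution(cfg)

spec = TestSpec(level=0.99, hypotheses=hypotheses)
observed = [0.90, 0.95, 0.97, 0.995]
report = screen_aucs(dist, observed, spec)
print(report.to_string(index=False))
print(f"critical value: {report.attrs['critical_value']:.4f}; "
      f"{report.attrs['rejections']} of {len(observed)} rejected")
# Only observations above the corrected critical value count as evidence
# of superiority over the predicate.
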
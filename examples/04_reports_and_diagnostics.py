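"""Post-call diagnostics: cross-tissue consistency and read-ratio
percentiles per designation group.

A real AEI signal driven by a cis-regulatory variant should recur in most
tissues where the gene is expressed; the ratio table shows how the
model-based calls relate to the classic max/min read-ratio statistic.
"""

from aeimix import (
    PipelineConfig,
    SimConfig,
    consistency_report,
    ratio_percentile_table,
    run_pipeline,
    simulate_dataset,
)

sim = SimConfig(
    n_subjects=4, tissues_per_subject=6, n_genes=250,
    coverage_classes=((0.5, 30.0), (0.5, 50.0)),
    aei_fraction=0.2, rho=3.0, expression_prob=0.5, seed=13,
)
counts, _ = simulate_dataset(sim)
cfg = PipelineConfig(poisson_k_range=(1, 4), skellam_k_range=(1, 3),
                     poisson_restarts=2, skellam_restarts=3, seed=2)
bundle = run_pipeline(cfg, counts)

rep = consistency_report(bundle.calls)
n_consistent = int(rep.consistent.sum())
print(f"{len(rep)} subject-SNP pairs expressed in >= 2 tissues; "
      f"{n_consistent} show AEI in at least half of them")

tab = ratio_percentile_table(bundle.calls)
print("\nread-ratio percentiles (max(R,V)/min(R,V)) per designation:")
print(tab.set_index("group")[["n", "p10", "p50", "p90", "max"]].round(2))
print("\nAEI calls concentrate at high ratios, but the mixture also "
      "weighs coverage — a 1.4-fold skew on deep counts can outrank a "
      "3-fold skew on shallow ones")
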
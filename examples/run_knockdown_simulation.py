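"""End-to-end splicing-factor prediction on a synthetic knock-down.

Simulates a dataset in which one driver RBP binds 200 events whose PSI
shifts by 0.3 between conditions and whose own gene expression drops
~2.8-fold (log2 FC -1.5), then runs the full pipeline: splicing regions ->
ExS matrix -> PSI -> expression filter -> differential-splicing test ->
top-1000 selection -> CLIP enrichment -> differential expression ->
ranking. The driver should come out as the top filter-passing candidate.
"""

from sfclip import (
    RunConfig,
    SimulationConfig,
    evaluate_recovery,
    run_on_bundle,
    simulate_dataset,
)

bundle = simulate_dataset(SimulationConfig(seed=0))
result = run_on_bundle(bundle, RunConfig(top_n=1000))

print("pipeline funnel:")
for stage, count in result.report.items():
    print(f"  {stage:32s} {count}")

cols = ["rbp", "m", "k", "expected", "p_clip", "log2_fc", "p_expr",
        "passes_filters"]
print("\ntop of the CLIP ranking:")
print(result.ranking[cols].head(5).to_string(index=False))

recovery = evaluate_recovery(result.ranking, bundle.truth)
print(f"\nplanted driver: {bundle.truth.driver_rbp}")
print(f"recovered at candidate rank {recovery['driver_rank']} "
      f"with CLIP p = {recovery['driver_p_clip']:.2e}")
# k far above `expected` for the driver (it binds every perturbed event)
# plus the knock-down expression signature is what puts it at rank 1.
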
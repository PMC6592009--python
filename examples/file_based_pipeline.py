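"""The same analysis driven from files, as with real data.

Writes a synthetic dataset to disk in the formats the pipeline consumes
(event table TSV, BED6 peak files + metadata, transcript/gene expression
TSVs, a design file), then runs the pipeline from those paths. The
equivalent shell form is:

    sfclip simulate --seed 7 --out data/
    sfclip run --config run.yaml
"""

import tempfile
from pathlib import Path

from sfclip import (
    RunConfig,
    SimulationConfig,
    run_pipeline,
    simulate_dataset,
    write_dataset,
)

workdir = Path(tempfile.mkdtemp(prefix="sfclip_example_"))
data = workdir / "data"
write_dataset(
    simulate_dataset(SimulationConfig(seed=7, n_events=500, n_rbps=15)), data
)
print(f"wrote inputs to {data}:")
for p in sorted(data.iterdir())[:6]:
    print(f"  {p.name}")
print("  ...")

cfg = RunConfig(
    event_table=str(data / "events.tsv"),
    peak_metadata=str(data / "peak_metadata.tsv"),
    tx_expr=str(data / "tx_expr.tsv"),
    gene_expr=str(data / "gene_expr.tsv"),
    design=str(data / "design.tsv"),
    output_dir=str(workdir / "out"),
    top_n=250,
)
result = run_pipeline(cfg)

print("\ncandidate splicing factors (pass CLIP + expression filters):")
print(result.candidates[["rbp", "p_clip", "log2_fc", "p_expr"]]
      .to_string(index=False))
print(f"\nall outputs written under {workdir / 'out'}")
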
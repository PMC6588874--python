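"""The full pipeline in one call: simulate -> qc -> discover -> de ->
targets -> enrich, with all stage outputs written to a directory."""

from lncweave.pipeline import PipelineConfig, run_pipeline
from lncweave.synthetic import SyntheticConfig

cfg = PipelineConfig(out_dir="scratch/pipeline_demo", seed=1,
                     synthetic=SyntheticConfig(seed=1))
report = run_pipeline(cfg)
print(report.to_text())
# Key fields: clean_percent (read QC retention), known/novel lncRNA counts
# with derived percentages, per-comparison up/down DE counts, cis/trans
# pair counts and the enrichment namespace tallies.
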
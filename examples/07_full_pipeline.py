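"""End-to-end simulated run: screen -> cluster -> prioritize -> mixture -> expression.

Generates the full synthetic input suite under one seed, runs every
pipeline stage and prints the report.  Equivalent to the shell command
`coexmix run-all --simulate --seed 1 --outdir out`.
"""

import tempfile
from pathlib import Path

from coexmix.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    outdir = Path(tmp) / "run"
    run_pipeline(PipelineConfig(seed=1), outdir, do_simulate=True)
    print((outdir / "report.txt").read_text())
    print("artifacts written:", ", ".join(sorted(p.name for p in outdir.iterdir()
                                                 if p.is_file())))
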
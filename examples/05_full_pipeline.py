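"""The file-based two-stage pipeline end to end.

Writes a small simulated cohort to disk (recordings + immune table),
runs preprocess -> per-subject fits -> both regression models -> SEXIT
and diagnostics, and regenerates the human-readable report from the
saved artifacts.  A reduced sampler configuration keeps the run short.
"""

import tempfile
from pathlib import Path

from cardiocas import (
    PipelineConfig,
    RegressionSpec,
    report,
    run_pipeline,
    simulate_cohort,
    write_immune_table,
    write_rri_file,
)

base = Path(tempfile.mkdtemp(prefix="cardiocas_demo_"))
(base / "recordings").mkdir()
truth, recordings = simulate_cohort(15, seed=6)
for rec, params in zip(recordings, truth.subject_parameters):
    write_rri_file(rec, base / "recordings" / f"{rec.subject_id}.csv", truth=params)
write_immune_table(truth.immune_table, base / "immune.csv")

config = PipelineConfig(
    recordings_dir=base / "recordings",
    immune_table=base / "immune.csv",
    output_dir=base / "run",
    regression=RegressionSpec(chains=2, warmup=500, sampling=500, seed=6),
    seed=6,
)
artifacts = run_pipeline(config)
print("stage counts:", artifacts["manifest"]["counts"])
print()
print(report(base / "run", make_plots=False))
print(f"\nartifacts under {base / 'run'}")
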
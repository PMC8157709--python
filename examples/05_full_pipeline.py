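"""Run the whole pipeline on synthetic data and print the consolidated report.

simulate -> screen -> design -> offtarget -> phenostats, all from one master
seed; the run report lists every artifact with a SHA-256 digest, so a rerun
with the same configuration can be verified bit-for-bit.
"""

import tempfile
from pathlib import Path

from suckerscreen.pipeline import RunConfig, run_pipeline, write_report

outdir = Path(tempfile.mkdtemp(prefix="suckerscreen_"))
config = RunConfig(
    outdir=outdir,
    seed=13,
    n_target_pairs=12,
    n_paralog_families=4,
    n_background=100,
    trigger_length_nt=300,
)
report = run_pipeline(config)
text = write_report(report, outdir / "run_report.txt")
print(text)
print(f"artifacts under {outdir}")
print("n_triggers equals n_target_pairs (one trigger per family); the "
      "effective-gene list recovers the constructs planted with a 0.1 "
      "secondary-shoot multiplier.")
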
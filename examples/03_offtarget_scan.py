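"""Scan a trigger for exact 22-nt off-target matches, with one planted positive.

A shared run of >= 22 consecutive nucleotides (either strand) between the
trigger and any non-target transcript is an off-target risk; the scanner
reports each maximal run once, with exact coordinates.
"""

import numpy as np

from suckerscreen.offtarget_scan import build_index, classify_trigger, scan_trigger
from suckerscreen.seqcore import Transcript
from suckerscreen.synthetic_data import SimConfig, plant_offtarget, simulate_transcriptome

config = SimConfig(seed=8, n_target_pairs=2, n_paralog_families=0, n_background=50)
transcripts, _ = simulate_transcriptome(config)

trigger = Transcript("trigger_fam01", transcripts[0].sequence[100:530])
modified, planted = plant_offtarget(transcripts, trigger.sequence, 26, np.random.default_rng(8))

index = build_index(modified, k=22)
hits = scan_trigger(trigger, index, modified, exclude_ids={"fam01_S", "fam01_T"})
verdict, report = classify_trigger(trigger, hits)

print(f"planted: {planted.length_nt} nt ({planted.strand}) into "
      f"{planted.transcript_id}[{planted.start}:{planted.end}]")
print(f"verdict: {verdict.value} ({len(report)} hit(s))")
for h in report:
    print(f"  {h.transcript_id}[{h.transcript_start}:{h.transcript_end}] "
          f"{h.strand.value}, {h.match_length_nt} nt "
          f"= trigger[{h.trigger_start}:{h.trigger_end}]")
print("The scanner recovered the planted match exactly; the intended S/T targets "
      "were excluded from the report.")
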
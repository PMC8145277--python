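#!/usr/bin/env python
"""Simulate a small paired cohort and write it to disk.

Writes behavioral tables (CSV) and ground-truth artifact annotations
(JSON) under results/cohort/, and EDF recordings under scratch/cohort/
(binary scratch output).  Prints what was generated.
"""

import json
from pathlib import Path

from pharmaeeg.io import write_edf
from pharmaeeg.pipeline import StudyConfig, simulate_behavioral
from pharmaeeg.simulate import EEGSimConfig, generate_subject_cohort

ROOT = Path(__file__).resolve().parents[1]

cfg = StudyConfig(n_subjects=2, n_cognitive=2,
                  conditions=("rest1", "simon_congruent"),
                  sim=EEGSimConfig(duration=10.0, fs_native=512.0), seed=7)

out_tables = ROOT / "results" / "cohort"
out_edf = ROOT / "scratch" / "cohort"
out_tables.mkdir(parents=True, exist_ok=True)
out_edf.mkdir(parents=True, exist_ok=True)

cohort = generate_subject_cohort(cfg.n_subjects, [], cfg.sim,
                                 conditions=cfg.conditions)
n_files = 0
truth_payload = {}
for subj in cohort:
    for cond, sessions in subj.recordings.items():
        for session, rec in sessions.items():
            name = f"sub{subj.subject:02d}_{cond}_{session}"
            write_edf(rec, out_edf / f"{name}.edf")
            truth_payload[name] = [
                {"kind": ev.kind, "start": ev.start, "end": ev.end,
                 "channels": sorted(ev.channels)}
                for ev in subj.truth[cond][session]]
            n_files += 1
(out_tables / "artifact_truth.json").write_text(json.dumps(truth_payload, indent=1))

behav = simulate_behavioral(cfg)
for name, tab in behav.items():
    tab.to_csv(out_tables / f"{name}.csv", index=False)

print(f"wrote {n_files} EDF recordings to {out_edf}")
print(f"behavioral tables ({', '.join(behav)}) and artifact truth in {out_tables}")
print(f"simon sessions: {len(behav['simon'])} trials total")
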
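#!/usr/bin/env python
"""Build the trial schedules for all experiments and tabulate their
structure (trial counts per mode and phase), confirming the protocol
arithmetic: 320 main trials (single-context), 64 + 15 x 30 (multi-context
de-adaptation), 3 x 90 (masses), 528 (dual-context), 580 (five contexts).
"""

from pathlib import Path

import pandas as pd

import ssadapt as sa

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for exp, group, seed in [
    ("exp1", None, 11), ("exp2", 1, 12), ("exp2", 2, 13),
    ("exp3", None, 14), ("exp4", None, 15), ("exp5", None, 16), ("expS1", None, 17),
]:
    sched = sa.build_schedule(exp, seed=seed, group=group)
    df = sched.to_frame()
    name = exp if group is None else f"{exp}_group{group}"
    df.to_csv(OUT / f"schedule_{name}.csv", index=False)
    rows.append({
        "experiment": name,
        "total_trials": len(sched),
        "main_trials": len(sched.main_trials),
        "exposure": int((df["mode"] == "exposure").sum()),
        "zero_force": int((df["mode"] == "zero_force").sum()),
        "error_clamp": int((df["mode"] == "error_clamp").sum()),
        "n_blocks": df["block_id"].nunique(),
        "orientations": ",".join(f"{o:g}" for o in sorted(df["orientation_deg"].unique())),
    })

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "schedule_summary.csv", index=False)
print(summary.to_string(index=False))
print("\nSchedules and summary written to", OUT)
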
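"""Generate the synthetic three-year study and summarise what it looks like.

Writes the full daily environmental series and admission-level records under
scratch/simulated/ (they are inputs, not findings) and prints the summary
moments that place the synthetic study next to the cohort it emulates.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1]))

import numpy as np

from analysis.common import SCRATCH, STUDY_CONFIG
from pm25_dlnm import simulate_study
from pm25_dlnm.io_cli import write_admissions, write_environment

env, counts, admissions = simulate_study(STUDY_CONFIG)

out = SCRATCH / "simulated"
out.mkdir(parents=True, exist_ok=True)
write_environment(env, out / "environment.csv")
write_admissions(admissions, out / "admissions.csv")
counts.to_csv(out / "daily_pneumonia_counts.csv", index=False)

pneu = (admissions["group"] == "pneumonia").sum()
print(f"simulated {len(env)} days ({env['date'].iloc[0].date()} .. {env['date'].iloc[-1].date()})")
print(f"PM2.5 mean (sd): {env.pm25.mean():.1f} ({env.pm25.std():.1f}) mcg/m3")
print(f"temperature mean (sd): {env.temperature.mean():.1f} ({env.temperature.std():.1f}) C")
print(f"admissions: {len(admissions)} total, {pneu} pneumonia "
      f"({np.nanmean(counts['count']):.2f}/day)")
print(f"tables written to {out}")
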
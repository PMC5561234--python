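"""Shared study configuration for the numbered analysis drivers.

One 1096-day (2014-01-01 .. 2016-12-31) synthetic study with the default
planted exposure-lag-response surface. Every driver regenerates the tables
from this seeded config, so each is independently reproducible.
"""

from pathlib import Path

from pm25_dlnm import SimulationConfig

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"

STUDY_CONFIG = SimulationConfig(n_days=1096, seed=42)
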
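"""Shared paths and config loading for the analysis drivers.

Bulky per-run files (genotypes, relationship matrices) live under
scratch/; only small summary tables are written to results/.
"""

from pathlib import Path

from isofeed.pipeline import load_config

ROOT = Path(__file__).resolve().parent.parent
CONFIG = load_config(Path(__file__).resolve().parent / "config.yaml")
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)
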
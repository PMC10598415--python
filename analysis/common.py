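"""Shared configuration for the analysis scripts.

Each numbered script is a thin driver over the :mod:`twinace` library:
01 simulates the three analysis-ready twin tables, later scripts read the
persisted artifacts of earlier ones, so stages can be rerun in isolation.
"""

from pathlib import Path

from twinace.data_io import ColumnMap
from twinace.pipeline import PipelineConfig

SEED = 2023
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORTS = RESULTS / "cohorts"
PREPARED = RESULTS / "prepared"
TABLES = RESULTS / "tables"

TRAITS = ["total_autistic_traits", "rrbid", "sic"]

CONFIG = PipelineConfig(seed=SEED, out_dir=str(RESULTS / "pipeline"))


def cohort_map(trait: str) -> ColumnMap:
    return ColumnMap(traits=["synaesthesia", trait])


def ensure_dirs() -> None:
    for d in (COHORTS, PREPARED, TABLES):
        d.mkdir(parents=True, exist_ok=True)
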
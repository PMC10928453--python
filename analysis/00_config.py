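"""Shared settings for the numbered analysis scripts.

One place for the study-scale conditions so every stage sees the same
cohort: 29 patients (the study's cohort size), 20×20-pixel cores (reduced
from the generator's 40×40 default to keep each stage interactive), a
planted class effect of 2.0, a deliberate 1–2 pixel mask misregistration,
and 200 bootstrap replicates.
"""

from pathlib import Path

from irsurv.pipeline import stage_seed

ROOT_SEED = 7
N_PATIENTS = 29
CORE_SIZE = 20
EFFECT_SIZE = 2.0
MASK_SHIFT = (1, 2)
N_REPLICATES = 200

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_DIR = RESULTS / "data"

SIMULATE_SEED = stage_seed(ROOT_SEED, 0)
CLASSIFY_SEED = stage_seed(ROOT_SEED, 1)
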
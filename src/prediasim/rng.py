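"""Named random substreams.

Every source of randomness in a run is derived from one master seed via a
(phase, year) keyed substream.  Paired control/intervention arms use the
same master seed, and every per-agent draw is made for the full id-aligned
agent array, so the two arms consume common random numbers: differences
between arms are attributable to the intervention alone.
"""

from __future__ import annotations

import numpy as np

PHASE_IDS = {
    "init": 0,
    "mortality": 1,
    "intervention": 2,
    "age_bmi": 3,
    "glycemic": 4,
    "entry": 5,
    "panel": 6,
    "scenario": 7,
    "calibration": 8,
}


def substream(master_seed: int, phase: str, year: int = 0) -> np.random.Generator:
    """Generator for a named (phase, year) substream of ``master_seed``."""
    if phase not in PHASE_IDS:
        raise KeyError(f"unknown stream phase {phase!r}")
    seq = np.random.SeedSequence([int(master_seed) % (2**31), PHASE_IDS[phase], int(year)])
    return np.random.default_rng(seq)
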
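"""Counter-based seed derivation.

All randomness in the package flows from a single master seed.  Each
(replicate, purpose) pair gets an independent substream derived with
`numpy.random.SeedSequence`, so results are identical whether replicates
run serially or in parallel, and adding a new purpose never perturbs
existing streams.
"""

from __future__ import annotations

import numpy as np

# stable purpose tags -> fixed integer codes (never renumber)
_PURPOSES = {
    "totals": 1,
    "alpha": 2,
    "counts": 3,
    "covariates": 4,
    "signal": 5,
    "noise": 6,
    "split": 7,
    "cv": 8,
    "calibration": 9,
    "phenotype": 10,
}


def substream(master_seed: int, replicate: int, purpose: str) -> np.random.Generator:
    """Return an independent Generator for (master_seed, replicate, purpose)."""
    try:
        code = _PURPOSES[purpose]
    except KeyError:
        raise ValueError(f"unknown purpose tag {purpose!r}") from None
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(replicate), code))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, replicate: int, purpose: str) -> int:
    """A plain integer seed (< 2**31) derived from the same substream."""
    return int(substream(master_seed, replicate, purpose).integers(0, 2**31 - 1))
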
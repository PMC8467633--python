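"""Seed-substream plumbing.

Every stochastic operation in the package derives its generator from a single
root seed through :class:`numpy.random.SeedSequence` spawn keys, one fixed key
per named stream. Adding draws to one operation therefore never perturbs the
output of another operation run under the same root seed.
"""

from __future__ import annotations

import numpy as np

#: Fixed spawn key per operation family. Never reorder — doing so changes
#: every downstream stream under a given root seed.
_STREAMS = {
    "genome": 0,
    "coverage": 1,
    "counts": 2,
    "cohort": 3,
    "isolation": 4,
    "mass": 5,
    "sequence": 6,
    "loci": 7,
}


def substream(seed: int, label: str) -> np.random.Generator:
    """Return the dedicated :class:`~numpy.random.Generator` for *label*.

    Parameters
    ----------
    seed
        Root seed shared by all operations of one run.
    label
        Name of the operation family; must be one of the documented streams.
    """
    try:
        key = _STREAMS[label]
    except KeyError:  # pragma: no cover - programming error
        raise KeyError(f"unknown RNG stream {label!r}; known: {sorted(_STREAMS)}")
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
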
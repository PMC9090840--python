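"""One run seed, expanded into named independent substreams.

Every stochastic component (genome layout, depth noise, count noise, embryo
counts, segmentation permutations, label-permutation test) draws from its
own child of the run's SeedSequence, so a component can be regenerated
without replaying the others and results are independent of evaluation
order or thread count.
"""

from __future__ import annotations

import numpy as np

STREAMS = ("genome", "depth", "counts", "embryo", "segmentation", "permutation")


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of a run seed."""
    if name not in STREAMS:
        raise KeyError(f"unknown stream {name!r}; known: {STREAMS}")
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return np.random.default_rng(children[STREAMS.index(name)])
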
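"""Named, independent random substreams derived from one master seed.

Every stochastic component of an experiment draws from its own named
substream so that toggling one noise source (e.g. running the uncoupled
control) never shifts the draws of another.
"""
from __future__ import annotations

import numpy as np

# Fixed registry order: a stream's child index never depends on which
# streams a particular run actually consumes.  init_shared seeds the
# common part of the two agents' initial expectations; init_A/init_B seed
# their individual perturbations.
STREAM_NAMES = ("init_shared", "init_A", "init_B", "noise_A", "noise_B", "trials")


def substreams(seed: int, names: tuple[str, ...] = STREAM_NAMES) -> dict[str, np.random.Generator]:
    """Spawn one `numpy` Generator per registered stream name.

    All registered children are spawned unconditionally, in registry
    order, so the mapping name -> stream is a pure function of the seed.
    """
    if not (0 <= int(seed) < 2**63):
        raise ValueError(f"seed must be a non-negative 63-bit integer, got {seed!r}")
    children = np.random.SeedSequence(int(seed)).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}
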
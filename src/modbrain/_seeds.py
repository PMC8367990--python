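"""Deterministic seed derivation shared by all stochastic stages."""

from __future__ import annotations

import random

import igraph
import numpy as np

_MODULUS = 2**31 - 1


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning so stages can be re-run
    in isolation without correlated streams; results fit in a signed int32.
    """
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0]) % _MODULUS for c in ss.spawn(int(n))]


def seed_igraph(seed: int) -> None:
    """Point igraph's RNG at a freshly seeded Python generator.

    igraph's community routines draw from the generator installed globally;
    installing a new ``random.Random(seed)`` before each run makes every
    Louvain call reproducible.
    """
    igraph.set_random_number_generator(random.Random(int(seed)))
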
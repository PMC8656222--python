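"""Named, independently seeded random substreams.

A single global integer seed drives the whole simulation, but each
stochastic component (disease truth, image quality, classifier scores,
grader draws, QA sampling, bootstrap) reads from its own named substream.
Changing, say, grader noise therefore never perturbs the cohort draw.

Substreams are derived with :class:`numpy.random.SeedSequence` using a
stable per-name spawn key, so the mapping seed -> stream is reproducible
across sessions and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_seed"]


def _name_key(name: str) -> int:
    # stable 32-bit key per stream name (crc32 is deterministic across runs)
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream *name* under the global *seed*."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return np.random.default_rng(ss)


def derive_seed(seed: int, name: str) -> int:
    """Derive a child integer seed (< 2**31) for components that take one."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
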
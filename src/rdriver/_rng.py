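"""Seed plumbing: one user seed fans out to named substreams.

Every stochastic component (CV fold assignment, permutation null,
simulation, consensus resampling) draws its generator from
:func:`substream` so that results are reproducible from a single seed and
independent of the order in which components consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Parameters
    ----------
    seed:
        The run-level seed.
    name:
        Substream label, e.g. ``"cv"``, ``"permutation"``, ``"simulation"``.
    index:
        Optional replicate index within the substream (e.g. permutation
        number), so replicates are independent but individually addressable.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, int(index)])
    return np.random.default_rng(ss)
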
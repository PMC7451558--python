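"""Deterministic named RNG substreams.

Every stochastic stage draws from its own child stream of one root seed so
stages can be re-run independently and still reproduce byte-identical output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and Python versions
    return zlib.crc32(name.encode("utf-8"))


def substream(root_seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The same ``(root_seed, names)`` pair always yields the same stream;
    distinct names yield statistically independent streams.
    """
    keys = [_name_key(n) if isinstance(n, str) else int(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), *keys]))
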
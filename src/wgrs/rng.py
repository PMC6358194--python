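"""Named, independent random substreams derived from one master seed.

Every stochastic stage (genotype draws, phenotype draws, missingness masks,
each imputation chain) pulls its own generator keyed by a stage name, so
adding or re-ordering stages never perturbs the draws of another stage and
end-to-end runs are reproducible from a single integer seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]

_MASK31 = 0x7FFFFFFF


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8")) & _MASK31


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a generator for the substream identified by ``names``.

    The same ``(seed, names)`` pair always yields the same stream;
    different names yield statistically independent streams.
    """
    ss = np.random.SeedSequence(
        entropy=int(seed) & _MASK31, spawn_key=tuple(_name_key(n) for n in names)
    )
    return np.random.default_rng(ss)


def child_seed(seed: int, *names: str) -> int:
    """A derived integer seed (< 2**31) for APIs that take a plain seed."""
    ss = np.random.SeedSequence(
        entropy=int(seed) & _MASK31, spawn_key=tuple(_name_key(n) for n in names)
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & _MASK31
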
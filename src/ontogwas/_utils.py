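"""Seed bookkeeping: every source of randomness draws from a named substream."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed", "substream_rng", "as_frame"]


def as_frame(obj):
    """Unwrap matrix containers (OntotypeMatrix, Kinship, ...) to a DataFrame.

    DataFrames pass through untouched; ``None`` stays ``None``.
    """
    import pandas as pd

    if obj is None or isinstance(obj, pd.DataFrame):
        return obj
    v = getattr(obj, "values", None)
    if isinstance(v, pd.DataFrame):
        return v
    raise TypeError(
        f"expected a DataFrame or a container holding one, got {type(obj)!r}")


def substream(seed: int, *names) -> np.random.SeedSequence:
    """Deterministic named child of a root seed.

    Names are hashed with crc32 so the derivation is stable across runs and
    platforms; integers are passed through verbatim.
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    for name in names:
        if isinstance(name, (int, np.integer)):
            entropy.append(int(name) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(name).encode("utf8")))
    return np.random.SeedSequence(entropy)


def substream_seed(seed: int, *names) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    return int(substream(seed, *names).generate_state(1)[0] & 0x7FFFFFFF)


def substream_rng(seed: int, *names) -> np.random.Generator:
    return np.random.default_rng(substream(seed, *names))
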
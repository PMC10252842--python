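"""Deterministic seed derivation.

All stochastic components of a simulated federation hang off one master
seed.  Sub-seeds are derived through :class:`numpy.random.SeedSequence`
so that (a) the same master seed always reproduces the same run and
(b) per-round / per-client streams are statistically independent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "rng_from"]

# stream tags keep e.g. round-7 selection independent of client-7 training
_TAGS = {
    "init": 0x1A,
    "select": 0x2B,
    "client": 0x3C,
    "dropout": 0x4D,
    "data": 0x5E,
}


def derive_seed(master: int, stream: str, *indices: int) -> int:
    """Derive a 31-bit sub-seed from ``master`` for a named stream.

    Parameters
    ----------
    master:
        Master seed of the run.
    stream:
        One of ``init``, ``select``, ``client``, ``dropout``, ``data``.
    indices:
        Extra coordinates, e.g. ``(round,)`` or ``(round, client_id)``.
    """
    tag = _TAGS[stream]
    seq = np.random.SeedSequence(entropy=int(master), spawn_key=(tag, *map(int, indices)))
    return int(seq.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(master: int, stream: str, *indices: int) -> np.random.Generator:
    """A fresh :class:`numpy.random.Generator` for the derived sub-seed."""
    return np.random.default_rng(derive_seed(master, stream, *indices))
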
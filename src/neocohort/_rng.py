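"""Seed derivation helpers.

One global seed is fanned out to per-component child seeds through a stable
hash, so components are reproducible independently of each other and of call
order.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed", "stable_unit"]


def child_seed(seed: int, label: str) -> int:
    """Derive a deterministic child seed (< 2**31) from ``seed`` and a label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stable_unit(*parts: object) -> float:
    """Map arbitrary hashable parts to a uniform float in [0, 1).

    Pure function of its arguments: identical inputs give identical output
    across processes and platforms (unlike builtin ``hash``).
    """
    key = "\x1f".join(str(p) for p in parts).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "big") / 2**64
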
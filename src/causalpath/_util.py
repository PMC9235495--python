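"""Seed plumbing: all randomness in the package flows through one derivation."""

from __future__ import annotations

import numpy as np


def spawn_seeds(seed: int, k: int) -> list:
    """Derive ``k`` independent child seeds (< 2**31) from one top-level seed."""
    return [int(s.generate_state(1, dtype=np.uint64)[0] % (2**31)) for s in np.random.SeedSequence(int(seed)).spawn(k)]


def derive_seed(seed: int, *labels) -> int:
    """Deterministically derive a child seed from a seed and string labels."""
    entropy = [int(seed)] + [abs(hash_label(l)) for l in labels]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def hash_label(label) -> int:
    """Stable (process-independent) 31-bit hash of a string label."""
    h = 0
    for ch in str(label):
        h = (h * 1000003 + ord(ch)) % (2**31 - 1)
    return h
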
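"""Vectorised 2-bit k-mer encoding.

Shared by the simulator's bounded-repeat rejection sampler and the
whole-genome comparator's unique-match anchoring.  k is limited to 31 so
a k-mer packs into one unsigned 64-bit word.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i


def base_codes(seq: str) -> np.ndarray:
    """Per-base 2-bit codes (255 for ambiguous bases)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Encode every k-mer of ``seq`` into a uint64.

    Returns ``(values, valid)`` where ``values[i]`` encodes
    ``seq[i:i+k]`` and ``valid[i]`` is False when the window contains an
    ambiguous base (its value is then meaningless).
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be in [1, 31]")
    codes = base_codes(seq)
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        vals = (vals << np.uint64(2)) | codes[i : i + m].astype(np.uint64)
    bad = (codes > 3).astype(np.int32)
    run = np.cumsum(bad)
    window_bad = run[k - 1 :].copy()
    window_bad[1:] -= run[: m - 1]
    return vals, window_bad == 0


def canonical_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-canonical k-mer codes: min(code, code of reverse complement)."""
    from .assembly import revcomp

    fwd, fwd_ok = encode_kmers(seq, k)
    rc, rc_ok = encode_kmers(revcomp(seq), k)
    rc_at_fwd = rc[::-1] if len(rc) else rc
    return np.minimum(fwd, rc_at_fwd), fwd_ok & (rc_ok[::-1] if len(rc_ok) else rc_ok)
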
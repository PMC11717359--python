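"""Low-level DNA helpers: encoding, reverse complement, vectorized PSSM scoring.

Alphabet order is (A, C, G, T) everywhere; index 4 encodes N/ambiguous and
scores 0 bits (background-neutral) in every scan.
"""
from __future__ import annotations

from collections.abc import Iterable

import numpy as np

BASES = "ACGT"
N_INDEX = 4

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving N and case-insensitively mapping bases."""
    return seq.translate(_COMPLEMENT)[::-1]


_LUT = np.full(256, N_INDEX, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_DECODE = np.array(list(BASES + "N"))


def encode(seq: str) -> np.ndarray:
    """Encode one sequence to a uint8 vector (A=0, C=1, G=2, T=3, other=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_many(seqs: Iterable[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, W) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    widths = {len(s) for s in seqs}
    if len(widths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(widths)}")
    buf = "".join(seqs)
    return _LUT[np.frombuffer(buf.encode("ascii"), dtype=np.uint8)].reshape(
        len(seqs), widths.pop()
    )


def decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[np.asarray(arr)])


def sliding_scores(X: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Score every placement of a score matrix along encoded sequences.

    Parameters
    ----------
    X : (n, W) uint8 encoded sequences (4 = N).
    mat : (w, 4) per-position, per-base scores (any units).

    Returns
    -------
    (n, W - w + 1) array; entry [i, o] is the score of placing ``mat`` at
    offset ``o`` of sequence i. N positions contribute 0.
    """
    X = np.atleast_2d(X)
    n, W = X.shape
    w = mat.shape[0]
    m = W - w + 1
    if m < 1:
        raise ValueError(f"matrix of width {w} does not fit in sequences of width {W}")
    m5 = np.zeros((w, 5), dtype=np.float64)
    m5[:, :4] = mat
    S = np.zeros((n, m), dtype=np.float64)
    for j in range(w):
        S += m5[j][X[:, j : j + m]]
    return S


def scores_both_strands(X: np.ndarray, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(S_plus, S_minus) placement scores; offsets index the forward strand."""
    return sliding_scores(X, mat), sliding_scores(X, mat[::-1, ::-1])
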
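"""Low-level DNA string primitives shared by every pipeline stage.

All coordinates handed out by this module are 0-based offsets; the public
data model (``pirnet.io``) converts to 1-based transcript coordinates.
Mismatch model is substitutions-only (Hamming): the analyses these
primitives serve treat piRNA/target duplexes as ungapped.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 'N' never matches anything, including another 'N' (avoids fake exact hits).
_N = ord("N")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a DNA string for vectorized window comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_exact(target: str, query: str) -> list[int]:
    """All 0-based start offsets of exact occurrences of query in target.

    Overlapping occurrences are reported. A query containing N matches
    nowhere.
    """
    if not query or "N" in query:
        return []
    hits = []
    start = target.find(query)
    while start != -1:
        hits.append(start)
        start = target.find(query, start + 1)
    return hits


def hamming_profile(target_arr: np.ndarray, query_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of the query against every target window of its length.

    Returns an int array of length ``len(target) - len(query) + 1`` (empty if
    the target is shorter than the query). Positions where either base is N
    count as mismatches.
    """
    L = query_arr.size
    if target_arr.size < L:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target_arr, L)
    eq = windows == query_arr
    n_mask = (windows == _N) | (query_arr == _N)
    return (L - (eq & ~n_mask).sum(axis=1)).astype(np.int64)


def window_mismatch_offsets(
    target_arr: np.ndarray, query_arr: np.ndarray, start: int
) -> np.ndarray:
    """0-based offsets within the query-length window at ``start`` that mismatch."""
    L = query_arr.size
    win = target_arr[start : start + L]
    eq = win == query_arr
    n_mask = (win == _N) | (query_arr == _N)
    return np.nonzero(~(eq & ~n_mask))[0]
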
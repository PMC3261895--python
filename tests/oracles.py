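"""Independent oracles for the test suite.

Two implementations that share no code with the package's match engine:

* :func:`naive_count` — a pure-python window-by-window counter, the
  definitional reference for a single query on a tiny genome.
* :func:`shift_frequency_track` — exact frequencies of *every* position
  at once by exhaustive all-pairs window comparison, organised as a
  cross-correlation of the concatenated genome with itself and with its
  reverse complement (one vectorised pass per relative shift).  Used as
  the brute-force oracle for whole-track exactness checks; itself
  validated against :func:`naive_count` on tiny genomes.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _ham(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def naive_count(contigs, query: str, m: int, dna: bool = True):
    """(occurrence_count, sorted position list) by literal enumeration."""
    k = len(query)
    queries = [query, _revcomp(query)] if dna else [query]
    if dna and "N" in query:
        return 0, []
    occ = 0
    positions = set()
    offset = 0
    for _, seq in contigs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if dna and "N" in w:
                continue
            for q in queries:
                if _ham(w, q) <= m:
                    occ += 1
                    positions.add(offset + i)
        offset += len(seq)
    return occ, sorted(positions)


def naive_frequency_track(contigs, k: int, m: int) -> np.ndarray:
    """Per-position exact frequencies via :func:`naive_count` (tiny n only)."""
    n = sum(len(seq) for _, seq in contigs)
    F = np.zeros(n, dtype=np.int64)
    offset = 0
    for _, seq in contigs:
        for i in range(len(seq)):
            if i + k <= len(seq):
                w = seq[i : i + k]
                if "N" not in w:
                    F[offset + i] = naive_count(contigs, w, m)[0]
        offset += len(seq)
    return F


# ---------------------------------------------------------------------------
# shift-based exact track
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_SEP = 5


def _encode_padded(contigs) -> tuple[np.ndarray, list[int]]:
    parts = []
    starts = []
    pos = 0
    for _, seq in contigs:
        starts.append(pos)
        parts.append(np.array([_CODE[c] for c in seq], dtype=np.int8))
        parts.append(np.array([_SEP], dtype=np.int8))
        pos += len(seq) + 1
    return np.concatenate(parts), starts


def _window_ham_le(a: np.ndarray, b: np.ndarray, k: int, m: int) -> np.ndarray:
    """Boolean: Hamming(a[j:j+k], b[j:j+k]) <= m for each aligned start j."""
    neq = (a != b).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(neq)])
    return (cs[k:] - cs[:-k]) <= m


def shift_frequency_track(contigs, k: int, m: int) -> np.ndarray:
    """Exact dna-mode frequency of every position (0 where undefined)."""
    arr, starts = _encode_padded(contigs)
    n = len(arr)
    nwin = n - k + 1
    bad = arr >= 4  # N or separator
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = np.zeros(n, dtype=bool)
    if nwin > 0:
        valid[:nwin] = (cs[k:] - cs[:-k]) == 0

    F = np.zeros(n, dtype=np.int64)
    F[valid] = 1  # d = 0: every window matches itself on the forward strand

    # forward-vs-forward, relative shift d >= 1: each matching pair
    # (j, j+d) is one occurrence for both members
    for d in range(1, nwin):
        ok = _window_ham_le(arr[: n - d], arr[d:], k, m)
        js = np.flatnonzero(ok[: nwin - d] & valid[: nwin - d] & valid[d : d + nwin - d])
        F[js] += 1
        F[js + d] += 1

    # forward-vs-reverse-complement: window j of arr vs window p of r,
    # where r-window p equals revcomp of arr-window (n-k-p)
    comp = np.where(arr < 4, 3 - arr, arr).astype(np.int8)
    r = comp[::-1].copy()
    for delta in range(-(nwin - 1), nwin):
        if delta >= 0:
            a, b, j0 = arr[: n - delta], r[delta:], 0
        else:
            a, b, j0 = arr[-delta:], r[: n + delta], -delta
        ok = _window_ham_le(a, b, k, m)
        js = j0 + np.flatnonzero(ok)
        ps = js + delta
        js = js[(js < nwin) & (ps >= 0) & (ps < nwin)]
        iis = n - k - (js + delta)  # the position whose revcomp sits at p
        mask = valid[js] & valid[iis]
        F[iis[mask]] += 1

    # drop separator slots -> global coordinates
    keep = arr != _SEP
    return F[keep]
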
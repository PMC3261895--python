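"""Approximate k-mer matching: occurrence counting within m substitutions.

The primitive underlying every mappability computation is: given a query
k-mer, find all windows of the reference (and of its reverse complement)
within Hamming distance m.  Two routes are provided:

``count_matches``
    A direct sliding-window scan — the contract-defining reference
    implementation.  Linear in genome length per query.

``SearchIndex`` (via :func:`build_index`)
    A pigeonhole seed index: the query is split into ``m + 1`` disjoint
    seed chunks of length ``k // (m + 1)``; any window within m
    substitutions must match at least one chunk exactly, so exact seed
    lookups (rolling-hash tables built lazily per seed length) yield a
    candidate set that is then verified by full Hamming comparison.
    Results are bit-identical to ``count_matches`` for every (query, m).

Matching semantics:

* ``dna`` mode — the alphabet is {A,C,G,T,N}; occurrences of the query
  and of its reverse complement are both counted (a palindromic window
  therefore counts twice in ``occurrence_count``, but contributes one
  position).  A window containing N never matches, and a query
  containing N matches nothing: assembly gaps must not create spurious
  uniqueness or multiplicity.
* ``forward_only`` mode — arbitrary printable characters compared
  literally, forward strand only; intended for toy, non-DNA alphabets.

Only substitutions are considered; insertions and deletions are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import (
    N_CODE,
    ReferenceSequence,
    encode_bases,
    reverse_complement,
)

SEP_CODE = 5  # poisons windows spanning contig boundaries in the padded array
_HASH_BASE = np.uint64(1099511628211)  # FNV-1a prime; wraparound mod 2**64

COMPLEMENT_MODES = ("dna", "forward_only")


def hamming(a: str, b: str) -> int:
    """Number of substitutions between equal-length strings.

    Any position where either string carries an N counts as a mismatch:
    an ambiguous base can never be trusted to match.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} != {len(b)}")
    return sum(x != y or x == "N" for x, y in zip(a, b))


@dataclass
class MatchSet:
    """All matches of one query at <= m substitutions.

    ``positions`` holds the distinct forward-strand global start positions
    (sorted); ``occurrence_count`` counts forward and reverse-complement
    occurrences with multiplicity, so it can exceed ``len(positions)``.
    """

    query: str
    m: int
    positions: np.ndarray
    occurrence_count: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.occurrence_count < len(self.positions):
            raise ValueError("occurrence_count cannot be below |positions|")


def _check_query(query: str, m: int) -> None:
    k = len(query)
    if k == 0:
        raise ValueError("query must be non-empty")
    if m < 0 or m >= k:
        raise ValueError(f"need 0 <= m < k; got m={m}, k={k}")


# ---------------------------------------------------------------------------
# brute-force scan
# ---------------------------------------------------------------------------


def _scan_contig(codes: np.ndarray, q: np.ndarray, m: int, check_n: bool) -> np.ndarray:
    """Start offsets of windows of ``codes`` within m mismatches of ``q``."""
    k = len(q)
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    mism = (windows != q).sum(axis=1)
    ok = mism <= m
    if check_n:
        ok &= ~(windows == N_CODE).any(axis=1)
    return np.flatnonzero(ok).astype(np.int64)


def count_matches(
    ref: ReferenceSequence, query: str, m: int, complement_mode: str = "dna"
) -> MatchSet:
    """Scan every window of every contig; the reference implementation.

    See the module docstring for the dna / forward_only semantics.
    """
    if complement_mode not in COMPLEMENT_MODES:
        raise ValueError(f"complement_mode must be one of {COMPLEMENT_MODES}")
    _check_query(query, m)

    if complement_mode == "dna":
        if "N" in query:
            return MatchSet(query, m, np.empty(0, dtype=np.int64), 0)
        queries = [encode_bases(query), encode_bases(reverse_complement(query))]
        check_n = True
        enc = encode_bases
    else:
        queries = [np.frombuffer(query.encode("ascii"), dtype=np.uint8)]
        check_n = False
        enc = lambda s: np.frombuffer(s.encode("ascii"), dtype=np.uint8)  # noqa: E731

    occurrence = 0
    hit_positions: list[np.ndarray] = []
    for idx, (_, seq) in enumerate(ref.contigs):
        codes = enc(seq)
        offset = int(ref.offsets[idx])
        for q in queries:
            hits = _scan_contig(codes, q, m, check_n)
            occurrence += len(hits)
            if len(hits):
                hit_positions.append(hits + offset)
    if hit_positions:
        positions = np.unique(np.concatenate(hit_positions))
    else:
        positions = np.empty(0, dtype=np.int64)
    return MatchSet(query, m, positions, occurrence)


# ---------------------------------------------------------------------------
# indexed engine
# ---------------------------------------------------------------------------


def _rolling_hashes(arr: np.ndarray, s: int) -> np.ndarray:
    """Polynomial hash of every length-s window (wraps mod 2**64).

    Horner evaluation as s vectorised passes over the array.  Equal
    windows always share a hash; collisions only enlarge the candidate
    set, which full Hamming verification then prunes.
    """
    vals = arr.astype(np.uint64)
    n = len(vals)
    if n < s:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n - s + 1, dtype=np.uint64)
    for j in range(s):
        h = h * _HASH_BASE + vals[j : j + n - s + 1]
    return h


class _SeedTable:
    """Exact-match lookup of fixed-length seeds via sorted rolling hashes."""

    def __init__(self, arr: np.ndarray, s: int):
        self.s = s
        hashes = _rolling_hashes(arr, s)
        self.order = np.argsort(hashes, kind="stable").astype(np.int64)
        self.sorted_hashes = hashes[self.order]

    def lookup(self, seed_hash: np.uint64) -> np.ndarray:
        lo = np.searchsorted(self.sorted_hashes, seed_hash, side="left")
        hi = np.searchsorted(self.sorted_hashes, seed_hash, side="right")
        return self.order[lo:hi]


class SearchIndex:
    """Pigeonhole seed index over a reference; see the module docstring.

    Results are bit-identical to :func:`count_matches`; the index exists
    purely to avoid the per-query full scan when many queries share the
    same (k, m), as whole-track computation does.
    """

    def __init__(self, ref: ReferenceSequence):
        self.ref = ref
        # contigs are concatenated with a separator code so no window can
        # span a boundary and one table serves the whole genome
        starts = []
        pos = 0
        for _, seq in ref.contigs:
            starts.append(pos)
            pos += len(seq) + 1
        self.contig_padded_starts = np.asarray(starts, dtype=np.int64)
        self._padded: np.ndarray | None = None  # dna codes, lazy
        self._tables: dict[int, _SeedTable] = {}
        # toy-alphabet (forward_only) mirror, built on demand
        self._raw_padded: np.ndarray | None = None
        self._raw_tables: dict[int, _SeedTable] = {}

    @property
    def padded(self) -> np.ndarray:
        if self._padded is None:
            parts = []
            for _, seq in self.ref.contigs:
                parts.append(encode_bases(seq))
                parts.append(np.array([SEP_CODE], dtype=np.uint8))
            self._padded = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
            )
        return self._padded

    # -- plumbing ----------------------------------------------------------

    def _padded_to_global(self, p: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.contig_padded_starts, p, side="right") - 1
        return p - idx  # each preceding contig contributes one separator

    def _global_to_padded(self, g: int) -> int:
        idx = int(np.searchsorted(self.ref.offsets, g, side="right")) - 1
        return g + idx

    def _table(self, s: int, raw: bool) -> _SeedTable:
        cache = self._raw_tables if raw else self._tables
        if s not in cache:
            cache[s] = _SeedTable(self._array(raw), s)
        return cache[s]

    def _array(self, raw: bool) -> np.ndarray:
        if not raw:
            return self.padded
        if self._raw_padded is None:
            parts = []
            for _, seq in self.ref.contigs:
                parts.append(np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
                parts.append(np.zeros(1, dtype=np.uint8))  # NUL separator
            self._raw_padded = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
            )
        return self._raw_padded

    def _candidates(self, q: np.ndarray, m: int, raw: bool) -> np.ndarray:
        k = len(q)
        s = k // (m + 1)
        table = self._table(s, raw)
        qh = _rolling_hashes(q, s)
        cands = []
        for i in range(m + 1):
            hits = table.lookup(qh[i * s])
            if len(hits):
                cands.append(hits - i * s)
        if not cands:
            return np.empty(0, dtype=np.int64)
        cand = np.unique(np.concatenate(cands))
        arr = self._array(raw)
        return cand[(cand >= 0) & (cand + k <= len(arr))]

    def _verify(self, cand: np.ndarray, q: np.ndarray, m: int, raw: bool) -> np.ndarray:
        if len(cand) == 0:
            return cand
        arr = self._array(raw)
        k = len(q)
        windows = arr[cand[:, None] + np.arange(k)]
        mism = (windows != q).sum(axis=1)
        if raw:
            ok = (mism <= m) & ~(windows == 0).any(axis=1)
        else:
            ok = (mism <= m) & ~(windows >= N_CODE).any(axis=1)
        return cand[ok]

    # -- queries -----------------------------------------------------------

    def count(self, query: str, m: int, complement_mode: str = "dna") -> MatchSet:
        """Indexed equivalent of :func:`count_matches`."""
        if complement_mode not in COMPLEMENT_MODES:
            raise ValueError(f"complement_mode must be one of {COMPLEMENT_MODES}")
        _check_query(query, m)
        if complement_mode == "dna":
            if "N" in query:
                return MatchSet(query, m, np.empty(0, dtype=np.int64), 0)
            q = encode_bases(query)
            occ, padded_hits = self._count_encoded(q, m)
            positions = self._padded_to_global(padded_hits)
            return MatchSet(query, m, positions, occ)
        q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        hits = self._verify(self._candidates(q, m, raw=True), q, m, raw=True)
        # raw layout has one NUL per preceding contig, same arithmetic
        positions = self._padded_to_global(hits)
        return MatchSet(query, m, np.sort(positions), len(hits))

    def _count_encoded(self, q: np.ndarray, m: int) -> tuple[int, np.ndarray]:
        """dna-mode core on an encoded query; returns (occurrences, padded P)."""
        rc = (3 - q[::-1]).astype(np.uint8)  # N never occurs here (query N-free)
        fwd = self._verify(self._candidates(q, m, raw=False), q, m, raw=False)
        rev = self._verify(self._candidates(rc, m, raw=False), rc, m, raw=False)
        occ = len(fwd) + len(rev)
        padded = np.unique(np.concatenate([fwd, rev]))
        return occ, padded

    def match_position(self, g: int, k: int, m: int) -> tuple[int, np.ndarray] | None:
        """Occurrence count and global match positions for the k-mer at
        global position ``g``, or None if the window is invalid (crosses
        the contig end or contains N)."""
        p = self._global_to_padded(g)
        window = self.padded[p : p + k]
        if len(window) < k or (window >= N_CODE).any():
            return None
        occ, padded_hits = self._count_encoded(window, m)
        return occ, self._padded_to_global(padded_hits)


def build_index(ref: ReferenceSequence) -> SearchIndex:
    """Build the indexed engine for ``ref``."""
    return SearchIndex(ref)
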
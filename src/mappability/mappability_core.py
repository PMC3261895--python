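"""Frequency and mappability tracks: exact computation and the
threshold-t approximation.

The k-frequency F[i] of a genome position i is the number of occurrences
of the k-mer starting at i, in the sequence and in its reverse
complement, counting every k-mer within m substitutions as equivalent.
The k-mappability is M[i] = 1 / F[i]; positions hosting no valid k-mer
(an N in the window, or fewer than k bases left in the contig) carry
F[i] = 0 and M[i] = 0.

Computing F exactly requires one counting query per position.  The
approximation trades exactness for speed via a threshold t: whenever a
query at position i matches a set P of positions with |P| >= t, the
occurrence count is propagated to every position in P, and those
positions are skipped when the traversal reaches them.  The propagation
is write-once-or-max: a position hit repeatedly keeps the maximum of
the propagated counts, so an underestimate is avoided where possible.
Properties of the approximation (all tested):

* exact for every position when m = 0 (equivalence classes coincide);
* exact when t is disabled (no propagation happens);
* exact at every position that is unique at (k, m) — a unique k-mer can
  never appear in another k-mer's match set;
* any position whose reported value is below t was computed directly,
  hence is exact (propagated values are always >= t).

The traversal visits positions in ascending global order, which makes
the output a pure function of (ref, k, m, t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import ReferenceSequence
from .match_engine import SearchIndex

#: sentinel meaning "approximation disabled, compute every position"
T_DISABLED = None


@dataclass
class TrackParams:
    k: int
    m: int
    t: int | None  # None = exact

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.m < self.k:
            raise ValueError(f"need 0 <= m < k; got m={self.m}, k={self.k}")
        if self.t is not None and self.t < 2:
            # t = 1 would propagate over singleton (unique) classes and
            # destroy the unique-position exactness guarantee
            raise ValueError("t must be >= 2, or None to disable the approximation")


@dataclass
class FrequencyTrack:
    """Per-global-position occurrence counts with their parameters."""

    values: np.ndarray  # uint32/int64 F, 0 = undefined
    params: TrackParams
    contig_names: list[str]
    contig_lengths: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if len(self.values) != sum(self.contig_lengths):
            raise ValueError("track length does not match contig lengths")

    @property
    def n(self) -> int:
        return len(self.values)

    def contig_slice(self, name: str) -> slice:
        idx = self.contig_names.index(name)
        start = sum(self.contig_lengths[:idx])
        return slice(start, start + self.contig_lengths[idx])

    def same_layout(self, other: "FrequencyTrack") -> bool:
        return (
            self.params.k == other.params.k
            and self.params.m == other.params.m
            and self.contig_names == other.contig_names
            and self.contig_lengths == other.contig_lengths
        )


@dataclass
class MappabilityTrack:
    """Per-position 1/F in (0, 1]; 0 where F is undefined."""

    values: np.ndarray
    params: TrackParams
    contig_names: list[str]
    contig_lengths: list[int]

    @property
    def n(self) -> int:
        return len(self.values)

    def contig_slice(self, name: str) -> slice:
        idx = self.contig_names.index(name)
        start = sum(self.contig_lengths[:idx])
        return slice(start, start + self.contig_lengths[idx])


def default_threshold(n: int) -> int:
    """Default approximation threshold, grown slowly with genome size.

    max(8, ceil(log2 n)): small frequency classes stay exact while large
    repeat families are still collapsed (~27 for 100 Mb, ~32 for 3 Gb).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(8, int(np.ceil(np.log2(max(n, 2)))))


def _valid_mask(index: SearchIndex, k: int) -> np.ndarray:
    """True where a position hosts a valid k-mer (fits the contig, no N)."""
    from .genome_io import N_CODE

    padded = index.padded
    bad = padded >= N_CODE  # N or separator
    # windows with any bad symbol, via cumulative sums
    cs = np.concatenate([[0], np.cumsum(bad)])
    nwin = len(padded) - k + 1
    ok_padded = np.zeros(len(padded), dtype=bool)
    if nwin > 0:
        ok_padded[:nwin] = (cs[k:] - cs[:-k]) == 0
    # map padded window starts back to global positions
    valid = np.zeros(index.ref.n, dtype=bool)
    starts = index.contig_padded_starts
    for idx, (name, seq) in enumerate(index.ref.contigs):
        p0 = int(starts[idx])
        g0 = int(index.ref.offsets[idx])
        L = len(seq)
        valid[g0 : g0 + L] = ok_padded[p0 : p0 + L]
    return valid


def compute_frequency_track(
    ref: ReferenceSequence,
    k: int,
    m: int,
    t: int | None,
    index: SearchIndex | None = None,
) -> FrequencyTrack:
    """Approximate (or, with ``t=None``, exact) frequency track.

    For each valid position i in ascending order with F[i] still 0: count
    the occurrences of the k-mer at i (both strands, <= m substitutions)
    and set F[i].  If the match-position set P has |P| >= t, write the
    count to every j in P — directly if F[j] is unset, else as
    max(F[j], count).  Undefined positions stay 0 throughout.
    """
    params = TrackParams(k, m, t)
    if index is None:
        index = SearchIndex(ref)
    F = np.zeros(ref.n, dtype=np.int64)
    valid = _valid_mask(index, k)
    for i in np.flatnonzero(valid):
        i = int(i)
        if F[i] != 0:
            continue
        occ, positions = index.match_position(i, k, m)
        F[i] = occ
        if t is not None and len(positions) >= t:
            # write-once-or-max: unset members of P receive the count,
            # already-written ones keep the larger value
            F[positions] = np.maximum(F[positions], occ)
    return FrequencyTrack(F, params, ref.names, ref.lengths)


def exact_frequency_track(
    ref: ReferenceSequence, k: int, m: int, index: SearchIndex | None = None
) -> FrequencyTrack:
    """Exact frequencies: every position counted directly (t disabled)."""
    return compute_frequency_track(ref, k, m, T_DISABLED, index=index)


def frequency_to_mappability(track: FrequencyTrack) -> MappabilityTrack:
    """Elementwise 1/F; undefined (F = 0) positions map to 0."""
    F = track.values.astype(np.float64)
    M = np.zeros_like(F)
    np.divide(1.0, F, out=M, where=F >= 1)
    return MappabilityTrack(M, track.params, track.contig_names, track.contig_lengths)


def compare_bins(
    exact: FrequencyTrack, approx: FrequencyTrack, codec
) -> np.ndarray:
    """Bin-migration matrix between an exact and an approximate run.

    Entry (a, b) counts positions whose exact frequency encodes to code a
    and whose approximate frequency encodes to code b under ``codec`` (an
    :class:`~mappability.track_io.EncodingTable`).  Row sums therefore
    equal the exact bin occupancies; with the approximation disabled (or
    m = 0) the matrix is diagonal.
    """
    if not exact.same_layout(approx):
        raise ValueError("tracks differ in (k, m) or contig layout")
    a = codec.encode(exact.values)
    b = codec.encode(approx.values)
    ncodes = codec.code_count
    return np.bincount(a * ncodes + b, minlength=ncodes * ncodes).reshape(
        ncodes, ncodes
    )
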
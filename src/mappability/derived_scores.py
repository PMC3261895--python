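"""Scores derived from a mappability track: pileup mappability,
paired-end mappability with mate rescue, rescue fractions, and the
proper length of a sequence.

Pileup mappability models a pileup column: a position p of the genome
can be covered by up to l reads of length l (one per start offset), so
its pileup mappability is the mean single-position mappability over the
valid k-mer starts in [p - l + 1, p] (k = l).

Paired-end mappability exploits the mate at insert-size distance d
(start-to-start, standard deviation assumed zero).  With u the pileup
mappability of the target and v-, v+ those of the two possible mates,
exactly three cases arise:

1. u >= both available mates        -> u (the pairs cannot help);
2. u < exactly one available mate   -> (u + that mate) / 2;
3. u < both available mates         -> (v- + v+) / 2.

A mate is unavailable when it falls off the contig or on an undefined
position; with no mate available the single-end value is returned.

The rescue fraction asks, among non-unique positions (F > 1), which
proportion becomes fully rescuable because *both* mates are unique
(F = 1): short repeats flanked by unique sequence are rescued once the
insert size exceeds the repeat scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mappability_core import FrequencyTrack, MappabilityTrack


@dataclass
class LibrarySpec:
    """Sequencing-library geometry: read length l and insert size d
    (start-to-start distance between the two mate windows).  The
    fragment-size standard deviation is fixed at zero."""

    read_length: int
    insert_size: int

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read length must be >= 1")
        if self.insert_size <= self.read_length:
            raise ValueError("insert size must exceed the read length")


def pileup_mappability(track: MappabilityTrack, p: int, l: int) -> float:
    """Mean mappability of the l-mers covering position p.

    Valid covering starts are those in [p - l + 1, p] that lie in the
    same contig as p and host a defined k-mer (M > 0).  Returns 0.0 when
    no covering k-mer is valid.
    """
    if l != track.params.k:
        raise ValueError(
            f"track was computed with k={track.params.k}, not read length {l}"
        )
    if not 0 <= p < track.n:
        raise IndexError(f"position {p} outside [0, {track.n})")
    bounds = np.concatenate([[0], np.cumsum(track.contig_lengths)])
    c = int(np.searchsorted(bounds, p, side="right")) - 1
    lo = max(p - l + 1, int(bounds[c]))
    window = track.values[lo : p + 1]
    defined = window[window > 0]
    if len(defined) == 0:
        return 0.0
    return float(defined.mean())


def _mate_value(track: MappabilityTrack, p: int, mate: int, l: int) -> float | None:
    """Pileup mappability at a mate position, or None if unavailable."""
    if not 0 <= mate < track.n:
        return None
    bounds = np.concatenate([[0], np.cumsum(track.contig_lengths)])
    if np.searchsorted(bounds, p, side="right") != np.searchsorted(
        bounds, mate, side="right"
    ):
        return None  # different contig
    if track.values[mate] == 0:
        return None  # undefined position
    return pileup_mappability(track, mate, l)


def paired_end_mappability(
    track: MappabilityTrack, p: int, lib: LibrarySpec
) -> float:
    """Three-case paired-end mappability at position p (module docstring)."""
    l, d = lib.read_length, lib.insert_size
    u = pileup_mappability(track, p, l)
    mates = [
        v
        for v in (
            _mate_value(track, p, p - d, l),
            _mate_value(track, p, p + d, l),
        )
        if v is not None
    ]
    if not mates:
        return u
    better = [v for v in mates if u < v]
    if not better:  # case 1: target already at least as mappable
        return u
    if len(better) == 1:  # case 2: average with the single better mate
        return (u + better[0]) / 2.0
    return sum(mates) / 2.0  # case 3: average of the two mates


def rescue_fraction(
    freq_track: FrequencyTrack, lib: LibrarySpec
) -> float:
    """Fraction of non-unique positions whose both mates are unique.

    Eligible positions have F > 1; a position is rescued when both
    p - d and p + d fall on the same contig and have F = 1.  Returns NaN
    when no position is eligible.
    """
    total_eligible = 0
    total_rescued = 0
    for name in freq_track.contig_names:
        eligible, rescued = _contig_rescue_counts(freq_track, name, lib.insert_size)
        total_eligible += eligible
        total_rescued += rescued
    if total_eligible == 0:
        return float("nan")
    return total_rescued / total_eligible


def _contig_rescue_counts(
    freq_track: FrequencyTrack, contig: str, d: int
) -> tuple[int, int]:
    F = freq_track.values[freq_track.contig_slice(contig)]
    L = len(F)
    eligible = np.flatnonzero(F > 1)
    if len(eligible) == 0:
        return 0, 0
    both_in = (eligible - d >= 0) & (eligible + d < L)
    candidates = eligible[both_in]
    rescued = (F[candidates - d] == 1) & (F[candidates + d] == 1)
    return len(eligible), int(rescued.sum())


def rescue_sweep(
    freq_track: FrequencyTrack, lib_l: int, insert_sizes: list[int]
) -> pd.DataFrame:
    """Per-contig rescue fractions over a sweep of insert sizes.

    Returns a DataFrame with columns contig, d, eligible_positions,
    rescued, fraction (NaN where no position is eligible).
    """
    rows = []
    for d in insert_sizes:
        LibrarySpec(lib_l, d)  # validate geometry
        for name in freq_track.contig_names:
            eligible, rescued = _contig_rescue_counts(freq_track, name, d)
            rows.append(
                {
                    "contig": name,
                    "d": d,
                    "eligible_positions": eligible,
                    "rescued": rescued,
                    "fraction": rescued / eligible if eligible else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def proper_length(n: int, s: int = 4) -> int:
    """Shortest word length at which a random n-length sequence over an
    s-letter alphabet is expected to contain any given word about once:
    the smallest l with s**l >= n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if s < 2:
        raise ValueError("alphabet size must be >= 2")
    l = 0
    power = 1
    while power < n:
        power *= s
        l += 1
    return l
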
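"""Track serialisation: reduced-precision codec, pseudo-multi-FASTA
files, an indexed region retriever, and BedGraph export.

A frequency track is written one printable ASCII character per genome
position, in a FASTA-like layout (one ``>name`` header per contig,
60-column lines) preceded by ``~``-prefixed metadata lines that make the
file self-describing: the (k, m, t) parameters, the codec constants and
the contig table.

The codec mirrors reduced-precision 8-bit frequency encoding with 94
printable codes ('!' .. '~'): code 0 marks an undefined position (F = 0),
codes 1..exact_max store the frequency exactly, and the remaining codes
partition (exact_max, 2^32] into geometrically growing ranges, the last
code doubling as an overflow catch-all.  Each range code decodes to the
geometric midpoint of its range, which keeps the multiplicative error
small — and the mappability 1/F of a large frequency is insensitive to
it anyway.

A faidx-style sidecar index (JSON: per-contig byte offsets plus the line
width) lets :func:`query_region` fetch an interval without reading the
whole file.
"""

from __future__ import annotations

import json
import math
import os

import numpy as np

from .mappability_core import FrequencyTrack, MappabilityTrack, TrackParams

CHAR_OFFSET = 33  # '!'
LINE_WIDTH = 60
MAGIC = "~mappability-track v1"

DEFAULT_EXACT_MAX = 60
DEFAULT_CODE_COUNT = 94
DEFAULT_MAX_VALUE = 2**32


class EncodingTable:
    """Frequency -> printable code mapping (see module docstring).

    Invariants (validated on construction): codes are contiguous and
    monotone in F; ``encode(representative(c)) == c`` for every code;
    ranges are non-overlapping and jointly cover (exact_max, max_value].
    """

    def __init__(
        self,
        exact_max: int = DEFAULT_EXACT_MAX,
        code_count: int = DEFAULT_CODE_COUNT,
        max_value: int = DEFAULT_MAX_VALUE,
    ):
        n_range = code_count - 1 - exact_max
        if exact_max < 1 or n_range < 1:
            raise ValueError("need >= 1 exact code and >= 1 range code")
        self.exact_max = exact_max
        self.code_count = code_count
        self.max_value = max_value
        growth = (max_value / exact_max) ** (1.0 / n_range)
        # integer upper bounds, forced strictly increasing; the last one
        # is pinned to max_value so the ranges tile (exact_max, max_value]
        his = []
        prev = exact_max
        for j in range(1, n_range + 1):
            hi = int(math.floor(exact_max * growth**j))
            hi = max(hi, prev + 1)
            his.append(hi)
            prev = hi
        his[-1] = max(max_value, prev)
        self.range_his = np.asarray(his, dtype=np.int64)
        self.range_los = np.concatenate([[exact_max + 1], self.range_his[:-1] + 1])
        # decodable representative per code
        reps = np.arange(code_count, dtype=np.int64)
        for j in range(n_range):
            lo, hi = int(self.range_los[j]), int(self.range_his[j])
            reps[exact_max + 1 + j] = round(math.sqrt(lo * hi))
        self.representatives = reps
        if not (self.encode(reps[1:]) == np.arange(1, code_count)).all():
            raise AssertionError("codec self-check failed: encode(rep) != code")

    def encode(self, F) -> np.ndarray | int:
        """Code(s) for frequency value(s); monotone non-decreasing in F."""
        scalar = np.isscalar(F)
        F = np.atleast_1d(np.asarray(F, dtype=np.int64))
        if (F < 0).any():
            raise ValueError("frequencies must be non-negative")
        codes = np.where(F <= self.exact_max, F, 0).astype(np.int64)
        big = F > self.exact_max
        if big.any():
            idx = np.searchsorted(self.range_his, F[big], side="left")
            codes[big] = np.minimum(self.exact_max + 1 + idx, self.code_count - 1)
        return int(codes[0]) if scalar else codes

    def decode(self, codes) -> np.ndarray | int:
        """Representative frequency value(s) for code(s)."""
        scalar = np.isscalar(codes)
        codes = np.atleast_1d(np.asarray(codes, dtype=np.int64))
        if (codes < 0).any() or (codes >= self.code_count).any():
            raise ValueError("code out of range")
        out = self.representatives[codes]
        return int(out[0]) if scalar else out

    def range_of(self, code: int) -> tuple[int, int]:
        """Inclusive [lo, hi] of frequencies mapping to ``code``."""
        if code == 0:
            return (0, 0)
        if code <= self.exact_max:
            return (code, code)
        j = code - self.exact_max - 1
        return (int(self.range_los[j]), int(self.range_his[j]))


# ---------------------------------------------------------------------------
# pseudo-multi-FASTA writer / reader
# ---------------------------------------------------------------------------


def _codes_to_chars(codes: np.ndarray) -> np.ndarray:
    return (codes.astype(np.uint8) + CHAR_OFFSET).view("S1")


def write_track(track: FrequencyTrack, table: EncodingTable, path) -> None:
    """Serialise a frequency track (metadata preamble + one record per
    contig, one character per position, 60-column wrapped)."""
    if not track.contig_names:
        raise ValueError("track has no contigs")
    t_str = "exact" if track.params.t is None else str(track.params.t)
    with open(path, "w", newline="\n") as fh:
        fh.write(MAGIC + "\n")
        fh.write(f"~params k={track.params.k} m={track.params.m} t={t_str}\n")
        fh.write(
            f"~encoding exact_max={table.exact_max} "
            f"code_count={table.code_count} max_value={table.max_value}\n"
        )
        for name, length in zip(track.contig_names, track.contig_lengths):
            fh.write(f"~contig {name} {length}\n")
        for name in track.contig_names:
            codes = np.asarray(table.encode(track.values[track.contig_slice(name)]))
            chars = _codes_to_chars(codes).tobytes().decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(chars), LINE_WIDTH):
                fh.write(chars[i : i + LINE_WIDTH] + "\n")


def _parse_preamble(fh, label: str):
    magic = fh.readline().rstrip("\n")
    if magic != MAGIC:
        raise ValueError(f"{label}: not a mappability track file")
    params = None
    enc = None
    contigs: list[tuple[str, int]] = []
    while True:
        pos = fh.tell()
        line = fh.readline()
        if not line.startswith("~"):
            fh.seek(pos)
            break
        fields = line[1:].split()
        if fields[0] == "params":
            kv = dict(f.split("=") for f in fields[1:])
            t = None if kv["t"] == "exact" else int(kv["t"])
            params = TrackParams(int(kv["k"]), int(kv["m"]), t)
        elif fields[0] == "encoding":
            kv = dict(f.split("=") for f in fields[1:])
            enc = EncodingTable(
                int(kv["exact_max"]), int(kv["code_count"]), int(kv["max_value"])
            )
        elif fields[0] == "contig":
            contigs.append((fields[1], int(fields[2])))
    if params is None or enc is None or not contigs:
        raise ValueError(f"{label}: incomplete track preamble")
    return params, enc, contigs


def read_track(path) -> tuple[FrequencyTrack, EncodingTable]:
    """Read a track file back; values are the decoded representatives."""
    with open(path) as fh:
        params, table, contigs = _parse_preamble(fh, str(path))
        per_contig: dict[str, str] = {}
        current = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                current = line[1:].split()[0]
                per_contig[current] = ""
            elif line:
                per_contig[current] += line
    values = []
    for name, length in contigs:
        chars = per_contig.get(name, "")
        if len(chars) != length:
            raise ValueError(
                f"{path}: contig {name}: expected {length} codes, found {len(chars)}"
            )
        codes = np.frombuffer(chars.encode("ascii"), dtype=np.uint8).astype(
            np.int64
        ) - CHAR_OFFSET
        values.append(table.decode(codes))
    track = FrequencyTrack(
        np.concatenate(values),
        params,
        [name for name, _ in contigs],
        [length for _, length in contigs],
    )
    return track, table


# ---------------------------------------------------------------------------
# indexed retrieval
# ---------------------------------------------------------------------------


def build_track_index(path) -> str:
    """Write the faidx-style sidecar (<path>.idx) and return its path.

    Records, per contig, the byte offset of its first encoded character
    plus the fixed line width, enabling O(1) seeks into the body.
    """
    entries = []
    with open(path, "rb") as fh:  # binary mode: byte offsets must be exact
        offset = 0
        for line in iter(fh.readline, b""):
            if line.startswith(b">"):
                name = line[1:].split()[0].decode()
                entries.append({"name": name, "offset": offset + len(line)})
            offset += len(line)
    # attach lengths from the preamble
    with open(path) as fh:
        _, _, contigs = _parse_preamble(fh, str(path))
    lengths = dict(contigs)
    for e in entries:
        e["length"] = lengths[e["name"]]
    idx_path = str(path) + ".idx"
    with open(idx_path, "w") as fh:
        json.dump({"line_width": LINE_WIDTH, "contigs": entries}, fh)
    return idx_path


def query_region(
    path, contig: str, start: int, end: int, as_mappability: bool = False
):
    """Decoded values for [start, end) of ``contig`` via the sidecar index.

    Builds the index on first use.  Returns representative frequencies,
    or their reciprocals (0 where undefined) when ``as_mappability``.
    Agrees exactly with slicing the full :func:`read_track` result.
    """
    idx_path = str(path) + ".idx"
    if not os.path.exists(idx_path):
        build_track_index(path)
    with open(idx_path) as fh:
        index = json.load(fh)
    width = index["line_width"]
    entry = next((e for e in index["contigs"] if e["name"] == contig), None)
    if entry is None:
        raise KeyError(f"unknown contig {contig!r}")
    if start < 0 or end > entry["length"] or start >= end:
        raise ValueError(
            f"invalid interval [{start}, {end}) for contig {contig!r} "
            f"of length {entry['length']}"
        )
    first_byte = entry["offset"] + (start // width) * (width + 1) + start % width
    last = end - 1
    last_byte = entry["offset"] + (last // width) * (width + 1) + last % width
    with open(path, "rb") as fh:
        fh.seek(first_byte)
        blob = fh.read(last_byte - first_byte + 1)
    chars = blob.replace(b"\n", b"")
    codes = np.frombuffer(chars, dtype=np.uint8).astype(np.int64) - CHAR_OFFSET
    # rebuild the codec from the file itself
    with open(path) as fh:
        _, table, _ = _parse_preamble(fh, str(path))
    freqs = table.decode(codes)
    if not as_mappability:
        return freqs
    M = np.zeros(len(freqs), dtype=np.float64)
    np.divide(1.0, freqs, out=M, where=freqs >= 1)
    return M


# ---------------------------------------------------------------------------
# BedGraph export
# ---------------------------------------------------------------------------


def export_bedgraph(track: MappabilityTrack, path) -> None:
    """0-based half-open BedGraph with adjacent equal values merged.

    Undefined positions are emitted with value 0, so the intervals of
    each contig tile it completely (their lengths sum to the contig
    length).
    """
    with open(path, "w", newline="\n") as fh:
        for name, length in zip(track.contig_names, track.contig_lengths):
            vals = track.values[track.contig_slice(name)]
            if length == 0:
                continue
            breaks = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [length]])
            for s, e in zip(starts, ends):
                fh.write(f"{name}\t{s}\t{e}\t{vals[s]:.10g}\n")
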
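"""Reference-sequence loading, validation and coordinate arithmetic.

A genome is held as a :class:`ReferenceSequence`: an ordered list of contigs
over the alphabet ``{A, C, G, T, N}`` together with a single global,
0-based coordinate system obtained by concatenating the contigs in file
order.  Every other module addresses positions through this global index;
k-mers never span contig boundaries.

Normalisation on load: lowercase (soft-masked) bases are folded to
uppercase, and any IUPAC ambiguity code other than A/C/G/T becomes ``N``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric codes used by the match engine; N deliberately last
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
N_CODE = BASE_CODES["N"]

_NORMALIZE = {c: c for c in "ACGT"}
_NORMALIZE.update({c.lower(): c for c in "ACGT"})


def _normalize_seq(raw: str) -> str:
    """Uppercase and collapse non-ACGT IUPAC codes to N."""
    out = []
    for ch in raw:
        up = _NORMALIZE.get(ch)
        if up is None:
            if not ch.isalpha():
                raise ValueError(f"invalid character {ch!r} in sequence")
            up = "N"
        out.append(up)
    return "".join(out)


class FastaError(ValueError):
    """Malformed FASTA input."""


@dataclass
class ReferenceSequence:
    """Validated multi-contig DNA with global <-> (contig, offset) maps.

    Parameters
    ----------
    contigs:
        Ordered ``(name, sequence)`` pairs.  Sequences must already be
        normalised to the ``{A,C,G,T,N}`` alphabet (use :func:`read_fasta`
        or :meth:`from_raw` for arbitrary input).
    """

    contigs: list[tuple[str, str]]
    dna: bool = True  # False: toy alphabet of arbitrary printable characters
    offsets: np.ndarray = field(init=False, repr=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.contigs]
        if len(names) != len(set(names)):
            raise ValueError("contig names must be unique")
        if any(not name for name in names):
            raise ValueError("contig names must be non-empty")
        if self.dna:
            for name, seq in self.contigs:
                bad = set(seq) - ALPHABET
                if bad:
                    raise ValueError(
                        f"contig {name!r} contains characters outside ACGTN: "
                        f"{sorted(bad)}"
                    )
        lengths = [len(seq) for _, seq in self.contigs]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        self.n = int(self.offsets[-1])

    @classmethod
    def from_raw(cls, contigs: Iterable[tuple[str, str]]) -> "ReferenceSequence":
        """Build from arbitrary-case, possibly ambiguous sequences."""
        return cls([(name, _normalize_seq(seq)) for name, seq in contigs])

    # -- coordinate maps ---------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.contigs]

    def contig_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown contig {name!r}") from None

    def global_to_local(self, g: int) -> tuple[str, int]:
        """Map a global position to its unique ``(contig, offset)`` pair."""
        if not 0 <= g < self.n:
            raise IndexError(f"global position {g} outside [0, {self.n})")
        idx = int(np.searchsorted(self.offsets, g, side="right")) - 1
        name, _ = self.contigs[idx]
        return name, g - int(self.offsets[idx])

    def local_to_global(self, contig: str, offset: int) -> int:
        idx = self.contig_index(contig)
        length = len(self.contigs[idx][1])
        if not 0 <= offset < length:
            raise IndexError(f"offset {offset} outside contig {contig!r} [0, {length})")
        return int(self.offsets[idx]) + offset

    def sequence(self, contig: str) -> str:
        return self.contigs[self.contig_index(contig)][1]

    def window(self, g: int, k: int) -> str | None:
        """The k-mer starting at global position ``g``, or None if it would
        cross the contig end."""
        name, off = self.global_to_local(g)
        seq = self.sequence(name)
        if off + k > len(seq):
            return None
        return seq[off : off + k]


def reverse_complement(s: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"characters outside ACGTN: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> ReferenceSequence:
    """Load a (multi-)FASTA file into a :class:`ReferenceSequence`.

    Lowercase is folded to uppercase and non-ACGT IUPAC codes become N.
    Raises :class:`FastaError` on an empty file, an empty record, or text
    before the first header.
    """
    with open(path) as fh:
        return _read_fasta_handle(fh, str(path))


def _read_fasta_handle(fh: TextIO, label: str) -> ReferenceSequence:
    first = fh.read(1)
    if first == "":
        raise FastaError(f"{label}: empty FASTA file")
    if first != ">":
        raise FastaError(f"{label}: line 1: expected FASTA header ('>')")
    fh.seek(0)
    contigs: list[tuple[str, str]] = []
    for record in SeqIO.parse(fh, "fasta"):
        if len(record.seq) == 0:
            raise FastaError(f"{label}: record {record.id!r} is empty")
        contigs.append((record.id, _normalize_seq(str(record.seq))))
    if not contigs:
        raise FastaError(f"{label}: no FASTA records found")
    return ReferenceSequence(contigs)


def read_fasta_string(text: str) -> ReferenceSequence:
    """Parse FASTA from a string (test/fixture helper)."""
    return _read_fasta_handle(io.StringIO(text), "<string>")


def write_fasta(ref: ReferenceSequence, path, width: int = 60) -> None:
    """Write 60-column wrapped FASTA (fixture helper; round-trips with
    :func:`read_fasta`)."""
    with open(path, "w") as fh:
        for name, seq in ref.contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def encode_bases(seq: str) -> np.ndarray:
    """Encode a normalised DNA string as uint8 codes (A,C,G,T,N -> 0..4)."""
    table = np.full(128, 255, dtype=np.uint8)
    for base, code in BASE_CODES.items():
        table[ord(base)] = code
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return arr
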
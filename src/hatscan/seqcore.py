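"""Sequence primitives shared by the whole package.

DNA sequences are stored uppercase over the IUPAC nucleotide alphabet
(``ACGTRYSWKMBDHVN``; ``U`` is converted to ``T`` on construction).
Coordinates follow the GenBank convention used throughout: 1-based,
fully closed intervals, so an interval ``start..end`` has length
``end - start + 1``.  Conversion to 0-based half-open happens only at
the BED boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_EXPANSION",
    "IUPAC_COMPLEMENT",
    "Sequence",
    "Interval",
    "Primer",
    "AlphabetError",
    "MoltypeError",
    "FastaParseError",
    "UndefinedValueError",
    "reverse_complement",
    "iupac_match",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "find_orfs",
    "write_bed",
    "write_gff3",
]

# Degenerate symbol -> set of concrete bases it stands for.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Complement over the full degenerate alphabet (W and S are self-complementary).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_DNA_ALPHABET = frozenset(IUPAC_EXPANSION)
_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)


class AlphabetError(ValueError):
    """Residue outside the declared alphabet."""


class MoltypeError(TypeError):
    """Operation applied to the wrong molecule type."""


class FastaParseError(ValueError):
    """Malformed or inconsistent FASTA input."""


class UndefinedValueError(ValueError):
    """A quantity is undefined for this input (e.g. GC of an all-N sequence)."""


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide or protein string.

    Residues are canonicalised to uppercase; for DNA, ``U`` becomes ``T``.
    An empty residue string is permitted as an explicit degenerate case.
    """

    id: str
    residues: str
    moltype: str = "dna"

    def __post_init__(self) -> None:
        if self.moltype not in ("dna", "protein"):
            raise MoltypeError(f"unknown moltype {self.moltype!r}")
        res = self.residues.upper()
        if self.moltype == "dna":
            res = res.replace("U", "T")
            bad = set(res) - _DNA_ALPHABET
        else:
            bad = set(res) - _PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r}: invalid {self.moltype} symbols {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def slice1(self, start: int, end: int) -> str:
        """Residues of the 1-based, fully-closed interval ``start..end``."""
        if start < 1 or end > len(self.residues) or end < start:
            raise IndexError(f"interval {start}..{end} outside sequence of length {len(self)}")
        return self.residues[start - 1 : end]


@dataclass(frozen=True, order=True)
class Interval:
    """1-based fully-closed genomic interval (GenBank convention)."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.start}..{self.end} (1-based closed)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Primer:
    """A PCR primer: a short IUPAC DNA string, possibly degenerate."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues.upper().replace("U", "T")
        bad = set(res) - _DNA_ALPHABET
        if bad:
            raise AlphabetError(f"primer {self.name!r}: invalid symbols {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(s: Sequence | str) -> Sequence | str:
    """Reverse complement over the full IUPAC alphabet.

    Degenerate symbols map to the complement of their expansion
    (R<->Y, K<->M, B<->V, D<->H; W, S, N are self-complementary), so the
    operation is an involution on every DNA string.  Accepts either a
    :class:`Sequence` (returned as a new ``Sequence``) or a plain string.
    """
    if isinstance(s, Sequence):
        if s.moltype != "dna":
            raise MoltypeError("reverse_complement requires a DNA sequence")
        return dataclasses.replace(s, residues=_rc(s.residues))
    return _rc(str(s).upper().replace("U", "T"))


def _rc(residues: str) -> str:
    return residues.translate(_COMPLEMENT_TABLE)[::-1]


def iupac_match(pattern_base: str, genome_base: str, *, n_matches: bool = False) -> bool:
    """Does a (possibly degenerate) pattern symbol match a genome base?

    The genome side is restricted to ``A/C/G/T/N``.  A genome ``N`` matches
    nothing by default (conservative for assembly gaps); set
    ``n_matches=True`` to let it match any pattern symbol.
    """
    p = pattern_base.upper()
    g = genome_base.upper()
    if p not in IUPAC_EXPANSION:
        raise AlphabetError(f"invalid pattern symbol {pattern_base!r}")
    if g not in "ACGTN" or len(g) != 1:
        raise AlphabetError(f"invalid genome symbol {genome_base!r}")
    if g == "N":
        return n_matches
    return g in IUPAC_EXPANSION[p]


def read_fasta(path: str | Path, moltype: str = "dna") -> list[Sequence]:
    """Read a (possibly wrapped) multi-FASTA file into Sequence records.

    Duplicate identifiers are rejected: downstream tables key on the id.
    """
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise FastaParseError(f"{path}: record {idx} has an empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r} (record {idx})")
        seen.add(rec.id)
        try:
            seqs.append(Sequence(rec.id, str(rec.seq), moltype))
        except AlphabetError as exc:
            raise FastaParseError(f"{path}: record {idx} ({rec.id!r}): {exc}") from exc
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(_BioSeq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def gc_content(s: Sequence | str) -> float:
    """G+C fraction over unambiguous bases only.

    Degenerate symbols are excluded from both numerator and denominator;
    a sequence with no A/C/G/T at all has no defined GC content.
    """
    res = s.residues if isinstance(s, Sequence) else str(s).upper()
    gc = sum(res.count(b) for b in "GC")
    at = sum(res.count(b) for b in "AT")
    if gc + at == 0:
        raise UndefinedValueError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


_STOPS = ("TAA", "TAG", "TGA")


def find_orfs(s: Sequence, min_aa: int) -> list[Interval]:
    """All ATG-to-stop open reading frames of at least ``min_aa`` codons.

    Both strands are scanned in all three frames under the standard
    genetic code.  Each ORF is reported as a stranded interval in forward
    coordinates spanning start codon through stop codon inclusive; ORF
    length in aa excludes the stop.  ORFs whose ATG is never closed by a
    stop before the sequence ends are not reported.
    """
    if s.moltype != "dna":
        raise MoltypeError("find_orfs requires DNA")
    n = len(s.residues)
    out: list[Interval] = []
    for strand, res in (("+", s.residues), ("-", _rc(s.residues))):
        for frame in range(3):
            i = frame
            while i + 3 <= n:
                if res[i : i + 3] == "ATG":
                    j = i + 3
                    while j + 3 <= n and res[j : j + 3] not in _STOPS:
                        j += 3
                    if j + 3 <= n:  # found a stop
                        aa_len = (j - i) // 3
                        if aa_len >= min_aa:
                            if strand == "+":
                                out.append(Interval(s.id, i + 1, j + 3, "+"))
                            else:
                                out.append(Interval(s.id, n - (j + 3) + 1, n - i, "-"))
                        i = j + 3
                        continue
                i += 3
    out.sort(key=lambda iv: (iv.start, iv.end, iv.strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path,
              names: TypingSequence[str] | None = None) -> None:
    """BED6 export; internal 1-based closed coordinates become 0-based half-open."""
    ivs = list(intervals)
    if names is None:
        names = [f"iv{i}" for i in range(len(ivs))]
    with open(path, "w") as fh:
        for iv, name in zip(ivs, names):
            fh.write(f"{iv.seq_id}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_gff3(features: Iterable[tuple[Interval, str, dict[str, str]]],
               path: str | Path, source: str = "hatscan") -> None:
    """Minimal GFF3 writer: (interval, feature_type, attributes) triples."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{iv.seq_id}\t{source}\t{ftype}\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t{attr_s}\n"
            )
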
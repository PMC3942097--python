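"""In-silico PCR discovery and structural validation of DNA-transposon copies.

The workflow mirrors how class II (hAT-like) elements are annotated from
assemblies when only primer sequences and structural expectations are
known: scan a genome for degenerate primer sites, pair convergent hits
into candidate amplicons, then validate each candidate by its terminal
inverted repeats (TIRs) and the target-site duplication (TSD) left by
staggered-cut insertion, and finally classify each copy as a complete
(transposase-bearing) element, a MITE (short, non-coding,
internal-deletion derivative that retains the TIRs), or a fragment.

Defaults encode hAT structural expectations: 12-bp TIRs with up to two
mismatches, 8-bp TSDs with up to one mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq as _BioSeq

from .seqcore import (
    IUPAC_EXPANSION,
    Interval,
    Primer,
    Sequence,
    find_orfs,
    reverse_complement,
)

__all__ = [
    "PrimerHit",
    "Amplicon",
    "TirPair",
    "TsdPair",
    "ElementCopy",
    "GeneModel",
    "FlankError",
    "build_ispcr_query",
    "scan_primer",
    "pair_amplicons",
    "detect_tir",
    "detect_tsd",
    "classify_copy",
    "splice_and_translate",
    "discover_copies",
    "copies_to_gff",
]

# Structural defaults for hAT-like elements.
DEFAULT_TIR_LEN = 12
DEFAULT_TIR_MAX_MISMATCH = 2
DEFAULT_TIR_SEARCH_WINDOW = 5
DEFAULT_TSD_LEN = 8
DEFAULT_TSD_MAX_MISMATCH = 1
DEFAULT_MITE_MAX_LEN = 1000
DEFAULT_ORF_MIN_AA = 100
DEFAULT_PRIMER_MAX_MISMATCH = 3
MITE_AMPLICON_BOUNDS = (400, 1200)
ELEMENT_AMPLICON_BOUNDS = (2000, 5000)


class FlankError(ValueError):
    """Not enough flanking sequence to evaluate a TSD."""


@dataclass(frozen=True)
class PrimerHit:
    interval: Interval
    primer: str
    mismatches: int
    orientation: str  # "forward" | "reverse"


@dataclass(frozen=True)
class Amplicon:
    interval: Interval
    forward_hit: PrimerHit
    reverse_hit: PrimerHit
    sequence: Sequence


@dataclass(frozen=True)
class TirPair:
    left: Interval
    right: Interval
    length: int
    mismatches: int


@dataclass(frozen=True)
class TsdPair:
    left: str
    right: str
    mismatches: int


@dataclass(frozen=True)
class ElementCopy:
    interval: Interval
    klass: str  # "complete" | "mite" | "fragment"
    tir: TirPair | None = None
    tsd: TsdPair | None = None
    notes: str = ""


@dataclass(frozen=True)
class GeneModel:
    exons: tuple[Interval, ...]
    cds: Sequence
    protein: Sequence
    premature_stop: bool


def build_ispcr_query(forward: Primer, reverse: Primer) -> Sequence:
    """Concatenate the forward primer with the reverse complement of the
    reverse primer — the synthetic query used for homology-based
    in-silico PCR screens."""
    rc = reverse_complement(reverse.residues)
    return Sequence(f"{forward.name}+{reverse.name}_rc", forward.residues + rc)


# ---------------------------------------------------------------------------
# primer scanning

_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}

# match_table[pattern_symbol][genome_base_index] — genome N matches nothing
# unless the scan is told otherwise.
def _match_row(sym: str, n_matches: bool) -> np.ndarray:
    row = np.zeros(5, dtype=bool)
    for b in IUPAC_EXPANSION[sym]:
        row[_BASE_INDEX[b]] = True
    row[4] = n_matches
    return row


def _encode(genome: str) -> np.ndarray:
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    return code[arr]


def _mismatch_profile(enc: np.ndarray, pattern: str, n_matches: bool) -> np.ndarray:
    """Mismatch count of ``pattern`` at every start position of the encoded genome."""
    n, m = enc.size, len(pattern)
    if m == 0 or m > n:
        return np.empty(0, dtype=np.int32)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j, sym in enumerate(pattern):
        row = _match_row(sym, n_matches)
        mism += ~row[enc[j : j + mism.size]]
    return mism


def scan_primer(genome: Sequence, primer: Primer, max_mismatch: int = DEFAULT_PRIMER_MAX_MISMATCH,
                *, n_matches: bool = False) -> list[PrimerHit]:
    """All annealing sites of a degenerate primer on both strands.

    A genome base inside a degenerate primer position's IUPAC set counts
    as an exact match.  Forward-orientation hits are matches of the
    primer on the plus strand; reverse-orientation hits are matches of
    its reverse complement (reported in plus-strand coordinates).  Hits
    are sorted by coordinate.  A primer longer than the genome yields an
    empty list.
    """
    enc = _encode(genome.residues)
    hits: list[PrimerHit] = []
    for orientation, pattern in (
        ("forward", primer.residues),
        ("reverse", reverse_complement(primer.residues)),
    ):
        mism = _mismatch_profile(enc, pattern, n_matches)
        for pos in np.nonzero(mism <= max_mismatch)[0]:
            start = int(pos) + 1
            strand = "+" if orientation == "forward" else "-"
            hits.append(
                PrimerHit(
                    Interval(genome.id, start, start + len(pattern) - 1, strand),
                    primer.name,
                    int(mism[pos]),
                    orientation,
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.orientation))
    return hits


def pair_amplicons(f_hits: list[PrimerHit], r_hits: list[PrimerHit],
                   min_len: int, max_len: int, genome: Sequence | None = None) -> list[Amplicon]:
    """Pair convergent primer hits into candidate amplicons.

    A forward-orientation hit pairs with every reverse-orientation hit
    downstream of it whose span (outermost primer bounds inclusive) falls
    within ``[min_len, max_len]``; of the valid partners each forward hit
    keeps only the innermost (shortest span) one, so nested candidate
    sites resolve deterministically.  If ``genome`` is given the amplicon
    sequence is extracted.
    """
    fwd = sorted((h for h in f_hits if h.orientation == "forward"),
                 key=lambda h: h.interval.start)
    rev = sorted((h for h in r_hits if h.orientation == "reverse"),
                 key=lambda h: h.interval.start)
    out: list[Amplicon] = []
    for f in fwd:
        best: PrimerHit | None = None
        best_span = None
        for r in rev:
            if r.interval.start <= f.interval.start:
                continue
            span = r.interval.end - f.interval.start + 1
            if min_len <= span <= max_len and (best_span is None or span < best_span):
                best, best_span = r, span
        if best is not None:
            iv = Interval(f.interval.seq_id, f.interval.start, best.interval.end, "+")
            seq = Sequence(f"{iv.seq_id}:{iv.start}-{iv.end}",
                           genome.slice1(iv.start, iv.end) if genome is not None else "")
            out.append(Amplicon(iv, f, best, seq))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_tir(copy: Sequence, tir_len: int = DEFAULT_TIR_LEN,
               max_mismatch: int = DEFAULT_TIR_MAX_MISMATCH,
               search_window: int = DEFAULT_TIR_SEARCH_WINDOW) -> TirPair | None:
    """Locate terminal inverted repeats near the two ends of a copy.

    Every prefix window starting within ``search_window`` bases of the 5'
    terminus is compared against the reverse complement of every suffix
    window ending within ``search_window`` of the 3' terminus.  The best
    pair has the fewest mismatches; ties go to the outermost pair
    (smallest combined offset, then smallest left offset).  Returns
    ``None`` when no pair is within ``max_mismatch``.
    """
    if tir_len <= 0:
        raise ValueError("tir_len must be positive")
    n = len(copy.residues)
    if n < 2 * tir_len:
        return None
    best: tuple[int, int, int] | None = None  # (mismatches, a+b, a) -> offsets
    best_ab = (0, 0)
    for a in range(search_window + 1):
        if a + tir_len > n:
            break
        left = copy.residues[a : a + tir_len]
        for b in range(search_window + 1):
            if n - b - tir_len < a + tir_len:
                continue
            right = copy.residues[n - b - tir_len : n - b]
            mm = _hamming(left, reverse_complement(right))
            key = (mm, a + b, a)
            if mm <= max_mismatch and (best is None or key < best):
                best, best_ab = key, (a, b)
    if best is None:
        return None
    a, b = best_ab
    return TirPair(
        left=Interval(copy.id, a + 1, a + tir_len, "+"),
        right=Interval(copy.id, n - b - tir_len + 1, n - b, "+"),
        length=tir_len,
        mismatches=best[0],
    )


def detect_tsd(genome: Sequence, element_iv: Interval, k: int = DEFAULT_TSD_LEN,
               max_mismatch: int = DEFAULT_TSD_MAX_MISMATCH) -> TsdPair | None:
    """Compare the k-mers immediately flanking an element.

    Staggered-cut insertion duplicates the target site, so a genuine
    recent insertion carries (near-)identical k-mers on both flanks.
    """
    if element_iv.start - k < 1 or element_iv.end + k > len(genome.residues):
        raise FlankError(
            f"element {element_iv.start}..{element_iv.end} lacks {k} bp of flank"
        )
    left = genome.slice1(element_iv.start - k, element_iv.start - 1)
    right = genome.slice1(element_iv.end + 1, element_iv.end + k)
    mm = _hamming(left, right)
    if mm > max_mismatch:
        return None
    return TsdPair(left, right, mm)


def classify_copy(copy: Sequence, tir: TirPair | None, tsd: TsdPair | None,
                  mite_max_len: int = DEFAULT_MITE_MAX_LEN,
                  orf_min_aa: int = DEFAULT_ORF_MIN_AA,
                  interval: Interval | None = None, notes: str = "") -> ElementCopy:
    """Assign a structural class to a candidate copy.

    complete: TIRs plus an ORF long enough to encode a transposase;
    mite: TIRs, short, and no such ORF (no coding capacity);
    fragment: everything else.
    """
    iv = interval or Interval(copy.id, 1, max(len(copy.residues), 1), "+")
    has_orf = bool(find_orfs(copy, orf_min_aa)) if len(copy.residues) >= 3 * orf_min_aa else False
    if tir is not None and has_orf:
        klass = "complete"
    elif tir is not None and len(copy.residues) <= mite_max_len and not has_orf:
        klass = "mite"
    else:
        klass = "fragment"
    return ElementCopy(interval=iv, klass=klass, tir=tir, tsd=tsd, notes=notes)


def splice_and_translate(element: Sequence, exons: list[Interval]) -> GeneModel:
    """Splice an exon model off an element and translate the CDS.

    Exons are 1-based closed intervals on the element, must be ordered,
    non-overlapping, and in frame (total length divisible by 3).  The
    protein excludes the terminal stop; ``premature_stop`` flags any stop
    codon before the final one.
    """
    prev_end = 0
    parts: list[str] = []
    for ex in exons:
        if ex.start <= prev_end:
            raise ValueError("exons must be strictly increasing and non-overlapping")
        if ex.end > len(element.residues):
            raise IndexError(f"exon {ex.start}..{ex.end} outside element of length {len(element)}")
        parts.append(element.slice1(ex.start, ex.end))
        prev_end = ex.end
    cds = "".join(parts)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(_BioSeq(cds).translate())
    premature = "*" in aa[:-1]
    protein = aa[:-1] if aa.endswith("*") else aa
    return GeneModel(
        exons=tuple(exons),
        cds=Sequence(f"{element.id}_cds", cds),
        protein=Sequence(f"{element.id}_protein", protein, "protein"),
        premature_stop=premature,
    )


# ---------------------------------------------------------------------------
# end-to-end discovery

def discover_copies(genome: Sequence, forward: Primer, reverse: Primer,
                    bounds: tuple[tuple[int, int], ...] = (MITE_AMPLICON_BOUNDS,
                                                           ELEMENT_AMPLICON_BOUNDS),
                    max_mismatch: int = DEFAULT_PRIMER_MAX_MISMATCH,
                    tir_len: int = DEFAULT_TIR_LEN,
                    tir_max_mismatch: int = DEFAULT_TIR_MAX_MISMATCH,
                    tir_window: int = DEFAULT_TIR_SEARCH_WINDOW,
                    tsd_len: int = DEFAULT_TSD_LEN,
                    tsd_max_mismatch: int = DEFAULT_TSD_MAX_MISMATCH,
                    mite_max_len: int = DEFAULT_MITE_MAX_LEN,
                    orf_min_aa: int = DEFAULT_ORF_MIN_AA) -> list[ElementCopy]:
    """Full pipeline: scan -> pair -> detect TIR/TSD -> classify.

    Unlike the low-level :func:`pair_amplicons` (which resolves nested
    hits to the innermost span per forward hit), the pipeline enumerates
    *every* convergent primer-hit pair inside the length windows and
    postpones resolution until after structural validation.  Spurious
    primer matches inside an element body, or cross-pairings between
    neighbouring copies, produce candidate spans that lack a duplicated
    target site or carry worse TIRs; among overlapping candidates the
    one with the best structural evidence wins (TSD+TIR first, then
    fewer TIR mismatches, fewer primer mismatches, shorter span).
    """
    f_hits = [h for h in scan_primer(genome, forward, max_mismatch)
              if h.orientation == "forward"]
    r_hits = [h for h in scan_primer(genome, reverse, max_mismatch)
              if h.orientation == "reverse"]
    seen: set[tuple[int, int]] = set()
    candidates: list[tuple[tuple, ElementCopy]] = []
    for f in f_hits:
        for r in r_hits:
            if r.interval.start <= f.interval.start:
                continue
            span = r.interval.end - f.interval.start + 1
            if not any(lo <= span <= hi for lo, hi in bounds):
                continue
            key = (f.interval.start, r.interval.end)
            if key in seen:
                continue
            seen.add(key)
            iv = Interval(genome.id, f.interval.start, r.interval.end, "+")
            seq = Sequence(f"{iv.seq_id}:{iv.start}-{iv.end}",
                           genome.slice1(iv.start, iv.end))
            tir = detect_tir(seq, tir_len, tir_max_mismatch, tir_window)
            try:
                tsd = detect_tsd(genome, iv, tsd_len, tsd_max_mismatch)
            except FlankError:
                tsd = None
            copy = classify_copy(seq, tir, tsd, mite_max_len, orf_min_aa, interval=iv)
            evidence = (
                0 if (tir is not None and tsd is not None) else
                1 if tir is not None else 2,
                tir.mismatches if tir is not None else tir_max_mismatch + 1,
                f.mismatches + r.mismatches,
                span,
                iv.start,
            )
            candidates.append((evidence, copy))

    candidates.sort(key=lambda c: c[0])
    accepted: list[ElementCopy] = []
    for _, copy in candidates:
        s, e = copy.interval.start, copy.interval.end
        if any(a.interval.start <= e and s <= a.interval.end for a in accepted):
            continue
        accepted.append(copy)
    accepted.sort(key=lambda c: (c.interval.start, c.interval.end))
    return accepted


def copies_to_gff(copies: list[ElementCopy]) -> list[tuple[Interval, str, dict[str, str]]]:
    """Flatten ElementCopy records into (interval, type, attrs) GFF3 features,
    with TIRs as child features."""
    feats = []
    for i, c in enumerate(copies):
        cid = f"copy{i}"
        attrs = {"ID": cid, "klass": c.klass}
        if c.tsd is not None:
            attrs["tsd"] = f"{c.tsd.left}/{c.tsd.right}"
        if c.notes:
            attrs["Note"] = c.notes
        feats.append((c.interval, "mobile_genetic_element", attrs))
        if c.tir is not None:
            off = c.interval.start - 1
            for side, iv in (("left", c.tir.left), ("right", c.tir.right)):
                feats.append(
                    (Interval(c.interval.seq_id, iv.start + off, iv.end + off, "+"),
                     "terminal_inverted_repeat",
                     {"ID": f"{cid}_tir_{side}", "Parent": cid}),
                )
    return feats
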
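"""Synthetic genomes, elements, and divergence scenarios for testing.

Everything the pipeline consumes can be simulated here with known ground
truth: host genomes carrying full-length hAT-style elements inserted
with target-site duplication, internal-deletion MITE derivatives, and
pairs of species-level sequences (TE + nuclear gene) evolved to chosen
divergences under vertical-transmission (VT) or horizontal-transfer (HT)
scenarios.

The module also bundles the published structural constants of the
*Drosophila buzzatii* BuT2 element (canonical copy AF368884): the four
screening primers, the five-exon transposase gene model, and the
2,775-bp / 12-bp-TIR / 8-bp-TSD architecture.  Generated elements are
synthetic — random interiors laid out to the BuT2 architecture — so the
bundled primers amplify them and the bundled exon coordinates splice to
a transposase-sized protein.

All randomness flows through a ``numpy.random.Generator`` derived from
an integer seed; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .divergence import PairwiseAlignment
from .ht_inference import MarkerPair
from .seqcore import Interval, Primer, Sequence, find_orfs, reverse_complement

__all__ = [
    "But2Fixtures",
    "but2_fixtures",
    "SimulationConfig",
    "PlantedCopy",
    "ScenarioSpec",
    "random_genome",
    "make_element",
    "derive_mite",
    "make_mite",
    "plant_copies",
    "simulate_genome",
    "evolve_pair",
    "make_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class But2Fixtures:
    """Published constants of the canonical BuT2 element (AF368884)."""

    primers: dict[str, Primer]
    exons: tuple[Interval, ...]
    tss: int
    polya_site: int
    element_len: int
    tir_len: int
    tsd_len: int
    protein_len_aa: int


def but2_fixtures() -> But2Fixtures:
    """The four screening primers, the five-exon gene model, and the
    canonical structural constants of BuT2."""
    primers = {
        "BuT2_F": Primer("BuT2_F", "CAGTGCTGCCAACAWTTYGT"),
        "BuT2_R": Primer("BuT2_R", "CASTGCTGCCAATTTAGCYA"),
        "BuT2C_F": Primer("BuT2C_F", "AGACYTCGGGRACAGTTTTGC"),
        "BuT2C_R": Primer("BuT2C_R", "AGCATTAATGCYAARCTTTC"),
    }
    exons = tuple(
        Interval("BuT2", s, e)
        for s, e in ((366, 864), (925, 1331), (1486, 1985), (2044, 2436), (2495, 2627))
    )
    return But2Fixtures(
        primers=primers,
        exons=exons,
        tss=325,
        polya_site=2636,
        element_len=2775,
        tir_len=12,
        tsd_len=8,
        protein_len_aa=643,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated host genome.

    Defaults model a small Drosophila-like genomic region (GC ~ 0.4)
    carrying one autonomous 2,775-bp element and two MITE derivatives,
    all freshly inserted (zero post-insertion mutation).
    """

    seed: int = 0
    genome_len: int = 50_000
    gc: float = 0.4
    n_complete: int = 1
    n_mite: int = 2
    element_len: int = 2775
    tir_len: int = 12
    tsd_len: int = 8
    terminal_mut_rate: float = 0.0
    body_mut_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_complete, self.n_mite, self.genome_len) < 0:
            raise ValueError("counts and lengths must be >= 0")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must lie in (0, 1)")
        for r in (self.terminal_mut_rate, self.body_mut_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("mutation rates must lie in [0, 1]")
        if self.element_len <= 2 * self.tir_len:
            raise ValueError("element_len must exceed twice tir_len")


@dataclass(frozen=True)
class PlantedCopy:
    """Ground truth for one planted insertion (1-based final coordinates)."""

    interval: Interval
    klass: str  # "complete" | "mite"
    tsd: str
    tir_left: Interval
    tir_right: Interval
    n_terminal_muts: int = 0
    n_body_muts: int = 0


@dataclass(frozen=True)
class ScenarioSpec:
    """One VT or HT divergence scenario.

    Under VT the TE and the nuclear gene have diverged for the same time
    since the species split, so their true divergences coincide; under
    HT the TE moved between the species after the split and is less
    diverged than the gene.  Alignment lengths default to a ~1-kb TE
    alignment against a several-kb nuclear-gene alignment (two genes'
    worth of sequence), so the gene-side expectation is well estimated.
    """

    mode: str  # "VT" | "HT"
    d_gene: float = 0.2
    d_te: float | None = None
    L_te: int = 1000
    L_gene: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("VT", "HT"):
            raise ValueError(f"mode must be 'VT' or 'HT', got {self.mode!r}")
        if self.d_te is None:
            object.__setattr__(self, "d_te", self.d_gene if self.mode == "VT" else 0.02)
        if self.mode == "VT" and self.d_te != self.d_gene:
            raise ValueError("VT scenarios require d_te == d_gene")
        if self.mode == "HT" and not self.d_te < self.d_gene:
            raise ValueError("HT scenarios require d_te < d_gene")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# genome and element construction

def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def random_genome(cfg: SimulationConfig, rng: np.random.Generator | None = None,
                  seq_id: str = "genome") -> Sequence:
    """i.i.d. random genome at the configured GC content."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    arr = _random_bases(cfg.genome_len, cfg.gc, rng)
    return Sequence(seq_id, arr.tobytes().decode("ascii"))


# Fixed concretisations of the degenerate outer primers used when laying
# out element termini (W->A, Y->T; S->G keeps the 12-bp termini exactly
# inverted-complementary).
_F_SITE = "CAGTGCTGCCAACAATTTGT"
_R_SITE_RC = reverse_complement("CAGTGCTGCCAATTTAGCTA")

_STOP_CODONS = ("TAA", "TAG", "TGA")


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons - 2) random sense codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(chr(b) for b in _BASES[rng.integers(0, 4, size=3)])
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def make_element(cfg: SimulationConfig, rng: np.random.Generator | None = None,
                 seq_id: str = "element") -> Sequence:
    """Build a synthetic autonomous element to the BuT2 architecture.

    The termini are concrete annealing sites for the bundled outer
    primers (so in-silico PCR recovers the whole element), the first and
    last 12 bp form exact reverse-complement TIRs, and — at the default
    2,775-bp length — a five-exon transposase gene is laid out at the
    published coordinates, giving a 643-aa product when spliced.
    Shorter/longer elements get a single-exon ORF over most of the
    interior instead.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    fx = but2_fixtures()
    n = cfg.element_len
    if n < len(_F_SITE) + len(_R_SITE_RC):
        raise ValueError(f"element_len {n} too short for primer termini")
    arr = _random_bases(n, cfg.gc, rng)
    seq = bytearray(arr.tobytes())
    seq[: len(_F_SITE)] = _F_SITE.encode()
    seq[n - len(_R_SITE_RC):] = _R_SITE_RC.encode()

    if n == fx.element_len:
        exons = [(iv.start, iv.end) for iv in fx.exons]
    else:
        # generic layout: one exon covering most of the interior, in frame
        lo = len(_F_SITE) + 30
        hi = n - len(_R_SITE_RC) - 30
        span = ((hi - lo + 1) // 3) * 3
        exons = [(lo, lo + span - 1)]
    n_codons = sum(e - s + 1 for s, e in exons) // 3
    cds = _random_cds(n_codons, rng)
    pos = 0
    for s, e in exons:
        ln = e - s + 1
        seq[s - 1 : e] = cds[pos : pos + ln].encode()
        pos += ln
    # cosmetic GT..AG splice motifs on the introns
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        seq[e1 : e1 + 2] = b"GT"
        seq[s2 - 3 : s2 - 1] = b"AG"
    return Sequence(seq_id, seq.decode("ascii"))


def derive_mite(element: Sequence, keep5: int, keep3: int) -> Sequence:
    """Internal-deletion derivative: first ``keep5`` plus last ``keep3`` bases."""
    n = len(element.residues)
    if keep5 + keep3 >= n:
        raise ValueError(f"keep5 + keep3 = {keep5 + keep3} must be < element length {n}")
    if keep5 < 1 or keep3 < 1:
        raise ValueError("keep5 and keep3 must be positive")
    return Sequence(f"{element.id}_mite",
                    element.residues[:keep5] + element.residues[-keep3:])


def make_mite(element: Sequence, rng: np.random.Generator,
              keep5: int = 350, keep3: int = 350,
              orf_min_aa: int = 100, max_tries: int = 50) -> Sequence:
    """Derive a MITE and verify it has no coding capacity.

    The deletion junction occasionally creates a chance ORF; breakpoints
    are jittered until no ORF of ``orf_min_aa`` or more survives.
    """
    k5, k3 = keep5, keep3
    for _ in range(max_tries):
        mite = derive_mite(element, k5, k3)
        if not find_orfs(mite, orf_min_aa):
            return mite
        k5 = keep5 + int(rng.integers(-30, 31))
        k3 = keep3 + int(rng.integers(-30, 31))
    raise RuntimeError("could not derive an ORF-free MITE; regenerate the element")


def _mutate_element(res: str, tir_len: int, terminal_rate: float, body_rate: float,
                    rng: np.random.Generator) -> tuple[str, int, int]:
    """Per-site substitutions: terminal rate on the TIRs, body rate elsewhere."""
    if terminal_rate == 0.0 and body_rate == 0.0:
        return res, 0, 0
    arr = np.frombuffer(res.encode(), dtype=np.uint8).copy()
    n = arr.size
    rates = np.full(n, body_rate)
    rates[:tir_len] = terminal_rate
    rates[n - tir_len:] = terminal_rate
    hit = rng.random(n) < rates
    idx = np.nonzero(hit)[0]
    for i in idx:
        others = _BASES[_BASES != arr[i]]
        arr[i] = others[rng.integers(0, others.size)]
    n_term = int(np.sum(hit[:tir_len]) + np.sum(hit[n - tir_len:]))
    return arr.tobytes().decode("ascii"), n_term, int(idx.size) - n_term


def plant_copies(genome: Sequence, copies: list[tuple[Sequence, str]],
                 cfg: SimulationConfig,
                 rng: np.random.Generator | None = None) -> tuple[Sequence, list[PlantedCopy]]:
    """Insert copies with target-site duplication; return genome + truth.

    Each insertion picks an independent target k-mer which is duplicated
    on both flanks (staggered-cut repair), so within one copy the two
    TSDs are identical while TSDs of distinct copies are independent
    random k-mers.  Terminal/body substitutions are applied per copy
    after insertion at the configured rates.  ``copies`` is a list of
    (sequence, klass) pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    k = cfg.tsd_len
    margin = k + 20
    min_sep = k + 1
    n0 = len(genome.residues)
    need = sum(len(c.residues) for c, _ in copies) + len(copies) * min_sep + 2 * margin
    if n0 < need:
        raise ValueError(f"genome of {n0} bp too small for {len(copies)} insertions")

    sites: list[int] = []
    attempts = 0
    while len(sites) < len(copies):
        i = int(rng.integers(margin, n0 - margin - k))
        if all(abs(i - j) >= min_sep for j in sites):
            sites.append(i)
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place non-overlapping insertions")

    order = np.argsort(sites)
    parts: list[str] = []
    truth: list[PlantedCopy] = []
    prev = 0
    out_len = 0
    for oi in order:
        i = sites[oi]
        copy_seq, klass = copies[oi]
        mutated, n_term, n_body = _mutate_element(
            copy_seq.residues, cfg.tir_len, cfg.terminal_mut_rate,
            cfg.body_mut_rate, rng)
        chunk = genome.residues[prev : i + k]
        parts.append(chunk)
        out_len += len(chunk)
        start = out_len + 1  # 1-based
        parts.append(mutated)
        out_len += len(mutated)
        end = out_len
        prev = i  # re-emit the target k-mer as the right flank
        m = len(mutated)
        truth.append(
            PlantedCopy(
                interval=Interval(genome.id, start, end, "+"),
                klass=klass,
                tsd=genome.residues[i : i + k],
                tir_left=Interval(genome.id, start, start + cfg.tir_len - 1, "+"),
                tir_right=Interval(genome.id, end - cfg.tir_len + 1, end, "+"),
                n_terminal_muts=n_term,
                n_body_muts=n_body,
            )
        )
    parts.append(genome.residues[prev:])
    truth.sort(key=lambda t: t.interval.start)
    return Sequence(genome.id, "".join(parts)), truth


def simulate_genome(cfg: SimulationConfig,
                    seq_id: str = "genome") -> tuple[Sequence, list[PlantedCopy]]:
    """One host genome with planted autonomous copies and MITEs, plus truth."""
    rng = np.random.default_rng(cfg.seed)
    genome = random_genome(cfg, rng, seq_id)
    element = make_element(cfg, rng)
    copies: list[tuple[Sequence, str]] = [(element, "complete")] * cfg.n_complete
    if cfg.n_mite:
        mite = make_mite(element, rng)
        copies += [(mite, "mite")] * cfg.n_mite
    if not copies:
        return genome, []
    return plant_copies(genome, copies, cfg, rng)


# ---------------------------------------------------------------------------
# divergence scenarios

def evolve_pair(ancestor: Sequence, target_d: float,
                rng: np.random.Generator | int) -> tuple[Sequence, Sequence]:
    """Evolve two descendants whose expected p-distance is ``target_d``.

    Jukes–Cantor-style substitution without indels: each lineage
    substitutes each site independently with probability q, replacement
    uniform over the three other bases; q solves
    ``p = 1 - (1-q)^2 - q^2/3`` so the expected pairwise difference is
    exactly the target.  Valid for ``0 <= target_d < 0.75``.
    """
    if not (0.0 <= target_d < 0.75):
        raise ValueError(f"target_d must lie in [0, 0.75), got {target_d}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    q = 0.75 * (1.0 - np.sqrt(1.0 - 4.0 * target_d / 3.0))
    anc = np.frombuffer(ancestor.residues.encode(), dtype=np.uint8)

    def descend(tag: str) -> Sequence:
        arr = anc.copy()
        hit = np.nonzero(rng.random(arr.size) < q)[0]
        for i in hit:
            others = _BASES[_BASES != arr[i]]
            arr[i] = others[rng.integers(0, 3)]
        return Sequence(f"{ancestor.id}_{tag}", arr.tobytes().decode("ascii"))

    return descend("a"), descend("b")


def make_scenario(spec: ScenarioSpec) -> MarkerPair:
    """Materialise a VT/HT scenario as a MarkerPair of trivial alignments."""
    rng = np.random.default_rng(spec.seed)
    gene_anc = Sequence("gene", _random_bases(spec.L_gene, 0.5, rng).tobytes().decode())
    te_anc = Sequence("te", _random_bases(spec.L_te, 0.5, rng).tobytes().decode())
    gene_a, gene_b = evolve_pair(gene_anc, spec.d_gene, rng)
    te_a, te_b = evolve_pair(te_anc, spec.d_te, rng)
    return MarkerPair(
        species_a=f"{spec.mode}_sp1",
        species_b=f"{spec.mode}_sp2",
        te_aln=PairwiseAlignment.from_sequences(te_a, te_b),
        gene_aln=PairwiseAlignment.from_sequences(gene_a, gene_b),
        gene_name="nuclear",
    )
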
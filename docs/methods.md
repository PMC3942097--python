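# Methods

This note documents the models and procedures implemented in `hatscan`,
the defaults and why they were chosen, what the simulators do and do not
emulate, and the numerical conventions used throughout.

## Coordinates and alphabets

All coordinates are 1-based, fully closed (GenBank convention): the
interval 366–864 has length 499.  Conversion to 0-based half-open
happens only in the BED writer.  DNA is stored uppercase over the full
IUPAC alphabet; `U` becomes `T` on input.  Reverse complementation maps
degenerate symbols through the complement of their expansion sets
(R↔Y, K↔M, B↔V, D↔H; W, S, N self-complementary), making it an
involution on every DNA string.  On the genome side of a primer scan
only A/C/G/T/N occur, and an assembly `N` matches nothing by default —
a conservative policy (a gap character should not anchor a primer);
`n_matches=True` inverts it.

## In-silico PCR and structural validation

A primer site is a window where every genome base lies inside the IUPAC
expansion set of the corresponding primer symbol; a base inside a
degenerate position's set is a full match, not a partial one.  Scans run
over both strands (the reverse-orientation pattern is the primer's
reverse complement) with a mismatch budget of **3 per primer** by
default.  No published tolerance exists for degenerate-primer annealing
in silico, so the default is deliberately permissive and exposed as a
flag everywhere.

`pair_amplicons` implements the documented low-level rule for nested
hits: each forward hit takes its *innermost* (shortest-span) valid
reverse partner, which makes manual "contains both primer regions"
screening deterministic.

The end-to-end pipeline `discover_copies` deliberately does **not**
apply that rule before validation.  With a 3-mismatch budget, a spurious
reverse-primer match arises inside an element body roughly once per
fifty 2.8-kb copies, and an innermost-first rule would then truncate the
true span before the TIR/TSD detectors ever see it.  The pipeline
instead enumerates every convergent pair inside the length windows,
validates each candidate, and resolves overlapping candidates by
structural evidence: candidates with both a TSD and a TIR pair outrank
TIR-only candidates, then fewer TIR mismatches, fewer primer mismatches,
shorter span.  Chimeric cross-pairings between neighbouring copies lose
automatically because their two flanks are not a duplicated target site.

Structural defaults encode hAT expectations and are overridable:

| parameter | default | meaning |
|---|---|---|
| `tir_len` | 12 bp | TIR window length |
| `tir_max_mismatch` | 2 | tolerated TIR mismatches |
| `tir_search_window` | 5 bp | slack from each terminus for the TIR start |
| `tsd_len` | 8 bp | flank k-mer compared for target-site duplication |
| `tsd_max_mismatch` | 1 | tolerated TSD mismatches |
| `mite_max_len` | 1000 bp | MITE length ceiling |
| `orf_min_aa` | 100 aa | coding-capacity threshold |
| amplicon windows | 400–1200, 2000–5000 bp | MITE-scale and full-element screens |

The MITE thresholds bracket the 532–927 bp range reported for BuT2-type
MITEs while excluding anything that could still encode a transposase;
the full-element window brackets the canonical 2,775-bp element.  TIR
detection compares every prefix window within the search slack against
the reverse complement of every suffix window, and breaks mismatch ties
toward the outermost pair.  TSD detection is a plain Hamming comparison
of the two flanking k-mers; under the null of unrelated flanks the
exact-match false-positive rate is 4⁻⁸ ≈ 1.5 × 10⁻⁵.

Classification: `complete` = TIR pair plus an ORF of ≥ 100 codons
(either strand, ATG-to-stop, standard code); `mite` = TIR pair, length
≤ 1000 bp, no such ORF; everything else `fragment`.

## Gene models

`splice_and_translate` concatenates exon substrings in order and
translates with the standard code.  The bundled BuT2 model — five exons
at 366–864, 925–1331, 1486–1985, 2044–2436, 2495–2627 — sums to a
1,932-nt CDS, i.e. 644 codons, encoding a 643-aa transposase once the
terminal stop is removed.  Any stop before the final codon sets
`premature_stop`, the signature of a non-functional copy.

## Distances and trees

Both distances use **pairwise deletion**: a column is compared for a
pair only when both sequences carry an unambiguous A/C/G/T there.  This
keeps per-pair site counts maximal and matches the common default of
desktop phylogenetics packages; ambiguity codes are treated as missing
rather than fractionally matched.  Transitions are A↔G and C↔T.  The
Tamura 3-parameter distance takes θ as the mean GC content of the two
sequences over compared sites.  When a log argument is non-positive the
pair is saturated and a `SaturationError` reports P and Q rather than
returning a fictitious number.  A gamma-rates variant of the distance is
a documented extension point, not implemented: distance-based trees here
use the plain T92 form.

Neighbor joining follows Saitou–Nei with the rate-corrected selection
criterion Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ.  Ties break to the lowest
(i, j) index pair so output is reproducible; negative branch lengths are
clamped to zero and flagged on the tree
(`negative_branches_clamped`).  On exactly additive inputs the algorithm
recovers the generating tree's topology and branch lengths to machine
precision, which the test suite verifies against an independent
random-tree generator and against dendropy's NJ implementation.

## The horizontal-transfer test

A vertically transmitted TE diverges between species at least as much
as neutral nuclear sequence; markedly lower TE divergence indicates a
transfer after the species split.  For a species pair with TE alignment
counts (L compared sites, m differing) and nuclear-gene p-distance
d_gene, the test is a one-sample χ² goodness of fit on (m, L−m) against
expectation (d_gene·L, (1−d_gene)·L), df = 1, two-sided.  The call is:

* **VT** whenever d_TE ≥ d_gene, regardless of p — the rule is
  asymmetric by design, since elevated TE divergence is expected under
  vertical descent;
* **HT** only when d_TE < d_gene **and** p < α (default α = 0.01);
* **inconclusive** when an expected cell falls below 5 counts, where the
  χ² approximation is unreliable.

The construction treats the gene-side divergence as a fixed expectation;
its own sampling noise mildly inflates the nominal type-I error, which
is why scenario defaults pair a 1-kb TE alignment with a 5-kb gene
alignment (two nuclear genes' worth of sequence) — at that ratio the
null HT-call rate stays within the Monte-Carlo band of α.  Bonferroni
correction across a screen is available but off by default.

## Synthetic data: what it emulates and what it does not

`simulate_genome` draws an i.i.d. background genome (default 50 kb at
GC 0.4, a Drosophila-like base composition), builds one autonomous
element to the canonical architecture — concrete annealing sites for the
bundled outer primers at the termini, exact 12-bp inverted-repeat ends,
and the five-exon gene laid out at the published coordinates with random
sense codons (GT/AG intron boundaries are cosmetic) — and derives MITEs
by internal deletion (default 350 + 350 bp, re-jittering breakpoints if
a chance ORF survives).  Copies are inserted by explicit target-site
duplication: an independent random 8-mer at each insertion point is
copied to both flanks, so within-copy TSDs are identical while distinct
copies share a TSD only with probability 4⁻⁸.  Substitutions are applied
per copy after insertion, with separate rates for the terminal 12 bp
(TIR decay) and the body, so structural degradation is controllable
independently of coding-sequence divergence.  Insertions are placed
without overlap and on the forward strand only.

Divergence scenarios evolve an ancestor into two descendants by
per-site substitution (probability q per lineage, replacement uniform
over the other three bases) with q solving p = 1 − (1−q)² − q²/3, so the
*expected* realized p-distance equals the target exactly; there are no
indels, so the alignments are trivially correct.  VT scenarios force
equal true divergence for TE and gene; HT scenarios set the TE below the
gene.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real assemblies: indels and alignment error,
nested TE insertions (supported structurally but off by default),
rate heterogeneity along sequences, selection on the transposase,
segmental duplications that mimic TSD-free copies, and assembly
artefacts (collapsed repeats, Ns inside elements).  Recovery statistics
on simulated genomes are therefore upper bounds on real-data
performance.

## Problem sizes and determinism

The bundled verification runs use 100 simulated 50-kb genomes with
three planted copies each for recovery, 2,000 vertical-transmission
replicates for the type-I error of the HT test, 500 replicates for
power, 200 random 4–8-taxon trees for NJ exactness, and 100 random
instances per brute-force oracle comparison — sizes at which the
Monte-Carlo bands are tight while the whole suite completes in well
under a minute.  All randomness flows through `numpy.random.Generator`
seeded explicitly; identical seeds give byte-identical genomes, truths
and scenarios.

## Known limitations

* Primer scanning is exact-position Hamming matching; it does not model
  thermodynamics, 3′-end criticality, or indel-tolerant annealing.
* The HT test conditions on the gene divergence as a known expectation;
  a fully joint treatment (two-sample test on both alignments) would be
  more conservative with short gene alignments.
* Homology search beyond primer sites (e.g. BLAST-based discovery of
  decayed copies) is out of scope; only primer-anchored copies are
  found.
* Maximum-likelihood and Bayesian tree inference, bootstrap support,
  and multiple sequence alignment are intentionally not provided —
  the package consumes pre-aligned input.
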
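# hatscan

Discovery and evolutionary analysis of **hAT-superfamily DNA transposons**
and their **MITE** derivatives from genome assemblies.

Class II (cut-and-paste) transposons of the hAT superfamily — such as the
*Drosophila buzzatii* element **BuT2** — have a characteristic architecture:
short terminal inverted repeats (**TIRs**, 12 bp for BuT2), an internal
transposase gene, and, because insertion proceeds by staggered-cut repair, an
**8-bp target-site duplication (TSD)** identical on both flanks of each copy.
Non-autonomous derivatives (**MITEs**) arise by internal deletion: they keep
the TIRs and are mobilised in trans, but have no coding capacity.  `hatscan`
is for researchers who have primer sequences and structural expectations for
such an element and want to (i) find and classify its copies in assemblies,
(ii) quantify divergence between copies across species, and (iii) test
whether the element moved between species horizontally.

## What it does

* **In-silico PCR** (`element_discovery`): scan a genome for degenerate
  (IUPAC) primer sites on both strands, pair convergent hits into candidate
  amplicons, validate each candidate by its TIRs and flanking TSD, and
  classify it as `complete` (TIRs + transposase-sized ORF), `mite`
  (TIRs, short, no ORF) or `fragment`.  Exon models can be spliced and
  translated to check coding capacity.
* **Divergence** (`divergence`): p-distance and Tamura 3-parameter distance
  with pairwise deletion, distance matrices, Saitou–Nei neighbor joining with
  deterministic tie-breaking, Newick/PHYLIP I/O.

  The T92 distance, with transition proportion *P*, transversion proportion
  *Q* and GC content θ (h = 2θ(1−θ)):

      d = −h·ln(1 − P/h − Q) − ½·(1−h)·ln(1 − 2Q)

* **Horizontal-transfer test** (`ht_inference`): for a species pair, compare
  the TE p-distance *d*\_TE against the expectation set by a nuclear gene
  (e.g. *Adh*, *Amd*) with a one-sample χ² goodness-of-fit on the TE
  alignment's (different, identical) site counts, df = 1:

      E = (d_gene·L, (1−d_gene)·L),  χ² = Σ (O−E)²/E

  Decision rule: **VT** (vertical transmission) whenever *d*\_TE ≥ *d*\_gene;
  **HT** requires *d*\_TE < *d*\_gene *and* p < α (default α = 0.01).
* **Simulation** (`synthetic_data`): ground-truth generators — host genomes
  with elements inserted by target-site duplication, internal-deletion MITEs,
  Jukes–Cantor-style sequence evolution to a target divergence, and VT/HT
  scenario builders — plus the bundled BuT2 constants (the four screening
  primers, the five-exon gene model at positions 366–864, 925–1331,
  1486–1985, 2044–2436, 2495–2627, and the 2,775-bp / 12-bp-TIR / 8-bp-TSD
  architecture).

## Worked example

Simulate a 50-kb host genome carrying one autonomous copy and two MITEs,
then rediscover them with the bundled primers:

```python
from hatscan.synthetic_data import SimulationConfig, simulate_genome, but2_fixtures
from hatscan.element_discovery import discover_copies

fx = but2_fixtures()
genome, truth = simulate_genome(SimulationConfig(seed=5))
for c in discover_copies(genome, fx.primers["BuT2_F"], fx.primers["BuT2_R"]):
    print(c.interval.start, c.interval.end, c.klass,
          c.tir.mismatches, c.tsd.left, c.tsd.right)
```

```
36142 36841 mite 0 AATGTAAT AATGTAAT
45699 46398 mite 0 AATTACGT AATTACGT
46686 49460 complete 0 TTGGTGCT TTGGTGCT
```

Each line is one recovered copy: a 700-bp MITE or the 2,775-bp complete
element, with 0 TIR mismatches and the two flanking 8-mers identical — the
TSD signature of a genuine transposition.  The same run from the shell:

```sh
hatscan simulate genome --seed 5 --out-fasta g.fa --out-truth truth.json
hatscan annotate --genome g.fa --fwd CAGTGCTGCCAACAWTTYGT --rev CASTGCTGCCAATTTAGCYA
```

```
genome  36142  36841  mite      tir_mm=0  tsd_mm=0
genome  45699  46398  mite      tir_mm=0  tsd_mm=0
genome  46686  49460  complete  tir_mm=0  tsd_mm=0
```

And a horizontal-transfer scenario — a TE far less diverged than the
nuclear gene of the same species pair:

```sh
hatscan simulate scenario --mode HT --seed 2
```

```
HT_sp1  HT_sp2  d_te=0.0180  d_gene=0.2140  chi2=228.389  p=1.34e-51  call=HT
```

The TE is 1.8% diverged where the nuclear gene predicts 21.4%; the χ²
statistic of 228 on 1 df rejects equality decisively, and the verdict is HT.
Other subcommands: `hatscan ispcr` (amplicon prediction only),
`hatscan dist` / `hatscan njtree` (distance matrices and NJ trees from
aligned FASTA), `hatscan httest` (HT screen over all species pairs of a TE
alignment and a gene alignment).

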
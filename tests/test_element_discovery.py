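"""In-silico PCR, TIR/TSD detection, classification, and gene models."""

import itertools

import pytest

from hatscan.element_discovery import (
    FlankError,
    build_ispcr_query,
    classify_copy,
    detect_tir,
    detect_tsd,
    discover_copies,
    pair_amplicons,
    scan_primer,
    splice_and_translate,
)
from hatscan.seqcore import (
    IUPAC_EXPANSION,
    Interval,
    Primer,
    Sequence,
    reverse_complement,
)
from hatscan.synthetic_data import SimulationConfig, but2_fixtures, make_element, make_mite
from conftest import random_dna


class TestIspcrQuery:
    def test_bundled_outer_primers_give_40nt_query(self, fixtures):
        q = build_ispcr_query(fixtures.primers["BuT2_F"], fixtures.primers["BuT2_R"])
        assert q.residues == "CAGTGCTGCCAACAWTTYGTTRGCTAAATTGGCAGCASTG"
        assert len(q) == 40

    def test_degenerate_cases(self):
        assert build_ispcr_query(Primer("f", "A"), Primer("r", "T")).residues == "AA"
        assert build_ispcr_query(Primer("f", ""), Primer("r", "")).residues == ""


def _scan_oracle(genome, primer, max_mm):
    """Position-by-position O(n*m) IUPAC scan, both strands."""
    hits = []
    for orientation, pat in (("forward", primer), ("reverse", reverse_complement(primer))):
        m = len(pat)
        for i in range(len(genome) - m + 1):
            mm = sum(
                genome[i + j] == "N" or genome[i + j] not in IUPAC_EXPANSION[pat[j]]
                for j in range(m)
            )
            if mm <= max_mm:
                hits.append((i + 1, orientation, mm))
    return sorted(hits)


class TestScanPrimer:
    def test_planted_site_recovered_exactly(self, fixtures, rng):
        p = fixtures.primers["BuT2_F"]
        genome = Sequence("g", random_dna(rng, 500) + "CAGTGCTGCCAACAATTTGT" + random_dna(rng, 500))
        hits = [h for h in scan_primer(genome, p, 0) if h.orientation == "forward"]
        assert len(hits) == 1
        assert hits[0].interval.start == 501 and hits[0].mismatches == 0

    def test_strand_symmetry(self, fixtures, rng):
        p = fixtures.primers["BuT2_F"]
        genome = Sequence("g", random_dna(rng, 300) + "CAGTGCTGCCAACAATTTGT" + random_dna(rng, 300))
        mirrored = reverse_complement(genome)
        fwd = [h for h in scan_primer(genome, p, 0) if h.orientation == "forward"]
        rev = [h for h in scan_primer(mirrored, p, 0) if h.orientation == "reverse"]
        assert len(fwd) == len(rev) == 1
        n = len(genome)
        assert rev[0].interval.start == n - fwd[0].interval.end + 1
        assert rev[0].interval.strand == "-"

    def test_matches_brute_force_oracle(self, fixtures, rng):
        p = fixtures.primers["BuT2_R"]
        genome = random_dna(rng, 50_000)
        got = sorted(
            (h.interval.start, h.orientation, h.mismatches)
            for h in scan_primer(Sequence("g", genome), p, max_mismatch=2)
        )
        assert got == _scan_oracle(genome, p.residues, 2)

    def test_primer_longer_than_genome(self, fixtures):
        assert scan_primer(Sequence("g", "ACGT"), fixtures.primers["BuT2_F"], 3) == []

    def test_genome_n_excluded_by_default(self):
        genome = Sequence("g", "AANAA")
        assert scan_primer(genome, Primer("p", "ANA"), 0) == []
        with_n = scan_primer(genome, Primer("p", "ANA"), 0, n_matches=True)
        assert any(h.mismatches == 0 for h in with_n)


def _mk_hit(seq_id, start, length, orientation):
    from hatscan.element_discovery import PrimerHit
    strand = "+" if orientation == "forward" else "-"
    return PrimerHit(Interval(seq_id, start, start + length - 1, strand), "p", 0, orientation)


class TestPairAmplicons:
    def test_single_convergent_pair_within_bounds(self):
        f = [_mk_hit("g", 100, 20, "forward")]
        r = [_mk_hit("g", 780, 20, "reverse")]
        amps = pair_amplicons(f, r, 400, 1200)
        assert len(amps) == 1
        assert (amps[0].interval.start, amps[0].interval.end) == (100, 799)

    def test_span_bound_enforced(self):
        f = [_mk_hit("g", 100, 20, "forward")]
        r = [_mk_hit("g", 3080, 20, "reverse")]
        assert pair_amplicons(f, r, 400, 1200) == []

    def test_matches_exhaustive_pairing_oracle(self, rng):
        for _ in range(25):
            fs = sorted(rng.choice(5000, size=3, replace=False) + 1)
            rs = sorted(rng.choice(5000, size=3, replace=False) + 1)
            f = [_mk_hit("g", int(x), 20, "forward") for x in fs]
            r = [_mk_hit("g", int(x), 20, "reverse") for x in rs]
            got = {(a.interval.start, a.interval.end) for a in pair_amplicons(f, r, 400, 1200)}
            # oracle: innermost valid reverse partner per forward hit
            expected = set()
            for x in fs:
                spans = [(y + 19 - x + 1, y) for y in rs
                         if y > x and 400 <= y + 19 - x + 1 <= 1200]
                if spans:
                    span, y = min(spans)
                    expected.add((int(x), int(y) + 19))
            assert got == expected


class TestDetectTir:
    def test_exact_inverted_termini(self, rng):
        tir = "CAGTGCTGCCAA"
        seq = Sequence("c", tir + random_dna(rng, 300) + reverse_complement(tir))
        pair = detect_tir(seq, tir_len=12, max_mismatch=0)
        assert pair is not None and pair.mismatches == 0
        assert (pair.left.start, pair.left.end) == (1, 12)
        assert (pair.right.start, pair.right.end) == (len(seq) - 11, len(seq))

    def test_mismatch_threshold_boundary(self, rng):
        tir = "CAGTGCTGCCAA"
        body = random_dna(rng, 300)
        mutated = "TT" + tir[2:]  # two terminal substitutions
        seq = Sequence("c", mutated + body + reverse_complement(tir))
        found = detect_tir(seq, 12, max_mismatch=2, search_window=0)
        assert found is not None and found.mismatches == 2
        assert detect_tir(seq, 12, max_mismatch=1, search_window=0) is None

    def test_recovery_equals_exhaustive_window_oracle(self, rng):
        for _ in range(100):
            tir = random_dna(rng, 12)
            a = int(rng.integers(0, 4))
            b = int(rng.integers(0, 4))
            seq = (random_dna(rng, a) + tir + random_dna(rng, 150)
                   + reverse_complement(tir) + random_dna(rng, b))
            s = Sequence("c", seq)
            got = detect_tir(s, 12, 2, 5)
            # oracle: all window pairs, best by (mismatches, a+b, a)
            n = len(seq)
            best = None
            for aa in range(6):
                for bb in range(6):
                    if aa + 12 > n or n - bb - 12 < aa + 12:
                        continue
                    left = seq[aa:aa + 12]
                    right = seq[n - bb - 12:n - bb]
                    mm = sum(x != y for x, y in zip(left, reverse_complement(right)))
                    if mm <= 2 and (best is None or (mm, aa + bb, aa) < best):
                        best = (mm, aa + bb, aa)
            if best is None:
                assert got is None
            else:
                off_l = got.left.start - 1
                off_r = n - got.right.end
                assert (got.mismatches, off_l + off_r, off_l) == best

    def test_rejects_nonpositive_tir_len(self):
        with pytest.raises(ValueError):
            detect_tir(Sequence("c", "ACGT" * 10), tir_len=0)


class TestDetectTsd:
    def test_planted_duplication_found(self, rng):
        tsd = "TACGGATC"
        genome = Sequence("g", random_dna(rng, 50) + tsd + "ACGT" * 25 + tsd + random_dna(rng, 50))
        iv = Interval("g", 59, 158)
        pair = detect_tsd(genome, iv, k=8, max_mismatch=0)
        assert pair is not None and pair.left == pair.right == tsd

    def test_one_mismatch_tolerated(self, rng):
        genome = Sequence("g", random_dna(rng, 20) + "TACGGATC" + "ACGT" * 10 + "TACGGATA" + random_dna(rng, 20))
        pair = detect_tsd(genome, Interval("g", 29, 68), k=8, max_mismatch=1)
        assert pair is not None and pair.mismatches == 1

    def test_random_flank_false_positive_rate(self, rng):
        """Two random 8-mers collide with probability 4^-8; absence dominates."""
        absent = 0
        trials = 10_000
        for _ in range(trials):
            g = Sequence("g", random_dna(rng, 30))
            if detect_tsd(g, Interval("g", 9, 22), k=8, max_mismatch=0) is None:
                absent += 1
        assert absent >= trials - 5  # expect ~0.15 chance collisions

    def test_insufficient_flank_raises(self):
        with pytest.raises(FlankError):
            detect_tsd(Sequence("g", "ACGT" * 10), Interval("g", 3, 20), k=8)


class TestClassifyCopy:
    def test_simulated_copies_get_their_true_class(self, rng):
        cfg = SimulationConfig(seed=7)
        element = make_element(cfg, rng)
        mite = make_mite(element, rng)
        for seq, expected in ((element, "complete"), (mite, "mite")):
            tir = detect_tir(seq)
            assert classify_copy(seq, tir, None).klass == expected

    def test_tirless_copy_is_fragment(self, rng):
        decayed = Sequence("c", random_dna(rng, 600))
        assert classify_copy(decayed, None, None).klass == "fragment"


class TestSpliceAndTranslate:
    def test_five_exon_model_encodes_643aa_transposase(self, fixtures, rng):
        element = make_element(SimulationConfig(seed=11), rng)
        gm = splice_and_translate(element, list(fixtures.exons))
        assert len(gm.cds.residues) == 1932
        assert len(gm.protein.residues) == 643
        assert not gm.premature_stop

    def test_single_exon(self):
        gm = splice_and_translate(Sequence("e", "ATGAAATAG"), [Interval("e", 1, 9)])
        assert gm.protein.residues == "MK" and not gm.premature_stop

    def test_internal_stop_flagged(self):
        gm = splice_and_translate(Sequence("e", "ATGTAAAAATAG"), [Interval("e", 1, 12)])
        assert gm.premature_stop

    def test_frame_and_bounds_errors(self):
        with pytest.raises(ValueError, match="divisible"):
            splice_and_translate(Sequence("e", "ATGAAAT"), [Interval("e", 1, 7)])
        with pytest.raises(IndexError):
            splice_and_translate(Sequence("e", "ATGTAA"), [Interval("e", 1, 9)])


class TestEndToEndInvariants:
    def test_degradation_monotonicity(self, fixtures):
        """More terminal mutations never yield more TIR detections."""
        from hatscan.synthetic_data import simulate_genome
        detected = []
        for rate in (0.0, 0.1, 0.3, 0.6):
            n = 0
            for seed in range(5):
                cfg = SimulationConfig(seed=seed, terminal_mut_rate=rate)
                genome, truth = simulate_genome(cfg)
                copies = discover_copies(genome, fixtures.primers["BuT2_F"],
                                         fixtures.primers["BuT2_R"])
                n += sum(1 for c in copies if c.tir is not None)
            detected.append(n)
        assert all(a >= b for a, b in zip(detected, detected[1:]))

    def test_within_copy_tsd_identical_between_copy_different(self, fixtures):
        from hatscan.synthetic_data import simulate_genome
        seen = []
        for seed in range(10):
            genome, truth = simulate_genome(SimulationConfig(seed=seed))
            copies = discover_copies(genome, fixtures.primers["BuT2_F"],
                                     fixtures.primers["BuT2_R"])
            for c in copies:
                assert c.tsd is not None and c.tsd.left == c.tsd.right
            seen.extend(c.tsd.left for c in copies)
        assert len(set(seen)) == len(seen)
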
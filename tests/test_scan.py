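"""Hallmark scanner: planted-copy recovery, strand symmetry, oracle agreement."""

import numpy as np
import pytest

import pr77kit as pk
from pr77kit.errors import InputError, ParameterError
from pr77kit.scan import scan_genome, iterative_scan

from conftest import rc, random_dna, mutate_at, sw_oracle


@pytest.fixture(scope="module")
def query77():
    return pk.QueryProfile(id="q", consensus=pk.sample_ribozyme(rng_seed=3, length=77).seq)


def plant(rng, glen, copies):
    """Background of glen nt with (position, sequence) copies overwritten."""
    g = list(random_dna(rng, glen))
    for pos, seq in copies:
        g[pos : pos + len(seq)] = seq
    return "".join(g)


class TestScanGenome:
    def test_exact_planted_copy_found_once(self, query77):
        rng = np.random.default_rng(42)
        genome = pk.GenomeSequence("g", plant(rng, 10_000, [(5000, query77.consensus)]))
        hits = scan_genome(genome, query77)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (5000, 5077, "+")
        assert h.identity == 100.0

    def test_substituted_copy_identity(self, query77):
        """Five internal substitutions give identity 72/77 = 93.5%; the
        exhaustive Smith-Waterman oracle confirms interval and identity."""
        rng = np.random.default_rng(42)
        copy = mutate_at(query77.consensus, [10, 25, 40, 55, 70], rng)
        genome = pk.GenomeSequence("g", plant(rng, 10_000, [(5000, copy)]))
        hits = scan_genome(genome, query77)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == pytest.approx(100 * 72 / 77, abs=1e-9)
        score, t0, t1, matches, columns = sw_oracle(
            query77.consensus, genome.residues[4800:5300]
        )
        assert (4800 + t0, 4800 + t1) == (h.start, h.end)
        assert h.score == score
        assert 100 * matches / columns == pytest.approx(h.identity)

    def test_reverse_complement_copy_mirrors_coordinates(self, query77):
        rng = np.random.default_rng(42)
        genome = pk.GenomeSequence(
            "g", plant(rng, 10_000, [(5000, rc(query77.consensus))])
        )
        hits = scan_genome(genome, query77)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (5000, 5077, "-")
        assert hits[0].identity == 100.0

    def test_strand_symmetry(self, query77):
        """Scanning the reverse-complemented genome yields the mirror-image
        hit set: start' = L - end, strands flipped."""
        rng = np.random.default_rng(5)
        copy = mutate_at(query77.consensus, [5, 30, 60], rng)
        genome = pk.GenomeSequence(
            "g", plant(rng, 8_000, [(2000, copy), (5000, rc(query77.consensus))])
        )
        fwd = scan_genome(genome, query77)
        mirror = scan_genome(pk.GenomeSequence("g", rc(genome.residues)), query77)
        L = genome.length
        flipped = sorted(
            (L - h.end, L - h.start, {"+": "-", "-": "+"}[h.strand]) for h in mirror
        )
        assert flipped == sorted((h.start, h.end, h.strand) for h in fwd)

    def test_determinism(self, query77):
        rng = np.random.default_rng(9)
        genome = pk.GenomeSequence("g", plant(rng, 20_000, [(8000, query77.consensus)]))
        assert scan_genome(genome, query77) == scan_genome(genome, query77)

    def test_no_hits_on_random_background(self, query77):
        genome = pk.GenomeSequence("g", random_dna(np.random.default_rng(17), 100_000))
        assert scan_genome(genome, query77) == []

    def test_parameter_and_input_errors(self, query77):
        genome = pk.GenomeSequence("g", random_dna(np.random.default_rng(0), 1000))
        with pytest.raises(ParameterError):
            scan_genome(genome, query77, pk.ScanParams(k=5))
        with pytest.raises(ParameterError):
            scan_genome(genome, pk.QueryProfile("s", "ACGT" * 11), pk.ScanParams(k=80))
        with pytest.raises(InputError):
            pk.GenomeSequence("empty", "")
        with pytest.raises(InputError):
            pk.QueryProfile("short", "ACGT")  # below 40 nt


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_exhaustive_alignment_on_small_genomes(self, query77, seed):
        """On <= 2 kb genomes the scanner reproduces the interval and score of
        a full-matrix quadratic local alignment."""
        rng = np.random.default_rng(seed)
        copy = mutate_at(query77.consensus, rng.choice(70, size=4, replace=False) + 3, rng)
        genome = pk.GenomeSequence("g", plant(rng, 2_000, [(800, copy)]))
        hits = scan_genome(genome, query77)
        assert len(hits) == 1
        score, t0, t1, _m, _c = sw_oracle(query77.consensus, genome.residues)
        assert (hits[0].start, hits[0].end, hits[0].score) == (t0, t1, score)


def test_sensitivity_to_diverged_copies(query77):
    """Every planted copy with identity >= min_identity + 3 points is found
    (50 seeded plantings, 7 substitutions each, min_identity 85%)."""
    rng = np.random.default_rng(123)
    positions, copies = [], []
    for i in range(50):
        pos = 1000 + i * 2000
        muts = rng.choice(np.arange(2, 75), size=7, replace=False)
        copies.append((pos, mutate_at(query77.consensus, muts, rng)))
        positions.append(pos)
    genome = pk.GenomeSequence("g", plant(rng, 102_000, copies))
    hits = scan_genome(genome, query77, pk.ScanParams(min_identity=85.0))
    starts = {h.start for h in hits}
    missed = [p for p in positions if not any(abs(p - s) <= 5 for s in starts)]
    assert missed == []


class TestIterativeScan:
    def test_fixed_point_without_diverged_copies(self, query77):
        rng = np.random.default_rng(21)
        genome = pk.GenomeSequence("g", plant(rng, 10_000, [(4000, query77.consensus)]))
        r1 = scan_genome(genome, query77)
        assert iterative_scan(genome, [query77]) == r1

    def test_max_rounds_one_equals_plain_scan(self, query77):
        rng = np.random.default_rng(22)
        genome = pk.GenomeSequence("g", plant(rng, 10_000, [(4000, query77.consensus)]))
        assert iterative_scan(genome, [query77], max_rounds=1) == scan_genome(
            genome, query77
        )
        with pytest.raises(ParameterError):
            iterative_scan(genome, [query77], max_rounds=0)

    def test_chained_divergence_found_in_second_round(self, query77):
        """Copy chain A (exact), B (~12% from A), C (~12% from B, ~24% from A):
        with min_identity 85 round 1 finds A and B; C is only reachable with B
        as the query, so the iterative screen recovers it in round 2."""
        rng = np.random.default_rng(33)
        A = query77.consensus
        B = mutate_at(A, rng.choice(np.arange(2, 75), 9, replace=False), rng)
        C = mutate_at(B, rng.choice(np.arange(2, 75), 9, replace=False), rng)
        # oracle check of the construction: C near B, far from A
        _s, _t0, _t1, m_ab, c_ab = sw_oracle(A, C)
        assert 100 * m_ab / c_ab < 85.0
        genome = pk.GenomeSequence(
            "g", plant(rng, 30_000, [(2000, A), (10_000, B), (20_000, C)])
        )
        params = pk.ScanParams(min_identity=85.0)
        round1 = iterative_scan(genome, [query77], params, max_rounds=1)
        assert {h.start for h in round1} == {2000, 10_000}
        full = iterative_scan(genome, [query77], params)
        assert {2000, 10_000} < {h.start for h in full}
        assert any(abs(h.start - 20_000) <= 5 for h in full)
        # superset of round 1
        assert set(round1) <= set(full)
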
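"""Poly-A / TSD context detection and element classification."""

import dataclasses

import numpy as np
import pytest

import pr77kit as pk
from pr77kit.annotate import SHORT, LONG, find_polyA, find_TSD, classify_element
from pr77kit.errors import InputError

from conftest import rc, random_dna


def _hit(contig="c", start=1000, end=1077, strand="+"):
    return pk.HallmarkHit(contig, start, end, strand, 95.0, 70, "q", 77)


def _genome_with(insert: str, at: int, length: int, seed=0):
    rng = np.random.default_rng(seed)
    g = list(random_dna(rng, length))
    g[at : at + len(insert)] = insert
    return pk.GenomeSequence("c", "".join(g))


class TestPolyA:
    def test_short_window_track(self):
        g = _genome_with("G" + "A" * 20 + "G", 1077 + 600, 5000)
        tracks = find_polyA(g, _hit())
        short = [t for t in tracks if t.window_class == SHORT]
        assert len(short) == 1
        assert short[0].a_fraction == 1.0
        assert short[0].distance == 601
        assert (short[0].start, short[0].end) == (1678, 1698)

    def test_long_window_track(self):
        g = _genome_with("G" + "A" * 15 + "G", 1077 + 5500, 10_000)
        tracks = find_polyA(g, _hit())
        assert [t.window_class for t in tracks] == [LONG]

    def test_random_window_has_no_track(self):
        g = pk.GenomeSequence("c", random_dna(np.random.default_rng(3), 10_000))
        assert find_polyA(g, _hit()) == []

    def test_minus_strand_scans_t_runs_upstream(self):
        g = _genome_with("G" + "T" * 20 + "G", 8000 - 600 - 22, 12_000)
        tracks = find_polyA(g, _hit(start=8000, end=8077, strand="-"))
        short = [t for t in tracks if t.window_class == SHORT]
        assert len(short) == 1
        assert short[0].distance == pytest.approx(601, abs=1)

    def test_window_truncated_with_warning(self):
        g = _genome_with("A" * 20, 1077 + 600, 3000)
        with pytest.warns(UserWarning):
            tracks = find_polyA(g, _hit())
        assert len(tracks) == 1

    def test_widening_windows_is_monotone(self):
        """Widening the search windows never loses a track."""
        g = _genome_with("G" + "A" * 12 + "C", 1077 + 350, 10_000, seed=8)
        base = pk.PolyAConfig()
        wide = dataclasses.replace(base, short_window=(200, 1500), long_window=(4000, 7000))
        n_base = len(find_polyA(g, _hit(), base))
        n_wide = len(find_polyA(g, _hit(), wide))
        assert n_wide >= n_base >= 1


class TestTSD:
    def _flanked(self, tsd_l, tsd_r, elem_len=500, seed=0):
        rng = np.random.default_rng(seed)
        elem = random_dna(rng, elem_len - 25) + "A" * 25
        g = random_dna(rng, 200) + tsd_l + elem + tsd_r + random_dna(rng, 200)
        start = 200 + len(tsd_l)
        return pk.GenomeSequence("c", g), (start, start + elem_len)

    def test_exact_nine_mer(self):
        g, span = self._flanked("GCTTGACCC", "GCTTGACCC")
        tsd = find_TSD(g, span)
        assert tsd is not None
        assert (tsd.length, tsd.identity) == (9, 100.0)
        assert tsd.left_seq == tsd.right_seq == "GCTTGACCC"

    def test_partially_conserved_eight_mer(self):
        g, span = self._flanked("GCTTGACC", "GCTTGACG", seed=1)
        tsd = find_TSD(g, span)
        assert tsd is not None
        assert tsd.identity == pytest.approx(100 * 7 / 8)

    def test_random_flanks_yield_none(self):
        """Flanks sharing no sufficiently conserved k-mer give no TSD; the
        exhaustive offset/length comparison in this test confirms absence."""
        g, span = self._flanked("", "", seed=12)
        cfg = pk.TSDConfig()
        seq = g.residues
        start, end = span
        any_match = False
        for L in range(7, 12):
            for ol in range(-cfg.boundary_slack, cfg.max_offset + 1):
                for orr in range(-cfg.boundary_slack, cfg.max_offset + 1):
                    left = seq[start - ol - L : start - ol]
                    right = seq[end + orr : end + orr + L]
                    m = sum(a == b for a, b in zip(left, right))
                    if len(left) == L and m >= max(6, 0.75 * L):
                        any_match = True
        assert not any_match
        assert find_TSD(g, span) is None

    def test_symmetry_under_reverse_complement(self):
        g, (s, e) = self._flanked("GATTGCCCA", "GATTGCACA", seed=4)
        t_fwd = find_TSD(g, (s, e))
        g_rc = pk.GenomeSequence("c", rc(g.residues))
        L = g.length
        t_rev = find_TSD(g_rc, (L - e, L - s))
        assert (t_fwd is None) == (t_rev is None)
        if t_fwd:
            assert t_rev.length == t_fwd.length
            assert t_rev.identity == pytest.approx(t_fwd.identity)
            assert t_rev.left_seq == rc(t_fwd.right_seq)
            assert t_rev.right_seq == rc(t_fwd.left_seq)

    def test_raising_identity_threshold_is_monotone(self):
        """Raising min_identity_pct never increases the number of accepted
        TSDs over a batch of random flank pairs."""
        cfgs = [
            dataclasses.replace(pk.TSDConfig(), min_identity_pct=p)
            for p in (60.0, 75.0, 90.0, 100.0)
        ]
        counts = []
        for cfg in cfgs:
            n = 0
            for seed in range(30):
                g, span = self._flanked("", "", seed=seed)
                n += find_TSD(g, span, cfg) is not None
            counts.append(n)
        assert counts == sorted(counts, reverse=True)

    def test_insufficient_flank_warns_and_returns_none(self):
        g = pk.GenomeSequence("c", "ACGT" * 30)
        with pytest.warns(UserWarning):
            tsd = find_TSD(g, (5, 115))
        assert tsd is None


class TestClassify:
    def test_two_tandem_hallmarks_are_sider2(self):
        h1, h2 = _hit(start=1000, end=1077), _hit(start=1100, end=1177)
        polya = pk.PolyATrack(1700, 1725, 1.0, SHORT, 523)
        tsd = pk.TSDPair(9, 991, 1725, "X" * 9, "X" * 9, 100.0, 0, 0)
        cls, conf = classify_element([h1, h2], polya, tsd)
        assert (cls, conf) == ("SIDER2", "full")

    def test_long_span_is_line_dire(self):
        h = _hit()
        polya = pk.PolyATrack(6300, 6330, 1.0, LONG, 5223)
        cls, conf = classify_element([h], polya, None)
        assert (cls, conf) == ("LINE_DIRE", "no_tsd")

    def test_single_hallmark_short_polya_is_sider1(self):
        h = _hit()
        polya = pk.PolyATrack(1700, 1725, 1.0, SHORT, 623)
        cls, conf = classify_element([h], polya, None)
        assert (cls, conf) == ("SIDER1", "no_tsd")

    def test_no_polya_is_unclassified(self):
        cls, _conf = classify_element([_hit()], None, None)
        assert cls == "UNCLASSIFIED"

    def test_zero_hallmarks_is_an_error(self):
        with pytest.raises(InputError):
            classify_element([], None, None)

    def test_nar_requires_matching_reference_ends(self):
        """A short element sharing both ends with a reference long element is
        SIDE_NAR; with a random body it stays SIDER1."""
        ref = pk.build_element(
            "LINE_DIRE", rng_seed=5, options=pk.ElementOptions(divergence_pct=0.0)
        ).seq
        nar = pk.build_element(
            "SIDE_NAR", rng_seed=6,
            options=pk.ElementOptions(divergence_pct=2.0, long_ref=ref),
        )
        sider1 = pk.build_element("SIDER1", rng_seed=7)
        h = _hit()
        polya = pk.PolyATrack(1700, 1725, 1.0, SHORT, 623)
        cls_nar, _ = classify_element([h], polya, None, long_ref=ref, element_seq=nar.seq)
        cls_s1, _ = classify_element([h], polya, None, long_ref=ref, element_seq=sider1.seq)
        assert cls_nar == "SIDE_NAR"
        assert cls_s1 == "SIDER1"


class TestAnnotateGenome:
    def test_small_genome_recovery(self):
        specs = [
            pk.PlantSpec("SIDER1", "+"),
            pk.PlantSpec("SIDER2", "-"),
            pk.PlantSpec("LINE_DIRE", "+"),
        ]
        planted = pk.plant_genome(1, 60_000, specs, rng_seed=11)
        anns = pk.annotate_genome(planted.genomes[0], [planted.query])
        truth = sorted(planted.truth.records, key=lambda r: r.start)
        assert [a.element_class for a in anns] == [r.element_class for r in truth]
        assert [a.strand for a in anns] == [r.strand for r in truth]
        for a, r in zip(anns, truth):
            assert abs(a.start - r.start) <= 10 and abs(a.end - r.end) <= 10

    def test_hallmark_without_polya_is_unclassified(self):
        rz = pk.sample_ribozyme(rng_seed=19, length=77)
        g = _genome_with(rz.seq, 5000, 20_000, seed=19)
        anns = pk.annotate_genome(g, [pk.QueryProfile("q", rz.seq)])
        assert len(anns) == 1
        assert anns[0].element_class == "UNCLASSIFIED"

    def test_empty_hit_set_gives_empty_annotations(self):
        g = pk.GenomeSequence("c", random_dna(np.random.default_rng(2), 30_000))
        q = pk.QueryProfile("q", pk.sample_ribozyme(rng_seed=4, length=77).seq)
        assert pk.annotate_genome(g, [q]) == []
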
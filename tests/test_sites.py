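import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptrmap.io import Interval, Transcript
from ptrmap.motifs import (
    Motif,
    consensus_to_kmers,
    motif_similarity,
    motif_to_pfm,
    read_kmer_motifs,
    read_pfm_motifs,
    top_n_kmers,
    write_pfm_motifs,
)
from ptrmap.sites import (
    Site,
    annotate_clip,
    annotate_conservation,
    assemble_mirna_sites,
    collapse_homotypic,
    read_sites,
    scan_sites,
    write_sites,
)

from .oracles import naive_scan


def one_hot(kmer):
    pfm = np.zeros((len(kmer), 4))
    for i, b in enumerate(kmer):
        pfm[i, "ACGU".index(b)] = 1.0
    return pfm


class TestTopNKmers:
    def test_one_hot_identity(self):
        assert top_n_kmers(one_hot("UGUA"), 1) == ["UGUA"]

    def test_two_column_max_verified_by_enumeration(self):
        pfm = np.array([[0.7, 0.1, 0.1, 0.1], [1 / 30, 1 / 30, 1 / 30, 0.9]])
        # brute force over all 16 dimers
        probs = {
            a + b: pfm[0, "ACGU".index(a)] * pfm[1, "ACGU".index(b)]
            for a in "ACGU"
            for b in "ACGU"
        }
        best = max(probs, key=lambda k: probs[k])
        assert top_n_kmers(pfm, 1) == [best] == ["AU"]
        assert probs[best] == pytest.approx(0.63)

    def test_uniform_ties_break_lexicographically(self):
        pfm = np.full((3, 4), 0.25)
        expected = ["".join(t) for t in itertools.product("ACGU", repeat=3)][:10]
        assert top_n_kmers(pfm, 10) == expected

    def test_beam_matches_full_enumeration_on_random_pfms(self, rng):
        for _ in range(20):
            k = int(rng.integers(4, 7))
            pfm = rng.dirichlet(np.ones(4), size=k)
            full = sorted(
                (
                    ("".join(t), float(np.prod([pfm[i, "ACGU".index(b)] for i, b in enumerate(t)])))
                    for t in itertools.product("ACGU", repeat=k)
                ),
                key=lambda item: (-item[1], item[0]),
            )
            assert top_n_kmers(pfm, 10) == [kmer for kmer, _ in full[:10]]

    def test_requests_beyond_alphabet_return_all(self):
        pfm = np.full((4, 4), 0.25)
        assert len(top_n_kmers(pfm, 10**4)) == 256


class TestScanSites:
    def test_single_match(self):
        t = Transcript(id="t", utr_seq="UGUAAAUA")
        (site,) = scan_sites(t, Motif(factor_id="F", kmers=["UGUA"]))
        assert (site.start, site.end, site.matched_kmer) == (0, 4, "UGUA")

    def test_overlapping_matches_kept(self):
        t = Transcript(id="t", utr_seq="AAAAA")
        sites = scan_sites(t, Motif(factor_id="F", kmers=["AAAA"]))
        assert [(s.start, s.end) for s in sites] == [(0, 4), (1, 5)]

    def test_iupac_consensus_expansion(self):
        t = Transcript(id="t", utr_seq="UGUACAUA")
        (site,) = scan_sites(t, Motif(factor_id="F", consensus="UGUANAUA"))
        assert (site.start, site.end) == (0, 8)
        assert sorted(consensus_to_kmers("UGUANAUA"))[0] == "UGUAAAUA"

    def test_kmer_longer_than_utr_gives_empty(self):
        t = Transcript(id="t", utr_seq="ACG")
        assert scan_sites(t, Motif(factor_id="F", kmers=["ACGUACGU"])) == []

    def test_multiple_representations_pooled_under_one_factor(self):
        t = Transcript(id="t", utr_seq="UGUAGGGCCCAUUU")
        sites = scan_sites(
            t,
            [Motif(factor_id="F", kmers=["UGUA"]), Motif(factor_id="F", consensus="AUUU")],
        )
        assert {(s.start, s.end) for s in sites} == {(0, 4), (10, 14)}
        assert {s.factor_id for s in sites} == {"F"}

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.data())
    def test_matches_naive_sliding_window_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        seq = "".join(rng.choice(list("ACGU"), size=60))
        kmers = ["".join(rng.choice(list("ACGU"), size=4)) for _ in range(5)]
        t = Transcript(id="t", utr_seq=seq)
        got = {(s.start, s.end) for s in scan_sites(t, Motif(factor_id="F", kmers=kmers))}
        assert got == naive_scan(seq, kmers)


class TestAnnotateClip:
    def test_overlap_sets_flag_and_best_percentile(self):
        sites = [Site("t", "F", 5, 12)]
        (out,) = annotate_clip(sites, [Interval("t", 0, 20, score_percentile=8.0)])
        assert out.clip_supported and out.clip_percentile == 8.0

    def test_half_open_adjacency_is_not_overlap(self):
        sites = [Site("t", "F", 5, 12)]
        peaks = [Interval("t", 0, 5), Interval("t", 12, 30)]
        (out,) = annotate_clip(sites, peaks)
        assert not out.clip_supported

    def test_smallest_percentile_wins(self):
        sites = [Site("t", "F", 5, 12)]
        peaks = [
            Interval("t", 0, 8, score_percentile=40.0),
            Interval("t", 6, 20, score_percentile=9.0),
        ]
        (out,) = annotate_clip(sites, peaks)
        assert out.clip_percentile == 9.0

    def test_monotone_adding_peak_never_unsets(self, rng):
        sites = [Site("t", "F", int(s), int(s) + 7) for s in rng.integers(0, 90, size=12)]
        peaks = [Interval("t", int(s), int(s) + 15) for s in rng.integers(0, 90, size=5)]
        before = annotate_clip(sites, peaks)
        after = annotate_clip(sites, peaks + [Interval("t", 40, 60)])
        for b, a in zip(before, after):
            assert a.clip_supported >= b.clip_supported

    def test_gparclip_flag_separate(self):
        sites = [Site("t", "F", 5, 12)]
        (out,) = annotate_clip(sites, [Interval("t", 0, 20)], source="gparclip")
        assert out.gparclip_supported and not out.clip_supported


class TestAnnotateConservation:
    def test_mean_over_site(self):
        track = {"t": np.array([0.0, 0.0, 1.0, 1.0])}
        (out,) = annotate_conservation([Site("t", "F", 0, 4)], track)
        assert out.conservation_mean == pytest.approx(0.5)

    def test_missing_track_leaves_unset(self):
        (out,) = annotate_conservation([Site("t", "F", 0, 4)], {})
        assert out.conservation_mean is None


class TestAssembleMirnaSites:
    def test_overlapping_predictions_merge_with_both_flags(self):
        predicted = {
            "targetscan": [Site("t", "miR-1", 10, 17, factor_class="miRNA")],
            "pictar": [Site("t", "miR-1", 12, 19, factor_class="miRNA")],
        }
        (out,) = assemble_mirna_sites(predicted, [], [])
        assert (out.start, out.end) == (10, 19)
        assert out.pred_targetscan and out.pred_pictar

    def test_pair_level_validation_marks_all_sites_of_mirna(self):
        predicted = {
            "targetscan": [
                Site("t", "miR-1", 10, 17, factor_class="miRNA"),
                Site("t", "miR-1", 50, 57, factor_class="miRNA"),
                Site("t", "miR-2", 80, 87, factor_class="miRNA"),
            ]
        }
        out = assemble_mirna_sites(predicted, [("miR-1", "t")], [])
        flags = {(s.factor_id, s.start): s.pred_mirtarbase for s in out}
        assert flags[("miR-1", 10)] and flags[("miR-1", 50)]
        assert not flags[("miR-2", 80)]

    def test_ago_clip_requires_overlap(self):
        predicted = {"targetscan": [Site("t", "miR-1", 10, 17, factor_class="miRNA")]}
        out_far = assemble_mirna_sites(predicted, [], [Interval("t", 30, 40)])
        out_near = assemble_mirna_sites(predicted, [], [Interval("t", 16, 40)])
        assert not out_far[0].pred_agoclip
        assert out_near[0].pred_agoclip

    def test_unknown_transcripts_skipped(self):
        predicted = {"targetscan": [Site("ghost", "miR-1", 0, 7, factor_class="miRNA")]}
        assert assemble_mirna_sites(predicted, [], [], known_transcripts={"t"}) == []


class TestCollapseHomotypic:
    def test_transitive_chain_keeps_most_upstream(self):
        sites = [Site("t", "X", 0, 7), Site("t", "X", 3, 10), Site("t", "X", 20, 27)]
        out = collapse_homotypic(sites)
        assert [(s.start, s.end) for s in out] == [(0, 7), (20, 27)]

    def test_no_overlap_identity(self):
        sites = [Site("t", "X", 0, 7), Site("t", "X", 10, 17)]
        assert collapse_homotypic(sites) == sites

    def test_per_factor_rule_keeps_cross_factor_overlaps(self):
        sites = [Site("t", "X", 0, 7), Site("t", "Y", 3, 10)]
        assert len(collapse_homotypic(sites)) == 2

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.data())
    def test_output_subset_without_same_factor_overlap(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        sites = [
            Site("t", f"F{int(rng.integers(3))}", int(s), int(s) + 7)
            for s in rng.integers(0, 100, size=15)
        ]
        out = collapse_homotypic(sites)
        assert all(s in sites for s in out)
        for a, b in itertools.combinations(out, 2):
            if a.factor_id == b.factor_id:
                assert not a.overlaps(b)


class TestMotifSimilarity:
    def test_identical_pfms_fully_correlated(self):
        pfm = one_hot("UGUAAC")
        assert motif_similarity(pfm, pfm) == pytest.approx(1.0)

    def test_disjoint_one_hot_motifs_uncorrelated(self):
        # closed form: col corr of distinct one-hot 4-vectors is -1/3
        sim = motif_similarity(one_hot("AAAA"), one_hot("CCCC"))
        assert sim <= 0
        assert sim == pytest.approx(-1 / 3)

    def test_consensus_converts_to_uniform_degenerate_columns(self):
        pfm = motif_to_pfm(Motif(factor_id="F", consensus="AN"))
        np.testing.assert_allclose(pfm[0], [1, 0, 0, 0])
        np.testing.assert_allclose(pfm[1], [0.25] * 4)


class TestMotifIO:
    def test_pfm_round_trip(self, tmp_path):
        motifs = [Motif(factor_id="F1", pfm=one_hot("UGUA")), Motif(factor_id="F2", pfm=one_hot("CCCAA"))]
        p = tmp_path / "m.pfm"
        write_pfm_motifs(motifs, p)
        back = read_pfm_motifs(p)
        assert [m.factor_id for m in back] == ["F1", "F2"]
        np.testing.assert_allclose(back[0].pfm, motifs[0].pfm)

    def test_kmer_table(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("F1\tRBP\tkmers\tUGUA,ACGU\nM1\tmiRNA\tconsensus\tUGUR\n")
        motifs = read_kmer_motifs(p)
        assert motifs[0].kmers == ["UGUA", "ACGU"]
        assert motifs[1].consensus == "UGUR"

    def test_invalid_pfm_rejected(self):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            Motif(factor_id="F", pfm=bad)


class TestSiteTableIO:
    def test_round_trip_with_flags(self, tmp_path):
        sites = [
            Site("t1", "F", 3, 10, matched_kmer="UGUAAAC", clip_supported=True,
                 clip_percentile=8.5, conservation_mean=0.75),
            Site("t2", "miR-1", 0, 7, factor_class="miRNA", matched_kmer="ACGUACG",
                 pred_targetscan=True, pred_mirtarbase=True),
        ]
        p = tmp_path / "sites.bed"
        write_sites(sites, p)
        back = read_sites(p)
        assert back[0].clip_supported and back[0].clip_percentile == 8.5
        assert back[1].pred_targetscan and back[1].pred_mirtarbase
        assert [(s.transcript_id, s.start, s.end) for s in back] == [
            ("t1", 3, 10), ("t2", 0, 7)
        ]
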
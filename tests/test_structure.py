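import numpy as np
import pytest

from ptrmap.config import RunConfig
from ptrmap.io import Transcript
from ptrmap.sites import Site
from ptrmap.structure import (
    NussinovBackend,
    PrecomputedBackend,
    StemPairCandidate,
    accessibility_profile,
    enumerate_stem_windows,
    expected_inter_site_pairs,
    parse_dotbracket,
    read_dotbracket_samples,
    read_unpaired_table,
    revcomp_bp_count,
    screen_stem_candidates,
    select_stem_pairs,
    site_accessibility,
    stem_score,
)

from .oracles import (
    boltzmann_weights,
    enumerate_structures,
    exact_unpaired_by_enumeration,
    expected_intersite_pairs_by_enumeration,
    revcomp_bp_by_antidiagonal,
)


class TestNussinovBackend:
    def test_pairless_sequence_fully_unpaired(self):
        backend = NussinovBackend()
        np.testing.assert_allclose(backend.exact_unpaired("AAAA"), 1.0)

    @pytest.mark.parametrize(
        "seq",
        ["GGGAAAACCC", "ACGUACGUACGU", "GCGCAAAAGCGC", "UUUUAAAA", "GUGUGAAACACAC"[:12]],
    )
    def test_unpaired_probabilities_match_exhaustive_enumeration(self, seq):
        backend = NussinovBackend()
        exact = backend.exact_unpaired(seq)
        oracle = exact_unpaired_by_enumeration(seq, backend.pair_weight)
        np.testing.assert_allclose(exact, oracle, atol=1e-9)

    def test_max_span_restriction_matches_enumeration(self):
        seq = "GGGAAAACCC"
        backend = NussinovBackend()
        exact = backend.exact_unpaired(seq, max_span=6)
        oracle = exact_unpaired_by_enumeration(seq, backend.pair_weight, max_span=6)
        np.testing.assert_allclose(exact, oracle, atol=1e-9)

    def test_partition_function_equals_total_boltzmann_weight(self):
        seq = "GCGCAAAAGCGC"
        backend = NussinovBackend(temperature_weight=0.7)
        E = backend.inside(seq)
        structures = enumerate_structures(seq)
        z = boltzmann_weights(structures, backend.pair_weight).sum()
        assert E[0, len(seq)] == pytest.approx(z, rel=1e-12)

    def test_sampling_consistent_with_exact_probabilities(self, rng):
        seq = "GGCGAAAACGCC"
        backend = NussinovBackend()
        exact = backend.exact_unpaired(seq)
        n = 10_000
        samples = backend.sample_structures(seq, n, rng)
        est = np.zeros(len(seq))
        for s in samples:
            paired = {i for p in s for i in p}
            for i in range(len(seq)):
                est[i] += i not in paired
        est /= n
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-4) / n)
        assert np.all(np.abs(est - exact) <= 4 * se)

    def test_sampled_structures_are_valid(self, rng):
        backend = NussinovBackend()
        for s in backend.sample_structures("GCGCGCAAAAGCGCGC", 200, rng):
            flat = [i for p in s for i in p]
            assert len(flat) == len(set(flat))  # no base in two pairs
            for i, j in s:
                assert j - i > 3  # hairpin >= 3 unpaired

    def test_non_acgu_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            NussinovBackend().inside("ACGX")


class TestAccessibilityProfile:
    def test_pairless_sequence_all_one(self, config):
        t = Transcript(id="t", utr_seq="A" * 30)
        profile = accessibility_profile(t, NussinovBackend(), config)
        np.testing.assert_allclose(profile.values, 1.0)

    def test_short_sequence_degenerates_to_global_fold(self, config):
        t = Transcript(id="t", utr_seq="GGGAAAACCCGGGAAAACCC")
        backend = NussinovBackend()
        profile = accessibility_profile(t, backend, config)
        np.testing.assert_allclose(
            profile.values, backend.exact_unpaired(t.utr_seq, config.max_pair_span)
        )

    def test_windowed_average_equals_per_window_recomputation(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=120))
        backend = NussinovBackend()
        W, L = 40, 30
        got = backend.unpaired_probabilities(seq, W, L)
        sums = np.zeros(len(seq))
        counts = np.zeros(len(seq))
        for s in range(len(seq) - W + 1):
            p = backend.exact_unpaired(seq[s : s + W], L)
            sums[s : s + W] += p
            counts[s : s + W] += 1
        np.testing.assert_allclose(got, sums / counts, atol=1e-12)

    def test_flank_offsets_site_coordinates(self, config):
        t = Transcript(id="t", utr_seq="AAAA", flank_seq="GG")
        profile = accessibility_profile(t, NussinovBackend(), config)
        assert len(profile.values) == 6
        assert site_accessibility(Site("t", "F", 0, 4), profile) == pytest.approx(1.0)


class TestSiteAccessibility:
    def _profile(self, values):
        from ptrmap.structure import AccessibilityProfile

        return AccessibilityProfile("t", np.array(values), 200, 150)

    def test_mean_over_site(self):
        profile = self._profile([0.5, 0.5, 1.0])
        assert site_accessibility(Site("t", "F", 0, 3), profile) == pytest.approx(2 / 3)

    def test_single_base_site(self):
        profile = self._profile([0.2, 0.9, 0.4])
        assert site_accessibility(Site("t", "F", 1, 2), profile) == pytest.approx(0.9)

    def test_site_outside_profile_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            site_accessibility(Site("t", "F", 1, 5), self._profile([1.0, 1.0]))


class TestRevcompBpCount:
    def test_full_complement(self):
        assert revcomp_bp_count("AAAAAAA", "UUUUUUU") == 7

    def test_gu_wobble_counts(self):
        assert revcomp_bp_count("GGG", "UUU") == 3

    def test_matches_antidiagonal_oracle_on_random_8mers(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list("ACGU"), size=8))
            b = "".join(rng.choice(list("ACGU"), size=8))
            assert revcomp_bp_count(a, b) == revcomp_bp_by_antidiagonal(a, b)


class TestEnumerateStemWindows:
    def test_paper_point_site_count(self):
        windows = enumerate_stem_windows((300, 301), (350, 351), 1000, 200)
        assert len(windows) == 150

    def test_span_exceeding_window_gives_none(self):
        assert enumerate_stem_windows((100, 101), (350, 351), 1000, 200) == []

    def test_adjacent_sites_full_count(self):
        # 5-nt sites with span 10, far from boundaries: W - span + 1
        windows = enumerate_stem_windows((400, 405), (405, 410), 1000, 200)
        assert len(windows) == 191

    def test_windows_contain_both_sites_and_stay_in_sequence(self):
        for s in enumerate_stem_windows((30, 37), (80, 87), 300, 120):
            assert s <= 30 and s + 120 >= 87
            assert 0 <= s and s + 120 <= 300

    def test_boundary_truncation_drops_windows(self):
        # close to the 5' end: windows with negative starts are dropped
        windows = enumerate_stem_windows((10, 11), (60, 61), 1000, 200)
        assert len(windows) == 11  # starts 0..10


class TestStemScore:
    def _setup(self, utr_len=120):
        t = Transcript(id="t", utr_seq="".join(
            np.random.default_rng(5).choice(list("ACGU"), size=utr_len)
        ))
        sa = Site("t", "A", 20, 25)
        sb = Site("t", "B", 60, 65)
        cfg = RunConfig(window_length=80, n_structure_samples=50, seed=2)
        return t, sa, sb, cfg

    def test_forced_pair_backend_gives_min_length(self, rng):
        t, sa, sb, cfg = self._setup()

        class Forced:
            def sample_structures(self, seq, n, rng, max_span=None):
                # pair the sites base by base within any window (window start
                # is recoverable because windows slide over the same UTR)
                start = t.utr_seq.find(seq)
                return [
                    {(sa.start - start + i, sb.start - start + i) for i in range(5)}
                ] * n

        score = stem_score(sa, sb, t, Forced(), cfg, rng)
        assert score == pytest.approx(min(len(sa), len(sb)))

    def test_never_pairing_backend_gives_zero(self, rng):
        t, sa, sb, cfg = self._setup()

        class Never:
            def sample_structures(self, seq, n, rng, max_span=None):
                return [set() for _ in range(n)]

        assert stem_score(sa, sb, t, Never(), cfg, rng) == 0.0

    def test_no_window_warns_and_scores_zero(self, rng):
        t, sa, sb, cfg = self._setup()
        cfg = RunConfig(window_length=30, n_structure_samples=10, seed=2)
        with pytest.warns(UserWarning, match="no folding window"):
            assert stem_score(sa, sb, t, NussinovBackend(), cfg, rng) == 0.0

    def test_sampled_score_matches_enumeration_oracle(self, rng):
        # window = whole 12-nt sequence; exhaustive Boltzmann expectation
        seq = "GGCGAAAACGCC"
        t = Transcript(id="t", utr_seq=seq)
        sa, sb = Site("t", "A", 0, 4), Site("t", "B", 8, 12)
        cfg = RunConfig(window_length=12, n_structure_samples=4000, seed=3)
        backend = NussinovBackend()
        sampled = stem_score(sa, sb, t, backend, cfg, rng)
        oracle = expected_intersite_pairs_by_enumeration(
            seq, (0, 4), (8, 12), backend.pair_weight, max_span=cfg.max_pair_span
        )
        exact = expected_inter_site_pairs(sa, sb, t, backend, cfg)
        assert exact == pytest.approx(oracle, abs=1e-9)
        assert sampled == pytest.approx(oracle, abs=0.1)

    def test_fixed_seed_reproducible_and_spread_shrinks_with_samples(self):
        t, sa, sb, _ = self._setup()
        backend = NussinovBackend()

        def run(n_samples, seed):
            cfg = RunConfig(window_length=80, n_structure_samples=n_samples, seed=seed)
            return stem_score(sa, sb, t, backend, cfg)

        assert run(30, 7) == run(30, 7)  # bit-for-bit reproducible
        small = [run(20, s) for s in range(12)]
        large = [run(320, s) for s in range(12)]
        # 16x the samples: MC spread should shrink ~4x; allow slack
        assert np.std(large) < np.std(small)


class TestSelectStemPairs:
    def _sites(self):
        return (
            Site("t", "F", 0, 7),
            Site("t", "F", 20, 27),
            Site("t", "F", 40, 47),
            Site("t", "F", 60, 67),
        )

    def test_worked_example_selects_highest_pair_only(self, config):
        a, b, c, _ = self._sites()
        cands = [
            StemPairCandidate(a, b, bp_count=5, stem_score=0.3),
            StemPairCandidate(b, c, bp_count=5, stem_score=0.6),
            StemPairCandidate(a, c, bp_count=5, stem_score=0.4),
        ]
        selected = select_stem_pairs(cands, config)
        assert len(selected) == 1
        assert selected[0].stem_score == 0.6
        assert (selected[0].site_a, selected[0].site_b) == (b, c)

    def test_all_below_threshold_selects_nothing(self, config):
        a, b, *_ = self._sites()
        assert select_stem_pairs([StemPairCandidate(a, b, 5, 0.05)], config) == []

    def test_greedy_continues_past_blocked_pairs(self, config):
        a, b, c, d = self._sites()
        cands = [
            StemPairCandidate(a, b, 5, 0.5),
            StemPairCandidate(b, c, 5, 0.45),
            StemPairCandidate(c, d, 5, 0.4),
        ]
        selected = select_stem_pairs(cands, config)
        assert [(p.site_a.start, p.site_b.start) for p in selected] == [(0, 20), (40, 60)]

    def test_selection_is_a_matching_and_order_invariant(self, rng, config):
        sites = [Site("t", "F", int(10 * i), int(10 * i) + 7) for i in range(8)]
        cands = []
        for i in range(8):
            for j in range(i + 1, 8):
                cands.append(
                    StemPairCandidate(sites[i], sites[j], 5, float(rng.uniform(0, 1)))
                )
        sel1 = select_stem_pairs(list(cands), config)
        perm = [cands[i] for i in rng.permutation(len(cands))]
        for c in perm:
            c.selected = False
        sel2 = select_stem_pairs(perm, config)
        key = lambda p: (p.site_a.start, p.site_b.start)
        assert sorted(map(key, sel1)) == sorted(map(key, sel2))
        used = [s for p in sel1 for s in (p.site_a.start, p.site_b.start)]
        assert len(used) == len(set(used))


class TestScreenCandidates:
    def test_min_bp_filter(self, config):
        t = Transcript(id="t", utr_seq="AAAAAAA" + "C" * 20 + "UUUUUUU" + "C" * 20)
        sa = [Site("t", "A", 0, 7)]
        sb = [Site("t", "B", 27, 34)]
        (cand,) = screen_stem_candidates(sa, sb, t, config)
        assert cand.bp_count == 7
        t2 = Transcript(id="t", utr_seq="AAAAAAA" + "C" * 20 + "AAAAAAA" + "C" * 20)
        assert screen_stem_candidates(sa, sb, t2, config) == []


class TestAdapters:
    def test_parse_dotbracket(self):
        assert parse_dotbracket("((...))") == {(0, 6), (1, 5)}
        with pytest.raises(ValueError):
            parse_dotbracket("((..)")

    def test_read_samples_and_unpaired_table(self, tmp_path):
        p = tmp_path / "samples.txt"
        p.write_text(".....\n(...)\n")
        samples = read_dotbracket_samples(p)
        assert samples == [set(), {(0, 4)}]
        u = tmp_path / "lunp.txt"
        u.write_text("#pos p\n1 0.5\n2 1.0\n3 0.25\n")
        np.testing.assert_allclose(read_unpaired_table(u, 3), [0.5, 1.0, 0.25])

    def test_precomputed_backend_serves_samples(self, rng):
        backend = PrecomputedBackend(samples=[{(0, 5)}, set()])
        draws = backend.sample_structures("ACGUAC", 10, rng)
        assert all(d in ({(0, 5)}, set()) for d in draws)
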
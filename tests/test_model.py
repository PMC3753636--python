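"""Reference-profile training, Mahalanobis scoring, scanning and calling."""

import warnings

import numpy as np
import pandas as pd
import pytest

from stiffscan import (
    GridSpec,
    PromoterModel,
    PromoterModelResults,
    ReferenceProfile,
    ScoreTrack,
    TssPrediction,
    build_reference_profile,
    call_tss,
    filter_candidates,
    gen_stiffness_table,
    mahalanobis,
    make_regions,
    scan,
    step_series,
    window_average,
)
from stiffscan.model import write_calls_bed

from conftest import random_seq


def _iid_seq(rng, n, p):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _grid_features_by_hand(seq, tss_offset, table, grid):
    """Independent feature extraction: window_average per grid window."""
    feats = []
    for off in grid.offsets:
        s = tss_offset + int(off)
        sub = seq[s : s + grid.window_length]
        wp = window_average(step_series(sub, table), grid.window_length, grid.window_length)
        feats.append(wp.means[0])
    return np.concatenate(feats)


class TestBuildReferenceProfile:
    def test_identical_training_set_degenerates_to_ridge(self, table, small_grid, rng):
        seq = random_seq(rng, 600)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = build_reference_profile(
                [(seq, 100, "+")] * 10, table, small_grid, "promoter", force_diagonal=False
            )
        np.testing.assert_allclose(ref.mean, _grid_features_by_hand(seq, 100, table, small_grid))
        np.testing.assert_allclose(ref.covariance, 1e-9 * np.eye(small_grid.dim), atol=1e-12)

    def test_two_example_mean_is_midpoint(self, table, small_grid, rng):
        seqs = [random_seq(rng, 600), random_seq(rng, 600)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = build_reference_profile(
                [(s, 100, "+") for s in seqs], table, small_grid, "background"
            )
        stacked = np.vstack(
            [_grid_features_by_hand(s, 100, table, small_grid) for s in seqs]
        )
        np.testing.assert_allclose(ref.mean, stacked.mean(axis=0), rtol=1e-10)

    def test_antisense_examples_match_sense_features(self, table, small_grid, rng):
        from stiffscan import revcomp

        seq = random_seq(rng, 600)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sense = build_reference_profile([(seq, 100, "+")], table, small_grid, "p")
            anti = build_reference_profile(
                [(revcomp(seq), 499, "-")], table, small_grid, "p"
            )
        np.testing.assert_allclose(anti.mean, sense.mean, atol=1e-9)

    def test_shared_grid_between_classes(self, table, small_grid, rng):
        model = PromoterModel(
            [(random_seq(rng, 600), 100, "+")] * 3,
            [(random_seq(rng, 600), 100, "+")] * 3,
            table=table,
            grid=small_grid,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        assert res.promoter.grid == res.background.grid

    def test_no_usable_examples_errors(self, table, small_grid):
        with pytest.raises(ValueError, match="no usable"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            build_reference_profile([("N" * 600, 100, "+")], table, small_grid, "p")


class TestMahalanobis:
    def test_zero_at_mean(self):
        ref = ReferenceProfile("p", None, np.array([1.0, 2.0]), np.eye(2))
        assert mahalanobis(np.array([1.0, 2.0]), ref) == 0.0

    def test_identity_covariance_is_euclidean(self):
        ref = ReferenceProfile("p", None, np.zeros(2), np.eye(2))
        assert mahalanobis(np.array([3.0, 4.0]), ref) == pytest.approx(5.0)

    def test_diagonal_covariance_explicit_inverse(self):
        ref = ReferenceProfile("p", None, np.zeros(2), np.diag([4.0, 1.0]))
        # independent evaluation: x^T Sigma^-1 x with Sigma^-1 = diag(1/4, 1)
        expected = np.sqrt(2.0**2 / 4.0 + 1.0**2 / 1.0)
        assert mahalanobis(np.array([2.0, 1.0]), ref) == pytest.approx(expected)

    def test_dimension_mismatch_errors(self):
        ref = ReferenceProfile("p", None, np.zeros(3), np.eye(3))
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis(np.zeros(4), ref)

    def test_affine_invariance(self, rng):
        """Distance is invariant under invertible maps applied consistently."""
        for _ in range(50):
            d = 4
            mean = rng.normal(size=d)
            A0 = rng.normal(size=(d, d))
            cov = A0 @ A0.T + 0.5 * np.eye(d)
            x = rng.normal(size=d)
            M = rng.normal(size=(d, d)) + 2 * np.eye(d)
            ref = ReferenceProfile("p", None, mean, cov)
            ref_t = ReferenceProfile("p", None, M @ mean, M @ cov @ M.T)
            assert mahalanobis(M @ x, ref_t) == pytest.approx(
                mahalanobis(x, ref), rel=1e-8, abs=1e-8
            )

    def test_diagonal_and_full_agree_on_diagonal_covariance(self, rng):
        var = rng.uniform(0.5, 2.0, size=5)
        mean = rng.normal(size=5)
        x = rng.normal(size=5)
        full = ReferenceProfile("p", None, mean, np.diag(var))
        diag = ReferenceProfile("p", None, mean, var, diagonal=True)
        assert full.mahalanobis(x) == pytest.approx(diag.mahalanobis(x), rel=1e-12)


@pytest.fixture(scope="module")
def fitted_small():
    """Classifier over clearly separated iid compositions, D = 24."""
    rng = np.random.default_rng(99)
    table = gen_stiffness_table(3)
    grid = GridSpec(span_start=-100, span_end=500, window_length=300, stride=100)
    p_comp, b_comp = [0.7, 0.1, 0.1, 0.1], [0.25] * 4
    prom = [(_iid_seq(rng, 600, p_comp), 100, "+") for _ in range(40)]
    bg = [(_iid_seq(rng, 600, b_comp), 100, "+") for _ in range(40)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = PromoterModel(prom, bg, table=table, grid=grid).fit()
    return res, table, grid, p_comp, b_comp


class TestScan:
    def test_promoter_like_genome_all_promoter(self, fitted_small):
        res, table, grid, p_comp, _ = fitted_small
        rng = np.random.default_rng(5)
        genome = {"chrP": _iid_seq(rng, 4000, p_comp)}
        tracks = res.scan(genome, stride=100)
        for t in tracks:
            s = t.score[t.valid]
            assert len(s) and (s > 0).all()

    def test_background_genome_all_background(self, fitted_small):
        res, table, grid, _, b_comp = fitted_small
        rng = np.random.default_rng(6)
        genome = {"chrB": _iid_seq(rng, 4000, b_comp)}
        tracks = res.scan(genome, stride=100)
        for t in tracks:
            s = t.score[t.valid]
            assert len(s) and (s < 0).all()

    def test_strand_mirror(self, fitted_small):
        """Scanning the reverse complement mirrors predictions across strands."""
        from stiffscan import revcomp

        res, *_ = fitted_small
        rng = np.random.default_rng(7)
        L = 5001  # L-1 divisible by the stride keeps mirrored positions on-lattice
        seq = random_seq(rng, L)
        fwd = {t.strand: t for t in res.scan({"c": seq}, stride=50)}
        rev = {t.strand: t for t in res.scan({"c": revcomp(seq)}, stride=50)}
        for s_f, s_r in (("+", "-"), ("-", "+")):
            tf, tr = fwd[s_f], rev[s_r]
            mirrored = (L - 1) - tr.positions[::-1]
            np.testing.assert_array_equal(tf.positions, mirrored)
            np.testing.assert_allclose(tf.score, tr.score[::-1], atol=1e-6)

    def test_checksum_mismatch_rejected(self, fitted_small, table):
        res, *_ = fitted_small
        other = ReferenceProfile(
            "background",
            res.background.grid,
            res.background.mean,
            res.background.covariance,
            n_training=1,
            table_checksum="deadbeef",
        )
        with pytest.raises(ValueError, match="incoherence"):
            scan({"c": "ACGT" * 500}, res.table, res.promoter, other)

    def test_tie_scores_label_background(self):
        pred = TssPrediction("c", 0, "+", 1.5, 1.5)
        assert pred.score == 0.0 and pred.label == "background"

    def test_no_call_on_masked_stretch(self, fitted_small):
        res, *_ = fitted_small
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 1500) + "N" * 1000 + random_seq(rng, 1500)
        tracks = res.scan({"c": seq}, stride=100)
        assert any((~t.valid).any() for t in tracks)


def _track(scores, stride=50, strand="+", chrom="c"):
    scores = np.asarray(scores, dtype=float)
    return ScoreTrack(
        chrom=chrom,
        strand=strand,
        positions=np.arange(len(scores)) * stride,
        d_promoter=np.zeros(len(scores)),
        d_background=scores,
        valid=np.ones(len(scores), dtype=bool),
    )


class TestCallTss:
    def test_single_peak_called_at_argmax(self):
        calls = call_tss(_track([0, 1, 5, 2, 0]), tau=3.0)
        assert [(c.position, c.score) for c in calls] == [(100, 5.0)]

    def test_equal_peaks_within_separation_keep_leftmost(self):
        # two equal maxima 600 bp apart; 1200-bp suppression keeps the left one
        scores = np.zeros(25)
        scores[4] = scores[16] = 7.0  # positions 200 and 800
        calls = call_tss(_track(scores), tau=1.0, min_separation=1200)
        assert [c.position for c in calls] == [200]

    def test_distant_peaks_both_kept(self):
        scores = np.zeros(60)
        scores[5] = 7.0
        scores[55] = 6.0  # 2500 bp apart
        calls = call_tss(_track(scores), tau=1.0, min_separation=1200)
        assert [c.position for c in calls] == [250, 2750]

    def test_suppression_is_strand_agnostic(self):
        plus = _track([0, 0, 9, 0, 0], strand="+")
        minus = _track([0, 0, 0, 8, 0], strand="-")
        calls = call_tss([plus, minus], tau=1.0, min_separation=1200)
        assert len(calls) == 1 and calls[0].strand == "+"

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            call_tss(_track([1.0]), tau=-1.0)

    def test_deterministic_bed_output(self, tmp_path, fitted_small):
        res, *_ = fitted_small
        rng = np.random.default_rng(11)
        genome = {"c": random_seq(rng, 6000)}
        outs = []
        for name in ("a.bed", "b.bed"):
            tracks = res.scan(genome, stride=100)
            calls = res.call_tss(tracks, tau=0.0)
            write_calls_bed(calls, tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]


class TestFilterCandidates:
    @pytest.fixture()
    def setup(self, rng):
        genome = {"c": random_seq(rng, 30000)}
        call = TssPrediction("c", 15000, "+", 0.0, 2.0)
        return genome, call

    def _annotation(self, *positions):
        return pd.DataFrame({"chrom": ["c"] * len(positions), "position": list(positions)})

    def test_annotated_tss_at_1199_rejected_1200_kept(self, setup):
        genome, call = setup
        kept, rejects = filter_candidates([call], self._annotation(16199), genome)
        assert not kept and "too close" in rejects.iloc[0]["reason"]
        kept, rejects = filter_candidates([call], self._annotation(16200), genome)
        assert kept and rejects.empty

    def test_repeat_fraction_over_70_percent_rejected(self, rng):
        # 71% of the 1200-bp tested region [14000, 15200) soft-masked
        seq = list(random_seq(rng, 30000))
        for i in range(14000, 14852):
            seq[i] = seq[i].lower()
        genome = {"c": "".join(seq)}
        call = TssPrediction("c", 15000, "+", 0.0, 2.0)
        kept, rejects = filter_candidates([call], self._annotation(1), genome)
        assert not kept and "repeat fraction" in rejects.iloc[0]["reason"]

    def test_repeat_fraction_exactly_70_percent_kept(self, rng):
        seq = list(random_seq(rng, 30000))
        for i in range(14000, 14840):  # exactly 840/1200 = 0.70
            seq[i] = seq[i].lower()
        genome = {"c": "".join(seq)}
        call = TssPrediction("c", 15000, "+", 0.0, 2.0)
        kept, _ = filter_candidates([call], self._annotation(1), genome)
        assert kept

    def test_isolated_unmasked_call_kept(self, setup):
        genome, call = setup
        kept, rejects = filter_candidates([call], self._annotation(100, 29000), genome)
        assert kept == [call] and rejects.empty

    def test_mask_bed_alternative(self, setup):
        genome, call = setup
        mask = pd.DataFrame({"chrom": ["c"], "start": [14000], "end": [14900]})  # 75%
        kept, rejects = filter_candidates(
            [call], self._annotation(1), genome, mask_intervals=mask
        )
        assert not kept and "repeat fraction" in rejects.iloc[0]["reason"]

    def test_missing_annotation_errors(self, setup):
        genome, call = setup
        with pytest.raises(ValueError):
            filter_candidates([call], None, genome)


class TestMakeRegions:
    def test_plus_strand_core_promoter(self):
        r = make_regions(TssPrediction("c", 10_000, "+", 0, 1), "core_promoter")
        assert (r.start, r.end) == (9000, 10_200) and r.length == 1200

    def test_minus_strand_core_promoter_reflected(self):
        r = make_regions(TssPrediction("c", 10_000, "-", 0, 1), "core_promoter")
        assert (r.start, r.end) == (9800, 11_000)

    def test_expanded_2000_centered(self):
        r = make_regions(TssPrediction("c", 10_000, "+", 0, 1), "expanded_2000")
        assert (r.start, r.end) == (9000, 11_000) and r.length == 2000

    def test_truncation_warns_and_flags(self):
        with pytest.warns(UserWarning, match="truncated"):
            r = make_regions(TssPrediction("c", 500, "+", 0, 1), "core_promoter")
        assert r.truncated and r.start == 0

    def test_five_prime_end_convention(self):
        plus = make_regions(TssPrediction("c", 10_000, "+", 0, 1), "tested_1200")
        minus = make_regions(TssPrediction("c", 10_000, "-", 0, 1), "tested_1200")
        assert plus.five_prime == plus.start
        assert minus.five_prime == minus.end - 1

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            make_regions(TssPrediction("c", 10_000, "+", 0, 1), "nope")


class TestResultsObject:
    def test_summary_mentions_grid_and_training(self, fitted_small):
        res, *_ = fitted_small
        text = res.summary()
        assert "feature dimension" in text and "promoter 40" in text

    def test_save_load_roundtrip_scores_identically(self, fitted_small, tmp_path, rng):
        res, table, grid, p_comp, _ = fitted_small
        res.save(tmp_path / "model.json")
        loaded = PromoterModelResults.load(tmp_path / "model.json", table=table)
        genome = {"c": random_seq(rng, 3000)}
        t1 = res.scan(genome, stride=100)
        t2 = loaded.scan(genome, stride=100)
        np.testing.assert_allclose(t1[0].score, t2[0].score, rtol=1e-12)
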
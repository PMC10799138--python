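import numpy as np
import pytest

from poolimpute import metrics


class TestMafBinning:
    def test_edges_half_open_last_closed(self):
        maf = np.array([0.0, 0.049, 0.05, 0.1, 0.19, 0.2, 0.39, 0.4, 0.5])
        assert metrics.assign_maf_bins(maf).tolist() == [0, 0, 1, 2, 2, 3, 4, 5, 5]

    def test_out_of_range_rejected(self):
        with pytest.raises(metrics.MetricsError):
            metrics.assign_maf_bins(np.array([0.6]))

    def test_maf_from_dosages_with_missing(self):
        d = np.array([[0, 2], [2, -1], [2, 0]])
        # AAF: (0+2+2)/6 = 2/3 -> MAF 1/3; (2+0)/4 = 0.5
        assert metrics.minor_allele_frequency(d) == pytest.approx([1 / 3, 0.5])


class TestConcordance:
    def test_perfect_prediction(self):
        truth = np.array([[0, 2], [2, 0]])
        post = np.eye(3)[truth]
        assert metrics.concordance(truth, post)["overall"] == 1.0

    def test_one_of_four_wrong(self):
        truth = np.array([[0, 2], [2, 0]])
        post = np.eye(3)[[[0, 2], [2, 2]]]
        assert metrics.concordance(truth, post)["overall"] == pytest.approx(0.75)

    def test_soft_call_concordant_hard_wrong_call_discordant(self):
        # truth alt-homozygote: (0.407351, 0, 0.592649) calls correctly,
        # (1, 0, 0) does not
        truth = np.array([[2, 2]])
        post = np.array([[[0.407351, 0.0, 0.592649], [1.0, 0.0, 0.0]]])
        assert metrics.concordance(truth, post)["overall"] == pytest.approx(0.5)

    def test_exact_tie_counts_as_discordant(self):
        truth = np.array([[0]])
        post = np.array([[[0.5, 0.0, 0.5]]])
        assert metrics.concordance(truth, post)["overall"] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(metrics.MetricsError):
            metrics.concordance(np.zeros((2, 2)), np.zeros((2, 3, 3)))

    def test_concordance_plus_discordance_is_one_per_bin(self, rng):
        truth = rng.choice([0, 2], size=(20, 40))
        post = rng.dirichlet([1, 1, 1], size=(20, 40))
        maf = metrics.minor_allele_frequency(truth)
        conc = metrics.concordance(truth, post, maf=maf)
        disc = (metrics.best_guess(post) != truth).mean(axis=0)
        assert np.allclose(conc["per_marker"] + disc, 1.0)
        bins = metrics.assign_maf_bins(maf)
        for b in np.unique(bins):
            assert conc["per_bin"][b] + disc[bins == b].mean() == pytest.approx(1.0)


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        truth = np.array([[0, 2]])
        post = np.eye(3)[truth]
        assert metrics.cross_entropy(truth, post)["overall"] == 0.0

    def test_soft_call_value(self):
        truth = np.array([[2]])
        post = np.array([[[0.407351, 0.0, 0.592649]]])
        expected = -np.log(0.592649)
        ce = metrics.cross_entropy(truth, post)["overall"]
        assert ce == pytest.approx(expected, abs=1e-9)
        assert ce == pytest.approx(0.52316, abs=1e-5)

    def test_confident_wrong_call_clipped_maximal(self):
        truth = np.array([[2]])
        post = np.array([[[1.0, 0.0, 0.0]]])
        ce = metrics.cross_entropy(truth, post, eps=1e-12)["overall"]
        assert ce == pytest.approx(-np.log(1e-12))
        assert ce == pytest.approx(27.631, abs=1e-3)

    def test_monotone_in_true_class_probability(self):
        truth = np.array([[2]])
        lo = metrics.cross_entropy(truth, np.array([[[0.5, 0.0, 0.5]]]))
        hi = metrics.cross_entropy(truth, np.array([[[0.3, 0.0, 0.7]]]))
        assert hi["overall"] < lo["overall"]

    def test_invalid_eps_rejected(self):
        with pytest.raises(metrics.MetricsError):
            metrics.cross_entropy(np.array([[0]]), np.eye(3)[[[0]]], eps=0.5)


class TestRollingWindow:
    def test_constant_scores_unchanged(self):
        df = metrics.rolling_window_scores(
            np.full(10, 0.7), np.linspace(0, 0.5, 10)
        )
        assert np.allclose(df["smoothed"], 0.7)

    def test_center_window_mean(self):
        df = metrics.rolling_window_scores(
            np.array([0.0, 1.0, 0.0, 1.0, 0.0]), np.linspace(0.1, 0.5, 5)
        )
        assert df["smoothed"].iloc[2] == pytest.approx(0.4)

    def test_matches_bruteforce_windowed_mean(self, rng):
        scores = rng.random(37)
        mafs = rng.uniform(0, 0.5, 37)
        df = metrics.rolling_window_scores(scores, mafs)
        order = np.argsort(mafs, kind="stable")
        s = scores[order]
        brute = [
            s[max(0, i - 2): i + 3].mean() for i in range(len(s))
        ]
        assert np.allclose(df["smoothed"].to_numpy(), brute)

    def test_too_few_markers_rejected(self):
        with pytest.raises(metrics.MetricsError):
            metrics.rolling_window_scores(np.ones(3), np.ones(3) * 0.1)


class TestAafHeatmap:
    def test_identical_frequencies_all_on_diagonal(self, rng):
        aaf = rng.uniform(0, 1, 50)
        H, _ = metrics.aaf_heatmap(aaf, aaf)
        off = H - np.diag(np.diag(H))
        assert off.sum() == 0.0

    def test_all_simulated_zero_mass_in_first_row(self, rng):
        aaf = rng.uniform(0.2, 0.9, 30)
        H, _ = metrics.aaf_heatmap(aaf, np.zeros(30))
        assert (H[1:, :].sum()) == 0.0
        cols = H.sum(axis=0)
        assert np.allclose(H[0, cols > 0], 1.0)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(metrics.MetricsError):
            metrics.aaf_heatmap(np.array([]), np.array([]))

    def test_pooled_data_underestimates_midrange_aaf(self, small_truth):
        # decoding hides alt carriers in heterogeneous blocks, biasing the
        # observable AAF downward for intermediate-frequency markers
        from poolimpute import decoding, pooling
        from poolimpute.formats_io import MISSING

        design = pooling.assign_blocks(small_truth.lines.sample_ids, seed=0)
        outcomes = pooling.simulate_pools_all(small_truth.lines.dosages, design)
        simplexes, _ = decoding.decode_all(
            outcomes, design, small_truth.lines.n_samples
        )
        decoded_dosage = np.where(
            simplexes[:, :, 0] == 1.0, 0, np.where(simplexes[:, :, 2] == 1.0, 2, MISSING)
        )
        true_aaf = metrics.alternate_allele_frequency(small_truth.lines.dosages)
        dec_aaf = metrics.alternate_allele_frequency(decoded_dosage)
        # markers with every entry undecided have no observable AAF
        mid = (true_aaf > 0.05) & (true_aaf < 0.45) & ~np.isnan(dec_aaf)
        assert (dec_aaf[mid] <= true_aaf[mid] + 1e-12).mean() > 0.9
        assert dec_aaf[mid].mean() < true_aaf[mid].mean()


class TestCrossModuleConsistency:
    def test_decoded_fraction_matches_decoder_counts(self, small_truth):
        from poolimpute import decoding, pooling

        design = pooling.assign_blocks(small_truth.lines.sample_ids, seed=0)
        outcomes = pooling.simulate_pools_all(small_truth.lines.dosages, design)
        simplexes, summary = decoding.decode_all(
            outcomes, design, small_truth.lines.n_samples,
            truth_dosages=small_truth.lines.dosages,
        )
        maf = metrics.minor_allele_frequency(small_truth.lines.dosages)
        dec = metrics.decoded_fraction(simplexes, maf=maf)
        assert dec["overall"] == pytest.approx(1.0 - summary["missing_fraction"])
        valid = ~np.isnan(summary["missing_per_bin"])
        assert np.allclose(
            dec["per_bin"][valid], 1.0 - summary["missing_per_bin"][valid]
        )
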
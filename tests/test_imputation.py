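import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hmm_path_posterior
from poolimpute import imputation as im


class TestSwitchProbability:
    def test_zero_distance_no_switch(self):
        assert im.switch_probability(0.0, ne=16, k=16) == 0.0

    def test_large_distance_saturates(self):
        assert im.switch_probability(1e6, ne=16, k=16) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # r = 1 - exp(-4 * 16 * 0.01 / 16) = 1 - exp(-0.04)
        r = im.switch_probability(0.01, ne=16, k=16)
        assert r == pytest.approx(0.0392106, abs=1e-7)

    def test_negative_distance_rejected(self):
        with pytest.raises(im.ImputationError):
            im.switch_probability(-0.1, ne=16, k=16)


class TestEmissionProbability:
    @pytest.mark.parametrize(
        "obs,state,lam,expected",
        [
            ((1, 0, 0), (0, 0), 0.0, 1.0),
            ((0, 0, 1), (0, 0), 0.01, 0.0001),  # both copies must flip
            ((0.5, 0, 0.5), (0, 0), 0.0, 0.5),
            ((0, 1, 0), (0, 1), 0.0, 1.0),
        ],
    )
    def test_examples(self, obs, state, lam, expected):
        assert im.emission_probability(obs, state, lam) == pytest.approx(expected)

    def test_copy_table_rows_normalized(self):
        T = im.allele_copy_table(0.037)
        assert np.allclose(T.sum(axis=2), 1.0)


class TestForwardBackwardSmall:
    def test_single_marker_two_haplotypes(self):
        # alt homozygote observed without error: all mass on (h2, h2)
        panel = im.ReferencePanel(np.array([[0], [1]]))
        post = im.forward_backward(
            np.array([[0.0, 0.0, 1.0]]), panel, np.empty(0),
            im.HMMParams(lam=0.0),
        )
        assert np.allclose(post, [[0.0, 0.0, 1.0]])

    def test_single_alt_haplotype_forces_missing_marker(self):
        panel = im.ReferencePanel(np.array([[1]]))
        post = im.forward_backward(
            np.array([[0.5, 0.0, 0.5]]), panel, np.empty(0),
            im.HMMParams(lam=0.0),
        )
        assert np.allclose(post, [[0.0, 0.0, 1.0]])

    def test_zero_likelihood_raises(self):
        panel = im.ReferencePanel(np.array([[0]]))
        with pytest.raises(im.ImputationError, match="lam > 0"):
            im.forward_backward(
                np.array([[0.0, 0.0, 1.0]]), panel, np.empty(0),
                im.HMMParams(lam=0.0),
            )

    def test_marker_mismatch_raises(self):
        panel = im.ReferencePanel(np.array([[0, 1]]))
        with pytest.raises(im.ImputationError, match="marker mismatch"):
            im.forward_backward(
                np.array([[1.0, 0.0, 0.0]]), panel, np.empty(0), im.HMMParams()
            )


class TestOracleEquivalence:
    """Forward-backward must match explicit path enumeration."""

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        k=st.integers(1, 3),
        m=st.integers(1, 4),
        seed=st.integers(0, 10**6),
        projection=st.sampled_from(["conditional", "template"]),
    )
    def test_matches_path_enumeration(self, k, m, seed, projection):
        rng = np.random.default_rng(seed)
        hap = rng.integers(0, 2, size=(k, m)).astype(np.int8)
        obs = rng.dirichlet([1.0, 1.0, 1.0], size=m)
        dists = rng.uniform(1e-4, 0.1, size=max(m - 1, 0))
        ne = rng.uniform(1, 50)
        lam = rng.uniform(1e-4, 0.1)
        params = im.HMMParams(ne=ne, lam=lam, projection=projection)
        mine = im.forward_backward(obs, im.ReferencePanel(hap), dists, params)
        oracle = hmm_path_posterior(obs, hap, dists, ne, lam, projection)
        assert np.abs(mine - oracle).max() < 1e-10


@pytest.fixture(scope="module")
def decoded_run(small_truth):
    from poolimpute import decoding, pooling

    design = pooling.assign_blocks(small_truth.lines.sample_ids, seed=0)
    outcomes = pooling.simulate_pools_all(small_truth.lines.dosages, design)
    decoded, _ = decoding.decode_all(
        outcomes, design, small_truth.lines.n_samples
    )
    dists = im._pair_distances(small_truth.markers["cm"].to_numpy())
    return decoded, dists


class TestImputePopulation:

    def test_posteriors_normalized(self, small_truth, decoded_run):
        decoded, dists = decoded_run
        post = im.impute_population(decoded, small_truth.founders, dists)
        assert np.abs(post.sum(axis=2) - 1.0).max() < 1e-9

    def test_independent_of_chunking(self, small_truth, decoded_run):
        decoded, dists = decoded_run
        a = im.impute_population(decoded, small_truth.founders, dists)
        b = im.impute_population(
            decoded, small_truth.founders, dists, chunk_size=5
        )
        assert np.allclose(a, b, atol=1e-12)

    def test_panel_relabeling_is_unobservable(self, small_truth, decoded_run, rng):
        decoded, dists = decoded_run
        perm = rng.permutation(small_truth.founders.k)
        shuffled = im.ReferencePanel(small_truth.founders.haplotypes[perm])
        a = im.impute_population(decoded, small_truth.founders, dists)
        b = im.impute_population(decoded, shuffled, dists)
        assert np.allclose(a, b, atol=1e-9)

    def test_panel_copies_recover_truth(self, small_truth):
        # samples that ARE panel haplotypes must be imputed back exactly
        hap = small_truth.founders.haplotypes
        obs = np.full((hap.shape[0], hap.shape[1], 3), [0.5, 0.0, 0.5])
        dists = im._pair_distances(small_truth.markers["cm"].to_numpy())
        # anchor every 5th marker so the copying path is identified
        anchored = 2 * hap[:, ::5]
        obs[:, ::5, :] = np.eye(3)[anchored]
        post = im.impute_population(
            obs, small_truth.founders, dists, im.HMMParams(lam=1e-3)
        )
        bg = post.argmax(axis=2)
        assert (bg == 2 * hap).mean() > 0.97

    def test_fully_decoded_sample_preserved(self, small_truth, decoded_run):
        decoded, dists = decoded_run
        post = im.impute_population(decoded, small_truth.founders, dists)
        known0 = decoded[:, :, 0] == 1.0
        known2 = decoded[:, :, 2] == 1.0
        bg = post.argmax(axis=2)
        assert (bg[known0] == 0).all()
        assert (bg[known2] == 2).all()

    def test_no_heterozygote_mass_with_homozygous_priors(
        self, small_truth, decoded_run
    ):
        decoded, dists = decoded_run
        post = im.impute_population(decoded, small_truth.founders, dists)
        assert post[:, :, 1].max() < 0.01

    def test_empty_sample_set(self, small_truth):
        dists = im._pair_distances(small_truth.markers["cm"].to_numpy())
        post = im.impute_population(
            np.zeros((0, small_truth.founders.n_markers, 3)),
            small_truth.founders,
            dists,
        )
        assert post.shape == (0, small_truth.founders.n_markers, 3)

    def test_haploid_mode_close_to_diploid(self, small_truth, decoded_run):
        decoded, dists = decoded_run
        a = im.impute_population(decoded, small_truth.founders, dists)
        b = im.impute_population(
            decoded, small_truth.founders, dists, im.HMMParams(haploid=True)
        )
        agree = (a.argmax(axis=2) == b.argmax(axis=2)).mean()
        assert agree > 0.95


class TestPanelFromMatrix:
    def test_homozygous_dosages_halved(self):
        panel = im.panel_from_matrix(np.array([[0, 2], [2, 0]]), ["a", "b"])
        assert panel.haplotypes.tolist() == [[0, 1], [1, 0]]

    def test_heterozygote_rejected(self):
        with pytest.raises(im.ImputationError, match="homozygous"):
            im.panel_from_matrix(np.array([[0, 1]]), ["a"])
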
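"""Factorized signature model: probabilities, likelihood, EM fitting."""

import numpy as np
import pytest

from factorsig.catalog_io import MutationCatalog, MutationFeature, all_features
from factorsig.signature_model import (
    ExposureMatrix,
    Signature,
    SignatureSet,
    em_fit,
    feature_probability,
    log_likelihood,
    read_exposures,
    read_signature_set,
    write_exposures,
    write_signature_set,
)
from factorsig.synthetic_data import make_signature_set, simulate_catalog


def uniform_signature(includes_strand=True):
    factors = {
        "sub_type": np.full(6, 1 / 6),
        "flank_m2": np.full(4, 0.25),
        "flank_m1": np.full(4, 0.25),
        "flank_p1": np.full(4, 0.25),
        "flank_p2": np.full(4, 0.25),
    }
    if includes_strand:
        factors["strand"] = np.array([0.5, 0.5])
    return Signature(factors)


def point_mass_signature(feature: MutationFeature):
    from factorsig.catalog_io import POSITION_CATEGORIES

    includes_strand = feature.strand is not None
    factors = {}
    positions = ["sub_type", "flank_m2", "flank_m1", "flank_p1", "flank_p2"]
    if includes_strand:
        positions.append("strand")
    for p in positions:
        cats = POSITION_CATEGORIES[p]
        v = np.zeros(len(cats))
        v[cats.index(feature.category(p))] = 1.0
        factors[p] = v
    return Signature(factors)


FEAT = MutationFeature("C>T", "A", "G", "T", "T", "+")


class TestFeatureProbability:
    def test_uniform_gives_one_over_3072(self):
        assert feature_probability(uniform_signature(), FEAT) == pytest.approx(1 / 3072)

    def test_zero_factor_gives_zero(self):
        sig = point_mass_signature(FEAT)
        other = MutationFeature("C>A", "A", "G", "T", "T", "+")
        assert feature_probability(sig, other) == 0.0

    def test_product_matches_hand_multiplied_oracle(self):
        rng = np.random.default_rng(5)
        sig = make_signature_set(1, separation="random", seed=5).signatures[0]
        # independent oracle: explicit product of the looked-up entries
        from factorsig.catalog_io import POSITION_CATEGORIES

        expected = 1.0
        for p in sig.positions:
            expected *= sig.factors[p][POSITION_CATEGORIES[p].index(FEAT.category(p))]
        assert feature_probability(sig, FEAT) == pytest.approx(expected, rel=1e-12)

    def test_missing_strand_in_feature_raises(self):
        strandless = MutationFeature("C>T", "A", "G", "T", "T", None)
        with pytest.raises(ValueError):
            feature_probability(uniform_signature(), strandless)


def catalog_from_features(features, counts, includes_strand=True, samples=None):
    counts = np.atleast_2d(np.asarray(counts))
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    return MutationCatalog(
        samples=samples, features=list(features), counts=counts,
        includes_strand=includes_strand,
    )


class TestLogLikelihood:
    def test_closed_form_uniform_single_signature(self):
        catalog = catalog_from_features([FEAT], [[2]])
        sigset = SignatureSet([uniform_signature()], includes_strand=True)
        expo = ExposureMatrix(["s0"], np.array([[1.0]]))
        assert log_likelihood(catalog, sigset, expo) == pytest.approx(2 * np.log(1 / 3072))

    def test_aggregated_equals_per_mutation_oracle(self):
        """Likelihood over unique-feature counts equals the naive sum over
        individual mutations."""
        rng = np.random.default_rng(7)
        sigset = make_signature_set(2, separation="random", seed=7)
        space = all_features(True)
        feats = [space[i] for i in rng.choice(len(space), size=6, replace=False)]
        counts = np.array([[3, 1, 2, 0, 0, 0], [0, 0, 1, 2, 1, 0]])
        catalog = catalog_from_features(feats, counts)
        expo = ExposureMatrix(["s0", "s1"], rng.dirichlet(np.ones(2), size=2))
        # brute-force oracle: iterate every single mutation
        expected = 0.0
        for i in range(2):
            for j, f in enumerate(feats):
                for _ in range(counts[i, j]):
                    p = sum(
                        expo.values[i, k] * feature_probability(sigset.signatures[k], f)
                        for k in range(2)
                    )
                    expected += np.log(p)
        got = log_likelihood(catalog, sigset, expo)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_mixture_probability_gives_minus_inf(self):
        sig_a = point_mass_signature(FEAT)
        other = MutationFeature("C>A", "A", "G", "T", "T", "+")
        sig_b = point_mass_signature(other)
        catalog = catalog_from_features([other], [[1]])
        sigset = SignatureSet([sig_a, sig_b], includes_strand=True)
        expo = ExposureMatrix(["s0"], np.array([[1.0, 0.0]]))
        assert log_likelihood(catalog, sigset, expo) == -np.inf

    def test_dimension_mismatch_raises(self):
        catalog = catalog_from_features([FEAT], [[1]])
        sigset = SignatureSet([uniform_signature()], includes_strand=True)
        expo = ExposureMatrix(["s0"], np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            log_likelihood(catalog, sigset, expo)


class TestEMFit:
    def test_point_mass_data_recovers_degenerate_signature(self):
        catalog = catalog_from_features([FEAT], [[50]])
        fit = em_fit(catalog, K=1, n_restarts=2, seed=3)
        sig = fit.signature_set.signatures[0]
        from factorsig.catalog_io import POSITION_CATEGORIES

        for p in sig.positions:
            idx = POSITION_CATEGORIES[p].index(FEAT.category(p))
            assert sig.factors[p][idx] >= 0.999

    @pytest.mark.parametrize("seed", range(20))
    def test_loglik_trace_is_nondecreasing(self, seed):
        sigset = make_signature_set(2, separation="random", seed=seed)
        catalog, _ = simulate_catalog(sigset, n_samples=4, seed=seed)
        fit = em_fit(catalog, K=2, n_restarts=1, max_iter=60, seed=seed)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-8 * np.abs(trace[:-1])).all()

    def test_disjoint_substitution_signatures_recovered(self):
        """Two signatures concentrated on different substitution types are
        recovered with near-perfect cosine after best-match pairing."""
        from factorsig.model_selection import greedy_align
        from factorsig.signature_compare import cosine_similarity, expand_full

        rng = np.random.default_rng(17)
        truth = make_signature_set(2, separation="well_separated", seed=17)
        catalog, _ = simulate_catalog(
            truth, n_samples=10, count_range=(400, 600), seed=17
        )
        assert catalog.n_mutations >= 4000
        fit = em_fit(catalog, K=2, n_restarts=5, seed=18)
        perm = greedy_align(truth, fit.signature_set)
        for k in range(2):
            cos = cosine_similarity(
                expand_full(truth.signatures[k]),
                expand_full(fit.signature_set.signatures[perm[k]]),
            )
            assert cos >= 0.99

    def test_factors_and_exposures_normalized_after_fit(self, small_catalog):
        catalog, _ = small_catalog
        fit = em_fit(catalog, K=3, n_restarts=2, max_iter=100, seed=9)
        for sig in fit.signature_set.signatures:
            for v in sig.factors.values():
                assert abs(v.sum() - 1.0) < 1e-9
                assert (v >= 0).all()
        rows = fit.exposures.values.sum(axis=1)
        assert np.abs(rows - 1.0).max() < 1e-9

    def test_permutation_invariance_of_loglik(self, small_catalog):
        catalog, _ = small_catalog
        fit = em_fit(catalog, K=3, n_restarts=2, max_iter=100, seed=9)
        base = log_likelihood(catalog, fit.signature_set, fit.exposures)
        perm = [2, 0, 1]
        shuffled = SignatureSet(
            [fit.signature_set.signatures[p] for p in perm], catalog.includes_strand
        )
        expo = ExposureMatrix(fit.exposures.samples, fit.exposures.values[:, perm])
        assert log_likelihood(catalog, shuffled, expo) == pytest.approx(base, rel=1e-12)

    def test_loglik_equals_last_trace_entry(self, small_catalog):
        catalog, _ = small_catalog
        fit = em_fit(catalog, K=2, n_restarts=1, max_iter=50, seed=1)
        assert fit.loglik == fit.loglik_trace[-1]

    def test_k_above_feature_count_warns(self):
        catalog = catalog_from_features([FEAT], [[5]])
        with pytest.warns(UserWarning, match="exceeds"):
            em_fit(catalog, K=2, n_restarts=1, max_iter=10, seed=0)

    def test_background_component_is_held_fixed(self, small_catalog):
        catalog, _ = small_catalog
        bg = uniform_signature(includes_strand=catalog.includes_strand)
        fit = em_fit(catalog, K=2, n_restarts=2, max_iter=100, seed=4, background=bg)
        assert fit.signature_set.background is bg
        assert fit.exposures.values.shape == (catalog.n_samples, 3)
        for p, v in fit.signature_set.background.factors.items():
            np.testing.assert_array_equal(v, bg.factors[p])


class TestSerialization:
    def test_signature_round_trip(self, tmp_path, separated_sigset):
        path = tmp_path / "sigs.tsv"
        write_signature_set(separated_sigset, path)
        back = read_signature_set(path)
        assert back.K == separated_sigset.K
        assert back.includes_strand == separated_sigset.includes_strand
        for a, b in zip(back.signatures, separated_sigset.signatures):
            for p in a.positions:
                np.testing.assert_allclose(a.factors[p], b.factors[p], rtol=1e-11)

    def test_exposure_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        expo = ExposureMatrix(["a", "b"], rng.dirichlet(np.ones(3), size=2))
        path = tmp_path / "expo.tsv"
        write_exposures(expo, path)
        back = read_exposures(path)
        assert back.samples == expo.samples
        np.testing.assert_allclose(back.values, expo.values, rtol=1e-11)
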
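"""Refitting, the exhaustive oracle, de novo extraction, and mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import spectrum_from_mixture
from sigtrace import synthetic
from sigtrace.signature_fit import (
    ConfigurationError,
    DegenerateInputError,
    cosine,
    extract_denovo,
    map_to_catalog,
    nnls_subset_oracle,
    refit_exposures,
)
from sigtrace.spectrum import Spectrum96


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.arange(1, 97, dtype=float)
        assert cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_support_is_zero(self):
        u = np.zeros(96)
        v = np.zeros(96)
        u[:48], v[48:] = 1, 1
        assert cosine(u, v) == 0.0

    def test_hand_case(self):
        u = np.zeros(96)
        v = np.zeros(96)
        u[0] = u[1] = 1
        v[0] = v[2] = 1
        assert cosine(u, v) == pytest.approx(0.5)

    def test_zero_vector_errors(self):
        with pytest.raises(DegenerateInputError):
            cosine(np.zeros(96), np.ones(96))


class TestRefit:
    def test_identity_case(self, block5):
        spec = spectrum_from_mixture(block5, [0, 0, 1, 0, 0], 1000)
        prof = refit_exposures(spec, block5)
        assert prof.weights == pytest.approx({"S3": 1.0})
        assert prof.residual_error <= 1e-12

    def test_two_component_mix_recovery(self, block2):
        spec = spectrum_from_mixture(block2, [0.7, 0.3], 10_000)
        prof = refit_exposures(spec, block2)
        oracle = nnls_subset_oracle(spec, block2, max_subset=2)
        for name, truth in [("S1", 0.7), ("S2", 0.3)]:
            assert prof.weights[name] == pytest.approx(truth, abs=0.02)
            assert prof.weights[name] == pytest.approx(oracle.weights[name], abs=1e-9)

    def test_cutoff_zeroes_small_components(self, block5):
        spec = spectrum_from_mixture(block5, [0.56, 0.4, 0.04, 0, 0], 100_000)
        prof = refit_exposures(spec, block5, cutoff=0.06)
        assert "S3" not in prof.weights
        assert all(w >= 0.06 for w in prof.weights.values())

    def test_empty_spectrum_errors(self, block5):
        with pytest.raises(DegenerateInputError):
            refit_exposures(Spectrum96("s", np.zeros(96, dtype=int)), block5)

    def test_empty_catalog_errors(self, block5):
        from sigtrace.catalog import SignatureCatalog

        empty = SignatureCatalog([], np.zeros((0, 96)))
        with pytest.raises(ConfigurationError):
            refit_exposures(spectrum_from_mixture(block5, [1, 0, 0, 0, 0], 100), empty)

    @given(factor=st.integers(min_value=2, max_value=50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, block5, factor):
        """Weights depend on proportions only, not the total count."""
        rng = np.random.default_rng(3)
        spec = spectrum_from_mixture(block5, [0.5, 0.3, 0.2, 0, 0], 2000, rng=rng)
        scaled = Spectrum96(spec.sample_id, spec.counts * factor)
        w1 = refit_exposures(spec, block5).weights
        w2 = refit_exposures(scaled, block5).weights
        assert w1.keys() == w2.keys()
        for k in w1:
            assert w1[k] == pytest.approx(w2[k], abs=1e-9)

    def test_weights_sum_at_most_one(self, catalog10):
        rng = np.random.default_rng(5)
        for i in range(10):
            expo = rng.dirichlet(np.ones(10))
            spec = spectrum_from_mixture(catalog10, expo, 500, rng=rng, sample_id=f"s{i}")
            prof = refit_exposures(spec, catalog10)
            assert sum(prof.weights.values()) <= 1 + 1e-9
            assert all(w >= 0.06 for w in prof.weights.values())


class TestOracle:
    def test_single_signature_projection(self, block5):
        cat1 = block5.subset(["S1"])
        spec = spectrum_from_mixture(cat1, [1.0], 1000)
        prof = nnls_subset_oracle(spec, cat1, max_subset=1)
        assert prof.weights["S1"] == pytest.approx(1.0, abs=1e-9)

    def test_max_subset_zero(self, block5):
        spec = spectrum_from_mixture(block5, [1, 0, 0, 0, 0], 1000)
        prof = nnls_subset_oracle(spec, block5, max_subset=0)
        assert prof.weights == {}
        p = spec.normalized()
        assert prof.residual_error == pytest.approx(float(p @ p))

    def test_large_catalog_refused(self):
        cat = synthetic.random_catalog(13, seed=0)
        spec = spectrum_from_mixture(cat, np.ones(13) / 13, 100)
        with pytest.raises(ConfigurationError, match="refit_exposures"):
            nnls_subset_oracle(spec, cat, max_subset=2)


class TestDeNovo:
    def test_rank_one_identity(self, block5):
        profile = block5.matrix[0]
        spectra = [
            Spectrum96(f"s{i}", np.round(profile * n).astype(int))
            for i, n in enumerate([1000, 2000, 3000])
        ]
        res = extract_denovo(spectra, k=1, n_restarts=3, seed=0)
        assert cosine(res.signatures[0], profile) >= 0.999
        assert res.signatures[0] == pytest.approx(
            res.signatures[0] / res.signatures[0].sum()
        )

    def test_planted_two_signature_recovery(self, block2):
        rng = np.random.default_rng(9)
        spectra = [
            spectrum_from_mixture(
                block2, rng.dirichlet([1, 1]), 5000, rng=rng, sample_id=f"s{i}"
            )
            for i in range(40)
        ]
        res = extract_denovo(spectra, k=2, n_restarts=5, seed=1)
        sims = [
            max(cosine(sig, block2.matrix[j]) for sig in res.signatures)
            for j in range(2)
        ]
        assert min(sims) >= 0.95

    def test_determinism(self, block2):
        rng = np.random.default_rng(2)
        spectra = [
            spectrum_from_mixture(block2, [0.6, 0.4], 1000, rng=rng, sample_id=f"s{i}")
            for i in range(5)
        ]
        r1 = extract_denovo(spectra, k=2, n_restarts=3, seed=5)
        r2 = extract_denovo(spectra, k=2, n_restarts=3, seed=5)
        np.testing.assert_array_equal(r1.signatures, r2.signatures)
        np.testing.assert_array_equal(r1.sample_loadings, r2.sample_loadings)

    def test_k_exceeding_samples_errors(self, block2):
        spec = spectrum_from_mixture(block2, [1, 0], 100)
        with pytest.raises(ConfigurationError):
            extract_denovo([spec], k=2)


class TestMapToCatalog:
    def _denovo(self, rows):
        from sigtrace.signature_fit import DeNovoResult

        rows = np.atleast_2d(rows)
        return DeNovoResult(rows, np.ones((1, len(rows))), len(rows), 0.0)

    def test_exact_match_maps_at_one(self, block5):
        res = map_to_catalog(self._denovo(block5.matrix[2]), block5)
        assert res.mapping[0] == ("S3", pytest.approx(1.0))

    def test_below_threshold_unmapped(self, block5):
        # a mixture whose best cosine with any single block signature is
        # 1/sqrt(2) ~ 0.707 < 0.75
        row = (block5.matrix[0] + block5.matrix[1]) / 2
        res = map_to_catalog(self._denovo(row), block5)
        name, sim = res.mapping[0]
        assert name is None
        assert sim == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_uniform_row_matches_brute_force(self, block5):
        row = np.full(96, 1 / 96)
        sims = [cosine(row, block5.matrix[j]) for j in range(5)]
        res = map_to_catalog(self._denovo(row), block5, threshold=0.75)
        name, sim = res.mapping[0]
        assert sim == pytest.approx(max(sims), abs=1e-12)
        assert (name is None) == (max(sims) <= 0.75)
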
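"""Ground-truth cohort generator."""

import numpy as np
import pytest

from sigtrace import synthetic
from sigtrace.signature_fit import cosine, refit_cohort
from sigtrace.synthetic import (
    CancerTypeProfile,
    ConfigurationError,
    simulate_cfdna,
    simulate_cohort,
    simulate_metastases,
    simulate_ppi,
)


@pytest.fixture(scope="module")
def cat5():
    return synthetic.random_catalog(5, seed=7)


@pytest.fixture(scope="module")
def profiles3(cat5):
    return synthetic.default_profiles(cat5, type_names=["A", "B", "C"])


class TestSimulateCohort:
    def test_determinism(self, cat5, profiles3):
        a = simulate_cohort(profiles3, 5, cat5, seed=3)
        b = simulate_cohort(profiles3, 5, cat5, seed=3)
        for sa, sb in zip(a[0], b[0]):
            np.testing.assert_array_equal(sa.counts, sb.counts)
        assert a[1].equals(b[1])
        for sid in a[2].samples:
            np.testing.assert_array_equal(
                a[2].samples[sid].exposures, b[2].samples[sid].exposures
            )

    def test_infinite_concentration_degenerates_to_mean(self, cat5, profiles3):
        _, _, truth = simulate_cohort(
            profiles3, 3, cat5, seed=1, concentration=np.inf
        )
        for sid, t in truth.samples.items():
            prof = next(p for p in profiles3 if p.type_name == t.type_name)
            np.testing.assert_array_equal(t.exposures, prof.exposure_mean)

    def test_dirichlet_moment(self, cat5):
        """Empirical mean exposure matches the closed-form Dirichlet moment
        within 3 standard errors."""
        mean = np.array([0.5, 0.5, 0, 0, 0])
        prof = CancerTypeProfile("T", mean, ["S1"], {})
        conc = 50.0
        _, _, truth = simulate_cohort([prof], 1000, cat5, seed=8, concentration=conc)
        draws = np.array([t.exposures[0] for t in truth.samples.values()])
        var = mean[0] * (1 - mean[0]) / (conc + 1)
        se = np.sqrt(var / 1000)
        assert abs(draws.mean() - 0.5) <= 3 * se

    def test_spectrum_totals_equal_recorded_burden(self, cat5, profiles3):
        spectra, _, truth = simulate_cohort(profiles3, 10, cat5, seed=4)
        for s in spectra:
            assert s.total == truth.samples[s.sample_id].mutation_count
            assert s.total >= 10  # burden floor

    def test_unknown_signature_in_profile_errors(self, cat5):
        bad = CancerTypeProfile("T", np.array([1, 0, 0, 0, 0.0]), ["S99"], {})
        with pytest.raises(ConfigurationError, match="S99"):
            simulate_cohort([bad], 2, cat5, seed=0)

    def test_invalid_parameters(self, cat5, profiles3):
        with pytest.raises(ConfigurationError):
            simulate_cohort(profiles3, 0, cat5, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_cohort(profiles3, 2, cat5, seed=0, concentration=0)


class TestSimulateMetastases:
    def test_drift_to_zero_limit(self, cat5, profiles3):
        spectra, _, truth = simulate_cohort(profiles3, 5, cat5, seed=5)
        _, truth = simulate_metastases(truth, cat5, 3, drift=1e-12, seed=6)
        for mid in truth.ids_in("metastasis"):
            met = truth.samples[mid]
            prim = truth.samples[met.paired_primary_id]
            np.testing.assert_allclose(met.exposures, prim.exposures, atol=1e-4)

    def test_zero_pairs_adds_nothing(self, cat5, profiles3):
        _, _, truth = simulate_cohort(profiles3, 5, cat5, seed=5)
        n_before = len(truth.samples)
        _, truth = simulate_metastases(truth, cat5, 0, drift=0.05, seed=6)
        assert len(truth.samples) == n_before

    def test_nonpositive_drift_errors(self, cat5, profiles3):
        _, _, truth = simulate_cohort(profiles3, 5, cat5, seed=5)
        with pytest.raises(ConfigurationError):
            simulate_metastases(truth, cat5, 2, drift=0.0, seed=6)

    def test_pairs_closer_than_cross_type(self, cat5, profiles3):
        """At drift 0.05 a metastasis stays closer to its primary than a
        random other-type sample in >= 95% of 200 seeded pairs."""
        _, _, truth = simulate_cohort(profiles3, 100, cat5, seed=10)
        a_ids = [s for s, t in truth.samples.items() if t.type_name == "A"]
        b_ids = [s for s, t in truth.samples.items() if t.type_name == "B"]
        _, truth = simulate_metastases(
            truth, cat5, 100, drift=0.05, seed=11, source_ids=a_ids
        )
        rng = np.random.default_rng(12)
        hits = 0
        pairs = truth.ids_in("metastasis")
        for mid in pairs * 2:  # 200 comparisons
            met = truth.samples[mid]
            prim = truth.samples[met.paired_primary_id]
            other = truth.samples[rng.choice(b_ids)]
            if cosine(prim.exposures, met.exposures) >= cosine(
                prim.exposures, other.exposures
            ):
                hits += 1
        assert hits / (2 * len(pairs)) >= 0.95


class TestSimulateCfdna:
    def test_identity_at_full_dilution(self, cat5, profiles3):
        spectra, genes, truth = simulate_cohort(profiles3, 4, cat5, seed=20)
        cf, cf_genes, truth = simulate_cfdna(
            truth, spectra, genes, dilution=1.0, dropout=0.0, seed=21
        )
        for t, c in zip(spectra, cf):
            np.testing.assert_array_equal(t.counts, c.counts)
        np.testing.assert_array_equal(genes.to_numpy(), cf_genes.to_numpy())

    def test_binomial_thinning_moments(self, cat5):
        prof = CancerTypeProfile("T", np.array([1, 0, 0, 0, 0.0]), ["S1"], {})
        spectra, genes, truth = simulate_cohort(
            [prof], 1, cat5, seed=22, burden_dist=(np.log(1000), 1e-9)
        )
        assert spectra[0].total == 1000
        cf, _, _ = simulate_cfdna(truth, spectra, genes, 0.2, 0.0, seed=23)
        n, p = 1000, 0.2
        assert abs(cf[0].total - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_dropout_moments(self, cat5):
        genes = [f"G{i}" for i in range(100)]
        prof = CancerTypeProfile(
            "T", np.array([1, 0, 0, 0, 0.0]), ["S1"], {g: 1.0 for g in genes}
        )
        spectra, gm, truth = simulate_cohort(
            [prof], 1, cat5, seed=24, genes=genes, background_rate=0.0
        )
        assert gm.to_numpy().sum() == 100  # all drivers planted
        _, cf_genes, _ = simulate_cfdna(truth, spectra, gm, 1.0, 0.5, seed=25)
        retained = cf_genes.to_numpy().sum()
        assert abs(retained - 50) <= 3 * np.sqrt(25)

    def test_invalid_dilution_errors(self, cat5, profiles3):
        spectra, genes, truth = simulate_cohort(profiles3, 2, cat5, seed=26)
        with pytest.raises(ConfigurationError):
            simulate_cfdna(truth, spectra, genes, 0.0, 0.0, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_cfdna(truth, spectra, genes, 1.5, 0.0, seed=0)


class TestSimulatePpi:
    def test_deterministic_module_clique(self):
        net = simulate_ppi(["A", "B", "C"], 0, p_in=1.0, p_out=1e-9, seed=0)
        assert net.edges == {
            frozenset({"A", "B"}),
            frozenset({"A", "C"}),
            frozenset({"B", "C"}),
        }

    def test_equal_rates_error(self):
        with pytest.raises(ConfigurationError):
            simulate_ppi(["A", "B"], 10, p_in=0.1, p_out=0.1, seed=0)

    def test_determinism(self):
        a = simulate_ppi(list("ABCDE"), 50, 0.3, 0.01, seed=4)
        b = simulate_ppi(list("ABCDE"), 50, 0.3, 0.01, seed=4)
        assert a.edges == b.edges


def test_exposure_recovery_end_to_end(catalog10):
    """Refitting simulated spectra recovers the planted exposures with
    per-signature RMSE <= 0.05 at 1,000 mutations per sample."""
    profiles = synthetic.default_profiles(
        catalog10, type_names=[f"T{i}" for i in range(4)]
    )
    spectra, _, truth = simulate_cohort(
        profiles, 25, catalog10, seed=30, burden_dist=(np.log(1000), 1e-9)
    )
    fitted = refit_cohort(spectra, catalog10)
    true = truth.exposures_df(catalog10.names).loc[fitted.index]
    rmse = np.sqrt(((fitted - true) ** 2).mean())
    assert (rmse <= 0.05).all()
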
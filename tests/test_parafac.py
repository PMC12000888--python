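import numpy as np
import pytest

from fdomlink.errors import FdomlinkError, RankError, UndefinedIndexError, ValidationError
from fdomlink.parafac import (
    classify_component,
    component_fingerprints,
    core_consistency,
    fit_parafac,
    fmax_scores,
    load_model,
    match_components,
    match_reference,
    model_order_scan,
    percent_composition,
    save_model,
    split_half_validate,
    tucker_congruence,
)
from fdomlink.synth import ComponentSpec, generate_eem_dataset


def gaussian(x, center, width):
    return np.exp(-0.5 * ((np.asarray(x, dtype=float) - center) / width) ** 2)


@pytest.fixture(scope="module")
def rank3_dataset():
    comps = [
        ComponentSpec("a", 260.0, 15.0, 330.0, 20.0),
        ComponentSpec("b", 300.0, 20.0, 400.0, 30.0),
        ComponentSpec("c", 350.0, 25.0, 470.0, 35.0),
    ]
    ds, truth = generate_eem_dataset(
        n_samples=12, components=comps, noise_sd=0.0, snr=None,
        ex_nm=np.arange(250.0, 401.0, 10.0), em_nm=np.arange(300.0, 521.0, 8.0),
        seed=3)
    return ds, truth


def min_matched_congruence(model, truth):
    matches = match_components(
        model.em_loadings, model.ex_loadings,
        np.asarray(truth["em_loadings"]), np.asarray(truth["ex_loadings"]))
    return min(min(c_ex, c_em) for _, _, c_ex, c_em in matches)


class TestTuckerCongruence:
    def test_identical_vectors(self):
        assert tucker_congruence([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert tucker_congruence([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_closed_form(self):
        assert tucker_congruence([1, 1], [1, 3]) == pytest.approx(
            4 / np.sqrt(20), abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(FdomlinkError):
            tucker_congruence([0, 0], [1, 2])


class TestFitParafac:
    def test_rank1_noiseless(self):
        comp = [ComponentSpec("a", 300.0, 20.0, 400.0, 30.0)]
        ds, _ = generate_eem_dataset(
            n_samples=5, components=comp, noise_sd=0.0, snr=None,
            ex_nm=np.arange(250.0, 401.0, 10.0),
            em_nm=np.arange(300.0, 521.0, 10.0), seed=0)
        model = fit_parafac(ds, 1, n_starts=2, seed=0)
        assert model.explained_variance >= 0.9999

    def test_rank3_recovery(self, rank3_dataset):
        ds, truth = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=3, seed=1)
        assert min_matched_congruence(model, truth) >= 0.999

    def test_pure_noise_low_ev(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 20, 15))
        model = fit_parafac(x, 4, n_starts=2, max_iter=300, seed=0)
        assert model.explained_variance < 0.5

    def test_rank_error(self, rank3_dataset):
        ds, _ = rank3_dataset
        with pytest.raises(RankError):
            fit_parafac(ds, 100, seed=0)

    def test_loss_monotone_within_fit(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=4)
        diffs = np.diff(model.loss_history)
        assert np.all(diffs <= 1e-9 * np.maximum(model.loss_history[:-1], 1e-30))

    def test_unit_max_convention(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=0)
        np.testing.assert_allclose(model.ex_loadings.max(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(model.em_loadings.max(axis=0), 1.0, atol=1e-12)
        assert np.all(model.scores >= 0)

    def test_sample_order_invariance(self, rank3_dataset):
        ds, _ = rank3_dataset
        x = ds.tensor()
        rng = np.random.default_rng(5)
        perm = rng.permutation(x.shape[0])
        m1 = fit_parafac(x, 3, n_starts=2, seed=2)
        m2 = fit_parafac(x[perm], 3, n_starts=2, seed=2)
        matches = match_components(m1.em_loadings, m1.ex_loadings,
                                   m2.em_loadings, m2.ex_loadings)
        assert min(c_ex * c_em for _, _, c_ex, c_em in matches) >= 0.999

    def test_single_sample_scaling_moves_score_only(self, rank3_dataset):
        ds, _ = rank3_dataset
        x = ds.tensor()
        x10 = x.copy()
        x10[4] *= 10.0
        m1 = fit_parafac(x, 3, n_starts=2, seed=2, normalize_samples=True)
        m2 = fit_parafac(x10, 3, n_starts=2, seed=2, normalize_samples=True)
        matches = match_components(m1.em_loadings, m1.ex_loadings,
                                   m2.em_loadings, m2.ex_loadings)
        assert min(c_ex * c_em for _, _, c_ex, c_em in matches) >= 0.999
        for i, j, _, _ in matches:
            assert m2.scores[4, j] == pytest.approx(10 * m1.scores[4, i], rel=1e-2)

    def test_missing_cells_recovery(self, rank3_dataset):
        ds, truth = rank3_dataset
        x = ds.tensor().copy()
        rng = np.random.default_rng(11)
        mask = rng.uniform(size=x.shape) < 0.05
        x[mask] = np.nan
        model = fit_parafac(x, 3, n_starts=3, seed=1)
        assert min_matched_congruence(model, truth) >= 0.99

    def test_deterministic_given_seed(self, rank3_dataset):
        ds, _ = rank3_dataset
        m1 = fit_parafac(ds, 3, n_starts=2, seed=9)
        m2 = fit_parafac(ds, 3, n_starts=2, seed=9)
        np.testing.assert_array_equal(m1.scores, m2.scores)
        np.testing.assert_array_equal(m1.em_loadings, m2.em_loadings)


class TestModelOrderScan:
    @pytest.fixture(scope="class")
    def scan(self):
        ds, _ = generate_eem_dataset(
            n_samples=16, noise_sd=0.0, snr=None,
            ex_nm=np.arange(250.0, 451.0, 10.0),
            em_nm=np.arange(300.0, 601.0, 10.0), seed=6)
        return model_order_scan(ds, range(2, 7), n_starts=2, max_iter=800, seed=0)

    def test_ev_non_decreasing(self, scan):
        ev = scan["explained_variance"].to_numpy()
        assert np.all(np.diff(ev) >= -1e-6)

    def test_plateau_at_true_rank(self, scan):
        ev = scan.set_index("K")["explained_variance"]
        assert ev[4] >= ev[6] - 0.005

    def test_core_consistency_at_true_rank(self, scan):
        assert scan.set_index("K")["core_consistency"][4] >= 90.0


class TestSplitHalf:
    def test_passes_on_clean_fixture(self):
        ds, _ = generate_eem_dataset(n_samples=24, snr=200.0, seed=8,
                                     ex_nm=np.arange(250.0, 451.0, 10.0),
                                     em_nm=np.arange(300.0, 601.0, 10.0))
        report = split_half_validate(ds, 4, n_splits=1, seed=0, n_starts=2,
                                     max_iter=1200)
        assert report.passed
        assert report.min_congruence >= 0.95

    def test_unattainable_threshold(self):
        ds, _ = generate_eem_dataset(n_samples=10, snr=100.0, seed=8,
                                     ex_nm=np.arange(250.0, 451.0, 20.0),
                                     em_nm=np.arange(300.0, 601.0, 20.0))
        report = split_half_validate(ds, 2, threshold=1.01, n_splits=1,
                                     seed=0, n_starts=1, max_iter=300)
        assert not report.passed

    def test_too_few_samples(self):
        ds, _ = generate_eem_dataset(n_samples=4, snr=100.0, seed=8,
                                     ex_nm=np.arange(250.0, 451.0, 20.0),
                                     em_nm=np.arange(300.0, 601.0, 20.0))
        with pytest.raises(ValidationError):
            split_half_validate(ds, 4, seed=0)

    def test_fails_on_disjoint_populations(self):
        # half the samples contain one fluorophore pair, half a disjoint pair;
        # an underfactored K=2 model cannot be stable across random halves
        comps_a = [ComponentSpec("p1", 270.0, 12.0, 310.0, 14.0),
                   ComponentSpec("p2", 285.0, 14.0, 350.0, 20.0)]
        comps_b = [ComponentSpec("h1", 260.0, 25.0, 450.0, 40.0),
                   ComponentSpec("h2", 320.0, 25.0, 420.0, 35.0)]
        ex = np.arange(250.0, 451.0, 10.0)
        em = np.arange(300.0, 601.0, 10.0)
        ds_a, _ = generate_eem_dataset(n_samples=17, components=comps_a,
                                       snr=100.0, ex_nm=ex, em_nm=em, seed=1)
        ds_b, _ = generate_eem_dataset(n_samples=3, components=comps_b,
                                       snr=100.0, ex_nm=ex, em_nm=em, seed=2)
        x = np.concatenate([ds_a.tensor(), ds_b.tensor()])
        report = split_half_validate(x, 2, n_splits=3, seed=0, n_starts=2,
                                     max_iter=600)
        assert not report.passed


class TestScoresAndComposition:
    def test_fmax_equals_scores_under_convention(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=0)
        np.testing.assert_allclose(fmax_scores(model), model.scores)

    def test_fmax_invariant_to_rescaling(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=0)
        hacked = model
        hacked.ex_loadings = model.ex_loadings * 0.5
        hacked.scores = model.scores * 2.0
        np.testing.assert_allclose(fmax_scores(hacked), fmax_scores(model))

    def test_fmax_tracks_true_weights(self, rank3_dataset):
        ds, truth = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=3, seed=1)
        fmax = fmax_scores(model)
        w = np.asarray(truth["weights"])
        matches = match_components(
            model.em_loadings, model.ex_loadings,
            np.asarray(truth["em_loadings"]), np.asarray(truth["ex_loadings"]))
        for i, j, _, _ in matches:
            r = np.corrcoef(fmax[:, i], w[:, j])[0, 1]
            assert r >= 0.99

    def test_percent_uniform(self):
        np.testing.assert_allclose(percent_composition(np.array([[1.0, 1, 1, 1]])),
                                   [[25, 25, 25, 25]])

    def test_percent_closed_form(self):
        np.testing.assert_allclose(percent_composition(np.array([[3.0, 1, 0, 0]])),
                                   [[75, 25, 0, 0]])

    def test_percent_rows_sum_100(self):
        rng = np.random.default_rng(0)
        fmax = rng.uniform(0.1, 5.0, size=(30, 4))
        np.testing.assert_allclose(percent_composition(fmax).sum(axis=1),
                                   100.0, atol=1e-9)

    def test_zero_row_raises(self):
        with pytest.raises(UndefinedIndexError):
            percent_composition(np.array([[0.0, 0.0]]))


class TestClassification:
    @pytest.mark.parametrize("ex,em,label", [
        (275.0, 304.0, "tyrosine-like"),
        (280.0, 340.0, "tryptophan-like"),
        (250.0, 450.0, "terrestrial humic-like"),
        (310.0, 410.0, "microbial humic-like"),
        (np.nan, 400.0, "unclassified"),
    ])
    def test_rules(self, ex, em, label):
        assert classify_component(ex, em) == label

    def test_fingerprints_on_fit(self, rank3_dataset):
        ds, truth = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=1)
        fps = component_fingerprints(model)
        assert len(fps) == 3
        peaks = sorted((fp.ex_peak_nm, fp.em_peak_nm) for fp in fps)
        # true centers (260,330), (300,400), (350,470); peaks lie on the grid
        for (ex_peak, em_peak), (ex_true, em_true) in zip(
                peaks, [(260, 330), (300, 400), (350, 470)]):
            assert abs(ex_peak - ex_true) <= 10
            assert abs(em_peak - em_true) <= 8


class TestMatchReference:
    def test_self_library_perfect(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=1)
        library = [
            {"label": f"own{k}", "ex_nm": model.ex_nm,
             "ex_loading": model.ex_loadings[:, k],
             "em_nm": model.em_nm, "em_loading": model.em_loadings[:, k]}
            for k in range(3)
        ]
        result = match_reference(model, library)
        assert (result["congruence"] >= 1.0 - 1e-9).all()
        assert list(result["best_match"]) == ["own0", "own1", "own2"]

    def test_junk_library_poor(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=1)
        # spiky one-hot "spectra" share almost no mass with smooth loadings
        ex = model.ex_nm
        em = model.em_nm
        library = []
        for k in range(3):
            ex_l = np.zeros(ex.size)
            ex_l[k] = 1.0
            em_l = np.zeros(em.size)
            em_l[-(k + 1)] = 1.0
            library.append({"label": f"junk{k}", "ex_nm": ex, "ex_loading": ex_l,
                            "em_nm": em, "em_loading": em_l})
        result = match_reference(model, library)
        assert (result["congruence"] < 0.5).all()

    def test_resampled_copy_matches(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=1)
        fine_ex = np.arange(model.ex_nm[0], model.ex_nm[-1] + 0.5)
        fine_em = np.arange(model.em_nm[0], model.em_nm[-1] + 0.5)
        library = [{
            "label": "fine",
            "ex_nm": fine_ex,
            "ex_loading": np.interp(fine_ex, model.ex_nm, model.ex_loadings[:, 0]),
            "em_nm": fine_em,
            "em_loading": np.interp(fine_em, model.em_nm, model.em_loadings[:, 0]),
        }]
        result = match_reference(model, library)
        assert result.loc[0, "congruence"] >= 0.999

    def test_empty_library(self, rank3_dataset):
        ds, _ = rank3_dataset
        model = fit_parafac(ds, 3, n_starts=2, seed=1)
        with pytest.raises(FdomlinkError):
            match_reference(model, [])


def test_save_load_round_trip(tmp_path, rank3_dataset):
    ds, _ = rank3_dataset
    model = fit_parafac(ds, 3, n_starts=2, seed=1)
    save_model(model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    np.testing.assert_allclose(back.scores, model.scores)
    np.testing.assert_allclose(back.ex_loadings, model.ex_loadings)
    assert back.n_components == 3
    assert back.explained_variance == pytest.approx(model.explained_variance)
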
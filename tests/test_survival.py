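"""Cox pipeline stages, Harrell's c-index, and nested cross-validation."""

import numpy as np
import pytest
from sksurv.metrics import concordance_index_censored

from mamip.survival import (
    CohortFeatures,
    CVConfig,
    SurvivalRecord,
    concordance_index,
    drop_correlated,
    fit_cox,
    fit_pipeline,
    nested_cv,
    reduce_ica,
    scale_standard,
)


def make_features(matrix, prefix="f"):
    matrix = np.asarray(matrix, dtype=np.float64)
    return CohortFeatures(
        matrix,
        [f"{prefix}{j}" for j in range(matrix.shape[1])],
        [f"P{i}" for i in range(matrix.shape[0])],
    )


def make_records(time, event):
    return [
        SurvivalRecord(f"P{i}", float(t), bool(e)) for i, (t, e) in enumerate(zip(time, event))
    ]


def cox_cohort(n, beta, censor_frac, seed, d_noise=0):
    """Exponential-hazard cohort with one informative standardized feature.

    Features are unit-variance Laplace rather than Gaussian: the pipeline's
    ICA reduction requires non-Gaussian directions to exist, as they do for
    real pooled image features.
    """
    rng = np.random.default_rng(seed)
    x = rng.laplace(scale=1.0 / np.sqrt(2.0), size=(n, 1 + d_noise))
    lam = 0.1 * np.exp(beta * x[:, 0])
    t_event = rng.exponential(1.0 / lam)
    if censor_frac > 0:
        c = rng.exponential(1.0 / (0.1 * censor_frac / (1 - censor_frac)), size=n)
        time, event = np.minimum(t_event, c), t_event <= c
    else:
        time, event = t_event, np.ones(n, bool)
    return x, make_records(time, event)


class TestScaling:
    def test_train_equals_apply_standardizes(self):
        rng = np.random.default_rng(0)
        feats = make_features(rng.normal(2.0, 3.0, size=(50, 4)))
        out = scale_standard(feats, feats)
        np.testing.assert_allclose(out.matrix.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.matrix.std(axis=0), 1.0, atol=1e-6)

    def test_constant_feature_maps_to_zero(self):
        feats = make_features(np.full((10, 2), 7.0))
        out = scale_standard(feats, feats)
        np.testing.assert_array_equal(out.matrix, 0.0)

    def test_two_point_feature(self):
        feats = make_features(np.array([[0.0], [2.0]]))
        out = scale_standard(feats, feats)
        np.testing.assert_allclose(out.matrix.ravel(), [-1.0, 1.0])

    def test_train_statistics_applied_to_held_out(self):
        train = make_features(np.array([[0.0], [2.0]]))
        test = CohortFeatures(np.array([[4.0]]), ["f0"], ["Q0"])
        out = scale_standard(train, test)
        np.testing.assert_allclose(out.matrix.ravel(), [3.0])


class TestDropCorrelated:
    def test_duplicate_and_negated_columns_dropped(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 1))
        mat = np.hstack([base, rng.normal(size=(30, 1)), base.copy(), -base])
        kept = drop_correlated(make_features(mat), 0.95)
        np.testing.assert_array_equal(kept, [0, 1])

    def test_independent_features_all_kept(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            mat = rng.normal(size=(200, 12))
            kept = drop_correlated(make_features(mat), 0.95)
            np.testing.assert_array_equal(kept, np.arange(12))

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(2)
        mat = np.hstack([np.full((20, 1), 5.0), rng.normal(size=(20, 2))])
        kept = drop_correlated(make_features(mat), 0.95)
        np.testing.assert_array_equal(kept, [1, 2])


class TestReduceIca:
    def test_full_rank_transform_is_invertible(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 5))
        tr = reduce_ica(x, 5, seed=0)
        recon = tr.inverse(tr.apply(x))
        np.testing.assert_allclose(recon, x, atol=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 6))
        a = reduce_ica(x, 3, seed=9)
        b = reduce_ica(x, 3, seed=9)
        np.testing.assert_array_equal(a.ica.components_, b.ica.components_)
        assert a.seed_used == b.seed_used

    def test_planted_independent_sources_recovered(self):
        rng = np.random.default_rng(5)
        n = 500
        sources = np.column_stack(
            [rng.laplace(size=n), rng.uniform(-1, 1, size=n), rng.exponential(size=n)]
        )
        mixing = rng.normal(size=(3, 6))
        x = sources @ mixing
        tr = reduce_ica(x, 3, seed=0)
        est = tr.apply(x)
        corr = np.abs(np.corrcoef(sources.T, est.T)[:3, 3:])
        # each true source matches some estimated component up to sign
        assert np.all(corr.max(axis=1) >= 0.9)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            reduce_ica(np.zeros((10, 3)), 5, seed=0)


class TestFitCox:
    def test_perfectly_ordering_feature_gives_high_training_cindex(self):
        rng = np.random.default_rng(6)
        n = 50
        x = rng.normal(size=(n, 1))
        time = np.exp(-2.0 * x[:, 0]) * (1 + 0.01 * rng.random(n))  # monotone in -x
        records = make_records(time, np.ones(n, bool))
        model = fit_cox(x, records, penalty=0.1)
        assert concordance_index(records, model.risk(x)) >= 0.95
        assert model.coef[0] > 0

    def test_null_feature_gives_small_coefficient_and_chance_cindex(self):
        x, records = cox_cohort(200, beta=0.0, censor_frac=0.2, seed=7)
        x_test, records_test = cox_cohort(200, beta=0.0, censor_frac=0.2, seed=8)
        model = fit_cox(x, records, penalty=0.1)
        assert abs(model.coef[0]) < 0.2
        c = concordance_index(records_test, model.risk(x_test))
        assert 0.4 <= c <= 0.6

    def test_refit_is_identical(self):
        x, records = cox_cohort(80, beta=1.0, censor_frac=0.2, seed=9)
        a = fit_cox(x, records, penalty=0.5)
        b = fit_cox(x, records, penalty=0.5)
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_no_events_is_an_error(self):
        x = np.zeros((10, 1))
        records = make_records(np.arange(1, 11), np.zeros(10, bool))
        with pytest.raises(ValueError, match="no events"):
            fit_cox(x, records)


class TestConcordanceIndex:
    def test_perfect_and_uninformative_risks(self):
        records = make_records([5.0, 4.0, 3.0, 2.0, 1.0], [True] * 5)
        assert concordance_index(records, np.arange(5.0)) == 1.0
        assert concordance_index(records, np.zeros(5)) == 0.5

    def test_five_patient_mixed_censoring_hand_case(self):
        # exhaustively enumerated: comparable pairs and their contributions
        records = make_records([2.0, 1.0, 3.0, 2.0, 4.0], [True, False, True, True, False])
        risks = np.array([3.0, 1.0, 2.0, 3.0, 0.5])
        # comparable: (0,2)c=1, (0,4)c=1, (3,2)c=1, (3,4)c=1, (2,4)c=1,
        #             (0,1)? t0=2>t1=1, e1=False -> not; (1,*) censored first -> none
        #             (0,3) tied times both events -> not comparable
        expected = 5 / 5
        assert concordance_index(records, risks) == expected

    def test_matches_bruteforce_enumeration_and_sksurv(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            n = int(rng.integers(5, 60))
            time = rng.exponential(5.0, n).round(1) + 0.1  # induce ties
            event = rng.random(n) < 0.7
            risk = rng.normal(size=n).round(1)  # induce risk ties
            records = make_records(time, event)
            # O(n^2) oracle written independently of the implementation
            num = den = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    if (time[i] < time[j] and event[i]) or (
                        time[i] == time[j] and event[i] and not event[j]
                    ):
                        den += 1
                        if risk[i] > risk[j]:
                            num += 1
                        elif risk[i] == risk[j]:
                            num += 0.5
            if den == 0:
                continue
            got = concordance_index(records, risk)
            assert got == num / den
            sk = concordance_index_censored(event, time, risk)[0]
            assert got == pytest.approx(sk, abs=1e-12)

    def test_sign_flip_complements_cindex_without_ties(self):
        rng = np.random.default_rng(11)
        n = 40
        time = rng.exponential(5.0, n)
        event = rng.random(n) < 0.8
        risk = rng.normal(size=n)
        records = make_records(time, event)
        c = concordance_index(records, risk)
        assert concordance_index(records, -risk) == pytest.approx(1.0 - c, abs=1e-12)

    def test_no_comparable_pairs_is_an_error(self):
        records = make_records([1.0, 2.0], [False, False])
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(records, np.array([1.0, 2.0]))


QUICK_CV = dict(
    n_outer=5,
    n_repeats=1,
    n_inner=3,
    n_components_grid=(2,),
    penalty_grid=(0.1,),
)


class TestNestedCV:
    def test_same_seed_reproduces_result_exactly(self):
        x, records = cox_cohort(60, beta=1.0, censor_frac=0.2, seed=12, d_noise=4)
        feats = make_features(x)
        a = nested_cv(feats, records, CVConfig(seed=3, **QUICK_CV))
        b = nested_cv(feats, records, CVConfig(seed=3, **QUICK_CV))
        assert a.to_dict() == b.to_dict()

    def test_informative_feature_beats_chance(self):
        x, records = cox_cohort(120, beta=1.5, censor_frac=0.2, seed=13, d_noise=4)
        res = nested_cv(make_features(x), records, CVConfig(seed=4, **QUICK_CV))
        assert res.mean > 0.65
        assert not res.failures

    def test_summaries_recomputable_from_split_scores(self):
        x, records = cox_cohort(60, beta=0.5, censor_frac=0.2, seed=14, d_noise=2)
        res = nested_cv(make_features(x), records, CVConfig(seed=5, **QUICK_CV))
        assert res.mean == pytest.approx(np.mean(res.per_split_cindex))
        assert res.std == pytest.approx(np.std(res.per_split_cindex))
        # every outer split is either scored or recorded as a failure
        assert len(res.per_split_cindex) + len(res.failures) == 5

    def test_outer_fold_preprocessing_rederivable_from_training_data(self):
        """Leakage audit: refitting on the recorded outer-training indices
        with the recorded hyperparameters reproduces the applied transforms
        bit for bit."""
        x, records = cox_cohort(60, beta=1.0, censor_frac=0.2, seed=15, d_noise=3)
        feats = make_features(x)
        config = CVConfig(seed=6, **QUICK_CV)
        res = nested_cv(feats, records, config)
        for split in res.splits:
            tr = np.asarray(split["train_idx"])
            hp = split["hyperparams"]
            pipe = fit_pipeline(
                x[tr],
                [records[i] for i in tr],
                hp["corr_threshold"],
                hp["n_components"],
                hp["penalty"],
                seed=config.seed,
                cox_on_error=config.cox_on_error,
            )
            assert pipe.fingerprint() == split["pipeline_fingerprint"]

    def test_too_small_cohort_rejected(self):
        x, records = cox_cohort(20, beta=1.0, censor_frac=0.0, seed=16)
        with pytest.raises(ValueError, match="at least 25"):
            nested_cv(make_features(x), records, CVConfig(**QUICK_CV))
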
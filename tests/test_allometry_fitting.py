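"""Log-linear fitting, metrics, the staged candidate set and model ranking."""

import math

import numpy as np
import pytest

from raphia_allometry import (
    MetricSet,
    SimConfig,
    build_candidates,
    compute_metrics,
    correction_factor,
    fit_log_linear,
    fit_with_metrics,
    partial_f_test,
    rank_models,
    simulate_palm_dataset,
)
from raphia_allometry.data_model_io import PalmRecord
from raphia_allometry.errors import DomainError


def _records_from_arrays(sdp, h, td, agb):
    out = []
    for i, (s, hh, t, a) in enumerate(zip(sdp, h, td, agb)):
        npf = 4
        out.append(PalmRecord(
            palm_id=f"X{i}", class_label="2-4 cm", D=12.0, MDp=s / npf, SDp=s,
            H=hh, Npf=npf, TD=t, stem_kg=a, sheath_kg=0.0, petiole_kg=0.0,
            rachis_kg=0.0, leaflet_kg=0.0, agb_kg=a,
        ))
    return out


def _random_records(rng, n):
    sdp = rng.uniform(5, 120, n)
    h = rng.uniform(5, 20, n)
    td = rng.uniform(0.15, 0.38, n)
    agb = np.exp(-2.0 + 1.5 * np.log(sdp) + rng.normal(0, 0.3, n))
    return _records_from_arrays(sdp, h, td, agb)


def test_zero_noise_fit_recovers_generating_coefficients():
    rng = np.random.default_rng(0)
    sdp = rng.uniform(5, 120, 15)
    agb = np.exp(1.0 + 2.0 * np.log(sdp))
    fit = fit_log_linear(_records_from_arrays(sdp, [10] * 15, [0.2] * 15, agb), ["SDp"])
    assert fit.coefficients == pytest.approx((1.0, 2.0), abs=1e-10)
    assert fit.RSS == pytest.approx(0.0, abs=1e-18)


def test_two_point_fit_is_exact_with_zero_df():
    rng = np.random.default_rng(1)
    recs = _random_records(rng, 2)
    fit = fit_log_linear(recs, ["SDp"])
    assert fit.df == 0
    assert fit.RSS == pytest.approx(0.0, abs=1e-16)
    with pytest.raises(DomainError):
        compute_metrics(fit, recs)


def test_fit_matches_normal_equations_oracle():
    """OLS agrees with an independent X'X beta = X'y solve to 1e-8."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        n = int(rng.integers(6, 50))
        recs = _random_records(rng, n)
        preds = ["SDp", "H", "TD"][: int(rng.integers(1, 4))]
        fit = fit_log_linear(recs, preds)
        y = np.log([r.agb_kg for r in recs])
        X = np.column_stack(
            [np.ones(n)] + [np.log([r.predictor(p) for r in recs]) for p in preds])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, beta, atol=1e-8)
        assert fit.RSS == pytest.approx(float(np.sum((y - X @ beta) ** 2)), abs=1e-8)


def test_nonpositive_values_rejected():
    recs = _random_records(np.random.default_rng(3), 10)
    recs[0].TD = 0.0
    with pytest.raises(DomainError):
        fit_log_linear(recs, ["TD"])


def test_rank_deficient_design_rejected():
    recs = _random_records(np.random.default_rng(4), 10)
    for r in recs:
        r.H = r.SDp  # perfectly collinear on the log scale
    with pytest.raises(DomainError):
        fit_log_linear(recs, ["SDp", "H"])


def test_rescaling_predictor_shifts_only_intercept():
    """P -> kP changes the intercept by -b ln k; slope and RSE unchanged."""
    rng = np.random.default_rng(5)
    recs = _random_records(rng, 30)
    base = fit_with_metrics(recs, ["SDp"])
    k = 2.5
    scaled = [PalmRecord(**{**r.__dict__, "SDp": r.SDp * k, "MDp": r.MDp * k})
              for r in recs]
    refit = fit_with_metrics(scaled, ["SDp"])
    b = base.slopes[0]
    assert refit.slopes[0] == pytest.approx(b, abs=1e-10)
    assert refit.intercept == pytest.approx(base.intercept - b * math.log(k), abs=1e-10)
    assert refit.metrics.RSE == pytest.approx(base.metrics.RSE, abs=1e-12)
    assert refit.metrics.RMSE == pytest.approx(base.metrics.RMSE, abs=1e-8)


# ---------------------------------------------------------------------------
# metrics


def test_perfect_fit_metrics():
    rng = np.random.default_rng(6)
    sdp = rng.uniform(5, 120, 12)
    agb = np.exp(0.5 + 1.7 * np.log(sdp))
    recs = _records_from_arrays(sdp, [10] * 12, [0.2] * 12, agb)
    met = fit_with_metrics(recs, ["SDp"]).metrics
    assert met.R2adj == pytest.approx(1.0)
    assert met.RMSE == pytest.approx(0.0, abs=1e-9)
    assert met.BiasPct == pytest.approx(0.0, abs=1e-9)
    assert met.CF == pytest.approx(1.0)


def test_nested_model_never_increases_rss(palms):
    small = fit_log_linear(palms, ["SDp"])
    large = fit_log_linear(palms, ["SDp", "H"])
    largest = fit_log_linear(palms, ["SDp", "H", "TD"])
    assert largest.RSS <= large.RSS <= small.RSS


def test_aic_matches_direct_log_likelihood(palms):
    """AIC equals -2*(Gaussian log-likelihood at the MLE) + 2*(k+2)."""
    fit = fit_with_metrics(palms, ["SDp", "H"])
    n, k = fit.n, 3
    sigma2 = fit.RSS / n
    llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
    assert fit.metrics.AIC == pytest.approx(-2 * llf + 2 * (k + 1), rel=1e-12)


def test_r2adj_not_above_r2(palms):
    fit = fit_with_metrics(palms, ["SDp"])
    y = np.log([r.agb_kg for r in palms])
    r2 = 1 - fit.RSS / np.sum((y - y.mean()) ** 2)
    assert fit.metrics.R2adj <= r2


@pytest.mark.parametrize("rse, expected", [(0.0, 1.0), (0.21, 1.02), (1.15, 1.94)])
def test_correction_factor_values(rse, expected):
    assert round(correction_factor(rse), 2) == expected


def test_correction_factor_monotone_and_domain():
    grid = np.linspace(0, 2, 50)
    cfs = [correction_factor(r) for r in grid]
    assert cfs[0] == 1.0
    assert np.all(np.diff(cfs) > 0)
    with pytest.raises(DomainError):
        correction_factor(-0.1)


# ---------------------------------------------------------------------------
# partial F-test


def test_partial_f_zero_when_added_predictor_explains_nothing():
    from raphia_allometry import FitResult

    red = FitResult(predictors=("SDp",), coefficients=(0.1, 1.7),
                    residuals=np.zeros(10), RSS=2.0, df=8, n=10)
    full = FitResult(predictors=("SDp", "H"), coefficients=(0.1, 1.7, 0.0),
                     residuals=np.zeros(10), RSS=2.0, df=7, n=10)
    f, p = partial_f_test(red, full)
    assert (f, p) == (0.0, 1.0)


def test_partial_f_hand_worked_six_points():
    """F on a 6-point nested pair matches the direct formula evaluation."""
    rng = np.random.default_rng(8)
    recs = _random_records(rng, 6)
    red = fit_log_linear(recs, ["SDp"])
    full = fit_log_linear(recs, ["SDp", "H"])
    f, p = partial_f_test(red, full)
    f_direct = ((red.RSS - full.RSS) / 1) / (full.RSS / (6 - 3))
    assert f == pytest.approx(f_direct, rel=1e-12)
    from scipy import stats

    assert p == pytest.approx(float(stats.f.sf(f_direct, 1, 3)), rel=1e-12)


def test_partial_f_rejects_non_nested_pair(palms):
    a = fit_log_linear(palms, ["SDp"])
    b = fit_log_linear(palms, ["H", "TD"])
    with pytest.raises(DomainError):
        partial_f_test(a, b)


# ---------------------------------------------------------------------------
# candidate building and ranking


def test_staged_candidate_structure(palms):
    """6 singles; best-single (SDp) pairs; best-pair (SDp+H) triples."""
    cands = build_candidates(palms, mdp_min=2.0)
    by_stage = {}
    for spec, _ in cands:
        by_stage.setdefault(spec.stage, []).append(spec.predictors)
    assert len(by_stage[1]) == 6
    assert sorted(by_stage[2]) == sorted([("SDp", "H"), ("SDp", "TD"), ("SDp", "Npf")])
    assert sorted(by_stage[3]) == sorted([("SDp", "H", "TD"), ("SDp", "H", "Npf")])
    assert len(cands) == 11


def test_candidates_annotated_with_partial_f(palms):
    cands = build_candidates(palms, mdp_min=2.0)
    for spec, _ in cands:
        if spec.stage > 1:
            assert spec.partial_F is not None and 0 <= spec.partial_p <= 1


def test_empty_subset_rejected(palms):
    with pytest.raises(DomainError):
        build_candidates(palms, mdp_min=99.0)


def _published_metric_candidates(published_models, subset):
    return [
        (m, MetricSet(R2adj=m.metrics["R2adj"], RSE=m.RSE, AIC=m.metrics["AIC"],
                      RMSE=m.metrics["RMSE"], BiasPct=m.metrics["BiasPct"], CF=m.CF))
        for m in published_models if m.subset == subset
    ]


def test_ranking_published_full_subset_selects_m11(published_models):
    ranked = rank_models(_published_metric_candidates(published_models, "2-15 cm"))
    assert ranked[0][0].model_id == "m11"


def test_ranking_published_large_subset_selects_m18(published_models):
    ranked = rank_models(_published_metric_candidates(published_models, "5-15 cm"))
    assert ranked[0][0].model_id == "m18"


def test_ranking_single_candidate_is_itself(published_models):
    only = _published_metric_candidates(published_models, "2-15 cm")[:1]
    assert rank_models(only) == only


def test_parameter_recovery_at_large_n():
    """Bias of the recovered slopes shrinks toward zero for n = 5000."""
    cfg = SimConfig(seed=99, n_per_class=834)  # 5004 palms
    records, _ = simulate_palm_dataset(cfg)
    fit = fit_log_linear(records, ("SDp", "H", "TD"))
    truth = cfg.resolved_model()
    # 3 MC SEs using the asymptotic slope SE from the fit itself
    y = np.log([r.agb_kg for r in records])
    X = np.column_stack([np.ones(len(records))] + [
        np.log([r.predictor(p) for r in records]) for p in ("SDp", "H", "TD")])
    cov = fit.RSS / fit.df * np.linalg.inv(X.T @ X)
    for est, true, var in zip(fit.slopes, truth.slopes, np.diag(cov)[1:]):
        assert abs(est - true) < 3 * math.sqrt(var)
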
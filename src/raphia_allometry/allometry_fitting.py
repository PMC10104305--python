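"""Log-linear allometric model fitting, metrics and staged selection.

Models take the form ln(AGB) = a + b ln(P1) [+ c ln(P2) [+ d ln(P3)]] and
are fitted by ordinary least squares on natural logarithms. Candidate sets
are built in stages: all six single-predictor models first; then the best
single predictor combined with one predictor from each of the other two
parameter groups (coarseness D/MDp/SDp, height H, intrinsic TD/Npf); then
the best pair extended by the remaining group. A partial F-test annotates
whether each added predictor is statistically justified.

Back-transformed predictions exp(ln AGB_hat) systematically underestimate
the arithmetic mean under log-normal errors; the Baskerville correction
factor CF = exp(RSE^2/2) removes this, and the kg-scale error metrics
(RMSE, Bias%) are computed on CF-corrected predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .data_model_io import AllometricModel, PalmRecord
from .errors import DomainError

#: predictor parameter groups; multi-predictor models combine across groups
PARAMETER_GROUPS = {
    "coarseness": ("D", "MDp", "SDp"),
    "height": ("H",),
    "intrinsic": ("TD", "Npf"),
}


def group_of(predictor: str) -> str:
    for g, members in PARAMETER_GROUPS.items():
        if predictor in members:
            return g
    raise DomainError(f"unknown predictor {predictor!r}")


@dataclass
class MetricSet:
    """Performance metrics of one fitted allometric model.

    RSE is on the log scale; RMSE and BiasPct are on the kg scale with the
    correction factor applied; AIC uses the full Gaussian log-likelihood
    (the convention of mainstream statistical software, which yields the
    negative values seen for well-fitting log-scale models).
    """

    R2adj: float
    RSE: float
    AIC: float
    RMSE: float
    BiasPct: float
    CF: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R2adj": self.R2adj, "RSE": self.RSE, "AIC": self.AIC,
            "RMSE": self.RMSE, "BiasPct": self.BiasPct, "CF": self.CF,
        }


@dataclass
class FitResult:
    """OLS output on the log scale for one candidate model."""

    predictors: tuple[str, ...]
    coefficients: tuple[float, ...]  # intercept first, then one slope per predictor
    residuals: np.ndarray
    RSS: float
    df: int
    n: int
    metrics: MetricSet | None = None

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    @property
    def slopes(self) -> tuple[float, ...]:
        return tuple(self.coefficients[1:])


@dataclass
class CandidateSpec:
    """One entry of the staged candidate set."""

    predictors: tuple[str, ...]
    stage: int
    subset: str
    parent: tuple[str, ...] | None = None
    partial_F: float | None = None
    partial_p: float | None = None
    significant: bool | None = None


def _design(records: Sequence[PalmRecord], predictors: Sequence[str]):
    y = np.array([r.agb_kg for r in records], dtype=float)
    X = np.column_stack(
        [np.array([r.predictor(p) for r in records], dtype=float) for p in predictors]
    )
    if np.any(y <= 0) or np.any(X <= 0):
        raise DomainError("AGB and all predictors must be strictly positive to log")
    return np.log(y), np.log(X)


def fit_log_linear(records: Sequence[PalmRecord], predictors: Sequence[str]) -> FitResult:
    """Fit ln(AGB) on the natural logs of the named predictors by OLS."""
    predictors = tuple(predictors)
    k = len(predictors) + 1
    if len(records) <= len(predictors):
        raise DomainError(
            f"need more than {len(predictors)} observations for {predictors}"
        )
    ln_y, ln_X = _design(records, predictors)
    X = sm.add_constant(ln_X, has_constant="add")
    if np.linalg.matrix_rank(X) < k:
        raise DomainError(f"rank-deficient design for predictors {predictors}")
    res = sm.OLS(ln_y, X).fit()
    return FitResult(
        predictors=predictors,
        coefficients=tuple(float(b) for b in res.params),
        residuals=np.asarray(res.resid),
        RSS=float(res.ssr),
        df=len(records) - k,
        n=len(records),
    )


def correction_factor(rse: float) -> float:
    """Baskerville back-transformation correction CF = exp(RSE^2 / 2)."""
    if rse < 0:
        raise DomainError(f"RSE must be >= 0, got {rse}")
    return math.exp(rse**2 / 2.0)


def compute_metrics(fit: FitResult, records: Sequence[PalmRecord]) -> MetricSet:
    """Full metric set for a fit, evaluated on the records it was fitted to."""
    if fit.df <= 0:
        raise DomainError("zero residual degrees of freedom: metrics undefined")
    n, k = fit.n, len(fit.predictors) + 1
    rse = math.sqrt(fit.RSS / fit.df)
    cf = correction_factor(rse)

    ln_y, _ = _design(records, fit.predictors)
    tss = float(np.sum((ln_y - ln_y.mean()) ** 2))
    r2 = 1.0 - fit.RSS / tss if tss > 0 else 1.0
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / fit.df

    # Gaussian log-likelihood at the MLE sigma^2 = RSS/n; +1 free parameter
    # for sigma on top of the k regression coefficients.
    if fit.RSS > 0:
        llf = -0.5 * n * (math.log(2 * math.pi) + math.log(fit.RSS / n) + 1.0)
        aic = -2.0 * llf + 2.0 * (k + 1)
    else:
        aic = -math.inf

    obs = np.array([r.agb_kg for r in records], dtype=float)
    pred = cf * np.exp(ln_y - fit.residuals)  # fitted values, back-transformed
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    bias_pct = float(np.mean((pred - obs) / obs) * 100.0)
    return MetricSet(R2adj=r2adj, RSE=rse, AIC=aic, RMSE=rmse, BiasPct=bias_pct, CF=cf)


def fit_with_metrics(records: Sequence[PalmRecord], predictors: Sequence[str]) -> FitResult:
    fit = fit_log_linear(records, predictors)
    fit.metrics = compute_metrics(fit, records)
    return fit


def partial_f_test(reduced: FitResult, full: FitResult) -> tuple[float, float]:
    """Nested F-test for the predictors the full model adds over the reduced.

    F = ((RSS_red - RSS_full)/q) / (RSS_full/df_full), q = number of added
    predictors; p from the F(q, df_full) distribution.
    """
    if not set(reduced.predictors) < set(full.predictors):
        raise DomainError(
            f"{reduced.predictors} is not nested in {full.predictors}"
        )
    if reduced.n != full.n:
        raise DomainError("nested models must be fitted on the same records")
    q = len(full.predictors) - len(reduced.predictors)
    if full.RSS <= 0 or full.df <= 0:
        raise DomainError("full model has no residual variation")
    f_stat = ((reduced.RSS - full.RSS) / q) / (full.RSS / full.df)
    f_stat = max(f_stat, 0.0)
    from scipy import stats

    p = float(stats.f.sf(f_stat, q, full.df))
    return float(f_stat), p


def _rank_key(metrics: MetricSet, n_predictors: int):
    return (-metrics.R2adj, metrics.AIC, metrics.RSE, metrics.RMSE,
            abs(metrics.BiasPct), n_predictors)


def rank_models(
    candidates: Sequence[tuple[object, MetricSet]],
) -> list[tuple[object, MetricSet]]:
    """Rank candidates best-first: R2adj desc, then AIC, RSE, RMSE, |Bias%| asc.

    Ties break toward fewer predictors. Each candidate is (spec, metrics)
    where spec is anything exposing a ``predictors`` tuple (CandidateSpec,
    AllometricModel, FitResult).
    """
    if not candidates:
        raise DomainError("no candidates to rank")
    return sorted(
        candidates, key=lambda c: _rank_key(c[1], len(getattr(c[0], "predictors")))
    )


def filter_subset(records: Sequence[PalmRecord], mdp_min: float) -> list[PalmRecord]:
    """Restrict to palms with mean petiole diameter >= the threshold (cm)."""
    return [r for r in records if r.MDp >= mdp_min]


def build_candidates(
    records: Sequence[PalmRecord],
    mdp_min: float = 2.0,
    alpha: float = 0.05,
) -> list[tuple[CandidateSpec, FitResult]]:
    """Build and fit the staged candidate set on one size subset.

    Stage 1 fits all six single-predictor models; stage 2 pairs the best
    single predictor with every predictor from the other two parameter
    groups; stage 3 extends the best pair by each predictor of the
    remaining group. "Best" at each stage uses the same lexicographic
    criteria as :func:`rank_models`, restricted to that stage. Partial
    F-tests against the parent annotate (not veto) stages 2 and 3.
    """
    subset = filter_subset(records, mdp_min)
    if not subset:
        raise DomainError(f"no palms with MDp >= {mdp_min} cm")
    label = f">={mdp_min:g} cm"

    def fit_spec(spec: CandidateSpec, parent_fit: FitResult | None):
        fit = fit_with_metrics(subset, spec.predictors)
        if parent_fit is not None:
            spec.partial_F, spec.partial_p = partial_f_test(parent_fit, fit)
            spec.significant = spec.partial_p < alpha
        return spec, fit

    out: list[tuple[CandidateSpec, FitResult]] = []
    stage1 = [
        fit_spec(CandidateSpec((p,), 1, label), None)
        for members in PARAMETER_GROUPS.values() for p in members
    ]
    out.extend(stage1)
    best1 = min(stage1, key=lambda c: _rank_key(c[1].metrics, 1))
    p1 = best1[0].predictors[0]

    other_groups = [g for g in PARAMETER_GROUPS if g != group_of(p1)]
    stage2 = [
        fit_spec(CandidateSpec((p1, p2), 2, label, parent=(p1,)), best1[1])
        for g in other_groups for p2 in PARAMETER_GROUPS[g]
    ]
    out.extend(stage2)
    best2 = min(stage2, key=lambda c: _rank_key(c[1].metrics, 2))
    p2 = best2[0].predictors[1]

    last_group = [g for g in other_groups if g != group_of(p2)]
    stage3 = [
        fit_spec(CandidateSpec((p1, p2, p3), 3, label, parent=(p1, p2)), best2[1])
        for g in last_group for p3 in PARAMETER_GROUPS[g]
    ]
    out.extend(stage3)
    return out


def to_allometric_model(
    model_id: str, fit: FitResult, subset: str = ""
) -> AllometricModel:
    """Package a fit (with metrics) as an applicable AllometricModel."""
    if fit.metrics is None:
        raise DomainError("fit has no metrics; call fit_with_metrics")
    m = AllometricModel(
        model_id=model_id,
        predictors=fit.predictors,
        intercept=fit.intercept,
        slopes=fit.slopes,
        RSE=fit.metrics.RSE,
        CF=fit.metrics.CF,
        n=fit.n,
        subset=subset,
        metrics=fit.metrics.as_dict(),
    )
    m.validate()
    return m
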
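"""Binomial-logit turnover models with AICc multimodel inference.

For each species and each turnover process (colonization, survival) a
global generalized linear model (binomial error, logit link) over the
local and landscape covariates is expanded into all subsets, ranked by
AICc, reduced to the set within delta-AICc <= 2 of the best model, and
full-model-averaged (zero substitution) with unconditional standard
errors and per-term relative importance (RI = summed Akaike weights of
the top-set models containing the term).

Squared vegetation terms are screened beforehand: each vegetation
proportion is offered a quadratic companion, kept in the global model only
when the single-predictor AIC strictly decreases.  Subset enumeration
enforces marginality (a squared term never appears without its linear
term).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from .patch_io import TurnoverDataset

logger = logging.getLogger(__name__)

VEG_TERMS = ("veg_disturbed", "veg_undisturbed", "veg_mixed")


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected in a logistic fit."""


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of non-intercept terms; the intercept is implicit.

    A squared term ``<v>^2`` is only valid together with its linear term.
    """

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        for t in self.terms:
            if t.endswith("^2") and t[:-2] not in self.terms:
                raise ValueError(f"squared term {t} requires its linear term")

    @property
    def k(self) -> int:
        return len(self.terms) + 1  # + intercept

    def __str__(self) -> str:
        return " + ".join(("1",) + self.terms)


def design_matrix(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    cols = [np.ones(len(data))]
    for t in spec.terms:
        if t.endswith("^2"):
            cols.append(data[t[:-2]].to_numpy(dtype=float) ** 2)
        else:
            cols.append(data[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_logistic(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-8, maxiter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """ML logistic regression by IRLS; returns (coef, covariance, loglik).

    Quasi-complete separation (fitted probabilities collapsing to 0/1 at
    every event boundary, with exploding coefficients) is flagged with a
    :class:`SeparationWarning`; coefficients are still returned, with the
    inflated standard errors that separation produces.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n < k:
        raise ValueError(f"{n} rows < {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=maxiter, tol=tol)
        if not res.converged:
            raise RuntimeError(
                f"IRLS failed to converge in {maxiter} iterations "
                f"(deviance {res.deviance:.3g})"
            )
        coef = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        llf = float(res.llf)
    if y.min() == y.max() or np.abs(coef).max() > 15.0:
        warnings.warn(
            "possible (quasi-)complete separation: degenerate response or "
            "extreme coefficients; standard errors are unreliable",
            SeparationWarning,
            stacklevel=2,
        )
    return coef, cov, llf


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the small-sample correction 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"model too rich for sample: n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FittedModel:
    spec: ModelSpec
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    k: int
    n: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef_dict(self) -> dict[str, float]:
        names = ("intercept",) + self.spec.terms
        return dict(zip(names, self.coef))

    def var_dict(self) -> dict[str, float]:
        names = ("intercept",) + self.spec.terms
        return dict(zip(names, np.diag(self.cov)))


def fit_model(dataset: TurnoverDataset, spec: ModelSpec) -> FittedModel:
    y = dataset.data["y"].to_numpy(dtype=float)
    X = design_matrix(dataset.data, spec)
    coef, cov, ll = fit_logistic(y, X)
    k, n = spec.k, len(y)
    return FittedModel(spec=spec, coef=coef, cov=cov, loglik=ll, k=k, n=n, aicc=aicc(ll, k, n))


def screen_quadratic_terms(
    dataset: TurnoverDataset, vegetation_terms=VEG_TERMS
) -> list[str]:
    """Decide which squared vegetation terms enter the global model.

    For each vegetation proportion independently, a single-predictor model
    is compared with the same model plus the squared proportion; the
    squared term is retained iff plain AIC (no small-sample correction at
    this screening step) strictly decreases.  Returns the retained squared
    term names, e.g. ``["veg_mixed^2"]``.
    """
    retained = []
    y = dataset.data["y"].to_numpy(dtype=float)
    for term in vegetation_terms:
        try:
            lin = ModelSpec((term,))
            quad = ModelSpec((term, f"{term}^2"))
            _, _, ll_lin = fit_logistic(y, design_matrix(dataset.data, lin))
            _, _, ll_quad = fit_logistic(y, design_matrix(dataset.data, quad))
        except (ValueError, RuntimeError) as exc:
            logger.warning("quadratic screening skipped for %s: %s", term, exc)
            continue
        aic_lin = -2 * ll_lin + 2 * lin.k
        aic_quad = -2 * ll_quad + 2 * quad.k
        if aic_quad < aic_lin:
            retained.append(f"{term}^2")
    return retained


def all_subsets(global_spec: ModelSpec, max_terms: int = 12) -> list[ModelSpec]:
    """All marginality-respecting submodels of the global model.

    2^p specs for p plain terms; a squared term is only combined with its
    linear companion, which prunes the count accordingly.  Always includes
    the intercept-only model.
    """
    terms = global_spec.terms
    if len(terms) > max_terms:
        raise ValueError(f"global model has {len(terms)} terms > {max_terms} guard")
    specs = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            combo_set = set(combo)
            if any(t.endswith("^2") and t[:-2] not in combo_set for t in combo):
                continue
            specs.append(ModelSpec(tuple(t for t in terms if t in combo_set)))
    return specs


def rank_models(dataset: TurnoverDataset, specs: list[ModelSpec]) -> list[FittedModel]:
    """Fit every candidate and sort by AICc (ties: fewer terms, then spec order)."""
    fitted = []
    for spec in specs:
        try:
            fitted.append(fit_model(dataset, spec))
        except (ValueError, RuntimeError) as exc:
            logger.warning("model {%s} dropped: %s", spec, exc)
    if not fitted:
        raise RuntimeError("no candidate model could be fitted")
    fitted.sort(key=lambda m: (m.aicc, m.k, m.spec.terms))
    best = fitted[0].aicc
    for m in fitted:
        m.delta = m.aicc - best
    return fitted


def top_model_set(fitted: list[FittedModel], delta_max: float = 2.0) -> list[FittedModel]:
    """Models within delta-AICc <= 2 (inclusive), Akaike weights renormalized."""
    if not fitted:
        raise ValueError("no fitted models")
    best = min(m.aicc for m in fitted)
    top = sorted(
        (m for m in fitted if m.aicc - best <= delta_max),
        key=lambda m: (m.aicc, m.k, m.spec.terms),
    )
    raw = np.array([np.exp(-0.5 * (m.aicc - best)) for m in top])
    w = raw / raw.sum()
    for m, wi in zip(top, w):
        m.delta = m.aicc - best
        m.weight = float(wi)
    return top


@dataclass
class AveragedModel:
    """Full (zero-substitution) model average over a top model set.

    ``coef[t]`` is sum_m w_m * beta_mt with beta_mt = 0 when term t is
    absent from model m; ``se`` is the unconditional standard error
    (Burnham-Anderson), the CI a normal interval on it, and ``ri`` the
    relative importance.  ``significant[t]`` flags a 95% CI excluding 0.
    """

    terms: tuple[str, ...]
    coef: dict[str, float]
    se: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    ri: dict[str, float]
    significant: dict[str, bool]
    weights: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, covariates: pd.Series | dict) -> float:
        lp = self.coef["intercept"]
        for t in self.terms:
            if t == "intercept":
                continue
            base = t[:-2] if t.endswith("^2") else t
            if base not in covariates:
                raise KeyError(f"missing covariate {base!r} for term {t!r}")
            x = float(covariates[base])
            lp += self.coef[t] * (x**2 if t.endswith("^2") else x)
        return lp


def model_average(top: list[FittedModel], ci_level: float = 0.95) -> AveragedModel:
    """Average the top set; see :class:`AveragedModel` for the estimator."""
    if not top:
        raise ValueError("empty top set")
    wsum = sum(m.weight for m in top)
    if not np.isfinite(wsum) or abs(wsum - 1.0) > 1e-8:
        raise ValueError("top-set weights must sum to 1; call top_model_set first")
    all_terms: list[str] = ["intercept"]
    for m in top:
        for t in m.spec.terms:
            if t not in all_terms:
                all_terms.append(t)

    z = norm.ppf(0.5 + ci_level / 2)
    coef, se, lo, hi, ri, sig = {}, {}, {}, {}, {}, {}
    for t in all_terms:
        betas, vars_, present_w = [], [], 0.0
        for m in top:
            cd, vd = m.coef_dict(), m.var_dict()
            if t in cd:
                betas.append(cd[t])
                vars_.append(vd[t])
                present_w += m.weight
            else:
                betas.append(0.0)
                vars_.append(0.0)
        w = np.array([m.weight for m in top])
        b = np.array(betas)
        v = np.array(vars_)
        bbar = float(np.sum(w * b))
        # unconditional SE, zero substitution for absent models
        se_t = float(np.sum(w * np.sqrt(v + (b - bbar) ** 2)))
        coef[t] = bbar
        se[t] = se_t
        lo[t] = bbar - z * se_t
        hi[t] = bbar + z * se_t
        ri[t] = 1.0 if t == "intercept" else float(present_w)
        sig[t] = bool(lo[t] > 0 or hi[t] < 0)
    return AveragedModel(
        terms=tuple(all_terms),
        coef=coef,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        ri=ri,
        significant=sig,
        weights={str(m.spec): m.weight for m in top},
    )


def conditional_average(top: list[FittedModel], ci_level: float = 0.95) -> AveragedModel:
    """Natural (conditional) averaging: weights renormalized over the models
    containing each term.  Provided for comparison; the default pipeline
    uses :func:`model_average` (full averaging)."""
    avg = model_average(top, ci_level)
    z = norm.ppf(0.5 + ci_level / 2)
    for t in avg.terms:
        num, den, vnum = 0.0, 0.0, []
        for m in top:
            cd, vd = m.coef_dict(), m.var_dict()
            if t in cd:
                num += m.weight * cd[t]
                den += m.weight
                vnum.append((m.weight, cd[t], vd[t]))
        if den == 0:
            continue
        bbar = num / den
        se_t = sum(w * np.sqrt(v + (b - bbar) ** 2) for w, b, v in vnum) / den
        avg.coef[t] = bbar
        avg.se[t] = se_t
        avg.ci_lower[t] = bbar - z * se_t
        avg.ci_upper[t] = bbar + z * se_t
        avg.significant[t] = bool(avg.ci_lower[t] > 0 or avg.ci_upper[t] < 0)
    return avg


def predict_probability(avg: AveragedModel, covariates: pd.DataFrame) -> pd.Series:
    """Inverse-logit of the averaged linear predictor for every row.

    ``covariates`` is indexed by patch_id; every averaged non-intercept
    term must have its base covariate present.
    """
    out = {}
    for pid, row in covariates.iterrows():
        try:
            lp = avg.linear_predictor(row)
        except KeyError as exc:
            raise KeyError(f"patch {pid!r}: {exc.args[0]}") from None
        out[pid] = float(expit(lp))
    return pd.Series(out, name="probability")


def ranking_table(fitted: list[FittedModel]) -> pd.DataFrame:
    """Model-ranking report: spec, k, loglik, AICc, delta, weight."""
    return pd.DataFrame(
        [
            {
                "model": str(m.spec),
                "k": m.k,
                "loglik": m.loglik,
                "AICc": m.aicc,
                "delta": m.delta,
                "weight": m.weight,
            }
            for m in fitted
        ]
    )


def averaged_table(avg: AveragedModel) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": t,
                "estimate": avg.coef[t],
                "se": avg.se[t],
                "ci_lower": avg.ci_lower[t],
                "ci_upper": avg.ci_upper[t],
                "RI": avg.ri[t],
                "significant": avg.significant[t],
            }
            for t in avg.terms
        ]
    )
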
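"""Multi-PGS stacking models.

Four model kinds combine a standardized score library with covariates:

* ``covariates_only`` — unregularized GLM baseline (sex, age, PCs).
* ``lasso`` — L1-penalized regression over [covariates + scores] where
  covariates carry penalty factor 0 (never shrunk) and scores factor 1;
  the penalty level is chosen by internal cross-validation.
* ``xgboost`` — gradient-boosted trees (eta=0.01, nrounds=10 by default,
  the published configuration; config-exposed).
* ``mixed`` — lasso over [scores + an unpenalized boosted-tree risk score
  built from covariates only], capturing non-linear covariate effects
  (e.g. sex-by-age interactions) while keeping linear score weights.

``simplify_stack`` refits a lasso stack on the scores whose absolute weight
exceeds a threshold (0.01 by default), mirroring the simplified multi-PGS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._glmnet import EnetFit, cv_enet

__all__ = [
    "StackModel", "fit_covariate_base", "fit_lasso_stack", "fit_xgb_stack",
    "fit_mixed_stack", "simplify_stack",
]


@dataclass
class StackModel:
    """A fitted stacking model; predictions are pure functions of features."""

    kind: str                       # lasso | xgboost | mixed | covariates_only
    family: str                     # binomial | gaussian
    feature_names: list[str]
    intercept: float = 0.0
    coef: Optional[np.ndarray] = None          # linear kinds
    penalty_factors: Optional[np.ndarray] = None
    lambda_: Optional[float] = None
    booster: object = None                     # xgboost kinds
    stage1: Optional["StackModel"] = None      # mixed: covariate tree model
    flags: dict = field(default_factory=dict)
    seed: int = 0

    # ---- weights ----
    def score_weights(self, score_names: list[str]) -> pd.Series:
        """Per-score weights of a linear model (zero for absent scores)."""
        if self.coef is None:
            raise ValueError("score weights only defined for linear kinds")
        s = pd.Series(self.coef, index=self.feature_names)
        return s.reindex(score_names).fillna(0.0)

    def n_nonzero_scores(self, score_names: list[str]) -> int:
        return int((self.score_weights(score_names).abs() > 0).sum())

    # ---- prediction ----
    def predict(self, scores: pd.DataFrame | None, covariates: pd.DataFrame | None
                ) -> np.ndarray:
        """Risk score on the linear-predictor scale (margin for trees)."""
        feats = _assemble(scores, covariates)
        if self.kind == "mixed":
            stage1_score = self.stage1.predict(None, covariates)
            feats = feats.copy() if feats is not None else pd.DataFrame(
                index=np.arange(len(stage1_score)))
            feats["__stage1__"] = stage1_score
        if self.booster is not None and self.kind != "mixed":
            import xgboost as xgb

            X = feats[self.feature_names].to_numpy(dtype=np.float32)
            return self.booster.predict(xgb.DMatrix(X), output_margin=True)
        X = feats[self.feature_names].to_numpy(dtype=float)
        return self.intercept + X @ self.coef


def _assemble(scores, covariates) -> pd.DataFrame | None:
    parts = []
    if scores is not None:
        parts.append(pd.DataFrame(scores).reset_index(drop=True))
    if covariates is not None:
        parts.append(pd.DataFrame(covariates).reset_index(drop=True))
    if not parts:
        return None
    return pd.concat(parts, axis=1)


def _check_inputs(y, covariates):
    if covariates is not None and pd.DataFrame(covariates).isna().any().any():
        raise ValueError("missing covariate values are not allowed")
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing outcome values are not allowed")
    return y


def _infer_family(y, family):
    if family is not None:
        return family
    u = np.unique(y)
    return "binomial" if len(u) <= 2 and set(u) <= {0.0, 1.0} else "gaussian"


def fit_covariate_base(covariates: pd.DataFrame, y, family: str | None = None
                       ) -> StackModel:
    """Unregularized GLM on covariates only (logistic for binary outcomes).

    Perfect separation (or non-convergence) triggers a tiny-ridge refit,
    flagged in ``model.flags['ridge_fallback']``.
    """
    import statsmodels.api as sm

    y = _check_inputs(y, covariates)
    family = _infer_family(y, family)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    X = sm.add_constant(cov.to_numpy(dtype=float), has_constant="add")
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()

    flags = {}
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=fam).fit(maxiter=100)
        params = np.asarray(res.params)
        bad = not np.all(np.isfinite(params))
        if family == "binomial" and np.max(np.abs(params)) > 30:
            bad = True          # log-odds this extreme mean (near-)separation
        if bad:
            raise RuntimeError("separation suspected")
    except Exception:
        res = sm.GLM(y, X, family=fam).fit_regularized(alpha=1e-4, L1_wt=0.0)
        params = np.asarray(res.params)
        flags["ridge_fallback"] = True

    return StackModel(kind="covariates_only", family=family,
                      feature_names=list(cov.columns),
                      intercept=float(params[0]), coef=params[1:],
                      penalty_factors=np.zeros(cov.shape[1]), flags=flags)


def fit_lasso_stack(library: pd.DataFrame, covariates: pd.DataFrame | None, y,
                    family: str | None = None, alpha: float = 1.0,
                    inner_folds: int = 10, seed: int = 0,
                    n_lambda: int = 50) -> StackModel:
    """L1-penalized stack of scores (penalty 1) and covariates (penalty 0)."""
    y = _check_inputs(y, covariates)
    family = _infer_family(y, family)
    feats = _assemble(library, covariates)
    score_names = list(pd.DataFrame(library).columns)
    pf = np.array([1.0 if c in score_names else 0.0 for c in feats.columns])
    fit = cv_enet(feats.to_numpy(dtype=float), y, penalty=pf, alpha=alpha,
                  family=family, n_folds=inner_folds, seed=seed,
                  n_lambda=n_lambda)
    return StackModel(kind="lasso", family=family,
                      feature_names=list(feats.columns),
                      intercept=fit.intercept, coef=fit.coef,
                      penalty_factors=pf, lambda_=fit.lambda_, seed=seed)


def fit_xgb_stack(library: pd.DataFrame | None, covariates: pd.DataFrame | None, y,
                  family: str | None = None, eta: float = 0.01, nrounds: int = 10,
                  seed: int = 0, nthread: int = 1) -> StackModel:
    """Gradient-boosted trees over [scores + covariates]."""
    import xgboost as xgb

    y = _check_inputs(y, covariates)
    family = _infer_family(y, family)
    feats = _assemble(library, covariates)
    X = feats.to_numpy(dtype=np.float32)
    params = {
        "eta": eta,
        "objective": "binary:logistic" if family == "binomial" else "reg:squarederror",
        "seed": seed,
        "nthread": nthread,
    }
    booster = xgb.train(params, xgb.DMatrix(X, label=y), num_boost_round=nrounds)
    return StackModel(kind="xgboost", family=family,
                      feature_names=list(feats.columns), booster=booster,
                      seed=seed)


def fit_mixed_stack(library: pd.DataFrame, covariates: pd.DataFrame, y,
                    family: str | None = None, eta: float = 0.01,
                    nrounds: int = 10, inner_folds: int = 10, seed: int = 0,
                    n_lambda: int = 50) -> StackModel:
    """Lasso over scores plus an unpenalized boosted covariate risk score."""
    y = _check_inputs(y, covariates)
    family = _infer_family(y, family)
    stage1 = fit_xgb_stack(None, covariates, y, family=family, eta=eta,
                           nrounds=nrounds, seed=seed)
    s1 = stage1.predict(None, covariates)
    flags = {}
    lib = pd.DataFrame(library).reset_index(drop=True)
    if np.ptp(s1) < 1e-6:
        # degenerate stage-1 score: reduces to a score-only lasso
        flags["constant_stage1"] = True
        feats = lib
        pf = np.ones(feats.shape[1])
    else:
        feats = lib.copy()
        feats["__stage1__"] = s1
        pf = np.array([0.0 if c == "__stage1__" else 1.0 for c in feats.columns])
    fit = cv_enet(feats.to_numpy(dtype=float), y, penalty=pf, family=family,
                  n_folds=inner_folds, seed=seed, n_lambda=n_lambda)
    return StackModel(kind="mixed", family=family,
                      feature_names=list(feats.columns),
                      intercept=fit.intercept, coef=fit.coef,
                      penalty_factors=pf, lambda_=fit.lambda_, stage1=stage1,
                      flags=flags, seed=seed)


def simplify_stack(model: StackModel, library: pd.DataFrame,
                   covariates: pd.DataFrame | None, y, threshold: float = 0.01,
                   inner_folds: int = 10, seed: int = 0) -> StackModel:
    """Refit a lasso stack keeping only scores with |weight| > threshold."""
    if model.kind != "lasso":
        raise ValueError("simplify_stack requires a lasso stack")
    y = _check_inputs(y, covariates)
    score_names = list(pd.DataFrame(library).columns)
    w = model.score_weights(score_names)
    selected = list(w.index[w.abs() > threshold])
    if not selected:
        out = fit_covariate_base(covariates, y, family=model.family)
        out.flags["empty_selection"] = True
        return out
    sub = pd.DataFrame(library)[selected]
    out = fit_lasso_stack(sub, covariates, y, family=model.family,
                          inner_folds=inner_folds, seed=seed)
    out.flags["selected_scores"] = selected
    return out
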
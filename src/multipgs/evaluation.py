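"""Out-of-sample evaluation of stacked polygenic predictors.

Five-fold cross-validation with covariate-adjusted variance explained,
R2_adj = (R2_full - R2_cov) / (1 - R2_cov),
conversion of observed-scale R2 to the liability scale under case-control
ascertainment (population prevalence K, sample case proportion P), rank-based
AUC, risk-quintile odds ratios against the middle quintile, and percentile
bootstrap confidence intervals (10,000 resamples by default).

Observed-scale R2 for binary outcomes is always computed from a linear
regression of the 0/1 outcome on the risk score, as the liability conversion
requires, regardless of the loss the predictor was trained with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for
from .stacking import (StackModel, fit_covariate_base, fit_lasso_stack,
                       fit_mixed_stack, fit_xgb_stack)

__all__ = [
    "EvalReport", "make_folds", "adjusted_r2", "liability_r2", "quintile_or",
    "bootstrap_ci", "auc", "recode_case_case", "cv_evaluate",
]


# ---------------------------------------------------------------------------
# building blocks


def make_folds(n_ind: int, k: int = 5, seed: int = 0, y=None) -> np.ndarray:
    """Deterministic fold assignment; stratified by case status when y given."""
    if n_ind < k:
        raise ValueError("need at least k individuals")
    rng = rng_for(seed, "folds")
    fold = np.empty(n_ind, dtype=int)
    if y is not None:
        y = np.asarray(y)
        if set(np.unique(y)) <= {0, 1}:
            n_cases = int((y == 1).sum())
            if 0 < n_cases < k:
                raise ValueError("fewer cases than folds")
            for cls in np.unique(y):
                idx = np.flatnonzero(y == cls)
                rng.shuffle(idx)
                fold[idx] = np.arange(len(idx)) % k
            return fold
    perm = rng.permutation(n_ind)
    fold[perm] = np.arange(n_ind) % k
    return fold


def adjusted_r2(r2_full: float, r2_cov: float) -> float:
    """Variance explained beyond the covariates-only base model."""
    if r2_cov >= 1.0:
        raise ValueError("r2_cov = 1 leaves no residual variance to explain")
    r2_full = float(np.clip(r2_full, 0.0, 1.0))
    r2_cov = float(np.clip(r2_cov, 0.0, min(r2_full, 1.0)))
    return (r2_full - r2_cov) / (1.0 - r2_cov)


def liability_r2(r2_obs: float, K: float, P: float) -> float:
    """Convert observed-scale (linear-regression) R2 to the liability scale.

    Uses the ascertainment-corrected transformation for case-control data:
    with t = Phi^-1(1-K), z = phi(t), m = z/K,
    C = K^2 (1-K)^2 / (z^2 P (1-P)),
    theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t),
    r2_liab = C r2_obs / (1 + C theta r2_obs).
    """
    if not (0 < K < 1) or not (0 < P < 1):
        raise ValueError("K and P must lie in (0, 1)")
    t = stats.norm.ppf(1.0 - K)
    z = stats.norm.pdf(t)
    m = z / K
    C = K ** 2 * (1 - K) ** 2 / (z ** 2 * P * (1 - P))
    theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
    return C * r2_obs / (1.0 + C * theta * r2_obs)


def _r2_linear(y: np.ndarray, score: np.ndarray) -> float:
    """R2 of the univariate linear regression of y on score."""
    if np.std(score) < 1e-12 or np.std(y) < 1e-12:
        return 0.0
    r = np.corrcoef(y, score)[0, 1]
    return float(r * r)


def auc(risk_score, y) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve."""
    y = np.asarray(y)
    s = np.asarray(risk_score, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    n1 = int((y == 1).sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def quintile_or(risk_score, y, covariates: pd.DataFrame | None = None,
                reference: str = "middle") -> pd.DataFrame:
    """Log odds ratios of risk-score quintiles vs the middle quintile.

    Logistic regression of the outcome on quintile indicators plus
    covariates; quintile boundaries use the pooled out-of-sample scores with
    stable rank tie-breaking. A quintile with an empty case or control cell
    is flagged (log-OR infinite, SE undefined).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    s = np.asarray(risk_score, dtype=float)
    ranks = stats.rankdata(s, method="ordinal")
    q = np.minimum(((ranks - 1) * 5) // len(s), 4).astype(int)
    ref = 2 if reference == "middle" else int(reference)

    dummies = np.zeros((len(s), 4))
    others = [i for i in range(5) if i != ref]
    for col, qi in enumerate(others):
        dummies[:, col] = q == qi
    X = dummies
    names = [f"q{qi + 1}" for qi in others]
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = np.column_stack([X, cov.to_numpy(dtype=float)])
        names = names + list(cov.columns)
    X = sm.add_constant(X, has_constant="add")

    degenerate = []
    for qi in range(5):
        cell = y[q == qi]
        if cell.size == 0 or cell.min() == cell.max():
            degenerate.append(qi)
    rows = []
    if not degenerate:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params, bse = np.asarray(res.params), np.asarray(res.bse)
        for col, qi in enumerate(others):
            rows.append({"quintile": qi + 1, "log_or": float(params[col + 1]),
                         "se": float(bse[col + 1]), "degenerate": False})
    else:
        for col, qi in enumerate(others):
            bad = qi in degenerate or ref in degenerate
            rows.append({"quintile": qi + 1,
                         "log_or": np.inf if bad else np.nan,
                         "se": np.nan, "degenerate": bad})
    rows.append({"quintile": ref + 1, "log_or": 0.0, "se": 0.0,
                 "degenerate": ref in degenerate})
    return pd.DataFrame(rows).sort_values("quintile").reset_index(drop=True)


def bootstrap_ci(values: np.ndarray, stat_fn, B: int = 10_000, seed: int = 0
                 ) -> tuple[float, float, float]:
    """Percentile bootstrap over individuals: (point, lo95, hi95).

    ``values`` is an array (or tuple of aligned arrays) of per-individual
    contributions; ``stat_fn`` maps resampled contributions to a scalar.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    rng = rng_for(seed, "bootstrap")
    arrays = values if isinstance(values, tuple) else (values,)
    n = len(arrays[0])
    point = float(stat_fn(*arrays))
    out = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        out[b] = stat_fn(*(a[idx] for a in arrays))
    lo, hi = np.percentile(out, [2.5, 97.5])
    return point, float(lo), float(hi)


def recode_case_case(pheno_A, pheno_B) -> tuple[np.ndarray, np.ndarray]:
    """Case-case outcome: A-only -> 1, B-only -> 0; comorbid and unaffected
    individuals are masked out. Returns (y_cc over masked subset, mask)."""
    a = np.asarray(pheno_A).astype(int)
    b = np.asarray(pheno_B).astype(int)
    if a.shape != b.shape:
        raise ValueError("phenotypes must be aligned")
    mask = (a + b) == 1
    y = a[mask]
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("case-case recoding left a single class")
    return y, mask


# ---------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class EvalReport:
    """Per model: pooled out-of-sample statistics with bootstrap CIs."""

    models: dict[str, dict]
    fold_assignment: np.ndarray
    n: int
    n_cases: int | None
    K: float | None
    P: float | None
    predictions: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, st in self.models.items():
            for key, val in st.items():
                if key.startswith("_") or isinstance(val, (list, dict)):
                    continue
                rows.append({"model": model, "statistic": key, "value": val})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, list):
                return [clean(x) for x in v]
            return v
        return {
            "n": self.n, "n_cases": self.n_cases, "K": self.K, "P": self.P,
            "models": clean(self.models),
        }


_FITTERS = {
    "lasso": fit_lasso_stack,
    "xgboost": fit_xgb_stack,
    "mixed": fit_mixed_stack,
}


def _standardize_columns(train: pd.DataFrame, test: pd.DataFrame,
                         min_sd: float = 1e-8):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > min_sd
    tr = (train.loc[:, keep] - mu[keep]) / sd[keep]
    te = (test.loc[:, keep] - mu[keep]) / sd[keep]
    return tr, te


def cv_evaluate(library: pd.DataFrame, covariates: pd.DataFrame, y,
                model_kinds=("lasso",), K_prevalence: float | None = None,
                seed: int = 0, k_folds: int = 5, B: int = 10_000,
                extra_scores: dict[str, np.ndarray] | None = None,
                standardize: str = "per_fold",
                xgb_params: dict | None = None) -> EvalReport:
    """Five-fold out-of-sample evaluation of one or more stacking models.

    Library scores are (by default) standardized with training-fold
    parameters applied to the test fold (leakage-safe); ``standardize=
    'full_sample'`` reproduces whole-sample standardization instead.
    ``extra_scores`` are fixed per-individual risk scores (e.g. a single PGS
    or an index predictor) evaluated out-of-sample alongside the fitted
    models — each is combined with the base-model linear predictor trained
    per fold so its adjusted R2 is comparable.
    """
    lib = pd.DataFrame(library).reset_index(drop=True)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = len(y)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    fold = make_folds(n, k=k_folds, seed=seed, y=y if binary else None)
    family = "binomial" if binary else "gaussian"
    xgb_params = xgb_params or {}

    if standardize == "full_sample":
        mu, sd = lib.mean(axis=0), lib.std(axis=0, ddof=0)
        keep = sd > 1e-8
        lib_full = (lib.loc[:, keep] - mu[keep]) / sd[keep]

    preds: dict[str, np.ndarray] = {m: np.full(n, np.nan) for m in model_kinds}
    preds["covariates_only"] = np.full(n, np.nan)
    for name in (extra_scores or {}):
        preds[name] = np.asarray(extra_scores[name], dtype=float)

    for kf in range(k_folds):
        tr = fold != kf
        te = ~tr
        if standardize == "full_sample":
            lib_tr, lib_te = lib_full[tr], lib_full[te]
        else:
            lib_tr, lib_te = _standardize_columns(lib[tr], lib[te])
        cov_tr, cov_te = cov[tr].reset_index(drop=True), cov[te].reset_index(drop=True)
        lib_tr = lib_tr.reset_index(drop=True)
        lib_te = lib_te.reset_index(drop=True)

        base = fit_covariate_base(cov_tr, y[tr], family=family)
        preds["covariates_only"][te] = base.predict(None, cov_te)
        for kind in model_kinds:
            if kind == "covariates_only":
                continue
            fitter = _FITTERS[kind]
            kw = {"seed": seed + kf}
            if kind in ("xgboost",):
                kw.update(xgb_params)
            model = fitter(lib_tr, cov_tr, y[tr], family=family, **kw)
            preds[kind][te] = model.predict(lib_te, cov_te)

    P = float(y.mean()) if binary else None
    K = K_prevalence if K_prevalence is not None else P
    cov_pred = preds["covariates_only"]
    results: dict[str, dict] = {}
    for name, score in preds.items():
        st: dict = {}
        if name == "covariates_only":
            full_score = cov_pred
        elif name in (extra_scores or {}):
            # fixed external score: add to base-model linear predictor
            full_score = score / max(np.std(score), 1e-12) + cov_pred
        else:
            full_score = score

        def stat_adj(yb, fb, cb):
            return adjusted_r2(_r2_linear(yb, fb), _r2_linear(yb, cb))

        point, lo, hi = bootstrap_ci((y, full_score, cov_pred), stat_adj, B=B,
                                     seed=seed)
        st["r2_adj"] = point
        st["r2_adj_lo"], st["r2_adj_hi"] = lo, hi
        st["r2_full"] = _r2_linear(y, full_score)
        st["r2_cov"] = _r2_linear(y, cov_pred)
        if binary and K is not None:
            def stat_adj_liab(yb, fb, cb):
                Pb = yb.mean()
                if not (0 < Pb < 1):
                    return np.nan
                return adjusted_r2(
                    liability_r2(_r2_linear(yb, fb), K, Pb),
                    liability_r2(_r2_linear(yb, cb), K, Pb))

            point, lo, hi = bootstrap_ci((y, full_score, cov_pred),
                                         stat_adj_liab, B=B, seed=seed)
            st["r2_liab_adj"] = point
            st["r2_liab_adj_lo"], st["r2_liab_adj_hi"] = lo, hi
            st["auc"] = auc(full_score, y)
            qtab = quintile_or(full_score, y, covariates=cov)
            st["_quintile_or"] = qtab.to_dict(orient="records")
            top = qtab[qtab["quintile"] == 5].iloc[0]
            st["top_vs_middle_log_or"] = float(top["log_or"])
            st["top_vs_middle_log_or_se"] = float(top["se"])
        results[name] = st

    return EvalReport(models=results, fold_assignment=fold, n=n,
                      n_cases=int(y.sum()) if binary else None, K=K, P=P,
                      predictions=preds)
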
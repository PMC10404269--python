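"""Reference predictors the multi-PGS is benchmarked against.

* :func:`wmt_weights` / :func:`wmt_predict` — a multi-trait selection index
  over standardized per-trait scores (wMT-SBLUP-style): weights are a
  function of each auxiliary GWAS's sample size, SNP-heritability and its
  genetic correlation with the target, with no individual-level training.
* :func:`blup_pgs` — best linear unbiased prediction (ridge regression on
  standardized dosages) trained on the individual-level cohort itself, with
  out-of-fold scores.
* :func:`estimate_rg` — thin cross-trait LD-score-regression slope estimator
  of genetic correlation, for plug-in index weights.

The index derivation assumes standardized score i decomposes as
sqrt(r2_i/h2_i) * (standardized genetic value of trait i) + independent
noise, where r2_i = h2_i / (1 + M_e/(n_i h2_i)) is the expected phenotype
variance explained by score i; the index solves V w = c with
V_ij = corr(score_i, score_j) and c_i = cov(score_i, target liability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticParams", "wmt_weights", "wmt_predict", "blup_pgs",
           "estimate_rg", "expected_r2", "nearest_correlation"]

M_E_DEFAULT = 60_000  # effective number of independent markers (config-exposed)


@dataclass
class GeneticParams:
    """Per-trait genetic parameters feeding the selection index."""

    h2: np.ndarray            # per trait
    n_gwas: np.ndarray        # per trait
    rg: np.ndarray            # pairwise genetic correlations, unit diagonal
    m_eff: float = M_E_DEFAULT
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.h2 = np.asarray(self.h2, dtype=float)
        self.n_gwas = np.asarray(self.n_gwas, dtype=float)
        self.rg = np.asarray(self.rg, dtype=float)
        T = len(self.h2)
        if self.rg.shape != (T, T):
            raise ValueError("rg must be n_traits x n_traits")
        if not np.allclose(self.rg, self.rg.T, atol=1e-10) or \
                not np.allclose(np.diag(self.rg), 1.0):
            raise ValueError("rg must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(self.rg).min() < -1e-8:
            raise ValueError("rg is not positive semi-definite")
        if self.m_eff <= 0:
            raise ValueError("m_eff must be positive")


def nearest_correlation(rg: np.ndarray) -> np.ndarray:
    """Project a noisy symmetric matrix onto the PSD cone and rescale to
    unit diagonal (for plug-in genetic-correlation estimates)."""
    rg = (rg + rg.T) / 2.0
    vals, vecs = np.linalg.eigh(rg)
    if vals.min() >= 1e-8:
        return rg
    out = vecs @ np.diag(np.clip(vals, 1e-6, None)) @ vecs.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


def expected_r2(h2: float, n: float, m_eff: float) -> float:
    """Expected phenotype variance explained by a single-trait score:
    r2 = h2 / (1 + M_e / (n h2))."""
    if h2 <= 0:
        return 0.0
    return h2 / (1.0 + m_eff / (n * h2))


def wmt_weights(params: GeneticParams, target_trait: int
                ) -> tuple[np.ndarray, dict]:
    """Selection-index weights over standardized scores for a target trait.

    Returns (weights, audit) where audit records every intermediate
    (r2_i, the score-correlation matrix V, the covariance vector c). A
    singular V falls back to the pseudo-inverse, flagged in the audit.
    """
    h2, n, rg = params.h2, params.n_gwas, params.rg
    t = target_trait
    if h2[t] <= 0:
        raise ValueError("target trait must have h2 > 0")
    T = len(h2)
    r2 = np.array([expected_r2(h2[i], n[i], params.m_eff) for i in range(T)])
    # accuracy of score i for its own standardized genetic value
    acc = np.sqrt(np.divide(r2, h2, out=np.zeros(T), where=h2 > 0))

    V = np.outer(acc, acc) * rg
    np.fill_diagonal(V, 1.0)
    c = acc * rg[:, t] * np.sqrt(h2[t])

    audit = {"r2": r2, "accuracy": acc, "V": V, "c": c, "pseudo_inverse": False}
    try:
        w = np.linalg.solve(V, c)
    except np.linalg.LinAlgError:
        w = np.linalg.pinv(V) @ c
        audit["pseudo_inverse"] = True
    if not np.all(np.isfinite(w)):
        w = np.linalg.pinv(V) @ c
        audit["pseudo_inverse"] = True
    audit["weights"] = w
    return w, audit


def wmt_predict(scores, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of standardized library scores."""
    S = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if S.shape[1] != len(weights):
        raise ValueError("score matrix and weight vector disagree")
    return S @ weights


def estimate_rg(ss1, ss2, ld: np.ndarray, h2_1: float, h2_2: float,
                m_total: int | None = None) -> float:
    """Cross-trait LD-score regression (slope-only) genetic correlation.

    Regresses z1*z2 through the origin on LD scores (no sample overlap, so
    the product has no intercept term); the slope estimates
    sqrt(n1 n2) * cov_g / M, so cov_g = slope * M / sqrt(n1 n2) and
    rg = cov_g / sqrt(h2_1 h2_2), clipped to [-1, 1].
    """
    t1, t2 = ss1.table, ss2.table
    if "panel_index" in t1.columns and "panel_index" in t2.columns:
        merged = t1.merge(t2, on="panel_index", suffixes=("_1", "_2"))
        l = ld[merged["panel_index"].to_numpy()]
        z1 = merged["beta_1"].to_numpy() / merged["se_1"].to_numpy()
        z2 = merged["beta_2"].to_numpy() / merged["se_2"].to_numpy()
        n1 = float(np.median(merged["n_eff_1"]))
        n2 = float(np.median(merged["n_eff_2"]))
    else:
        if len(t1) != len(t2) or len(t1) != len(ld):
            raise ValueError("un-harmonized sumstats must cover the panel")
        l = ld
        z1, z2 = ss1.z(), ss2.z()
        n1 = float(np.median(t1["n_eff"]))
        n2 = float(np.median(t2["n_eff"]))
    M = m_total if m_total is not None else len(ld)
    slope = float(np.sum(l * z1 * z2) / np.sum(l ** 2))
    cov_g = slope * M / np.sqrt(n1 * n2)
    if h2_1 <= 0 or h2_2 <= 0:
        return 0.0
    return float(np.clip(cov_g / np.sqrt(h2_1 * h2_2), -1.0, 1.0))


def blup_pgs(dosages_std: np.ndarray, y, folds: np.ndarray,
             h2_hint: float | None = None, h2_grid=None, seed: int = 0
             ) -> tuple[np.ndarray, np.ndarray]:
    """BLUP (ridge) polygenic score with out-of-fold predictions.

    Model: y = X beta + e with beta ~ N(0, h2/M) on standardized dosages X,
    giving the ridge solution beta_hat = (X'X + lam I)^-1 X'y with
    lam = M (1-h2)/h2. Solved in the dual (n x n) form when n < M, the
    primal otherwise; ``h2_hint`` fixes the shrinkage, else a small grid is
    chosen by out-of-fold MSE inside each training split.

    Returns (out_of_fold_scores, variant_effects_from_full_training_data).
    """
    X = np.asarray(dosages_std, dtype=np.float64)
    y = np.asarray(y, dtype=float)
    n, M = X.shape
    folds = np.asarray(folds)
    if h2_grid is None:
        h2_grid = [0.05, 0.1, 0.2, 0.3, 0.5, 0.7]

    def ridge_beta(Xtr, ytr, h2):
        lam = M * (1.0 - h2) / max(h2, 1e-6)
        yc = ytr - ytr.mean()
        ntr = Xtr.shape[0]
        if ntr < M:
            K = Xtr @ Xtr.T
            alpha = np.linalg.solve(K + lam * np.eye(ntr), yc)
            return Xtr.T @ alpha
        A = Xtr.T @ Xtr + lam * np.eye(M)
        return np.linalg.solve(A, Xtr.T @ yc)

    def pick_h2(Xtr, ytr):
        if h2_hint is not None:
            return h2_hint
        rng = np.random.default_rng(seed)
        ntr = Xtr.shape[0]
        if ntr < 4:
            return 0.3
        hold = rng.permutation(ntr) % 4 == 0
        best, best_mse = h2_grid[0], np.inf
        for h2 in h2_grid:
            b = ridge_beta(Xtr[~hold], ytr[~hold], h2)
            pred = Xtr[hold] @ b
            mse = float(np.mean((ytr[hold] - ytr[~hold].mean() - pred) ** 2))
            if mse < best_mse:
                best, best_mse = h2, mse
        return best

    oof = np.full(n, np.nan)
    for kf in np.unique(folds):
        tr = folds != kf
        if tr.sum() < 2:
            raise ValueError("need at least 2 training individuals per fold")
        h2 = pick_h2(X[tr], y[tr])
        b = ridge_beta(X[tr], y[tr], h2)
        oof[folds == kf] = X[folds == kf] @ b

    h2_full = pick_h2(X, y)
    beta_full = ridge_beta(X, y, h2_full)
    return oof, beta_full
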
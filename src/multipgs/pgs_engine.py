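"""Posterior-mean polygenic score weights from summary statistics.

The core is a multi-chain spike-and-slab Gibbs sampler of the LDpred-auto
family operating on the standardized-genotype scale:

    beta_hat = R beta + e,   e ~ N(0, R / n)
    beta_j ~ p * N(0, h2/(M p)) + (1-p) * delta_0

Each chain starts from its own prior proportion of causal variants (a log-
spaced grid over [1e-4, 0.9]) and a common h2 initial value from LD-score
regression; (p, h2) are resampled inside the Gibbs sampler, so no tuning data
are needed. Divergent chains are discarded and the surviving chains averaged
after a predictive-scale filter.

Full-scale defaults follow the published configuration (30 chains, 800
burn-in, 400 kept iterations); desk-scale work uses 10/200/100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._rng import rng_for
from .sumstats_io import SumStats

__all__ = [
    "PGSWeights", "ld_scores", "ldsc_h2", "ldpred_auto", "filter_chains",
    "project", "NoConvergedChainsError",
]

FULL_SCALE = dict(n_chains=30, burn_in=800, n_iter=400)
DESK_SCALE = dict(n_chains=10, burn_in=200, n_iter=100)


class NoConvergedChainsError(RuntimeError):
    pass


@dataclass
class PGSWeights:
    """Per-variant posterior-mean effects plus chain diagnostics."""

    panel_index: np.ndarray          # panel positions of the modeled variants
    rsid: np.ndarray
    a1: np.ndarray
    chain_betas: np.ndarray          # n_chains x m, per-chain averaged effects
    p_trace: np.ndarray              # n_chains x n_iter
    h2_trace: np.ndarray             # n_chains x n_iter
    alive: np.ndarray                # chains that did not diverge
    kept: np.ndarray = None          # chains surviving the scale filter
    beta: np.ndarray = None          # final averaged standardized effects
    p_hat: float = np.nan
    h2_hat: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.panel_index)

    def beta_allelic(self, panel) -> np.ndarray:
        """Per-allele-count effects: beta_std / sd(genotype)."""
        sd = panel.sd[self.panel_index]
        return self.beta / sd


# ---------------------------------------------------------------------------
# LD scores and LD-score regression


def ld_scores(panel) -> np.ndarray:
    """Per-variant LD score l_j = sum_k r^2_jk within the variant's block."""
    out = np.empty(panel.m)
    for (start, stop), R in panel.blocks:
        out[start:stop] = (R ** 2).sum(axis=1)
    return out


def ldsc_h2(sumstats: SumStats, ld: np.ndarray, m_total: int | None = None,
            intercept: str = "fixed") -> tuple[float, dict]:
    """SNP-heritability by unweighted LD-score regression.

    Regresses chi2_j = z_j^2 on l_j; h2 = slope * M / n_eff with n_eff the
    median across variants. Clamped to [0.001, 1].

    By default the intercept is constrained to 1 (no confounding), which is
    the identifiable estimator when the LD-score range is narrow;
    ``intercept="free"`` estimates it. When the LD scores are (numerically)
    constant, falls back to the mean-chi-square estimator
    h2 = (mean chi2 - 1) * M / (n * mean l), flagged in the metadata.
    """
    tab = sumstats.table
    if len(tab) < 50:
        raise ValueError("need at least 50 variants for LD-score regression")
    if "panel_index" in tab.columns:
        l = ld[tab["panel_index"].to_numpy()]
    else:
        if len(tab) != len(ld):
            raise ValueError("un-harmonized sumstats must match panel size")
        l = ld
    z = sumstats.z()
    chi2 = z ** 2
    n = float(np.median(tab["n_eff"].to_numpy()))
    M = m_total if m_total is not None else len(ld)

    meta = {"n_eff": n, "M": M}
    if np.ptp(l) < 1e-9:
        h2 = (chi2.mean() - 1.0) * M / (n * l.mean())
        meta["fallback"] = "mean_chi2"
    elif intercept == "fixed":
        slope = float(np.sum(l * (chi2 - 1.0)) / np.sum(l ** 2))
        meta["intercept"] = 1.0
        h2 = slope * M / n
    else:
        X = np.column_stack([np.ones_like(l), l])
        coef, *_ = np.linalg.lstsq(X, chi2, rcond=None)
        meta["intercept"] = float(coef[0])
        h2 = coef[1] * M / n
    h2 = float(np.clip(h2, 0.001, 1.0))
    meta["h2"] = h2
    return h2, meta


# ---------------------------------------------------------------------------
# Gibbs sampler


@njit(cache=True)
def _gibbs_sweep(R, beta_hat, beta, Rbeta, n, s2, p, u, z, deterministic):
    """One sweep over a block; updates beta/Rbeta in place, returns #causal."""
    b = R.shape[0]
    k = 0
    for j in range(b):
        r = beta_hat[j] - Rbeta[j] + beta[j]
        v_post = 1.0 / (n[j] + 1.0 / s2)
        m_post = n[j] * r * v_post
        if p >= 1.0:
            pj = 1.0
        else:
            v0 = 1.0 / n[j]
            v1 = v0 + s2
            log_odds = (np.log(p) - np.log(1.0 - p)
                        + 0.5 * np.log(v0 / v1)
                        + 0.5 * r * r * (1.0 / v0 - 1.0 / v1))
            if log_odds > 35.0:
                pj = 1.0
            elif log_odds < -35.0:
                pj = 0.0
            else:
                pj = 1.0 / (1.0 + np.exp(-log_odds))
        new = 0.0
        if deterministic:
            # fixed-point iteration on the conditional posterior mean
            new = pj * m_post
            if pj >= 0.5:
                k += 1
        elif u[j] < pj:
            new = m_post + np.sqrt(v_post) * z[j]
            k += 1
        d = new - beta[j]
        if d != 0.0:
            beta[j] = new
            for i in range(b):
                Rbeta[i] += R[i, j] * d
    return k


def _run_chain(blocks, beta_hat, n_per, M, p0, h2_0, burn_in, n_iter, rng,
               p_fixed, h2_fixed, sample_effects, dead_threshold):
    beta = np.zeros(M)
    Rbeta = [np.zeros(stop - start) for (start, stop), _ in blocks]
    p = p0 if p_fixed is None else p_fixed
    h2 = h2_0 if h2_fixed is None else h2_fixed
    avg = np.zeros(M)
    p_tr = np.zeros(n_iter)
    h2_tr = np.zeros(n_iter)
    deterministic = not sample_effects
    dead = False
    for it in range(burn_in + n_iter):
        s2 = max(h2, 1e-4) / (M * p)
        k_tot = 0
        for bi, ((start, stop), R) in enumerate(blocks):
            b = stop - start
            if deterministic:
                u = np.zeros(b)
                z = np.zeros(b)
            else:
                u = rng.uniform(size=b)
                z = rng.standard_normal(b)
            k_tot += _gibbs_sweep(R, beta_hat[start:stop], beta[start:stop],
                                  Rbeta[bi], n_per[start:stop], s2, p, u, z,
                                  deterministic)
        h2_cur = 0.0
        for bi, ((start, stop), _) in enumerate(blocks):
            h2_cur += float(beta[start:stop] @ Rbeta[bi])
        if p_fixed is None:
            p = float(rng.beta(1 + k_tot, 1 + M - k_tot))
            p = min(max(p, 1e-5), 1.0)
        if h2_fixed is None:
            h2 = max(h2_cur, 1e-6)
        if h2_cur > dead_threshold:
            dead = True
            break
        if it >= burn_in:
            j = it - burn_in
            avg += beta
            p_tr[j] = p
            h2_tr[j] = h2_cur
    if not dead:
        avg /= n_iter
    return avg, p_tr, h2_tr, dead


def ldpred_auto(sumstats: SumStats, panel, n_chains: int = 30, burn_in: int = 800,
                n_iter: int = 400, p_init_grid=None, h2_init: float | None = None,
                seed: int = 0, p_fixed: float | None = None,
                h2_fixed: float | None = None, sample_effects: bool = True,
                dead_chain_factor: float = 3.0) -> PGSWeights:
    """Multi-chain spike-and-slab Gibbs shrinkage of marginal GWAS effects.

    ``p_fixed`` / ``h2_fixed`` pin the hyperparameters (used by exactness
    tests and the p=1 infinitesimal mode); ``sample_effects=False`` replaces
    each Gibbs draw with its conditional posterior mean, giving a
    deterministic fixed-point iteration.

    Chains whose realized genetic variance exceeds
    ``dead_chain_factor * max(h2_init, 0.05)`` are marked dead and excluded;
    if every chain dies a :class:`NoConvergedChainsError` is raised.
    """
    tab = sumstats.table
    if "panel_index" in tab.columns:
        pidx = tab["panel_index"].to_numpy()
    else:
        if len(tab) != panel.m:
            raise ValueError("un-harmonized sumstats must cover the panel")
        pidx = np.arange(panel.m)

    # restrict panel blocks to the modeled variants
    blocks = []
    for (start, stop), R in panel.blocks:
        inb = (pidx >= start) & (pidx < stop)
        if not inb.any():
            continue
        local = pidx[inb] - start
        blocks.append(((int(np.flatnonzero(inb)[0]), int(np.flatnonzero(inb)[-1] + 1)),
                       np.ascontiguousarray(R[np.ix_(local, local)])))
    M = len(pidx)
    beta_hat = sumstats.beta_std()
    n_per = tab["n_eff"].to_numpy().astype(float)

    if h2_init is None:
        if h2_fixed is not None:
            h2_init = h2_fixed
        else:
            ld = ld_scores(panel)
            h2_init, _ = ldsc_h2(sumstats, ld, m_total=M)
    if p_init_grid is None:
        p_init_grid = np.logspace(np.log10(1e-4), np.log10(0.9), n_chains)
    else:
        p_init_grid = np.asarray(p_init_grid, dtype=float)
        n_chains = len(p_init_grid)
    dead_threshold = dead_chain_factor * max(h2_init, 0.05)

    chain_betas = np.zeros((n_chains, M))
    p_trace = np.zeros((n_chains, n_iter))
    h2_trace = np.zeros((n_chains, n_iter))
    alive = np.ones(n_chains, dtype=bool)
    for c in range(n_chains):
        rng = rng_for(seed, f"ldpred:{c}")
        avg, p_tr, h2_tr, dead = _run_chain(
            blocks, beta_hat, n_per, M, p_init_grid[c], h2_init, burn_in,
            n_iter, rng, p_fixed, h2_fixed, sample_effects, dead_threshold)
        chain_betas[c] = avg
        p_trace[c] = p_tr
        h2_trace[c] = h2_tr
        alive[c] = not dead
    if not alive.any():
        raise NoConvergedChainsError("no_converged_chains")

    w = PGSWeights(
        panel_index=pidx, rsid=tab["rsid"].to_numpy(), a1=tab["a1"].to_numpy(),
        chain_betas=chain_betas, p_trace=p_trace, h2_trace=h2_trace, alive=alive,
        meta={"h2_init": h2_init, "seed": seed, "n_chains": n_chains,
              "burn_in": burn_in, "n_iter": n_iter,
              "source": sumstats.meta.get("trait"),
              "n_eff": float(np.median(n_per)), "variant_count": M},
    )
    return filter_chains(w)


def filter_chains(weights: PGSWeights, quantile: float = 0.95,
                  factor: float = 0.95) -> PGSWeights:
    """Keep chains whose predictive scale is near the best chains' scale.

    The scale of a chain is the standard deviation of its averaged effect
    vector; chains with scale >= factor * (the ``quantile`` quantile of the
    live chains' scales) are kept and averaged. If nothing passes, falls back
    to the single live chain with median h2, flagged in metadata.
    """
    live = np.flatnonzero(weights.alive)
    scales = weights.chain_betas[live].std(axis=1)
    cut = factor * np.quantile(scales, quantile)
    kept_live = live[scales >= cut]
    meta = dict(weights.meta)
    if len(kept_live) == 0:
        h2_means = weights.h2_trace[live].mean(axis=1)
        kept_live = live[[int(np.argsort(h2_means)[len(h2_means) // 2])]]
        meta["fallback_single_chain"] = True
    kept = np.zeros(len(weights.alive), dtype=bool)
    kept[kept_live] = True

    weights.kept = kept
    weights.beta = weights.chain_betas[kept].mean(axis=0)
    weights.p_hat = float(weights.p_trace[kept].mean())
    weights.h2_hat = float(weights.h2_trace[kept].mean())
    meta["kept_chains"] = int(kept.sum())
    weights.meta = meta
    return weights


# ---------------------------------------------------------------------------
# projection


def project(weights: PGSWeights, cohort) -> np.ndarray:
    """Project standardized-scale weights onto cohort dosages.

    score_i = sum_j beta_j (dosage_ij - 2 maf_j) / sd_j over the variant
    intersection; missing dosages (NaN) are mean-imputed.
    """
    if hasattr(cohort, "dosages"):
        dosages, maf = cohort.dosages, cohort.maf
    else:
        dosages, maf = cohort
    idx = weights.panel_index
    if len(idx) == 0:
        raise ValueError("no_overlap")
    D = np.asarray(dosages, dtype=np.float32)[:, idx]
    f = maf[idx].astype(np.float32)
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)
        nan_pos = np.where(np.isnan(D))
        D[nan_pos] = col_mean[nan_pos[1]]
    sd = np.sqrt(2 * f * (1 - f))
    Z = (D - 2 * f) / sd
    return (Z @ weights.beta.astype(np.float32)).astype(float)
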
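"""Synthetic LD panels, genetic architectures, GWAS summary statistics and cohorts.

This module generates every input a multi-PGS analysis needs, so that the whole
pipeline (QC -> shrinkage -> projection -> stacking -> evaluation) can be
exercised end-to-end without access-restricted data:

* :func:`simulate_panel` — a block-diagonal LD reference panel with AR(1)
  correlation inside blocks (a stand-in for published LD-block references).
* :func:`simulate_architecture` — genetically correlated multi-trait effect
  sizes under a spike-and-slab architecture (per-trait heritability h2,
  polygenicity p, genetic-correlation matrix rg).
* :func:`simulate_sumstats` — external GWAS marginal effects, either sampled
  directly from their asymptotic distribution ("direct" mode) or obtained by
  actually regressing a simulated external cohort ("cohort" mode).
* :func:`simulate_cohort` — individual-level dosages via a Gaussian-copula
  threshold model, liabilities, binary/continuous phenotypes, covariates
  (sex, age, PCs, optional sex-by-age interaction) and case oversampling.

All effects are drawn on the standardized-genotype scale; summary statistics
are emitted on the allele-count scale (as real GWAS files are), the conversion
being beta_allelic = beta_std / sd(genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for

__all__ = [
    "LDPanel",
    "TraitArchitecture",
    "CovariateModel",
    "CohortData",
    "simulate_panel",
    "simulate_architecture",
    "simulate_sumstats",
    "simulate_cohort",
]

# allele pairs that are unambiguous under strand flips
_NON_PALINDROMIC = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                    ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class LDPanel:
    """Block-diagonal LD reference panel.

    Attributes
    ----------
    variants : DataFrame with columns (id, chromosome, position, allele_ref,
        allele_alt, maf); maf is the frequency of allele_alt, in (0, 0.5].
    blocks : list of ((start, stop), R) where R is the correlation matrix of
        variants[start:stop]. The ranges partition the variant table.
    """

    variants: pd.DataFrame
    blocks: list[tuple[tuple[int, int], np.ndarray]]

    def __post_init__(self) -> None:
        stops = 0
        for (start, stop), R in self.blocks:
            if start != stops:
                raise ValueError("block ranges must partition the variant table")
            stops = stop
            b = stop - start
            if R.shape != (b, b):
                raise ValueError("block matrix shape mismatch")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError("block matrix not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-8):
                raise ValueError("block matrix must have unit diagonal")
        if stops != len(self.variants):
            raise ValueError("block ranges must cover all variants")
        maf = self.variants["maf"].to_numpy()
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def m(self) -> int:
        return len(self.variants)

    @property
    def maf(self) -> np.ndarray:
        return self.variants["maf"].to_numpy()

    @property
    def sd(self) -> np.ndarray:
        """Genotype standard deviation under Hardy-Weinberg, sqrt(2 maf (1-maf))."""
        f = self.maf
        return np.sqrt(2.0 * f * (1.0 - f))

    def block_slices(self) -> list[slice]:
        return [slice(start, stop) for (start, stop), _ in self.blocks]

    # --- persistence: TSV variant table (PLINK .bim-like columns) + npz blocks
    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(d / "variants.tsv", sep="\t", index=False)
        arrays = {f"block_{i}": R for i, ((_, _), R) in enumerate(self.blocks)}
        bounds = np.array([[s, e] for (s, e), _ in self.blocks], dtype=np.int64)
        np.savez(d / "blocks.npz", bounds=bounds, **arrays)

    @classmethod
    def load(cls, directory) -> "LDPanel":
        from pathlib import Path

        d = Path(directory)
        variants = pd.read_csv(d / "variants.tsv", sep="\t",
                               dtype={"id": str, "allele_ref": str, "allele_alt": str})
        with np.load(d / "blocks.npz") as z:
            bounds = z["bounds"]
            blocks = [((int(s), int(e)), z[f"block_{i}"])
                      for i, (s, e) in enumerate(bounds)]
        return cls(variants=variants, blocks=blocks)


@dataclass
class TraitArchitecture:
    """True standardized effect sizes for a set of genetically correlated traits."""

    n_traits: int
    h2: np.ndarray                 # per trait, in [0, 1]
    rg: np.ndarray                 # genetic-correlation matrix
    polygenicity: np.ndarray       # per trait, in (0, 1]
    beta_true: np.ndarray          # variants x traits, standardized scale
    causal: np.ndarray = field(repr=False, default=None)  # bool, variants x traits

    def genetic_variance(self, panel: LDPanel, trait: int) -> float:
        """beta' R beta accumulated over LD blocks."""
        b = self.beta_true[:, trait]
        total = 0.0
        for (start, stop), R in panel.blocks:
            seg = b[start:stop]
            if np.any(seg):
                total += float(seg @ R @ seg)
        return total


@dataclass
class CovariateModel:
    """Linear (plus one interaction) covariate effects on the liability scale.

    Coefficients apply to standardized covariates; ``var_explained`` is their
    total liability-variance share and must leave room for h2 + residual.
    """

    sex_beta: float = 0.0
    age_beta: float = 0.0
    sex_age_beta: float = 0.0     # non-linear sex-by-age interaction
    n_pcs: int = 20

    @property
    def any_effect(self) -> bool:
        return any(abs(v) > 0 for v in (self.sex_beta, self.age_beta, self.sex_age_beta))


@dataclass
class CohortData:
    """Individual-level target cohort: dosages, phenotypes, covariates."""

    dosages: np.ndarray            # individuals x variants, values in {0,1,2}
    phenotypes: pd.DataFrame       # binary columns trait{t}; continuous trait{t}_liab
    covariates: pd.DataFrame       # sex, age, PC1..PCk
    genetic_values: np.ndarray     # individuals x traits (standardized-scale truth)
    prevalence: dict[int, float]   # per binary trait, population K
    case_proportion: dict[int, float]  # per binary trait, observed P
    maf: np.ndarray                # panel maf for the dosage columns

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    def standardized_dosages(self) -> np.ndarray:
        """(dosage - 2 maf) / sqrt(2 maf (1-maf)), float32."""
        f = self.maf
        sd = np.sqrt(2.0 * f * (1.0 - f))
        return ((self.dosages.astype(np.float32) - 2.0 * f.astype(np.float32))
                / sd.astype(np.float32))


# ---------------------------------------------------------------------------
# panel


def simulate_panel(m_variants: int, block_size: int, rho: float = 0.5,
                   maf_range: tuple[float, float] = (0.01, 0.5),
                   seed: int = 0, ambiguous_fraction: float = 0.0) -> LDPanel:
    """Simulate an LD panel with AR(1) correlation rho^|i-j| inside blocks.

    Parameters
    ----------
    m_variants, block_size : total variant count and block length (the last
        block absorbs the remainder).
    rho : AR(1) decay, |rho| < 1; 0 gives independent variants.
    maf_range : minor-allele frequencies drawn uniformly from this interval.
    ambiguous_fraction : fraction of variants given strand-ambiguous (A/T,
        C/G) allele pairs, for exercising harmonization drop rules.
    """
    if not (m_variants >= block_size >= 1):
        raise ValueError("need m_variants >= block_size >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    rng = rng_for(seed, "panel")
    maf = rng.uniform(lo, hi, size=m_variants)

    n_amb = int(round(ambiguous_fraction * m_variants))
    amb_idx = rng.choice(m_variants, size=n_amb, replace=False) if n_amb else np.array([], int)
    pair_idx = rng.integers(0, len(_NON_PALINDROMIC), size=m_variants)
    alleles = [_NON_PALINDROMIC[i] for i in pair_idx]
    for i in amb_idx:
        alleles[i] = _PALINDROMIC[rng.integers(0, len(_PALINDROMIC))]

    variants = pd.DataFrame({
        "id": [f"rs{i + 1}" for i in range(m_variants)],
        "chromosome": np.ones(m_variants, dtype=int),
        "position": np.arange(1, m_variants + 1) * 1000,
        "allele_ref": [a[0] for a in alleles],
        "allele_alt": [a[1] for a in alleles],
        "maf": maf,
    })

    blocks = []
    start = 0
    while start < m_variants:
        stop = min(start + block_size, m_variants)
        if m_variants - stop < block_size:
            stop = m_variants
        b = stop - start
        idx = np.arange(b)
        R = rho ** np.abs(idx[:, None] - idx[None, :]) if rho != 0 else np.eye(b)
        # AR(1) correlation matrices are positive definite for |rho|<1
        assert np.linalg.eigvalsh(R).min() > -1e-10
        blocks.append(((start, stop), R))
        start = stop
    return LDPanel(variants=variants, blocks=blocks)


# ---------------------------------------------------------------------------
# architecture


def _as_vec(x, n: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim == 0:
        v = np.full(n, float(v))
    if v.shape != (n,):
        raise ValueError(f"{name} must be scalar or length-{n}")
    return v


def simulate_architecture(panel: LDPanel, n_traits: int, h2, rg=None,
                          polygenicity=0.01, seed: int = 0) -> TraitArchitecture:
    """Draw spike-and-slab causal effects, correlated across traits.

    Causal indicators are coupled across traits through a shared per-variant
    uniform (a variant causal for the sparser trait is causal for every denser
    trait), and causal effect sizes are jointly multivariate normal with
    correlation ``rg``; each trait's effects are rescaled so that its total
    genetic variance beta' R beta equals ``h2``.
    """
    h2 = _as_vec(h2, n_traits, "h2")
    poly = _as_vec(polygenicity, n_traits, "polygenicity")
    if np.any((h2 < 0) | (h2 > 1)):
        raise ValueError("h2 must lie in [0, 1]")
    if np.any((poly <= 0) | (poly > 1)):
        raise ValueError("polygenicity must lie in (0, 1]")
    if rg is None:
        rg = np.eye(n_traits)
    rg = np.asarray(rg, dtype=float)
    if rg.shape != (n_traits, n_traits):
        raise ValueError("rg must be n_traits x n_traits")
    if not np.allclose(rg, rg.T, atol=1e-10) or not np.allclose(np.diag(rg), 1.0):
        raise ValueError("rg must be symmetric with unit diagonal")
    eig = np.linalg.eigvalsh(rg)
    if eig.min() < -1e-8:
        raise ValueError("rg is not positive semi-definite")

    rng = rng_for(seed, "architecture")
    m = panel.m
    u = rng.uniform(size=m)
    causal = u[:, None] < poly[None, :]

    # correlated slab effects at (potentially shared) causal variants
    jitter = max(0.0, -float(eig.min())) + 1e-12
    L = np.linalg.cholesky(rg + jitter * np.eye(n_traits))
    z = rng.standard_normal((m, n_traits)) @ L.T
    beta = np.where(causal, z, 0.0)

    for t in range(n_traits):
        if h2[t] == 0 or not causal[:, t].any():
            beta[:, t] = 0.0
            continue
        var = 0.0
        for (start, stop), R in panel.blocks:
            seg = beta[start:stop, t]
            if np.any(seg):
                var += float(seg @ R @ seg)
        if var <= 0:
            raise ValueError("degenerate genetic variance; increase polygenicity")
        beta[:, t] *= np.sqrt(h2[t] / var)

    return TraitArchitecture(n_traits=n_traits, h2=h2, rg=rg, polygenicity=poly,
                             beta_true=beta, causal=causal)


# ---------------------------------------------------------------------------
# summary statistics


def _panel_cholesky(panel: LDPanel) -> list[np.ndarray]:
    chols = []
    for (_, _), R in panel.blocks:
        try:
            chols.append(np.linalg.cholesky(R))
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(R)
            chols.append(V * np.sqrt(np.clip(w, 0, None)))
    return chols


def _bvn_upper(h, k, r):
    """P(X > h, Y > k) for standard bivariate normal with correlation r,
    via Owen's T (vectorized, exact)."""
    from scipy.special import owens_t

    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    r = np.asarray(r, dtype=float)
    r = np.clip(r, -0.9999, 0.9999)
    s = np.sqrt(1.0 - r * r)
    eps = 1e-12
    hs = np.where(np.abs(h) < eps, eps, h)
    ks = np.where(np.abs(k) < eps, eps, k)
    ah = (ks - r * hs) / (hs * s)
    ak = (hs - r * ks) / (ks * s)
    cdf_h = stats.norm.cdf(h)
    cdf_k = stats.norm.cdf(k)
    delta = np.where((hs * ks < 0) | ((hs * ks == 0) & (hs + ks < 0)), 0.5, 0.0)
    phi2 = 0.5 * (cdf_h + cdf_k) - owens_t(hs, ah) - owens_t(ks, ak) - delta
    return 1.0 - cdf_h - cdf_k + phi2


def _latent_block(R: np.ndarray, maf: np.ndarray) -> np.ndarray:
    """Latent-Gaussian correlations whose thresholded alleles realize R.

    Solves the tetrachoric inversion pairwise by bisection so that the
    Bernoulli(maf) allele correlation equals the panel's analytic R; without
    this correction thresholding attenuates LD. Targets beyond the maximum
    achievable binary correlation are clamped.
    """
    b = R.shape[0]
    thr = stats.norm.ppf(1.0 - maf)
    iu = np.triu_indices(b, k=1)
    target = R[iu]
    ti, tj = thr[iu[0]], thr[iu[1]]
    pi, pj = maf[iu[0]], maf[iu[1]]
    denom = np.sqrt(pi * (1 - pi) * pj * (1 - pj))

    lo = np.full(target.shape, -0.9999)
    hi = np.full(target.shape, 0.9999)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        phi = (_bvn_upper(ti, tj, mid) - pi * pj) / denom
        too_low = phi < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    latent = 0.5 * (lo + hi)
    latent[target == 0.0] = 0.0

    out = np.eye(b)
    out[iu] = latent
    out[(iu[1], iu[0])] = latent
    # re-project to the PSD cone (pairwise inversion can break PSD slightly)
    w, V = np.linalg.eigh(out)
    if w.min() < 1e-8:
        out = V @ np.diag(np.clip(w, 1e-8, None)) @ V.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
    return out


_LATENT_CACHE: dict[bytes, np.ndarray] = {}


def _copula_dosages(panel: LDPanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-copula genotypes: two thresholded latent haplotypes per person.

    Latent correlations are tetrachorically corrected so the realized
    genotype correlations match the panel's analytic LD matrices.
    """
    m = panel.m
    thr = stats.norm.ppf(1.0 - panel.maf)
    out = np.zeros((n, m), dtype=np.int8)
    for (start, stop), R in panel.blocks:
        sl = slice(start, stop)
        maf = panel.maf[sl]
        key = R.tobytes() + maf.tobytes()
        latent = _LATENT_CACHE.get(key)
        if latent is None:
            latent = _latent_block(R, maf) if R.shape[0] > 1 and np.any(
                R[~np.eye(R.shape[0], dtype=bool)]) else R
            if len(_LATENT_CACHE) > 4096:
                _LATENT_CACHE.clear()
            _LATENT_CACHE[key] = latent
        try:
            L = np.linalg.cholesky(latent)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(latent)
            L = V * np.sqrt(np.clip(w, 0, None))
        for _hap in range(2):
            z = rng.standard_normal((n, stop - start)) @ L.T
            out[:, sl] += (z > thr[sl])
    return out


def simulate_sumstats(panel: LDPanel, architecture: TraitArchitecture, trait: int,
                      n_gwas: int, seed: int = 0, mode: str = "direct",
                      freq_noise: float = 0.005, n_cases: int | None = None,
                      n_controls: int | None = None, trait_label: str | None = None):
    """Simulate external GWAS summary statistics for one trait.

    ``direct`` mode samples marginal standardized effects from their sampling
    distribution, per block: beta_hat = R beta_true + e with e ~ MVN(0, R/n).
    ``cohort`` mode simulates an external cohort of size n_gwas and runs the
    per-variant marginal regressions (slow; used as the oracle for the direct
    mode). Output is on the allele-count scale with se = 1/(sd_j sqrt(n)).
    """
    from .sumstats_io import SumStats

    if not (0 <= trait < architecture.n_traits):
        raise IndexError(f"trait index {trait} out of range")
    if n_gwas < 30:
        raise ValueError("n_gwas must be >= 30")
    rng = rng_for(seed, f"sumstats:{trait}:{mode}")
    m = panel.m
    beta = architecture.beta_true[:, trait]

    if mode == "direct":
        beta_hat_std = np.empty(m)
        for L, ((start, stop), R) in zip(_panel_cholesky(panel), panel.blocks):
            sl = slice(start, stop)
            mean = R @ beta[sl]
            noise = L @ rng.standard_normal(stop - start) / np.sqrt(n_gwas)
            beta_hat_std[sl] = mean + noise
    elif mode == "cohort":
        X = _copula_dosages(panel, n_gwas, rng).astype(np.float32)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X /= sd
        h2 = architecture.h2[trait]
        g = X @ beta.astype(np.float32)
        vg = float(np.var(g))
        resid_var = max(1e-6, 1.0 - vg)
        y = g + rng.standard_normal(n_gwas).astype(np.float32) * np.sqrt(resid_var)
        y = (y - y.mean()) / y.std()
        beta_hat_std = (X.T @ y) / n_gwas
        beta_hat_std = beta_hat_std.astype(float)
    else:
        raise ValueError("mode must be 'direct' or 'cohort'")

    sd_ref = panel.sd
    freq = panel.maf + rng.normal(0.0, freq_noise, size=m) if freq_noise > 0 else panel.maf.copy()
    freq = np.clip(freq, 1e-3, 1 - 1e-3)

    se = 1.0 / (sd_ref * np.sqrt(n_gwas))
    df = pd.DataFrame({
        "rsid": panel.variants["id"].to_numpy(),
        "chr": panel.variants["chromosome"].to_numpy(),
        "pos": panel.variants["position"].to_numpy(),
        "a1": panel.variants["allele_alt"].to_numpy(),
        "a0": panel.variants["allele_ref"].to_numpy(),
        "beta": beta_hat_std / sd_ref,
        "se": se,
        "freq": freq,
        "n_eff": float(n_gwas),
    })
    meta = {"trait": trait_label or f"trait{trait}", "source": f"simulated:{mode}",
            "n_gwas": n_gwas, "seed": seed, "mode": mode}
    if n_cases is not None:
        meta["n_cases"] = n_cases
    if n_controls is not None:
        meta["n_controls"] = n_controls
    return SumStats(table=df, meta=meta)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(panel: LDPanel, architecture: TraitArchitecture, n_ind: int,
                    prevalence=0.1, ascertainment: str | None = None,
                    target_case_proportion: float | None = None,
                    ascertain_trait: int = 0,
                    covariate_model: CovariateModel | None = None,
                    seed: int = 0) -> CohortData:
    """Simulate an individual-level cohort under the liability-threshold model.

    Liability per trait = genetic value (standardized dosages x true effects)
    + covariate effects + Gaussian residual, scaled to unit variance; an
    individual is a case when liability exceeds the 1-K normal quantile.

    ``prevalence`` may be a scalar, a per-trait sequence, or contain None for
    traits to keep continuous (no thresholding). ``ascertainment`` of
    "case_oversample" keeps all cases of ``ascertain_trait`` and subsamples
    controls until the case fraction reaches ``target_case_proportion``
    (which therefore must exceed the prevalence); the returned cohort keeps
    n_ind individuals.
    """
    rng = rng_for(seed, "cohort")
    T = architecture.n_traits
    prev = list(prevalence) if isinstance(prevalence, (list, tuple, np.ndarray)) \
        else [prevalence] * T
    if len(prev) != T:
        raise ValueError("prevalence must be scalar or per-trait")
    for K in prev:
        if K is not None and not (0 < K < 1):
            raise ValueError("prevalence must lie in (0, 1)")
    if ascertainment not in (None, "none", "case_oversample"):
        raise ValueError("ascertainment must be None or 'case_oversample'")
    oversample = ascertainment == "case_oversample"
    if oversample:
        K0 = prev[ascertain_trait]
        if K0 is None:
            raise ValueError("cannot ascertain on a continuous trait")
        if target_case_proportion is None or not (0 < target_case_proportion < 1):
            raise ValueError("case_oversample requires target_case_proportion in (0,1)")
        if target_case_proportion < K0:
            raise ValueError(
                "target case proportion below prevalence requires case subsampling; "
                "not supported")

    cm = covariate_model or CovariateModel()
    # draw a raw pool large enough to satisfy ascertainment
    if oversample:
        K0 = prev[ascertain_trait]
        need = int(np.ceil(n_ind * target_case_proportion / K0 * 1.25)) + 500
    else:
        need = n_ind
    dos = _copula_dosages(panel, need, rng)
    f = panel.maf
    sd = np.sqrt(2 * f * (1 - f))
    X = (dos.astype(np.float32) - (2 * f).astype(np.float32)) / sd.astype(np.float32)
    G = X @ architecture.beta_true.astype(np.float32)        # need x T
    G = G.astype(float)

    sex = rng.integers(0, 2, size=need).astype(float)
    age = rng.uniform(10.0, 40.0, size=need)
    sex_s = (sex - 0.5) / 0.5
    age_s = (age - 25.0) / (30.0 / np.sqrt(12.0))
    pcs = rng.standard_normal((need, cm.n_pcs))

    cov_term = cm.sex_beta * sex_s + cm.age_beta * age_s + cm.sex_age_beta * sex_s * age_s
    var_cov = float(np.var(cov_term)) if cm.any_effect else 0.0

    liab = np.empty((need, T))
    for t in range(T):
        h2 = architecture.h2[t]
        resid = 1.0 - h2 - var_cov
        if resid < 0:
            raise ValueError("h2 + covariate variance exceeds 1")
        liab[:, t] = G[:, t] + cov_term + rng.standard_normal(need) * np.sqrt(resid)

    keep = np.arange(need)
    if oversample:
        K0 = prev[ascertain_trait]
        thr0 = stats.norm.ppf(1 - K0)
        is_case = liab[:, ascertain_trait] > thr0
        case_idx = np.flatnonzero(is_case)
        ctrl_idx = np.flatnonzero(~is_case)
        n_cases_target = int(round(n_ind * target_case_proportion))
        if len(case_idx) < n_cases_target:
            n_cases_target = len(case_idx)
        n_ctrl_target = n_ind - n_cases_target
        keep = np.concatenate([
            rng.choice(case_idx, size=n_cases_target, replace=False),
            rng.choice(ctrl_idx, size=n_ctrl_target, replace=False),
        ])
        keep = np.sort(keep)
    keep = keep[:n_ind]

    pheno = {}
    prevalence_out, case_prop = {}, {}
    for t in range(T):
        l = liab[keep, t]
        pheno[f"trait{t}_liab"] = l
        K = prev[t]
        if K is not None:
            y = (l > stats.norm.ppf(1 - K)).astype(int)
            pheno[f"trait{t}"] = y
            prevalence_out[t] = float(K)
            case_prop[t] = float(y.mean())
    covariates = pd.DataFrame({"sex": sex[keep], "age": age[keep]})
    for j in range(cm.n_pcs):
        covariates[f"PC{j + 1}"] = pcs[keep, j]

    return CohortData(
        dosages=dos[keep],
        phenotypes=pd.DataFrame(pheno),
        covariates=covariates,
        genetic_values=G[keep],
        prevalence=prevalence_out,
        case_proportion=case_prop,
        maf=f.copy(),
    )
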
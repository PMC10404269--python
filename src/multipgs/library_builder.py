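"""Assemble a standardized polygenic-score library from many GWAS files.

For each entry in a manifest (tag + summary-statistics file or in-memory
object): parse -> harmonize to the LD panel -> SD QC -> minimum-SNP gate ->
spike-and-slab Gibbs shrinkage -> chain filtering -> projection onto the
cohort. Failures at any stage are logged with a reason code and skipped, not
fatal. Surviving scores form an individuals x scores matrix with per-score
metadata and stage-by-stage survivor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pgs_engine, sumstats_io
from .sumstats_io import SumStats, SumstatsError

__all__ = ["ScoreLibrary", "LibraryConfig", "build_library", "exclude_scores"]


@dataclass
class LibraryConfig:
    """Per-file derivation settings used by :func:`build_library`."""

    n_chains: int = 10
    burn_in: int = 200
    n_iter: int = 100
    min_snps: int = 200_000          # the genome-scale gate; scale down for desk runs
    sd_thresholds: sumstats_io.SdQcThresholds = field(
        default_factory=sumstats_io.SdQcThresholds)
    seed: int = 0
    min_score_sd: float = 1e-8


@dataclass
class ScoreLibrary:
    """Individuals x scores matrix with per-score metadata.

    ``scores`` holds standardized columns (mean 0, variance 1 on the
    standardization subset recorded in ``standardization``); ``raw`` keeps
    the unstandardized projections so cross-validation folds can
    re-standardize leakage-free.
    """

    scores: pd.DataFrame
    raw: pd.DataFrame
    metadata: pd.DataFrame          # one row per retained score
    provenance: pd.DataFrame        # one row per manifest entry (incl. failures)
    standardization: dict = field(default_factory=dict)

    @property
    def n_scores(self) -> int:
        return self.scores.shape[1]

    @property
    def tags(self) -> list[str]:
        return list(self.scores.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.scores.reset_index(names="IID").melt(
            id_vars="IID", var_name="score_tag", value_name="value")
        return long

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "scores.npz", raw=self.raw.to_numpy(),
                 standardized=self.scores.to_numpy())
        self.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
        self.provenance.to_csv(d / "provenance.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory) -> "ScoreLibrary":
        d = Path(directory)
        metadata = pd.read_csv(d / "metadata.tsv", sep="\t")
        provenance = pd.read_csv(d / "provenance.tsv", sep="\t")
        with np.load(d / "scores.npz") as z:
            raw = pd.DataFrame(z["raw"], columns=metadata["tag"])
            scores = pd.DataFrame(z["standardized"], columns=metadata["tag"])
        return cls(scores=scores, raw=raw, metadata=metadata,
                   provenance=provenance)


def _load_entry(entry, column_map) -> SumStats:
    src = entry.get("sumstats")
    if isinstance(src, SumStats):
        return src
    path = entry.get("path", src)
    return sumstats_io.parse_sumstats(path, column_map=column_map,
                                      trait_label=entry["tag"],
                                      n_override=entry.get("n_eff"))


def build_library(manifest, panel, cohort, config: LibraryConfig | None = None,
                  column_map=None) -> ScoreLibrary:
    """Run QC + derivation + projection over a manifest of sumstats files.

    ``manifest`` is a DataFrame (or list of dicts) with at least a ``tag``
    column and either ``path`` (a file) or ``sumstats`` (an in-memory
    object). Column order of the library equals manifest order of passing
    files, and results are independent of execution order.
    """
    cfg = config or LibraryConfig()
    if isinstance(manifest, pd.DataFrame):
        entries = manifest.to_dict(orient="records")
    else:
        entries = [dict(e) for e in manifest]
    if not entries:
        raise ValueError("empty manifest")

    raw_cols: dict[str, np.ndarray] = {}
    meta_rows, prov_rows = [], []
    for i, entry in enumerate(entries):
        tag = entry["tag"]
        prov = {"tag": tag, "order": i, "status": "ok", "reason": "",
                "n_parsed": 0, "n_harmonized": 0, "n_after_sd_qc": 0}
        try:
            ss = _load_entry(entry, column_map)
            prov["n_parsed"] = ss.n_variants
            ss = sumstats_io.harmonize(ss, panel)
            prov["n_harmonized"] = ss.n_variants
            ss, _ = sumstats_io.sd_qc(ss, panel, cfg.sd_thresholds)
            prov["n_after_sd_qc"] = ss.n_variants
            if not sumstats_io.qc_gate(ss, cfg.min_snps):
                raise SumstatsError(
                    "qc_gate", f"{ss.n_variants} <= {cfg.min_snps} SNPs")
            weights = pgs_engine.ldpred_auto(
                ss, panel, n_chains=cfg.n_chains, burn_in=cfg.burn_in,
                n_iter=cfg.n_iter, seed=cfg.seed + i)
            score = pgs_engine.project(weights, cohort)
            sd = float(np.std(score))
            if sd < cfg.min_score_sd:
                raise SumstatsError("constant_score", "projected score is constant")
            raw_cols[tag] = score
            src = ss.meta.get("source") or Path(str(entry.get("path", ""))).name
            meta_rows.append({
                "tag": tag, "source": src,
                "n_eff": weights.meta.get("n_eff"),
                "p_hat": weights.p_hat, "h2_hat": weights.h2_hat,
                "variant_count": weights.m,
                "kept_chains": weights.meta.get("kept_chains"),
                "qc_status": "pass",
            })
        except (SumstatsError, pgs_engine.NoConvergedChainsError,
                FileNotFoundError, ValueError) as exc:
            prov["status"] = "failed"
            prov["reason"] = getattr(exc, "code", str(exc))
        prov_rows.append(prov)

    if not raw_cols:
        raise SumstatsError("empty_library", "no scores survived the pipeline")

    raw = pd.DataFrame(raw_cols)
    mu, sd = raw.mean(axis=0), raw.std(axis=0, ddof=0)
    scores = (raw - mu) / sd
    return ScoreLibrary(
        scores=scores, raw=raw,
        metadata=pd.DataFrame(meta_rows),
        provenance=pd.DataFrame(prov_rows),
        standardization={"subset": "all", "mean": mu.to_dict(), "sd": sd.to_dict()},
    )


def exclude_scores(library: ScoreLibrary, tags) -> ScoreLibrary:
    """Return a copy of the library with the given score tags removed."""
    tags = [tags] if isinstance(tags, str) else list(tags)
    missing = [t for t in tags if t not in library.tags]
    if missing:
        raise KeyError(
            f"tags not in library: {missing}; available: {library.tags}")
    keep = [t for t in library.tags if t not in tags]
    return ScoreLibrary(
        scores=library.scores[keep].copy(),
        raw=library.raw[keep].copy(),
        metadata=library.metadata[library.metadata["tag"].isin(keep)]
            .reset_index(drop=True),
        provenance=library.provenance.copy(),
        standardization=library.standardization,
    )
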
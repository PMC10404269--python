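"""Parsing, harmonization and QC of GWAS summary-statistics files.

Real GWAS files come with wildly heterogeneous headers; a column-name alias
library (shipped as editable YAML) maps them onto a canonical schema
(rsid, chr, pos, a1, a0, beta, se, freq, n_eff). Files reporting odds ratios
are converted with beta = ln(OR); Z-score-only files use beta = z * se.

Harmonization aligns each record to an LD reference panel (allele flips
negate beta; strand-ambiguous A/T and C/G variants are dropped), and the
standard-deviation QC drops variants whose summary-statistics-implied genotype
SD, sd_ss = 1/(se * sqrt(n_eff)), disagrees with the panel's Hardy-Weinberg
SD, sd_ref = sqrt(2 maf (1-maf)).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SumStats", "ColumnMap", "SumstatsError",
    "default_column_map", "parse_sumstats", "compute_n_eff",
    "harmonize", "sd_qc", "qc_gate", "write_sumstats", "SdQcThresholds",
]

CANONICAL_COLUMNS = ["rsid", "chr", "pos", "a1", "a0", "beta", "se", "freq", "n_eff"]
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Raised when a file cannot be parsed/harmonized; carries a reason code."""

    def __init__(self, code: str, message: str = ""):
        super().__init__(message or code)
        self.code = code


@dataclass
class SumStats:
    """Canonical per-variant marginal effects plus file-level metadata."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns
                   and c != "freq"]
        if missing:
            raise ValueError(f"missing canonical columns: {missing}")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def z(self) -> np.ndarray:
        return self.table["beta"].to_numpy() / self.table["se"].to_numpy()

    def beta_std(self) -> np.ndarray:
        """Marginal effects on the standardized-genotype scale, z / sqrt(n_eff)."""
        return self.z() / np.sqrt(self.table["n_eff"].to_numpy())


@dataclass
class ColumnMap:
    """Canonical field -> ordered list of accepted header aliases."""

    aliases: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for canon, names in self.aliases.items():
            for a in names:
                a = a.lower()
                if a in seen:
                    raise ValueError(
                        f"alias '{a}' assigned to both '{seen[a]}' and '{canon}'")
                seen[a] = canon
        self._lookup = seen

    def resolve(self, header: list[str]) -> dict[str, str]:
        """Map canonical field -> actual column name present in the header."""
        out: dict[str, str] = {}
        for col in header:
            key = col.lower().lstrip("#")
            canon = self._lookup.get(key)
            if canon is not None and canon not in out:
                out[canon] = col
        return out


def default_column_map() -> ColumnMap:
    ref = importlib.resources.files("multipgs") / "data" / "column_aliases.yaml"
    aliases = yaml.safe_load(ref.read_text())
    return ColumnMap(aliases=aliases)


def compute_n_eff(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case-control GWAS: 4 / (1/Ncas + 1/Ncon)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def _sniff_sep(path) -> str:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        line = fh.readline()
    if "\t" in line:
        return "\t"
    if "," in line and " " not in line.strip():
        return ","
    return r"\s+"


def parse_sumstats(path, column_map: ColumnMap | None = None,
                   n_override: float | None = None,
                   trait_label: str | None = None) -> SumStats:
    """Parse one delimited (optionally gzipped) GWAS file to canonical form.

    Effect-size resolution order: beta column; ln(OR); z * se. Files with no
    resolvable effect column raise ``SumstatsError('no_effect_column')``;
    files with zero parsable rows raise ``SumstatsError('empty_after_parse')``.
    Duplicate ids keep the smallest-SE record.
    """
    cmap = column_map or default_column_map()
    sep = _sniff_sep(path)
    if sep in ("\t", ","):
        raw = pd.read_csv(path, sep=sep, compression="infer",
                          float_precision="round_trip")
    else:
        raw = pd.read_csv(path, sep=sep, engine="python", compression="infer")
    found = cmap.resolve(list(raw.columns))

    dropped: dict[str, int] = {}
    n_in = len(raw)

    def col(name):
        return pd.to_numeric(raw[found[name]], errors="coerce") if name in found else None

    beta = col("beta")
    if beta is None:
        orr = col("odds_ratio")
        if orr is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                beta = np.log(orr)
    se = col("se")
    if beta is None:
        z = col("z")
        if z is not None and se is not None:
            beta = z * se
    if beta is None:
        raise SumstatsError("no_effect_column",
                            f"no beta/OR/Z column resolvable in {path}")
    if se is None:
        raise SumstatsError("no_se_column", f"no standard-error column in {path}")
    if "a1" not in found or "a0" not in found:
        raise SumstatsError("no_allele_columns", f"missing allele columns in {path}")

    out = pd.DataFrame({
        "rsid": raw[found["rsid"]].astype(str) if "rsid" in found else None,
        "chr": col("chr"),
        "pos": col("pos"),
        "a1": raw[found["a1"]].astype(str).str.upper(),
        "a0": raw[found["a0"]].astype(str).str.upper(),
        "beta": np.asarray(beta, dtype=float),
        "se": np.asarray(se, dtype=float),
    })
    out["freq"] = col("freq") if "freq" in found else np.nan

    n_eff = None
    if n_override is not None:
        n_eff = np.full(len(out), float(n_override))
    elif "n_cases" in found and "n_controls" in found:
        ncas, ncon = col("n_cases"), col("n_controls")
        with np.errstate(divide="ignore", invalid="ignore"):
            n_eff = 4.0 / (1.0 / ncas + 1.0 / ncon)
    elif "n" in found:
        n_eff = np.asarray(col("n"), dtype=float)
    if n_eff is None:
        raise SumstatsError("no_sample_size", f"no sample-size column in {path}")
    out["n_eff"] = n_eff

    ok = (np.isfinite(out["beta"]) & np.isfinite(out["se"]) & (out["se"] > 0)
          & np.isfinite(out["n_eff"]) & (out["n_eff"] > 0))
    dropped["bad_rows"] = int((~ok).sum())
    out = out[ok]

    if out["rsid"].isna().all():
        out = out.drop(columns="rsid")
        out["rsid"] = out["chr"].astype("Int64").astype(str) + ":" + \
            out["pos"].astype("Int64").astype(str)

    before = len(out)
    out = out.sort_values("se", kind="stable").drop_duplicates("rsid", keep="first")
    out = out.sort_index()
    dropped["duplicate_ids"] = before - len(out)

    if len(out) == 0:
        raise SumstatsError("empty_after_parse", f"no parsable rows in {path}")

    meta = {"path": str(path), "trait": trait_label, "n_rows_in": n_in,
            "dropped": dropped, "columns_found": found}
    return SumStats(table=out.reset_index(drop=True), meta=meta)


def harmonize(sumstats: SumStats, panel) -> SumStats:
    """Align records to the panel's (allele_alt, allele_ref) orientation.

    Matching is by variant id, with a chromosome+position+allele-pair
    fallback; allele swaps negate beta and complement frequencies; strand
    flips are recognized via base complements; A/T and C/G (strand-ambiguous)
    variants and unmatched variants are dropped. Harmonizing an already
    harmonized file is a no-op.
    """
    pv = panel.variants
    tab = sumstats.table.copy()

    panel_by_id = pd.Series(np.arange(len(pv)), index=pv["id"].to_numpy())
    idx = tab["rsid"].map(panel_by_id)
    if idx.isna().any() and tab["chr"].notna().any():
        key = pv["chromosome"].astype(str) + ":" + pv["position"].astype(str)
        panel_by_pos = pd.Series(np.arange(len(pv)), index=key.to_numpy())
        fb = (tab["chr"].astype("Int64").astype(str) + ":" +
              tab["pos"].astype("Int64").astype(str)).map(panel_by_pos)
        idx = idx.fillna(fb)

    counts = {"input": len(tab), "unmatched": int(idx.isna().sum())}
    tab = tab[idx.notna()].copy()
    pi = idx.dropna().astype(int).to_numpy()
    tab["panel_index"] = pi

    a1 = tab["a1"].to_numpy()
    a0 = tab["a0"].to_numpy()
    ambiguous = np.fromiter(((x, y) in _AMBIGUOUS for x, y in zip(a1, a0)),
                            dtype=bool, count=len(tab))
    counts["ambiguous_dropped"] = int(ambiguous.sum())
    tab = tab[~ambiguous]
    pi, a1, a0 = tab["panel_index"].to_numpy(), tab["a1"].to_numpy(), tab["a0"].to_numpy()

    p_alt = pv["allele_alt"].to_numpy()[pi]
    p_ref = pv["allele_ref"].to_numpy()[pi]
    comp = np.vectorize(_COMPLEMENT.get)

    same = (a1 == p_alt) & (a0 == p_ref)
    flipped = (a1 == p_ref) & (a0 == p_alt)
    if len(tab):
        c1, c0 = comp(a1), comp(a0)
        strand_same = (c1 == p_alt) & (c0 == p_ref) & ~same & ~flipped
        strand_flip = (c1 == p_ref) & (c0 == p_alt) & ~same & ~flipped
    else:
        strand_same = strand_flip = np.zeros(0, dtype=bool)
    match_any = same | flipped | strand_same | strand_flip
    counts["allele_mismatch_dropped"] = int((~match_any).sum())
    counts["flipped"] = int((flipped | strand_flip).sum())
    counts["strand_corrected"] = int((strand_same | strand_flip).sum())

    tab = tab[match_any].copy()
    do_flip = (flipped | strand_flip)[match_any]
    tab.loc[do_flip, "beta"] = -tab.loc[do_flip, "beta"]
    tab.loc[do_flip, "freq"] = 1.0 - tab.loc[do_flip, "freq"]
    pi = tab["panel_index"].to_numpy()
    tab["a1"] = pv["allele_alt"].to_numpy()[pi]
    tab["a0"] = pv["allele_ref"].to_numpy()[pi]
    tab["chr"] = pv["chromosome"].to_numpy()[pi]
    tab["pos"] = pv["position"].to_numpy()[pi]
    tab["rsid"] = pv["id"].to_numpy()[pi]

    tab = tab.sort_values("panel_index", kind="stable").reset_index(drop=True)
    counts["survivors"] = len(tab)
    if len(tab) < 1:
        raise SumstatsError("no_overlap", "no variants overlap the panel")

    meta = dict(sumstats.meta)
    meta["harmonization"] = counts
    meta["harmonized"] = True
    return SumStats(table=tab, meta=meta)


@dataclass
class SdQcThresholds:
    """Bounds for the sd_ss vs sd_ref discrepancy filter (LDpred2 QC practice)."""

    t_low: float = 0.5     # drop when sd_ss < t_low * sd_ref
    t_high: float = 1.1    # drop when sd_ss > t_high * sd_ref
    t_abs: float = 0.05    # drop when sd_ss below this absolute floor
    t_ref: float = 0.05    # drop when sd_ref below this absolute floor


def sd_qc(sumstats: SumStats, panel, thresholds: SdQcThresholds | None = None
          ) -> tuple[SumStats, pd.DataFrame]:
    """Drop variants whose summary-stats-implied SD disagrees with the panel.

    Returns the filtered SumStats and a diagnostics table (sd_ss, sd_ref,
    kept flag) backing the usual QC scatter plot.
    """
    th = thresholds or SdQcThresholds()
    tab = sumstats.table
    if "panel_index" not in tab.columns:
        raise ValueError("sd_qc requires harmonized sumstats (run harmonize first)")
    se = tab["se"].to_numpy()
    n_eff = tab["n_eff"].to_numpy()
    sd_ss = 1.0 / (se * np.sqrt(n_eff))

    # sd_ref comes from the genotype reference (panel maf); the reported
    # allele frequency is only a fallback for variants missing from it
    freq = tab["freq"].to_numpy().astype(float)
    maf_panel = panel.variants["maf"].to_numpy()[tab["panel_index"].to_numpy()]
    f = np.where(np.isfinite(maf_panel), maf_panel, freq)
    f = np.minimum(f, 1 - f)
    sd_ref = np.sqrt(2.0 * f * (1.0 - f))

    keep = ((sd_ss >= th.t_low * sd_ref) & (sd_ss <= th.t_high * sd_ref)
            & (sd_ss >= th.t_abs) & (sd_ref >= th.t_ref))
    diag = pd.DataFrame({"rsid": tab["rsid"], "sd_ss": sd_ss, "sd_ref": sd_ref,
                         "kept": keep})
    out = tab[keep].reset_index(drop=True)
    meta = dict(sumstats.meta)
    meta["sd_qc"] = {"input": len(tab), "dropped": int((~keep).sum()),
                     "survivors": len(out),
                     "thresholds": vars(th)}
    return SumStats(table=out, meta=meta), diag


def qc_gate(sumstats: SumStats, min_snps: int = 200_000) -> bool:
    """Pass iff strictly more than ``min_snps`` variants survived QC."""
    return sumstats.n_variants > min_snps


def write_sumstats(sumstats: SumStats, path) -> None:
    """Write canonical TSV with fixed column order (lossless round-trip)."""
    cols = [c for c in CANONICAL_COLUMNS if c in sumstats.table.columns]
    # default float formatting is the shortest round-trip repr: lossless
    sumstats.table[cols].to_csv(path, sep="\t", index=False)
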
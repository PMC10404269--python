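"""Minimal PLINK 1 bed/bim/fam export/import for simulated cohorts.

Covers only what the pipeline needs: SNP-major .bed (magic 0x6c 0x1b 0x01)
with hard-called dosages, the accompanying .bim/.fam text tables, and
phenotype/covariate TSVs keyed by FID/IID.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_plink", "read_bed", "write_pheno_covar"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 2-bit codes (for allele-1 counts): 00=2 copies A1, 01=missing,
# 10=1 copy, 11=0 copies. We store the ALT-allele dosage as allele 1.
_CODE_FOR_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FOR_CODE = {0b00: 2, 0b10: 1, 0b11: 0, 0b01: -1}


def write_plink(prefix, dosages: np.ndarray, variants: pd.DataFrame,
                iids=None) -> None:
    """Write dosages (individuals x variants, values in {0,1,2}) as bed/bim/fam."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = dosages.shape
    if len(variants) != m:
        raise ValueError("variant table must match dosage columns")
    iids = [f"ind{i + 1}" for i in range(n)] if iids is None else list(iids)

    bim = pd.DataFrame({
        "chrom": variants["chromosome"], "id": variants["id"],
        "cm": 0, "pos": variants["position"],
        "a1": variants["allele_alt"], "a2": variants["allele_ref"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({"fid": iids, "iid": iids, "father": 0, "mother": 0,
                        "sex": 0, "pheno": -9})
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    codes = np.empty_like(dosages, dtype=np.uint8)
    for d, c in _CODE_FOR_DOSAGE.items():
        codes[dosages == d] = c
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        buf = np.zeros(n_bytes, dtype=np.uint8)
        for j in range(m):
            buf[:] = 0
            col = codes[:, j]
            for off in range(4):
                seg = col[off::4]
                buf[:len(seg)] |= (seg << (2 * off)).astype(np.uint8)
            fh.write(buf.tobytes())


def read_bed(prefix) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a SNP-major .bed; returns (dosages with -1 for missing, bim, fam)."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"])
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _MAGIC:
        raise ValueError("not a SNP-major PLINK 1 .bed file")
    body = raw[3:].reshape(m, (n + 3) // 4)
    dosages = np.empty((n, m), dtype=np.int8)
    lut = np.array([_DOSAGE_FOR_CODE[c] for c in range(4)], dtype=np.int8)
    for off in range(4):
        vals = lut[(body >> (2 * off)) & 0b11]     # m x n_bytes
        idx = np.arange(off, n, 4)
        dosages[idx, :] = vals[:, :len(idx)].T
    return dosages, bim, fam


def write_pheno_covar(path, phenotypes: pd.DataFrame,
                      covariates: pd.DataFrame | None = None,
                      iids=None) -> None:
    """Phenotype/covariate TSV with leading FID and IID columns."""
    n = len(phenotypes)
    iids = [f"ind{i + 1}" for i in range(n)] if iids is None else list(iids)
    out = pd.DataFrame({"FID": iids, "IID": iids})
    out = pd.concat([out, phenotypes.reset_index(drop=True)], axis=1)
    if covariates is not None:
        out = pd.concat([out, covariates.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
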
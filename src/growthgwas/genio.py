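"""Dosage matrix I/O: VCF with a DS FORMAT field, or a plain TSV.

The VCF writer emits a minimal, valid VCFv4.2 with per-variant EAF and
imputation INFO in the INFO column and one DS (expected alternate-allele
dosage) value per sample; the effect allele is taken to be ALT.  Reading
goes through cyvcf2.  The TSV layout is variants in rows (snp, chrom,
pos, ea, nea, eaf, info) followed by one column per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_dosage_vcf", "read_dosage_vcf", "write_dosage_tsv", "read_dosage_tsv"]

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=EAF,Number=1,Type=Float,Description="Effect (ALT) allele frequency">
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated ALT allele dosage">
"""


def write_dosage_vcf(path, dosages: pd.DataFrame, variants: pd.DataFrame) -> None:
    """Write dosages (subjects x variants, iid index) as an uncompressed VCF."""
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for _, v in variants.iterrows():
            ds = dosages[v["snp"]].to_numpy(dtype=float)
            fields = [
                str(v["chrom"]),
                str(int(v["pos"])),
                str(v["snp"]),
                str(v["nea"]),  # REF = other allele
                str(v["ea"]),  # ALT = effect allele, dosage counts ALT
                ".",
                "PASS",
                f"EAF={v['eaf']:.6g};INFO={v.get('info', 1.0):.6g}",
                "DS",
            ]
            fh.write("\t".join(fields + [f"{d:g}" for d in ds]) + "\n")


def read_dosage_vcf(path):
    """Read a DS-format VCF; returns ``(dosages, variants)``."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    meta = []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        rows.append(ds)
        info = var.INFO.get("INFO")
        eaf = var.INFO.get("EAF")
        meta.append(
            {
                "snp": var.ID,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ea": var.ALT[0],
                "nea": var.REF,
                "eaf": float(eaf) if eaf is not None else float(np.mean(ds) / 2),
                "info": float(info) if info is not None else 1.0,
            }
        )
    variants = pd.DataFrame(meta)
    dosages = pd.DataFrame(
        np.asarray(rows).T,
        index=pd.Index(samples, name="iid"),
        columns=variants["snp"].tolist() if len(variants) else [],
    )
    return dosages, variants


def write_dosage_tsv(path, dosages: pd.DataFrame, variants: pd.DataFrame) -> None:
    """Variant metadata columns then one dosage column per subject."""
    wide = variants.set_index("snp").join(dosages.T)
    wide.reset_index().to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path):
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp", "chrom", "pos", "ea", "nea", "eaf", "info"]
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    dosages = df.drop(columns=meta_cols).T
    dosages.columns = variants["snp"].tolist()
    dosages.index.name = "iid"
    return dosages.astype(float), variants
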
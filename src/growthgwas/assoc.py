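"""Per-cohort GWAS of the estimated phenotypes and fixed-effects meta-analysis.

Each variant is tested with ordinary least squares of the phenotype on the
imputed allelic dosage (additive model) plus covariates (sex, ancestry
PCs, cohort-specific terms).  The dosage effect, its standard error and a
two-sided t p-value come from the Frisch-Waugh partialling identity, so
ten thousand variants cost one QR factorisation plus vectorised dot
products.  Cohort-level pre-filters, cross-cohort allele harmonisation,
inverse-variance-weighted fixed-effects meta-analysis with Cochran's Q /
I-squared, and post-meta filters with distance-based clumping complete the
summary-statistics pipeline.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "run_gwas",
    "cohort_filters",
    "harmonize",
    "ivw_meta",
    "post_meta_filters",
    "genomic_inflation",
]

ASSOC_COLUMNS = [
    "snp", "chrom", "pos", "ea", "nea", "eaf", "info", "n", "beta", "se", "p",
]


def run_gwas(
    phenotype: pd.Series,
    dosages: pd.DataFrame,
    variants: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive-dosage OLS association for one phenotype.

    ``phenotype`` and ``covariates`` are indexed by iid; ``dosages`` is
    subjects x variants with iid index; ``variants`` supplies snp, chrom,
    pos, ea, nea and (optionally) info.  Subjects are intersected across
    the three tables and rows with missing phenotype/covariates dropped —
    outlier-excluded subjects simply do not appear in ``phenotype``.
    Monomorphic dosage columns are emitted with a ``monomorphic`` flag and
    missing statistics so the pre-filters can count them.
    """
    ids = phenotype.dropna().index.intersection(dosages.index)
    if covariates is not None:
        cov = covariates.reindex(ids).dropna()
        ids = ids.intersection(cov.index)
    y = phenotype.reindex(ids).to_numpy(dtype=float)
    Gm = dosages.reindex(ids).to_numpy(dtype=float)
    n, m = Gm.shape
    if covariates is not None and covariates.shape[1]:
        C = np.column_stack([np.ones(n), covariates.reindex(ids).to_numpy(dtype=float)])
    else:
        C = np.ones((n, 1))
    k = C.shape[1]

    # residualise phenotype and dosages on covariates (Frisch-Waugh)
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = Gm - Q @ (Q.T @ Gm)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    gy = G_r.T @ y_r
    yy = float(y_r @ y_r)
    mono = gg <= 1e-12
    df = n - k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, gy / gg)
        rss = yy - beta**2 * gg
        se = np.sqrt(np.maximum(rss, 0.0) / df / gg)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    eaf = Gm.mean(axis=0) / 2.0

    out = variants.reset_index(drop=True).copy()
    if "info" not in out.columns:
        out["info"] = 1.0
    out = out[["snp", "chrom", "pos", "ea", "nea", "info"]].copy()
    out["eaf"] = eaf
    out["n"] = n
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["monomorphic"] = mono
    return out[ASSOC_COLUMNS + ["monomorphic"]]


_FILTER_RULES = (
    "monomorphic", "multiallelic_or_indel", "low_n", "low_mac", "large_effect", "low_info",
)


def cohort_filters(table: pd.DataFrame, min_n: int = 20) -> tuple[pd.DataFrame, pd.Series]:
    """Cohort-level pre-meta variant filters; returns (kept, ledger).

    Removes, in order (each removal attributed to the first rule it
    trips): monomorphic variants; multiallelic/indel records (allele
    strings longer than one base or non-ACGT); sample size below
    ``min_n``; minor allele count ``2*n*min(eaf, 1-eaf) <= 3``; extreme
    effects (|beta| >= 10 or se >= 10 phenotype units per allele,
    boundaries inclusive); imputation info < 0.4.  The ledger counts
    removals per rule.
    """
    df = table.reset_index(drop=True)
    ledger = pd.Series(0, index=list(_FILTER_RULES), dtype=int)
    removed = pd.Series(False, index=df.index)

    def trip(rule, mask):
        mask = mask.fillna(False) & ~removed
        ledger[rule] += int(mask.sum())
        return removed | mask

    snv = df["ea"].astype(str).str.fullmatch("[ACGT]") & df["nea"].astype(str).str.fullmatch("[ACGT]")
    mac = 2.0 * df["n"] * np.minimum(df["eaf"], 1.0 - df["eaf"])
    removed = trip("monomorphic", df.get("monomorphic", pd.Series(False, index=df.index)).astype(bool))
    removed = trip("multiallelic_or_indel", ~snv)
    removed = trip("low_n", df["n"] < min_n)
    removed = trip("low_mac", mac <= 3.0)
    removed = trip("large_effect", (df["beta"].abs() >= 10.0) | (df["se"] >= 10.0))
    removed = trip("low_info", df["info"] < 0.4)
    return df[~removed].reset_index(drop=True), ledger


def _variant_key(df: pd.DataFrame) -> pd.Series:
    chrom = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
    a = df[["ea", "nea"]].astype(str).apply(lambda r: ":".join(sorted(r)), axis=1)
    return chrom + ":" + df["pos"].astype(int).astype(str) + ":" + a


_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def harmonize(
    tables: dict[str, pd.DataFrame],
    ambiguous_eaf_window: float = 0.08,
    eaf_diff_flag: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Align effect alleles across cohorts to the first cohort's labelling.

    Variants are keyed by chrom:pos:sorted alleles.  Where a cohort
    reports the alleles swapped relative to the reference cohort, its beta
    sign and EAF are flipped.  Strand-ambiguous (A/T, C/G) variants whose
    EAF is within ``ambiguous_eaf_window`` of 0.5 in any cohort are
    dropped everywhere (strand cannot be resolved); irreconcilable allele
    pairs are dropped with a reason.  Cross-cohort EAF differences larger
    than ``eaf_diff_flag`` are flagged, not dropped.
    """
    names = list(tables)
    keyed = {}
    for name in names:
        df = tables[name].reset_index(drop=True).copy()
        df["_key"] = _variant_key(df)
        keyed[name] = df.set_index("_key", drop=True)
    ref = keyed[names[0]]

    drop: set[str] = set()
    for name in names:
        df = keyed[name]
        amb = df[["ea", "nea"]].apply(lambda r: frozenset(r) in _AMBIGUOUS, axis=1)
        near_half = (df["eaf"] - 0.5).abs() < ambiguous_eaf_window
        drop |= set(df.index[amb & near_half])

    out = {}
    for name in names:
        df = keyed[name].drop(index=drop & set(keyed[name].index)).copy()
        if name != names[0]:
            common = df.index.intersection(ref.index)
            df = df.loc[common]
            same = (df["ea"] == ref.loc[common, "ea"]) & (df["nea"] == ref.loc[common, "nea"])
            swapped = (df["ea"] == ref.loc[common, "nea"]) & (df["nea"] == ref.loc[common, "ea"])
            bad = ~(same | swapped)
            df = df[~bad]
            sw = swapped[~bad]
            df.loc[sw, "beta"] = -df.loc[sw, "beta"]
            df.loc[sw, "eaf"] = 1.0 - df.loc[sw, "eaf"]
            df.loc[sw, ["ea", "nea"]] = df.loc[sw, ["nea", "ea"]].to_numpy()
            df["eaf_discrepant"] = (df["eaf"] - ref["eaf"].reindex(df.index)).abs() > eaf_diff_flag
        else:
            df["eaf_discrepant"] = False
        out[name] = df.reset_index(drop=True)
    return out


def ivw_meta(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effects meta-analysis.

    Per variant: weights ``w_k = 1/se_k^2``, pooled beta the weighted
    mean, pooled se ``1/sqrt(sum w)``, two-sided normal p.  Heterogeneity:
    Cochran's ``Q = sum w_k (beta_k - beta)^2`` on K-1 df with its
    chi-square p, and ``I2 = max(0, (Q - df)/Q) * 100``.  The direction
    string has one +/-/? per cohort in input order.
    """
    names = list(tables)
    frames = []
    for name in names:
        df = tables[name].reset_index(drop=True).copy()
        df["_key"] = _variant_key(df)
        df["_cohort"] = name
        frames.append(df)
    allrows = pd.concat(frames, ignore_index=True)
    meta_rows = []
    for key, grp in allrows.groupby("_key", sort=True):
        grp = grp.set_index("_cohort")
        w = 1.0 / grp["se"] ** 2
        beta = float((w * grp["beta"]).sum() / w.sum())
        se = float(1.0 / math.sqrt(w.sum()))
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        q = float((w * (grp["beta"] - beta) ** 2).sum())
        k = len(grp)
        q_df = k - 1
        q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
        i2 = max(0.0, (q - q_df) / q) * 100.0 if q > 0 else 0.0
        direction = "".join(
            ("+" if grp.loc[c, "beta"] >= 0 else "-") if c in grp.index else "?"
            for c in names
        )
        first = grp.iloc[0]
        ntot = int(grp["n"].sum())
        meta_rows.append(
            {
                "snp": first["snp"],
                "chrom": first["chrom"],
                "pos": int(first["pos"]),
                "ea": first["ea"],
                "nea": first["nea"],
                "eaf": float((grp["eaf"] * grp["n"]).sum() / grp["n"].sum()),
                "info": float(grp["info"].min()),
                "n": ntot,
                "beta": beta,
                "se": se,
                "p": float(p),
                "n_cohorts": k,
                "direction": direction,
                "q_stat": q,
                "q_df": q_df,
                "q_p": q_p,
                "i2": float(i2),
            }
        )
    return pd.DataFrame(meta_rows)


def post_meta_filters(
    meta: pd.DataFrame,
    total_cohorts: int,
    maf_min: float = 0.005,
    sig: float = 5e-8,
    clump_kb: float = 500.0,
):
    """Post-meta filters and genome-wide hits with distance clumping.

    Drops variants present in fewer than ``ceil(total_cohorts / 2)``
    cohorts or with meta MAF below ``maf_min``; hits are ``p < sig``;
    clump leads are the best-p hit per +/- ``clump_kb`` kb window per
    chromosome.  Returns ``(filtered table, hits, clump leads)``.
    """
    need = math.ceil(total_cohorts / 2)
    maf = np.minimum(meta["eaf"], 1.0 - meta["eaf"])
    kept = meta[(meta["n_cohorts"] >= need) & (maf >= maf_min)].reset_index(drop=True)
    hits = kept[kept["p"] < sig].reset_index(drop=True)
    leads = []
    for _, sub in hits.groupby("chrom", sort=True):
        sub = sub.sort_values("p", kind="stable")
        taken: list[int] = []
        for _, row in sub.iterrows():
            if all(abs(row["pos"] - t) > clump_kb * 1000 for t in taken):
                taken.append(row["pos"])
                leads.append(row)
    leads_df = (
        pd.DataFrame(leads).reset_index(drop=True) if leads else hits.iloc[0:0].copy()
    )
    return kept, hits, leads_df


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median association chi-square over 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))
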
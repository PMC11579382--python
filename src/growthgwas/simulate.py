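"""Synthetic longitudinal growth cohorts with known ground truth.

Generates cohorts with the structure the trajectory framework assumes:
a sex-specific spline mean curve for log BMI, multivariate-normal subject
random effects, optionally CAR(1)-correlated residuals, SNP dosages whose
effects act additively on named random-effect coefficients, and a
configurable menu of planted data errors (unit switches, duplicates,
carried-forward values, height drops, gross outliers) with a fault ledger
so QC sensitivity can be scored exactly.

Weight/height pairs are back-derived from the simulated log BMI so that
``weight / height**2`` reproduces ``exp(log_bmi)`` to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lmm import car1_matrix
from .splines import SplineSpec, design_matrix

__all__ = ["SimulationConfig", "default_config", "simulate_cohort", "inject_errors"]

LB_PER_KG = 2.2046

# mean log-BMI curve on the cubic-spline basis with knots at 1, 8, 12 yr:
# BMI ~13.5 kg/m2 at 2 weeks, adiposity peak ~17.7 at 0.74 yr, rebound
# ~15.3 at 5.0 yr, ~21.6 at 18 yr (a typical European-ancestry cohort).
DEFAULT_BETA = np.array(
    [2.567137, 1.042983, -1.128821, 0.380221, -0.3806554, 1.495623e-4, 1.385438e-4]
)
DEFAULT_KNOTS = (1.0, 8.0, 12.0)


def _anchored_random_covariance(
    anchors=(0.04, 5.0, 11.0, 17.0), sd=0.10, corr=0.7
) -> np.ndarray:
    """Covariance of random cubic-slope coefficients via anchor ages.

    Subject deviations from the mean curve are defined as a cubic through
    correlated Gaussian values at four anchor ages (SD ``sd`` log-BMI
    units, AR-type correlation ``corr``); the induced coefficient
    covariance keeps individual curves within a realistic band at every
    age instead of exploding like independent polynomial coefficients.
    """
    a = np.asarray(anchors, dtype=float)
    M = np.vander(a, 4, increasing=True)
    idx = np.arange(len(a))
    R = corr ** np.abs(np.subtract.outer(idx, idx))
    Minv = np.linalg.inv(M)
    return Minv @ (sd**2 * R) @ Minv.T


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic cohort."""

    n_subjects: int = 500
    visit_schedule: tuple[float, ...] = (
        0.04, 0.25, 0.5, 0.75, 1.0, 1.5, 2.5, 3.5, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0, 17.0,
    )
    visit_jitter_sd: float = 0.08
    age_range: tuple[float, float] = (2.0 / 52.0, 18.0)
    fixed: SplineSpec = field(default_factory=lambda: SplineSpec("cubic_spline", DEFAULT_KNOTS))
    random: SplineSpec = field(default_factory=lambda: SplineSpec("cubic_slope"))
    true_beta: tuple[float, ...] = tuple(DEFAULT_BETA)
    true_G: tuple[tuple[float, ...], ...] = tuple(
        tuple(row) for row in _anchored_random_covariance()
    )
    sigma: float = 0.035
    phi: float = 0.0
    sex_ratio: float = 0.5
    female_intercept_shift: float = -0.02
    error_rates: dict = field(default_factory=dict)
    n_snps: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_effects: dict = field(default_factory=dict)  # snp id -> (coef index, effect)
    seed: int = 0

    def __post_init__(self):
        G = np.asarray(self.true_G, dtype=float)
        if not np.allclose(G, G.T):
            raise ValueError("true_G must be symmetric")
        if np.linalg.eigvalsh(G).min() < -1e-10:
            raise ValueError("true_G must be positive semi-definite")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.phi < 1:
            raise ValueError("phi must be in [0, 1)")
        if not self.visit_schedule:
            raise ValueError("visit_schedule must not be empty")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        lo, hi = self.maf_range
        if self.n_snps and not (0 < lo <= hi <= 0.5):
            raise ValueError("MAFs must lie in (0, 0.5]")
        for rate in self.error_rates.values():
            if not 0 <= rate <= 1:
                raise ValueError("error rates must be in [0, 1]")
        if len(self.true_beta) != self.fixed.n_columns:
            raise ValueError("true_beta length does not match the fixed basis")
        if G.shape[0] != self.random.n_columns:
            raise ValueError("true_G dimension does not match the random basis")

    @property
    def G(self) -> np.ndarray:
        return np.asarray(self.true_G, dtype=float)

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(self.true_beta, dtype=float)


def default_config(**overrides) -> SimulationConfig:
    """The reference study conditions; keyword overrides for variants."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def _height_m(age, sex_is_male, height_factor):
    """Monotone logistic stature curve (m); the trajectory model never
    uses height directly, it only needs to be plausible and increasing."""
    age = np.asarray(age, dtype=float)
    h0 = 0.50
    h1 = np.where(sex_is_male, 1.80, 1.68)
    c, s = 7.0, 4.5
    L = 1.0 / (1.0 + np.exp(-(age - c) / s))
    L0 = 1.0 / (1.0 + np.exp(c / s))
    return (h0 + (h1 - h0) * (L - L0) / (1.0 - L0)) * height_factor


def simulate_cohort(config: SimulationConfig):
    """Draw one cohort; returns ``(records, truth)``.

    ``records`` is a long-format measurement table (rid, iid, sex, age,
    weight kg, height m, source) sorted by (iid, age).  ``truth`` maps
    "subjects" (true random-effect coefficients), "genotypes" (dosage
    matrix, subjects x SNPs), "variants" (SNP metadata) and
    "measurements" (rid, iid, age, true log BMI) for recovery tests.

    Per-subject RNG sub-streams are keyed by (seed, subject index), so a
    subject's data is invariant under changes to ``n_subjects`` above
    their index.
    """
    cfg = config
    rng_cohort = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    n = cfg.n_subjects
    sex_is_male = rng_cohort.random(n) < cfg.sex_ratio
    height_factor = 1.0 + 0.03 * rng_cohort.standard_normal(n)

    # genotypes
    variants = _variant_table(cfg, rng_cohort)
    if cfg.n_snps:
        dosages = rng_cohort.binomial(
            2, variants["eaf"].to_numpy()[None, :], size=(n, cfg.n_snps)
        ).astype(float)
        genotypes = pd.DataFrame(
            dosages,
            index=pd.Index([f"S{i:06d}" for i in range(n)], name="iid"),
            columns=variants["snp"].tolist(),
        )
    else:
        genotypes = pd.DataFrame(index=pd.Index([f"S{i:06d}" for i in range(n)], name="iid"))

    G = cfg.G
    L = np.linalg.cholesky(G + 1e-14 * np.eye(G.shape[0])) if G.any() else np.zeros_like(G)
    lo, hi = cfg.age_range

    rows = []
    subj_rows = []
    truth_meas = []
    rid = 0
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        iid = f"S{i:06d}"
        ages = np.asarray(cfg.visit_schedule) + cfg.visit_jitter_sd * rng.standard_normal(
            len(cfg.visit_schedule)
        )
        ages = np.clip(np.sort(ages), lo, hi)
        b = L @ rng.standard_normal(G.shape[0])
        for snp, (coef_idx, effect) in cfg.snp_effects.items():
            b[coef_idx] += effect * genotypes.loc[iid, snp]
        if not sex_is_male[i]:
            shift = np.zeros(cfg.fixed.n_columns)
            shift[0] = cfg.female_intercept_shift
        else:
            shift = 0.0
        mean = design_matrix(ages, cfg.fixed) @ (cfg.beta + shift)
        mean = mean + design_matrix(ages, cfg.random) @ b
        if cfg.sigma > 0:
            C = car1_matrix(ages, cfg.phi)
            eps = cfg.sigma * (np.linalg.cholesky(C + 1e-12 * np.eye(len(ages))) @ rng.standard_normal(len(ages)))
        else:
            eps = np.zeros(len(ages))
        log_bmi = mean + eps
        heights = _height_m(ages, sex_is_male[i], height_factor[i])
        weights = np.exp(log_bmi) * heights**2
        source = np.where(rng.random(len(ages)) < 0.7, "clinic", "parent")
        sex = "male" if sex_is_male[i] else "female"
        for a, w, h, s2, lb in zip(ages, weights, heights, source, log_bmi):
            rows.append((rid, iid, sex, float(a), float(w), float(h), s2))
            truth_meas.append((rid, iid, float(a), float(lb)))
            rid += 1
        subj_rows.append((iid, sex, *b, height_factor[i]))

    records = pd.DataFrame(
        rows, columns=["rid", "iid", "sex", "age", "weight", "height", "source"]
    )
    subjects = pd.DataFrame(
        subj_rows,
        columns=["iid", "sex"] + [f"b{j}" for j in range(G.shape[0])] + ["height_factor"],
    ).set_index("iid")
    truth = {
        "subjects": subjects,
        "genotypes": genotypes,
        "variants": variants,
        "measurements": pd.DataFrame(truth_meas, columns=["rid", "iid", "age", "log_bmi"]),
    }
    return records, truth


def _variant_table(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """SNP metadata; deterministic in (n_snps, maf_range) only, so cohorts
    simulated with different seeds share a common variant panel."""
    m = cfg.n_snps
    if not m:
        return pd.DataFrame(columns=["snp", "chrom", "pos", "ea", "nea", "eaf", "info"])
    rng = np.random.default_rng(np.random.SeedSequence([424242, m]))
    lo, hi = cfg.maf_range
    eaf = rng.uniform(lo, hi, size=m)
    chrom = (np.arange(m) % 22 + 1).astype(str)
    pos = 1_000_000 + 10_000 * (np.arange(m) // 22 + 1)
    alleles = np.array(["A", "C", "G", "T"])
    ea_idx = rng.integers(0, 4, size=m)
    shift = rng.integers(1, 4, size=m)
    nea_idx = (ea_idx + shift) % 4
    return pd.DataFrame(
        {
            "snp": [f"snp{j:05d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ea": alleles[ea_idx],
            "nea": alleles[nea_idx],
            "eaf": eaf,
            "info": np.round(rng.uniform(0.85, 1.0, size=m), 4),
        }
    )


_FAULTS = (
    "same_day_duplicate",
    "unit_switch",
    "carried_forward",
    "height_decrease",
    "gross_outlier",
)


def inject_errors(records: pd.DataFrame, error_rates: dict, seed: int):
    """Plant data errors; returns ``(corrupted records, fault ledger)``.

    Fault types: same-day duplicate rows, kg->lb unit switches (weight
    multiplied by 2.2046), carried-forward height+weight from the previous
    visit, height drops of 5 cm, and gross weight outliers.  At most one
    fault per record keeps the ledger unambiguous.  The ledger lists
    (rid, iid, age, fault) for every planted fault; duplicates get fresh
    rids.
    """
    for key, rate in error_rates.items():
        if key not in _FAULTS:
            raise ValueError(f"unknown fault type {key!r}")
        if not 0 <= rate <= 1:
            raise ValueError(f"rate for {key!r} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**21]))
    out = records.copy().reset_index(drop=True)
    next_rid = int(out["rid"].max()) + 1 if len(out) else 0
    ledger = []
    dup_rows = []
    for iid, grp in out.groupby("iid", sort=True):
        idx = grp.index.to_numpy()
        taken = np.zeros(len(idx), dtype=bool)
        for fault in _FAULTS:
            rate = error_rates.get(fault, 0.0)
            if rate == 0.0:
                continue
            hits = rng.random(len(idx)) < rate
            if fault in ("carried_forward", "height_decrease"):
                hits[0] = False  # needs a previous visit
            hits &= ~taken
            for j in np.where(hits)[0]:
                row = idx[j]
                if fault == "same_day_duplicate":
                    dup = out.loc[row].copy()
                    dup["rid"] = next_rid
                    dup_rows.append(dup)
                    ledger.append((next_rid, iid, out.at[row, "age"], fault))
                    next_rid += 1
                    taken[j] = True
                    continue
                if fault == "unit_switch":
                    out.at[row, "weight"] *= LB_PER_KG
                elif fault == "carried_forward":
                    prev = idx[j - 1]
                    out.at[row, "weight"] = out.at[prev, "weight"]
                    out.at[row, "height"] = out.at[prev, "height"]
                elif fault == "height_decrease":
                    # 5 cm below the previous visit's height: a true recorded
                    # decrease, as produced by e.g. a digit transposition
                    out.at[row, "height"] = out.at[idx[j - 1], "height"] - 0.05
                elif fault == "gross_outlier":
                    out.at[row, "weight"] *= 20.0  # implausible on any scale
                ledger.append((out.at[row, "rid"], iid, out.at[row, "age"], fault))
                taken[j] = True
    if dup_rows:
        out = pd.concat([out, pd.DataFrame(dup_rows)], ignore_index=True)
        out = out.sort_values(["iid", "age", "rid"], kind="stable").reset_index(drop=True)
    ledger_df = pd.DataFrame(ledger, columns=["rid", "iid", "age", "fault"])
    return out, ledger_df


def write_cohort(records: pd.DataFrame, path) -> None:
    """Long-format measurement CSV (height in cm, ages in decimal years)."""
    out = records.copy()
    out["height_cm"] = out["height"] * 100.0
    out = out.rename(columns={"age": "age_years", "weight": "weight_kg"})
    out[["iid", "sex", "age_years", "weight_kg", "height_cm", "source"]].to_csv(
        path, index=False
    )


def read_cohort(path) -> pd.DataFrame:
    """Read a measurement CSV produced by :func:`write_cohort`."""
    df = pd.read_csv(path)
    df = df.rename(columns={"age_years": "age", "weight_kg": "weight"})
    df["height"] = df["height_cm"] / 100.0
    df = df.drop(columns=["height_cm"])
    df.insert(0, "rid", np.arange(len(df)))
    return df[["rid", "iid", "sex", "age", "weight", "height", "source"]]
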
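"""End-to-end orchestration: simulate -> QC -> fit -> phenotypes -> GWAS -> meta.

A :class:`RunConfig` describes a multi-cohort study (cohort sizes, seeds,
planted SNP effects, analysis windows, the trajectory model).  The
pipeline fits the mixed model per sex within each cohort, concatenates
the sex-specific phenotype tables, runs a sex-combined GWAS per phenotype
with sex as a covariate, harmonises the per-cohort summary statistics and
meta-analyses them.  Every written artifact starts with a header comment
carrying the config hash and seed so reruns are attributable; with a
fixed seed the outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, qc
from .lmm import ModelSpec, fit_lmm
from .phenotypes import derive_phenotypes, iqr_exclusion
from .simulate import default_config, inject_errors, simulate_cohort
from .splines import SplineSpec

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Study-level configuration for a synthetic multi-cohort run."""

    cohorts: dict = field(default_factory=lambda: {"cohortA": {"n_subjects": 300}})
    seed: int = 1
    n_snps: int = 50
    snp_effects: dict = field(default_factory=dict)  # snp -> [coef index, effect]
    age_window: tuple = (2.0 / 52.0, 18.0)
    prediction_range: tuple = (2.0 / 52.0, 17.0)
    knots: tuple = (1.0, 8.0, 12.0)
    error_rates: dict = field(default_factory=dict)
    out_dir: str = "growthgwas_run"

    def __post_init__(self):
        if not (
            self.age_window[0] <= self.prediction_range[0]
            and self.prediction_range[1] <= self.age_window[1]
        ):
            raise ValueError("prediction range must lie within the age window")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("age_window", "prediction_range", "knots"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        # out_dir is excluded: where results land must not change what they are
        blob = json.dumps(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()
                if k != "out_dir"
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# growthgwas config_hash={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns artifact paths and in-memory results."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = ModelSpec(
        fixed=SplineSpec("cubic_spline", cfg.knots),
        random=SplineSpec("cubic_slope"),
        correlation="none",
    )
    per_cohort_stats: dict[str, dict[str, pd.DataFrame]] = {}
    artifacts: dict = {"out_dir": str(out)}
    phenos_by_cohort = {}
    for ci, (name, spec) in enumerate(sorted(cfg.cohorts.items())):
        seed = cfg.seed + 1000 * (ci + 1)
        sim = default_config(
            n_subjects=int(spec.get("n_subjects", 300)),
            n_snps=cfg.n_snps,
            snp_effects={k: tuple(v) for k, v in cfg.snp_effects.items()},
            error_rates=dict(cfg.error_rates),
            seed=seed,
        )
        try:
            records, truth = simulate_cohort(sim)
            if cfg.error_rates:
                records, _ = inject_errors(records, cfg.error_rates, seed)
        except Exception as exc:
            raise PipelineError("simulate", f"{name}: {exc}") from exc
        try:
            flagged, summary = qc.flag_records(records)
            clean = qc.derive_analysis_set(
                flagged, min_age=cfg.age_window[0], max_age=cfg.age_window[1]
            )
        except Exception as exc:
            raise PipelineError("qc", f"{name}: {exc}") from exc
        _write(summary, out / f"{name}.qc_report.tsv", cfg)

        pheno_parts = []
        for sex in ("male", "female"):
            sub = clean[clean["sex"] == sex]
            if not len(sub):
                continue
            fit = fit_lmm(sub, model)
            if not fit.ok:
                raise PipelineError("fit", f"{name}/{sex}: {fit.message}")
            fit.to_json(out / f"{name}.{sex}.fit.json")
            ph = derive_phenotypes(fit, sub, age_range=cfg.prediction_range)
            pheno_parts.append(ph)
        phenos = pd.concat(pheno_parts).sort_index()
        mask, kept = iqr_exclusion(phenos)
        phenos["outlier"] = mask
        _write(phenos, out / f"{name}.phenotypes.tsv", cfg, index=True)
        phenos_by_cohort[name] = phenos

        sex_cov = (
            records.drop_duplicates("iid").set_index("iid")["sex"].eq("male").astype(float)
        )
        covars = pd.DataFrame({"sex": sex_cov})
        stats = {}
        for col in kept.columns:
            res = assoc.run_gwas(
                kept[col], truth["genotypes"], truth["variants"], covars
            )
            filtered, _ledger = assoc.cohort_filters(res)
            stats[col] = filtered
            _write(filtered, out / f"{name}.{col}.gwas.tsv", cfg)
        per_cohort_stats[name] = stats

    phenotype_names = sorted({p for s in per_cohort_stats.values() for p in s})
    metas = {}
    for pheno in phenotype_names:
        tables = {
            c: s[pheno] for c, s in per_cohort_stats.items() if pheno in s
        }
        aligned = assoc.harmonize(tables)
        meta = assoc.ivw_meta(aligned)
        kept, hits, leads = assoc.post_meta_filters(meta, total_cohorts=len(tables))
        _write(kept, out / f"meta.{pheno}.tsv", cfg)
        metas[pheno] = {"meta": kept, "hits": hits, "leads": leads}
    artifacts.update(
        {"phenotypes": phenos_by_cohort, "gwas": per_cohort_stats, "meta": metas}
    )
    return artifacts
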
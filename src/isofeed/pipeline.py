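"""End-to-end orchestration: simulate -> derive -> grm -> fit -> regress.

Each stage reads the delimited outputs of its upstream stage from the run
directory and writes its own, so stages can be rerun individually.  A run
manifest (config snapshot, seed, per-stage timings, sha256 digests of
every output file, package version) makes reruns auditable: deterministic
stages reproduce their digests bit for bit under the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grm import (
    read_genotypes,
    read_relationship,
    tank_g,
    qc_filter,
    vanraden_g,
    write_genotypes,
    write_relationship,
)
from .isotopes import IsotopeStandards, derive_phenotypes
from .regression import backward_eliminate, single_covariate_scan
from .reml import ModelSpec, correlations, lr_test, ratio_estimates, reml_fit
from .simulate import SimulationConfig, simulate_genotypes, simulate_phenotypes

__all__ = ["RunManifest", "run_pipeline", "load_config", "STAGES"]

STAGES = ("simulate", "derive", "grm", "fit", "regress")
log = logging.getLogger("isofeed")


@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[str]
    timings: dict[str, float]
    outputs: dict[str, str]  # relative path -> sha256

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping of stage sections")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sim_config(section: Mapping, seed: int | None) -> SimulationConfig:
    kwargs = dict(section or {})
    for key in ("genetic_cov", "env_cov", "tank_var", "sampling_day_effects"):
        if key in kwargs:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    if "maf_range" in kwargs:
        kwargs["maf_range"] = tuple(kwargs["maf_range"])
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name} from stage '{stage}'; "
            f"run that stage first"
        )
    return path


def run_pipeline(
    config: Mapping,
    out_dir,
    stages: Sequence[str] = STAGES,
    seed: int | None = None,
) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``config`` holds one section per stage (see the bundled example
    configs); unknown stages raise immediately, and a stage whose
    upstream outputs are absent fails fast with a message naming the
    missing stage.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if not stages:
        raise ValueError("stage list is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    timings: dict[str, float] = {}
    ran: list[str] = []
    warnings_summary: list[str] = []
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            if stage == "simulate":
                _stage_simulate(config.get("simulate", {}), out, seed)
            elif stage == "derive":
                _stage_derive(config.get("derive", {}), out)
            elif stage == "grm":
                _stage_grm(config.get("grm", {}), out)
            elif stage == "fit":
                warnings_summary += _stage_fit(config.get("fit", {}), out)
            elif stage == "regress":
                _stage_regress(config.get("regress", {}), out)
            timings[stage] = time.perf_counter() - t0
            ran.append(stage)
            log.info("stage %s: done in %.2fs", stage, timings[stage])
        if warnings_summary:
            log.warning("run finished with %d warnings:", len(warnings_summary))
            for w in warnings_summary:
                log.warning("  %s", w)
    finally:
        log.removeHandler(handler)
        handler.close()

    outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("run.log", "manifest.json")
    }
    manifest = RunManifest(
        config=dict(config),
        seed=seed if seed is not None else int(config.get("simulate", {}).get("seed", 0)),
        version=__version__,
        stages=ran,
        timings=timings,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _stage_simulate(section: Mapping, out: Path, seed: int | None) -> None:
    cfg = _sim_config(section, seed)
    geno = simulate_genotypes(cfg)
    ind, tanks, truth = simulate_phenotypes(geno, cfg)
    ind.to_csv(out / "individuals.tsv", sep="\t", index=False)
    tanks.to_csv(out / "tanks.tsv", sep="\t", index=False)
    write_genotypes(geno, out / "genotypes.tsv")
    pd.Series(geno.base_freqs, index=geno.snp_ids, name="freq").to_csv(
        out / "base_freqs.tsv", sep="\t", index_label="snp"
    )
    truth.breeding_values.to_csv(out / "truth_breeding_values.tsv", sep="\t", index=False)
    truth.tank_effects.to_csv(out / "truth_tank_effects.tsv", sep="\t", index=False)
    truth.intakes.to_csv(out / "truth_intakes.tsv", sep="\t", index=False)
    log.info(
        "simulated %d fish in %d tanks, %d SNPs", cfg.n_fish, cfg.n_tanks, cfg.n_snps
    )


def _stage_derive(section: Mapping, out: Path) -> None:
    ind = pd.read_csv(_require(out / "individuals.tsv", "simulate", "derive"), sep="\t")
    tanks = pd.read_csv(_require(out / "tanks.tsv", "simulate", "derive"), sep="\t")
    std_kwargs = {}
    if "baseline_mean" in section:
        std_kwargs["baseline_mean"] = dict(section["baseline_mean"])
    if "baseline_sd" in section:
        std_kwargs["baseline_sd"] = dict(section["baseline_sd"])
    standards = IsotopeStandards(**std_kwargs)
    derived_ind, derived_tanks, counts = derive_phenotypes(
        ind,
        tanks,
        standards,
        units=section.get("units", "atom"),
        include_filtered_in_fcr=bool(section.get("include_filtered_in_fcr", False)),
    )
    derived_ind.to_csv(out / "derived_individuals.tsv", sep="\t", index=False)
    derived_tanks.to_csv(out / "derived_tanks.tsv", sep="\t", index=False)
    (out / "filter_counts.json").write_text(json.dumps(counts, indent=2))
    for reason in ("weight_missing", "low_growth", "high_growth"):
        log.info("filter: %s -> %d fish set missing", reason, counts[reason])
    log.info(
        "filter: %d of %d fish (%.1f%%) set to missing for growth",
        counts["total_missing"], len(derived_ind),
        100.0 * counts["total_missing"] / max(len(derived_ind), 1),
    )


def _stage_grm(section: Mapping, out: Path) -> None:
    geno = read_genotypes(_require(out / "genotypes.tsv", "simulate", "grm"))
    ind = pd.read_csv(_require(out / "individuals.tsv", "simulate", "grm"), sep="\t")
    geno, report = qc_filter(
        geno,
        maf_min=float(section.get("maf_min", 0.01)),
        call_rate_min=float(section.get("call_rate_min", 0.9)),
    )
    report.to_csv(out / "snp_qc_report.tsv", sep="\t", index=False)
    log.info("QC retained %d of %d SNPs", int(report["kept"].sum()), len(report))
    g = vanraden_g(geno)
    write_relationship(g, out / "grm_individual.tsv")
    assignment = dict(zip(ind["fish_id"].astype(str), ind["tank"].astype(str)))
    gt = tank_g(geno, assignment)
    write_relationship(gt, out / "grm_tank.tsv")
    log.info(
        "G: %d individuals; G_T: %d tanks (mean diagonal %.6f)",
        len(g.ids), len(gt.ids), float(np.mean(np.diag(gt.values))),
    )


_DEFAULT_PAIRS = (
    {"trait1": "fcr", "trait2": "mean_rg", "level": "tank"},
    {"trait1": "fi", "trait2": "mean_wg", "level": "tank"},
    {"trait1": "wg", "trait2": "rg", "level": "individual"},
    {"trait1": "atom_amn", "trait2": "rg", "level": "individual"},
)


def _stage_fit(section: Mapping, out: Path) -> list[str]:
    tanks = pd.read_csv(_require(out / "derived_tanks.tsv", "derive", "fit"), sep="\t")
    ind = pd.read_csv(
        _require(out / "derived_individuals.tsv", "derive", "fit"), sep="\t"
    )
    ind = ind[~ind["growth_missing"]].copy()
    g = read_relationship(_require(out / "grm_individual.tsv", "grm", "fit"))
    gt = read_relationship(_require(out / "grm_tank.tsv", "grm", "fit"), level="tank")
    pairs = section.get("pairs", [dict(p) for p in _DEFAULT_PAIRS])
    compute_se = bool(section.get("compute_se", False))
    warnings_summary: list[str] = []
    pair_rows, trait_rows = [], []
    tested: set[tuple[str, str]] = set()
    for pair in pairs:
        level = pair.get("level", "tank")
        data = tanks if level == "tank" else ind
        rel = gt if level == "tank" else g
        spec = ModelSpec(
            trait1=pair["trait1"], trait2=pair.get("trait2"), level=level,
            day_as_factor=bool(section.get("day_as_factor", False)),
        )
        fit = reml_fit(spec, data, rel, compute_se=compute_se)
        if not fit.converged:
            warnings_summary.append(
                f"non-convergence for {pair['trait1']}/{pair.get('trait2')}: {fit.message}"
            )
        row = {
            "trait1": pair["trait1"], "trait2": pair.get("trait2"), "level": level,
            "loglik": fit.loglik, "converged": fit.converged, "n": fit.n_obs,
        }
        for name, val in zip(fit.component_names, fit.component_values):
            row[name] = val
        if fit.n_traits == 2:
            corr = correlations(fit)
            row["r_genetic"] = corr["r_genetic"]
            row["r_phenotypic"] = corr["r_phenotypic"]
            row["rg_boundary"] = corr["boundary"]
            if corr["boundary"]:
                warnings_summary.append(
                    f"genetic correlation at boundary for "
                    f"{pair['trait1']}/{pair['trait2']}"
                )
        pair_rows.append(row)

        # Table-4-style per-trait summary: univariate components, ratios
        # and LR test of the genetic term.
        for trait in spec.traits:
            if (trait, level) in tested:
                continue
            tested.add((trait, level))
            uni = ModelSpec(trait1=trait, level=level)
            fit1 = reml_fit(uni, data, rel, compute_se=compute_se)
            uni0 = ModelSpec(trait1=trait, level=level, include_genetic=False)
            fit0 = reml_fit(uni0, data, None)
            lr, p = lr_test(fit1, fit0)
            ratios = ratio_estimates(fit1).iloc[0].to_dict()
            trow = {"trait": trait, "level": level, "lr": lr, "p": p,
                    "loglik_h1": fit1.loglik, "loglik_h0": fit0.loglik}
            for name, val in zip(fit1.component_names, fit1.component_values):
                trow[name] = val
            trow.update({k: v for k, v in ratios.items() if k != "trait"})
            trait_rows.append(trow)

    pd.DataFrame(pair_rows).to_csv(out / "genetic_correlations.tsv", sep="\t", index=False)
    pd.DataFrame(trait_rows).to_csv(out / "variance_components.tsv", sep="\t", index=False)
    return warnings_summary


def _stage_regress(section: Mapping, out: Path) -> None:
    tanks = pd.read_csv(
        _require(out / "derived_tanks.tsv", "derive", "regress"), sep="\t"
    )
    candidates = list(
        section.get(
            "candidates",
            ["fi", "mean_rg", "mean_amc", "mean_amn", "mean_alc", "mean_aln", "mean_aac"],
        )
    )
    missing = [c for c in candidates if c not in tanks.columns]
    if missing:
        raise KeyError(f"regress candidates not in tank table: {missing}")
    scan = single_covariate_scan(tanks["fcr"], tanks["day"], tanks[candidates])
    scan.to_csv(out / "regression_scan.tsv", sep="\t", index=False)
    best = backward_eliminate(
        tanks["fcr"], tanks["day"], tanks[candidates],
        interactions=bool(section.get("interactions", False)),
    )
    pd.DataFrame(best.elimination_trace).to_csv(
        out / "regression_elimination.tsv", sep="\t", index=False
    )
    summary = {
        "selected": best.covariates,
        "r2": best.r2,
        "adj_r2": best.adj_r2,
        "r2_hat": best.r2_hat,
        "press": best.press,
        "bias_loo": best.bias_loo,
        "bias_insample": best.bias_insample,
        "coefficients": {k: float(v) for k, v in best.coefficients.items()},
        "pvalues": {k: float(v) for k, v in best.pvalues.items()},
    }
    (out / "regression_selected.json").write_text(json.dumps(summary, indent=2))
    log.info(
        "backward elimination kept %s (PRESS %.4g, R2hat %.3f)",
        best.covariates, best.press, best.r2_hat,
    )
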
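"""End-to-end evaluation pipeline and its run configuration.

One run executes: simulate (or load) -> standardize test days to 210-day
lactations -> depurate -> connect to pedigree -> nonparametric screen ->
REML variance components for both model variants -> BLUP evaluation for
both -> ICO ranking and stratified sample -> two-model comparison.  Every
stage writes a TSV artifact; a JSON manifest records the seed, a config
hash, library versions and convergence diagnostics, so a rerun with the
same seed reproduces every number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blup import BLUPEvaluator
from .compare import comparison_report, heritability_delta
from .index import IndexConfig, ico_scores, rank_stratified_sample
from .lactation import (
    connect_to_pedigree,
    default_depuration_ranges,
    depurate_records,
    standardize_dataset,
)
from .pedigree import DOE, read_pedigree_csv
from .reml import TRAIT_COLUMNS, AnimalModelREML
from .screen import screen_dataset
from .simulate import (
    SimulationConfig,
    TRAITS,
    drop_genotypes,
    simulate_lactation_dataset,
    simulate_pedigree,
    simulate_test_day_dataset,
)

log = logging.getLogger("capribreed")


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Exactly one of `simulation` (a SimulationConfig) or the triple of real
    input paths (pedigree_csv, test_day_csv, genotype_csv) must be present.
    """

    output_dir: str = "capribreed_run"
    simulation: SimulationConfig = None
    pedigree_csv: str = None
    test_day_csv: str = None
    genotype_csv: str = None
    traits: tuple = TRAITS
    reml_tol: float = 1e-12
    reml_max_iter: int = 200
    seed: int = 20190913
    ico_strata: tuple = (236, 238, 236)

    def __post_init__(self):
        real = all(p is not None for p in (self.pedigree_csv, self.test_day_csv))
        sim = self.simulation is not None
        if real == sim:
            raise ConfigError(
                "config must contain exactly one of a simulation block or "
                "real input paths (pedigree_csv + test_day_csv)"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# capribreed {__version__} config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    A stage failure aborts with the stage name in the exception, leaving
    the artifacts of completed stages in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config_hash": cfg_hash,
        "stages": {},
    }
    stage = "init"
    t_start = time.time()

    def tick(name):
        nonlocal stage, t_start
        manifest["stages"][stage] = round(time.time() - t_start, 3)
        log.info("stage %s done in %.2fs", stage, time.time() - t_start)
        stage, t_start = name, time.time()

    try:
        if config.simulation is not None:
            sim = config.simulation.with_(seed=config.seed)
            ped = simulate_pedigree(sim)
            genotypes = drop_genotypes(ped, sim.allele_freqs, seed=sim.seed + 3)
            lact_truth = simulate_lactation_dataset(ped, genotypes, sim)
            test_days = simulate_test_day_dataset(lact_truth, sim)
            meta = lact_truth.drop(
                columns=[TRAIT_COLUMNS[t] for t in TRAITS]
            )
        else:
            ped = read_pedigree_csv(config.pedigree_csv)
            test_days = pd.read_csv(config.test_day_csv, dtype={"doe_id": str})
            genotypes = (
                pd.read_csv(config.genotype_csv, dtype={"animal_id": str})
                if config.genotype_csv
                else None
            )
            meta = None
        _write(ped.to_frame(), out / "pedigree.tsv", cfg_hash)
        _write(test_days, out / "test_days.tsv", cfg_hash)
        if genotypes is not None:
            _write(genotypes, out / "genotypes.tsv", cfg_hash)
        tick("standardize")

        records, rej_std = standardize_dataset(test_days, meta)
        _write(records, out / "lactations.tsv", cfg_hash)
        tick("depurate")

        records, rej_dep = depurate_records(records, default_depuration_ranges())
        rej = pd.concat([rej_std, rej_dep], ignore_index=True)
        _write(rej, out / "rejections.tsv", cfg_hash)
        tick("connect")

        records, rej_conn = connect_to_pedigree(records, ped)
        manifest["n_records"] = len(records)
        manifest["n_does"] = records["doe_id"].nunique()
        tick("screen")

        trait_cols = [TRAIT_COLUMNS[t] for t in config.traits]
        screen = screen_dataset(
            records,
            trait_cols,
            [c for c in ("farm", "year", "month", "season", "birth_type",
                         "genotype_class") if c in records.columns],
        )
        _write(screen, out / "screen.tsv", cfg_hash)
        tick("reml")

        reml_fits = {}
        vc_rows = []
        for variant, incl in (("incl_genotype", True), ("excl_genotype", False)):
            reml_fits[variant] = {}
            for t in config.traits:
                est = AnimalModelREML(
                    trait=t,
                    include_genotype=incl and "genotype_class" in records.columns,
                    tol=config.reml_tol,
                    max_iter=config.reml_max_iter,
                ).fit(records, pedigree=ped)
                reml_fits[variant][t] = est
                vc = est.components_
                vc_rows.append(
                    {
                        "model": variant,
                        "trait": t,
                        "sigma_a2": vc.sigma_a2,
                        "sigma_p2": vc.sigma_p2,
                        "sigma_pe2": vc.sigma_pe2,
                        "sigma_e2": vc.sigma_e2,
                        "h2": est.h2_,
                        "h2_se": est.h2_se_,
                        "repeatability": est.repeatability_,
                        "converged": est.converged_,
                        "n_iter": est.n_iter_,
                    }
                )
        _write(pd.DataFrame(vc_rows), out / "variance_components.tsv", cfg_hash)
        manifest["reml"] = {
            v: {t: {"converged": bool(f.converged_), "n_iter": int(f.n_iter_)}
                for t, f in fits.items()}
            for v, fits in reml_fits.items()
        }
        tick("blup")

        evals = {}
        for variant, incl in (("incl_genotype", True), ("excl_genotype", False)):
            vcs = {t: reml_fits[variant][t].components_ for t in config.traits}
            ev = BLUPEvaluator(
                traits=config.traits,
                include_genotype=incl and "genotype_class" in records.columns,
                variance_components=vcs,
            ).fit(records, pedigree=ped)
            evals[variant] = ev
            _write(ev.evaluation_, out / f"evaluation_{variant}.tsv", cfg_hash)
            blues = pd.concat(
                [b.assign(trait=t) for t, b in ev.blue_.items()], ignore_index=True
            )
            _write(blues, out / f"blue_{variant}.tsv", cfg_hash)
        tick("ico")

        ev = evals["incl_genotype"].evaluation_
        does = ev.loc[ev["sex"] == DOE]
        pbv_wide = does.pivot(index="animal_id", columns="trait", values="pbv")
        # ICO combines milk, fat and protein; restrict to the evaluated traits
        ico_traits = tuple(
            t for t in ("milk", "fat", "protein") if t in config.traits
        )
        idx_cfg = IndexConfig(
            traits=ico_traits, weights={t: 1.0 for t in ico_traits}
        )
        scores = ico_scores(pbv_wide, idx_cfg)
        n_low, n_mid, n_high = config.ico_strata
        k = len(scores)
        if n_low + n_mid + n_high > k:  # demo-scale populations
            n_low = n_mid = n_high = max(1, k // 4)
        ranking = rank_stratified_sample(scores, n_low, n_mid, n_high)
        _write(ranking, out / "ico_ranking.tsv", cfg_hash)
        tick("compare")

        report = comparison_report(
            evals["incl_genotype"].evaluation_,
            evals["excl_genotype"].evaluation_,
            traits=config.traits,
            phenotyped_ids=records["doe_id"].astype(str).unique(),
        )
        _write(report["correlations"], out / "model_comparison.tsv", cfg_hash)
        _write(report["descriptives"], out / "pbv_descriptives.tsv", cfg_hash)
        deltas = {
            t: heritability_delta(
                reml_fits["incl_genotype"][t].result_,
                reml_fits["excl_genotype"][t].result_,
            )
            for t in config.traits
        }
        manifest["h2_delta"] = {t: {"delta": d, "se": s} for t, (d, s) in deltas.items()}
        tick("finish")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest["stages"][stage] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
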
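"""End-to-end orchestration: DBH screening -> diversity -> maternity
assignment -> pedigree -> Moran's I -> model comparison -> variance
components, heritability and ranked breeding values.

Every stage writes its artifact to the output directory and can be re-run
from the previous stage's serialized outputs. All randomness flows from a
single root seed, split deterministically per stage; the config hash and
seed are recorded in every output header.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal_model import (
    ModelData,
    OptimizerConfig,
    blup,
    build_A,
    compare_models,
    rank_selection,
)
from .genotypes import diversity_summary, read_genotype_table, write_diversity_csv
from .parentage import ParentageConfig, assign_maternity, results_to_csv
from .spatial import morans_i, rasterize, read_tree_records, TreeRecord

__all__ = ["PipelineConfig", "PipelineError", "screen_by_dbh", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and knobs for a full pipeline run."""

    genotypes: str
    phenotypes: str
    output_dir: str
    genotype_dialect: str = "genalex_csv"
    candidate_group: str = "PT"
    offspring_groups: list[str] = field(default_factory=lambda: ["HC"])
    dbh_screen_threshold: float = 30.0
    grid_rows: int = 450
    grid_cols: int = 450
    parentage: ParentageConfig = field(default_factory=ParentageConfig)
    moran_weight_scheme: str = "inverse_distance"
    n_starts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dbh_screen_threshold <= 0:
            raise ValueError("dbh_screen_threshold must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "parentage" in raw and isinstance(raw["parentage"], dict):
            p = raw["parentage"]
            if "confidence_levels" in p:
                p["confidence_levels"] = tuple(p["confidence_levels"])
            raw["parentage"] = ParentageConfig(**p)
        return cls(**raw)

    def hash(self) -> str:
        # output_dir is excluded so runs into different directories of the
        # same inputs/settings stamp identically
        payload = asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def screen_by_dbh(
    records: list[TreeRecord], threshold: float
) -> tuple[list[TreeRecord], list[TreeRecord]]:
    """Split records into (kept, excluded): trees with DBH strictly above
    the threshold are excluded (outlier screening)."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    kept = [t for t in records if t.dbh <= threshold]
    excluded = [t for t in records if t.dbh > threshold]
    return kept, excluded


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages and return the artifact paths.

    Artifacts: diversity.csv, parentage_<group>.csv, assignment_tiers.csv,
    pedigree.csv, moran_<group>.json, model_comparison_<group>.csv,
    variance_components_<group>.csv, ebv_offspring_<group>.csv,
    ebv_mothers_<group>.csv and run_log.json. Deterministic given
    (inputs, config, seed). Offspring cohorts are fitted separately.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_sha256={config.hash()} seed={config.seed} orchardqg={__version__}"
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0]) % (2**31) for s in seeds]
    artifacts: dict[str, str] = {}
    log: dict = {"config": asdict(config), "config_hash": config.hash(),
                 "seed": config.seed, "version": __version__, "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:
                log["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_log(out, log, artifacts)
                raise PipelineError(name, exc) from exc
            log["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        return deco

    table = read_genotype_table(config.genotypes, config.genotype_dialect)
    all_records = read_tree_records(config.phenotypes)

    kept, excluded = screen_by_dbh(all_records, config.dbh_screen_threshold)
    log["screening"] = {
        "threshold": config.dbh_screen_threshold,
        "n_input": len(all_records),
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "excluded_ids": [t.id for t in excluded],
    }
    records_by_group: dict[str, list[TreeRecord]] = {}
    for t in kept:
        records_by_group.setdefault(t.group or "HC", []).append(t)

    @stage("diversity")
    def _diversity():
        groups = [config.candidate_group] + list(config.offspring_groups)
        summaries = [diversity_summary(table, g) for g in groups if table.ids_in_group(g)]
        path = out / "diversity.csv"
        write_diversity_csv(summaries, path, header_comment=stamp)
        artifacts["diversity"] = str(path)

    pedigrees: dict[str, object] = {}
    tier_rows = []

    @stage("parentage")
    def _parentage():
        for gi, group in enumerate(config.offspring_groups):
            pcfg = ParentageConfig(
                error_rate=config.parentage.error_rate,
                n_sim=config.parentage.n_sim,
                confidence_levels=config.parentage.confidence_levels,
                prop_candidates_sampled=config.parentage.prop_candidates_sampled,
                prop_loci_typed=config.parentage.prop_loci_typed,
                seed=stage_seed[0] + gi,
            )
            results, ped = assign_maternity(table, group, config.candidate_group, pcfg)
            pedigrees[group] = ped
            path = out / f"parentage_{group}.csv"
            results_to_csv(results, path, header_comment=stamp)
            artifacts[f"parentage_{group}"] = str(path)
            ped_path = out / f"pedigree_{group}.csv"
            ped.to_csv(ped_path, header_comment=stamp)
            artifacts[f"pedigree_{group}"] = str(ped_path)
            n = len(results)
            for tier in ("strict", "relaxed", "low", "unassigned"):
                cnt = sum(1 for r in results if r.tier == tier)
                tier_rows.append(
                    {"group": group, "tier": tier, "count": cnt,
                     "percent": round(100.0 * cnt / n, 1)}
                )
        tiers = pd.DataFrame(tier_rows)
        path = out / "assignment_tiers.csv"
        with open(path, "w") as fh:
            fh.write(f"# {stamp}\n")
            tiers.to_csv(fh, index=False)
        artifacts["assignment_tiers"] = str(path)

    @stage("moran")
    def _moran():
        for group, recs in records_by_group.items():
            if len(recs) < 4:
                continue
            mr = morans_i(
                [t.dbh for t in recs],
                [(t.x, t.y) for t in recs],
                config.moran_weight_scheme,
                n_perm=999,
                seed=stage_seed[1],
            )
            path = out / f"moran_{group}.json"
            with open(path, "w") as fh:
                json.dump({"stamp": stamp, **asdict(mr)}, fh, indent=2)
            artifacts[f"moran_{group}"] = str(path)

    @stage("genetic_testing")
    def _testing():
        opt = OptimizerConfig(n_starts=config.n_starts, seed=stage_seed[2])
        for group, recs in records_by_group.items():
            ped = pedigrees.get(group)
            if ped is None:
                continue
            rel = build_A(ped)
            data = ModelData.from_records(recs)
            # phenotyped trees missing from the pedigree cannot enter the fit
            known = [i for i in data.ids if i in ped.parents]
            data = ModelData(
                ids=known,
                y=np.array([recs[j].dbh for j, i in enumerate(data.ids) if i in ped.parents]),
                coords=data.coords,
            )
            grid = rasterize(
                [t for t in recs if t.id in ped.parents], config.grid_rows, config.grid_cols
            )
            comparison, fits = compare_models(data, rel, grid, pedigree=ped, optimizer_config=opt)
            path = out / f"model_comparison_{group}.csv"
            with open(path, "w") as fh:
                fh.write(f"# {stamp}\n")
                comparison.to_csv(fh, index=False, float_format="%.4f")
            artifacts[f"model_comparison_{group}"] = str(path)
            best_label = comparison.loc[comparison["status"] == "ok", "model"].iloc[0]
            animal_fits = {k: v for k, v in fits.items() if v.spec.genetic == "animal"}
            best_animal = min(animal_fits.values(), key=lambda f: f.aicc)
            vc_rows = [
                {"component": "Genetic", "estimate": best_animal.params.get("sigma2_a"),
                 "se": best_animal.se.get("sigma2_a")},
                {"component": "Spatial", "estimate": best_animal.params.get("sigma2_xi", 0.0),
                 "se": best_animal.se.get("sigma2_xi")},
                {"component": "Residual", "estimate": best_animal.params.get("sigma2_eta"),
                 "se": best_animal.se.get("sigma2_eta")},
                {"component": "h2", "estimate": best_animal.h2, "se": None},
            ]
            path = out / f"variance_components_{group}.csv"
            with open(path, "w") as fh:
                fh.write(f"# {stamp} model={best_animal.spec.label} best_overall={best_label}\n")
                pd.DataFrame(vc_rows).to_csv(fh, index=False, float_format="%.6g")
            artifacts[f"variance_components_{group}"] = str(path)

            ebv = blup(best_animal, data, rel, grid=grid, pedigree=ped)
            ebv_map = dict(zip(ebv["id"], ebv["ebv"]))
            offspring_ids = [i for i in rel.ids if ped.dam(i) is not None]
            mother_ids = [i for i in rel.ids if ped.dam(i) is None]
            fwd = rank_selection(ebv_map, len(offspring_ids), "forward", ids=offspring_ids)
            bwd = rank_selection(ebv_map, len(mother_ids), "backward", ids=mother_ids)
            for name, sel in (("offspring", fwd), ("mothers", bwd)):
                path = out / f"ebv_{name}_{group}.csv"
                with open(path, "w") as fh:
                    fh.write(f"# {stamp} model={best_animal.spec.label}\n")
                    sel.to_csv(fh, index=False, float_format="%.6g")
                artifacts[f"ebv_{name}_{group}"] = str(path)

    _write_log(out, log, artifacts)
    artifacts["run_log"] = str(out / "run_log.json")
    return artifacts


def _write_log(out: Path, log: dict, artifacts: dict) -> None:
    log["artifacts"] = artifacts
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
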
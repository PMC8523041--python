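"""End-to-end discovery -> replication workflow orchestration.

``run_pipeline`` executes scoring, the association stage, the interaction
scan (including the quadratic non-linearity check and the locus-exclusion
rerun), the percentile cut-off search on the discovery cohort, and the
fixed-cut-off validation on the replication cohort.  Every stage writes a
table; a single JSON manifest records the package version, a hash of the
configuration, the master seed, and a checksum per output, so a rerun with
the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .association import (
    categorize_risk_factors,
    compare_explained_variance,
    decile_summary,
    run_risk_factor_associations,
    run_trait_associations,
)
from .criterion import compare_models, fit_criterion_model, search_cutoff, validate_replication
from .exceptions import InvalidConfigError, PipelineStageError
from .interaction import activity_dependence_test, interaction_scan, nonlinearity_test
from .io import (
    read_dosages,
    read_phenotypes,
    read_weight_table,
    write_dosages,
    write_phenotypes,
    write_tsv,
    write_weight_table,
)
from .scoring import FTO_WINDOW, compute_score, exclude_region, filter_genomewide_significant
from .synthetic import SimulationConfig, generate_cohort, generate_genotypes, generate_weight_table

logger = logging.getLogger("prsgxe")


@dataclass
class PipelineConfig:
    """Pipeline inputs: either file paths or simulation configurations."""

    out_dir: str = "prsgxe_out"
    seed: int = 17
    simulation: Optional[SimulationConfig] = None
    replication_simulation: Optional[SimulationConfig] = None
    weights_path: Optional[str] = None
    dosages_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    replication_dosages_path: Optional[str] = None
    replication_phenotypes_path: Optional[str] = None
    gws_alpha: float = 5e-8
    exclude_chrom: Optional[str] = None
    exclude_center: Optional[int] = None
    exclude_window: int = FTO_WINDOW
    estimator: str = "robust"
    family_size: int = 12
    cutoff_min_samples: int = 200
    log_level: str = "INFO"

    def __post_init__(self):
        real = all(
            p is not None
            for p in (self.weights_path, self.dosages_path, self.phenotypes_path)
        )
        if self.simulation is None and not real:
            raise InvalidConfigError(
                "either a simulation config or weights/dosages/phenotypes paths are required"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("simulation", "replication_simulation"):
            if raw.get(key) is not None:
                raw[key] = SimulationConfig(**raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _load_or_simulate(config: PipelineConfig, out: Path) -> dict:
    """Materialize discovery (and optional replication) inputs."""
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        weights = generate_weight_table(sim)
        genotypes = generate_genotypes(sim, weights)
        scores = compute_score(genotypes, weights)
        cohort = generate_cohort(sim, scores["standardized_score"].to_numpy())
        write_weight_table(weights, out / "weights.tsv")
        write_dosages(genotypes, out / "dosages.tsv")
        write_phenotypes(cohort, out / "phenotypes.tsv")
        (out / "simulation_config.json").write_text(
            json.dumps(dataclasses.asdict(sim), indent=2, sort_keys=True, default=str)
        )
        bundle = {"weights": weights, "genotypes": genotypes, "cohort": cohort}
        if config.replication_simulation is not None:
            rep = dataclasses.replace(config.replication_simulation, seed=config.seed + 1)
            rep_geno = generate_genotypes(rep, weights)
            rep_scores = compute_score(rep_geno, weights)
            rep_cohort = generate_cohort(rep, rep_scores["standardized_score"].to_numpy())
            write_phenotypes(rep_cohort, out / "replication_phenotypes.tsv")
            bundle.update({"replication_genotypes": rep_geno, "replication_cohort": rep_cohort})
        return bundle
    weights = read_weight_table(config.weights_path)
    genotypes = read_dosages(config.dosages_path)
    cohort = read_phenotypes(config.phenotypes_path)
    bundle = {"weights": weights, "genotypes": genotypes, "cohort": cohort}
    if config.replication_dosages_path and config.replication_phenotypes_path:
        bundle["replication_genotypes"] = read_dosages(config.replication_dosages_path)
        bundle["replication_cohort"] = read_phenotypes(config.replication_phenotypes_path)
    return bundle


def _attach_scores(cohort, genotypes, weights, config: PipelineConfig):
    """PRS, GRS and (optionally) region-excluded PRS columns for one cohort."""
    prs = compute_score(genotypes, weights)
    cohort = cohort.copy()
    cohort["prs"] = prs["standardized_score"].reindex(cohort.index)
    cohort["prs_percentile"] = prs["percentile_rank"].reindex(cohort.index)
    cohort["prs_decile"] = prs["decile"].reindex(cohort.index)
    gws = filter_genomewide_significant(weights, config.gws_alpha)
    if len(gws):
        grs = compute_score(genotypes, gws)
        cohort["grs"] = grs["standardized_score"].reindex(cohort.index)
        cohort["grs_decile"] = grs["decile"].reindex(cohort.index)
    if config.exclude_chrom is not None and config.exclude_center is not None:
        kept = exclude_region(
            weights, config.exclude_chrom, config.exclude_center, config.exclude_window
        )
        noregion = compute_score(genotypes, kept)
        cohort["prs_noregion"] = noregion["standardized_score"].reindex(cohort.index)
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dictionary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": {},
    }
    results: dict = {}
    stage = "inputs"
    try:
        bundle = _load_or_simulate(config, out)
        manifest["stages"][stage] = "ok"

        stage = "scoring"
        # default exclusion window: the simulated lead locus
        if config.exclude_chrom is None and config.simulation is not None:
            config.exclude_chrom = config.simulation.lead_chrom
            config.exclude_center = config.simulation.lead_pos
        cohort = _attach_scores(
            bundle["cohort"], bundle["genotypes"], bundle["weights"], config
        )
        cohort = categorize_risk_factors(cohort)
        write_tsv(cohort.reset_index(), out / "cohort_scored.tsv")
        manifest["stages"][stage] = "ok"

        stage = "associations"
        traits = run_trait_associations(cohort, estimator=config.estimator)
        write_tsv(traits, out / "trait_associations.tsv")
        rf = run_risk_factor_associations(
            cohort, estimator=config.estimator, family_size=config.family_size
        )
        write_tsv(rf, out / "risk_factor_associations.tsv")
        deciles = decile_summary(cohort, "prs")
        write_tsv(deciles, out / "decile_summary.tsv")
        results["decile_top_bottom_diff"] = deciles.attrs["top_bottom_median_diff"]
        if "grs" in cohort.columns:
            results["explained_variance"] = compare_explained_variance(cohort)
        manifest["stages"][stage] = "ok"

        stage = "interactions"
        scan = interaction_scan(
            cohort, estimator=config.estimator, family_size=config.family_size
        )
        write_tsv(scan, out / "interactions.tsv")
        results["nonlinearity_prs"] = nonlinearity_test(cohort, "prs")
        if "grs" in cohort.columns:
            results["nonlinearity_grs"] = nonlinearity_test(cohort, "grs")
        act = activity_dependence_test(cohort)
        results["activity_dependence_p"] = float(act.p_values["prs"])
        if "prs_noregion" in cohort.columns:
            noregion = interaction_scan(
                cohort,
                factors=["physical_activity"],
                score="prs_noregion",
                estimator=config.estimator,
                family_size=config.family_size,
            )
            write_tsv(noregion, out / "interactions_noregion.tsv")
        manifest["stages"][stage] = "ok"

        stage = "cutoff_search"
        search = search_cutoff(cohort, min_samples=config.cutoff_min_samples)
        (out / "cutoff_search.json").write_text(json.dumps(search.to_dict(), indent=2))
        evaluation = fit_criterion_model(
            cohort, search.selected_percentile, estimator=config.estimator
        )
        payload = evaluation.to_dict() | {"comparison": compare_models(evaluation)}
        (out / "criterion_discovery.json").write_text(json.dumps(payload, indent=2))
        results["cutoff"] = search.to_dict() | {"discovery_evaluation": payload}
        manifest["stages"][stage] = "ok"

        stage = "validation"
        if "replication_cohort" in bundle:
            rep = _attach_scores(
                bundle["replication_cohort"],
                bundle["replication_genotypes"],
                bundle["weights"],
                config,
            )
            rep = categorize_risk_factors(rep)
            rep_eval = validate_replication(
                rep, search.selected_percentile, estimator=config.estimator
            )
            rep_payload = rep_eval.to_dict() | {"comparison": compare_models(rep_eval)}
            (out / "criterion_replication.json").write_text(json.dumps(rep_payload, indent=2))
            results["replication"] = rep_payload
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        _write_manifest(manifest, results, out)
        raise PipelineStageError(stage, exc) from exc

    _write_manifest(manifest, results, out)
    return manifest


def _write_manifest(manifest: dict, results: dict, out: Path) -> None:
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = {"sha256": _sha256(path)}
    manifest["results"] = results
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
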
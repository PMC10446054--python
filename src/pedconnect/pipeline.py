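"""End-to-end pipeline: declarative config, staged execution, manifest.

The pipeline runs (optionally) the simulator, then QC, marker/structure
statistics, parentage assignment, pedigree construction, connectivity and
the demographic/fitness analyses, writing every stage's tables under the
configured output directory together with a manifest (file → row count) and
a plain-text summary of the headline numbers. A fixed master seed makes the
whole run reproducible; per-stage seeds are split deterministically from it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import demofit, genotype_io, parentage, pedigree, popgen, simdata

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "popgen", "assign", "pedigree", "connect", "fitness"]

_DEFAULTS: dict[str, Any] = {
    "input": None,  # {"genotypes": path, "metadata": path, "dialect": "csv"}
    "simulation": None,  # subset of SimConfig fields
    "qc": {"max_locus_missing": 0.05, "max_indiv_missing": 0.10},
    "assignment": {
        "error_rate": 0.01,
        "posterior_threshold": 0.95,
        "min_typed_loci": 16,
        "repro_age_max": 20,
        "max_candidates": 14000,
    },
    "popgen": {"n_permutations": 199, "filter_hwe": True, "hwe_alpha": 0.05,
               "per_year_fst": True},
    "fitness": {"last_years_excluded": 2},
    "output_dir": "results/pipeline",
    "seed": 0,
}

_SIM_KEYS = {
    "n_years", "founders_per_patch", "m_pollen", "fecundity", "adult_survival",
    "seed_kernel_mean", "pollen_kernel_mean", "migrant_fecundity_multiplier",
    "genotyping_error_rate", "missing_rate", "capacity_per_patch", "start_year",
    "max_repro_age",
}
_INPUT_KEYS = {"genotypes", "metadata", "dialect"}


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    data: dict[str, Any]

    def __getitem__(self, key: str):
        return self.data[key]

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output_dir excluded)."""
        hashed = {k: v for k, v in self.data.items() if k != "output_dir"}
        text = yaml.safe_dump(hashed, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _merge_section(name: str, given: dict, defaults: dict, allowed: set[str] | None = None) -> dict:
    allowed = allowed if allowed is not None else set(defaults)
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load, default-fill and range-check a pipeline config.

    Exactly one of ``input`` and ``simulation`` must be present. Unknown keys
    are rejected by name. Normalization is idempotent.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg: dict[str, Any] = {}
    has_input = raw.get("input") is not None
    has_sim = raw.get("simulation") is not None
    if has_input == has_sim:
        raise ConfigError("exactly one of 'input' and 'simulation' must be given")
    cfg["input"] = (
        _merge_section("input", raw["input"], {"dialect": "csv"}, _INPUT_KEYS)
        if has_input
        else None
    )
    if has_input and ("genotypes" not in cfg["input"] or "metadata" not in cfg["input"]):
        raise ConfigError("input section needs 'genotypes' and 'metadata' paths")
    cfg["simulation"] = (
        _merge_section("simulation", raw["simulation"], {}, _SIM_KEYS) if has_sim else None
    )
    for section in ("qc", "assignment", "popgen", "fitness"):
        cfg[section] = _merge_section(section, raw.get(section) or {}, _DEFAULTS[section])
    cfg["output_dir"] = str(raw.get("output_dir", _DEFAULTS["output_dir"]))
    cfg["seed"] = int(raw.get("seed", _DEFAULTS["seed"]))
    # range checks (constructors re-validate downstream)
    for key in ("max_locus_missing", "max_indiv_missing"):
        if not 0 <= cfg["qc"][key] <= 1:
            raise ConfigError(f"qc.{key} must lie in [0, 1]")
    if not 0.5 < cfg["assignment"]["posterior_threshold"] <= 1.0:
        raise ConfigError("assignment.posterior_threshold must lie in (0.5, 1]")
    if cfg["popgen"]["n_permutations"] < 0:
        raise ConfigError("popgen.n_permutations must be >= 0")
    normalized = PipelineConfig(data=cfg)
    logger.info("config normalized, hash %s", normalized.config_hash)
    return normalized


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def run_pipeline(config: PipelineConfig | dict | str | Path, upto: str | None = None) -> dict:
    """Execute the pipeline and write all stage outputs.

    ``upto`` stops after the named stage (for the staged CLI subcommands).
    Returns a dict of in-memory results keyed by stage. On stage failure a
    :class:`PipelineStageError` names the stage; earlier outputs remain.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    if upto is not None and upto not in STAGES:
        raise ConfigError(f"unknown stage {upto!r}")
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config["seed"])
    results: dict[str, Any] = {"config_hash": config.config_hash}
    manifest: list[tuple[str, int]] = []

    def record(path: Path, n_rows: int) -> None:
        manifest.append((str(path.relative_to(out_dir)), n_rows))

    def done(stage: str) -> bool:
        return upto is not None and STAGES.index(stage) >= STAGES.index(upto)

    logger.info("pipeline start: hash=%s seed=%d", config.config_hash, config["seed"])

    # -- simulate / load -----------------------------------------------------
    stage = "simulate"
    try:
        if config["simulation"] is not None:
            sim_cfg = simdata.SimConfig(rng_seed=seeds["simulate"], **config["simulation"])
            genotypes, records, truth = simdata.simulate(sim_cfg)
            paths = simdata.write_fixture(genotypes, records, truth, out_dir / "sim")
            record(paths["genotypes_csv"], genotypes.n_individuals)
            record(paths["genotypes_dat"], -1)  # not a flat table
            record(paths["metadata_tsv"], genotypes.n_individuals)
            record(paths["truth_tsv"], len(truth.events))
            results["simulate"] = {"truth": truth, "sim_config": sim_cfg}
        else:
            inp = config["input"]
            genotypes = genotype_io.read_genotypes(inp["genotypes"], dialect=inp["dialect"])
            records = genotype_io.read_metadata_tsv(inp["metadata"])
        rec_frame = genotype_io.records_to_frame(records)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if done(stage):
        return results

    # -- qc ------------------------------------------------------------------
    stage = "qc"
    try:
        g_qc, qc_report = genotype_io.qc_filter(
            genotypes,
            max_locus_missing=config["qc"]["max_locus_missing"],
            max_indiv_missing=config["qc"]["max_indiv_missing"],
        )
        dup = genotype_io.find_duplicates(g_qc) if g_qc.n_individuals <= 5000 else []
        qc_path = out_dir / "qc_report.tsv"
        qc_report.to_frame().to_csv(qc_path, sep="\t", index=False)
        record(qc_path, len(qc_report.to_frame()))
        rec_frame = rec_frame.loc[g_qc.ids]
        results["qc"] = {"table": g_qc, "report": qc_report, "duplicates": dup}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if done(stage):
        return results

    # -- popgen --------------------------------------------------------------
    stage = "popgen"
    try:
        pg = config["popgen"]
        pops = rec_frame["patch"]
        div = popgen.diversity(g_qc, pops=pops)
        markers_path = out_dir / "marker_summary.tsv"
        div.markers.round(6).to_csv(markers_path, sep="\t")
        record(markers_path, len(div.markers))
        hs_path = out_dir / "hs_per_patch.tsv"
        div.hs.round(6).to_csv(hs_path, sep="\t")
        record(hs_path, len(div.hs))
        rng = np.random.default_rng(seeds["popgen"])
        fst_res = popgen.fst(
            g_qc, pops, n_perm=pg["n_permutations"],
            filter_hwe=pg["filter_hwe"], alpha=pg["hwe_alpha"], rng=rng,
        )
        fst_path = out_dir / "fst_pairwise.tsv"
        fst_res.pairwise.round(6).to_csv(fst_path, sep="\t")
        record(fst_path, len(fst_res.pairwise))
        per_year = None
        if pg["per_year_fst"]:
            per_year = popgen.fst_per_year(
                g_qc, pops, rec_frame, n_perm=0,
                filter_hwe=pg["filter_hwe"], alpha=pg["hwe_alpha"], rng=rng,
            )
            py_path = out_dir / "fst_per_year.tsv"
            per_year.round(6).to_csv(py_path, sep="\t")
            record(py_path, len(per_year))
        results["popgen"] = {"diversity": div, "fst": fst_res, "fst_per_year": per_year}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if done(stage):
        return results

    # -- assign --------------------------------------------------------------
    stage = "assign"
    try:
        a_cfg = parentage.AssignmentConfig(**config["assignment"])
        assign_res = parentage.assign_parents(g_qc, rec_frame, a_cfg)
        a_path = out_dir / "assignments.tsv"
        parentage.write_assignments_tsv(assign_res, a_path)
        record(a_path, len(assign_res.assignments))
        rates = parentage.assignment_rates(assign_res, rec_frame)
        r_path = out_dir / "assignment_rates.tsv"
        rates.to_csv(r_path, sep="\t", index=False)
        record(r_path, len(rates))
        results["assign"] = {"assignments": assign_res, "rates": rates}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if done(stage):
        return results

    # -- pedigree ------------------------------------------------------------
    stage = "pedigree"
    try:
        ped = pedigree.PedigreeGraph.from_assignments(assign_res, rec_frame)
        p_path = out_dir / "pedigree.tsv"
        ped.write_tsv(p_path)
        record(p_path, len(ped.nodes()))
        summary = pedigree.pedigree_summary(ped)
        s_path = out_dir / "pedigree_summary.tsv"
        summary.to_csv(s_path, sep="\t")
        record(s_path, len(summary))
        results["pedigree"] = {"graph": ped, "summary": summary}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if done(stage):
        return results

    # -- connect -------------------------------------------------------------
    stage = "connect"
    try:
        extraction = conn.events_from_pedigree(ped)
        ev_frame = conn.events_to_frame(extraction.events)
        e_path = out_dir / "dispersal_events.tsv"
        ev_frame.to_csv(e_path, sep="\t", index=False)
        record(e_path, len(ev_frame))
        report = conn.connectivity_stats(extraction.events)
        for name, p in conn.write_report(report, out_dir).items():
            record(p, -1)
        dists = conn.patch_distances(rec_frame)
        d_path = out_dir / "patch_distances.tsv"
        dists.round(1).to_csv(d_path, sep="\t", na_rep="NA")
        record(d_path, len(dists))
        try:
            rho, p_dd = conn.distance_decay(report.pairwise_pct, dists)
        except ValueError:
            rho, p_dd = float("nan"), float("nan")
        results["connect"] = {
            "events": extraction, "report": report,
            "patch_distances": dists, "distance_decay": (rho, p_dd),
        }
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    if done(stage):
        return results

    # -- fitness / demography ------------------------------------------------
    stage = "fitness"
    try:
        census = demofit.census_counts(rec_frame)
        growth = demofit.growth_rates(census)
        g_path = out_dir / "growth_rates.tsv"
        growth.to_frame().round(3).to_csv(g_path, sep="\t", na_rep="NA")
        record(g_path, len(growth.to_frame()))
        fr = demofit.fitness_records(
            ped, ev_frame, last_years_excluded=config["fitness"]["last_years_excluded"]
        )
        f_path = out_dir / "fitness_records.tsv"
        fr.to_csv(f_path, sep="\t", index=False)
        record(f_path, len(fr))
        model = None
        if len(fr) and (fr["status"] == "migrant").any() and (fr["status"] == "resident").any():
            model = demofit.fitness_model(fr)
            m_path = out_dir / "fitness_model.tsv"
            model.summary_frame().round(6).to_csv(m_path, sep="\t")
            record(m_path, len(model.summary_frame()))
        results["fitness"] = {"growth": growth, "records": fr, "model": model}
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # -- summary + manifest --------------------------------------------------
    summary_lines = [
        f"config_hash\t{config.config_hash}",
        f"seed\t{config['seed']}",
        f"individuals_after_qc\t{g_qc.n_individuals}",
        f"loci_after_qc\t{g_qc.n_loci}",
        f"mean_Hs\t{div.hs['Hs'].mean():.4f}",
        f"cumulative_PPexp\t{div.cumulative_ppexp:.6f}",
        f"global_fst\t{fst_res.theta:.4f}",
        f"n_triads\t{len(ped.parents)}",
        f"global_connectivity_pct\t{report.global_pct:.2f}",
        f"mean_seed_distance_m\t{ev_frame['seed_distance'].mean():.2f}",
        (
            "mean_between_pollen_distance_m\t"
            + (
                f"{ev_frame.loc[ev_frame['between_patch'], 'pollen_distance'].mean():.1f}"
                if report.n_between
                else "NA"
            )
        ),
        f"distance_decay_rho\t{results['connect']['distance_decay'][0]:.3f}",
    ]
    if model is not None:
        summary_lines.append(f"fitness_rate_ratio\t{model.rate_ratio:.3f}")
    summary_path = out_dir / "summary.txt"
    summary_path.write_text("\n".join(summary_lines) + "\n")
    manifest_frame = pd.DataFrame(manifest, columns=["file", "n_rows"])
    manifest_frame.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    results["summary_path"] = summary_path
    results["manifest"] = manifest_frame
    logger.info("pipeline complete: %s", summary_path)
    return results
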
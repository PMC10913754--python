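"""End-to-end pipeline orchestration from a single YAML config.

A run either simulates a scenario or loads table/tree/metadata files,
aligns them, standardizes, and executes the enabled analysis stages in
dependency order, writing one TSV per result plus a JSON manifest with
the sha256 checksum of every output — runs are byte-reproducible from
(config, seed).
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from ._rng import derive_seed
from .containers import CommunityTable
from .diversity import alpha_diversity, bray_curtis_matrix, pcoa, standardize_table
from .errors import ValidationError
from .groupstats import permanova
from .io import (
    align_inputs,
    read_community_table,
    read_newick_tree,
    read_sample_metadata,
    write_community_table,
    write_distance_matrix,
    write_newick_tree,
    write_sample_metadata,
)
from .nullmodels import (
    assembly_long_table,
    bnti_matrix,
    classify_assembly,
    rc_bray_matrix,
    summarize_process_fractions,
    zone_strata,
)
from .simulate import ScenarioSpec, simulate_scenario
from .spatial import distance_decay, environmental_distance, haversine_matrix, mantel_test

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "table", "tree", "metadata", "scenario", "outdir", "seed",
    "standardization", "rarefaction_depth",
    "alpha", "pcoa", "permanova_terms", "mantel_variables",
    "distance_decay", "assembly", "n_perm", "n_null",
}


@dataclass
class RunConfig:
    """Validated, defaulted pipeline configuration."""

    outdir: str
    seed: int
    table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    scenario: ScenarioSpec | None = None
    standardization: str = "relative"
    rarefaction_depth: int | None = None
    alpha: bool = True
    pcoa: bool = True
    permanova_terms: list[str] = field(default_factory=lambda: ["irradiance_zone"])
    mantel_variables: list[str] = field(default_factory=list)
    distance_decay: bool = False
    assembly: bool = True
    n_perm: int = 999
    n_null: int = 999

    def __post_init__(self) -> None:
        has_paths = self.table is not None
        has_scenario = self.scenario is not None
        if has_paths == has_scenario:
            raise ValidationError(
                "exactly one of an input table or a simulation scenario is required")
        if self.n_perm < 1 or self.n_null < 1:
            raise ValidationError("n_perm and n_null must be positive")
        if self.standardization not in ("relative", "rarefy"):
            raise ValidationError("standardization must be 'relative' or 'rarefy'")
        if self.assembly and not has_scenario and self.tree is None:
            raise ValidationError("assembly stage requires a tree")


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected
    with a suggestion for the closest known key."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ValidationError("run config must be a YAML mapping")
    for key in payload:
        if key not in _KNOWN_KEYS:
            hint = difflib.get_close_matches(key, _KNOWN_KEYS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(f"unknown config key {key!r}{suffix}")
    if "seed" not in payload:
        raise ValidationError("config must set a seed (stochastic stages are enabled)")
    if "outdir" not in payload:
        raise ValidationError("config must set outdir")
    scenario = payload.pop("scenario", None)
    if scenario is not None:
        scenario = ScenarioSpec(**scenario)
    return RunConfig(scenario=scenario, **payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    outputs: dict[str, str] = {}
    stage_log: list[str] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs[name] = _sha256(path)

    current = "inputs"
    try:
        if config.scenario is not None:
            tree, traits, meta, table = simulate_scenario(config.scenario)
            emit("table.tsv", lambda p: write_community_table(table, p))
            emit("tree.nwk", lambda p: write_newick_tree(tree, p))
            emit("metadata.tsv", lambda p: write_sample_metadata(meta, p))
            emit("traits.tsv", lambda p: traits.to_csv(p, sep="\t", header=True))
        else:
            table = read_community_table(config.table)
            tree = read_newick_tree(config.tree) if config.tree else None
            meta = read_sample_metadata(config.metadata) if config.metadata else None
        stage_log.append(current)

        current = "align"
        table, tree, meta = align_inputs(table, tree, meta)
        stage_log.append(current)

        current = "standardize"
        std = standardize_table(table, config.standardization,
                                depth=config.rarefaction_depth,
                                seed=derive_seed(config.seed, 10))
        emit("table_standardized.tsv", lambda p: write_community_table(std, p))
        stage_log.append(current)

        if config.alpha:
            current = "alpha"
            alpha = alpha_diversity(table, tree)
            emit("alpha_diversity.tsv",
                 lambda p: alpha.to_csv(p, sep="\t", index_label="sample_id"))
            stage_log.append(current)

        current = "bray_curtis"
        bc = bray_curtis_matrix(std)
        emit("bray_curtis.tsv", lambda p: write_distance_matrix(bc, p))
        stage_log.append(current)

        if config.pcoa:
            current = "pcoa"
            ord_res = pcoa(bc)
            emit("pcoa_coordinates.tsv",
                 lambda p: ord_res.coordinates.to_csv(p, sep="\t", index_label="sample_id"))
            eig = pd.DataFrame({
                "eigenvalue": ord_res.eigenvalues,
            })
            emit("pcoa_eigenvalues.tsv", lambda p: eig.to_csv(p, sep="\t", index_label="axis"))
            stage_log.append(current)

        if config.permanova_terms and meta is not None:
            current = "permanova"
            rows = []
            for term in config.permanova_terms:
                if term not in meta.columns or meta[term].nunique() < 2:
                    log.info("permanova: skipping term %r (absent or constant)", term)
                    continue
                counts = meta[term].value_counts()
                if (counts < 2).any():
                    log.info("permanova: skipping term %r (singleton group)", term)
                    continue
                res = permanova(bc, meta[term], n_perm=config.n_perm,
                                seed=derive_seed(config.seed, 11), term=term)
                rows.append(asdict(res))
            if rows:
                emit("permanova.tsv",
                     lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
            stage_log.append(current)

        if config.distance_decay and meta is not None:
            current = "distance_decay"
            geo = haversine_matrix(meta)
            if float(geo.to_numpy().max()) == 0.0:
                log.info("distance_decay: all samples co-located, stage skipped")
            else:
                dd = distance_decay(bc, geo)
                emit("distance_decay.tsv",
                     lambda p: pd.DataFrame([asdict(dd)]).to_csv(p, sep="\t", index=False))
            stage_log.append(current)

        if config.mantel_variables and meta is not None:
            current = "mantel"
            rows = []
            for var in config.mantel_variables:
                env = environmental_distance(meta, [var])
                shared = [s for s in bc.index if s in env.index]
                res = mantel_test(bc.loc[shared, shared], env.loc[shared, shared],
                                  n_perm=config.n_perm, seed=derive_seed(config.seed, 12))
                rows.append(dict(variable=var, **asdict(res)))
            emit("mantel.tsv", lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
            stage_log.append(current)

        if config.assembly:
            current = "assembly"
            bn = bnti_matrix(std, tree, n_null=config.n_null,
                             seed=derive_seed(config.seed, 13))
            rc = rc_bray_matrix(table, n_null=config.n_null,
                                seed=derive_seed(config.seed, 14))
            result = classify_assembly(bn, rc)
            strata = zone_strata(meta) if (
                meta is not None and "irradiance_zone" in meta.columns) else None
            long = assembly_long_table(result, strata)
            emit("assembly_pairs.tsv", lambda p: long.to_csv(p, sep="\t", index=False))
            summary = summarize_process_fractions(result, strata)
            emit("assembly_summary.tsv", lambda p: summary.to_csv(p, sep="\t"))
            stage_log.append(current)
    except Exception:
        (outdir / "FAILED").write_text(
            f"stage: {current}\ncompleted: {stage_log}\n")
        log.error("pipeline failed at stage %r", current)
        raise

    manifest = dict(
        stages=stage_log,
        outputs=outputs,
        settings=dict(
            seed=config.seed, n_perm=config.n_perm, n_null=config.n_null,
            standardization=config.standardization,
            scenario=(asdict(config.scenario) if config.scenario else None),
            inputs={k: getattr(config, k) for k in ("table", "tree", "metadata")},
        ),
        elapsed_s=round(time.time() - t_start, 3),
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
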
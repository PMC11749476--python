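"""Configured end-to-end runs: simulate -> score -> screen -> overlap.

The pipeline is driven by a single YAML config (see `example_config`)
whose sections map onto the library layers: input paths, walk parameters,
screening thresholds, and the synthetic-fixture generator. All outputs are
deterministic functions of the config, including the fixture RNG seed.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .network import (
    PPINetwork,
    read_edge_list,
    read_gene_list,
    read_ortholog_map,
    normalize_symbol,
)
from .rwr import RWRParams, score_contexts
from .screen import (
    ScreenParams,
    ScreenResult,
    map_deg_genes,
    read_deg_table,
    run_screen,
    secretory_fraction,
    write_ahg_set,
    write_screen_result,
)
from .synthetic import FixtureConfig, generate_fixture

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "load_config",
    "simulate",
    "run",
    "evaluate_recovery",
]

_SECTION_KEYS = {
    "networks": None,  # free-form mapping species -> path
    "deg_table": str,
    "secretome": str,
    "ortholog_map": str,
    "output_dir": str,
    "min_edge_weight": float,
    "rwr": {"restart_prob", "tol", "max_iter"},
    "screen": {"affinity_threshold", "top_k", "aggregation"},
    "fixture": {f.name for f in FixtureConfig.__dataclass_fields__.values()},
}


class ConfigError(ValueError):
    """Raised for unknown or ill-typed configuration keys."""


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and schema-check a pipeline YAML config."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = sorted(set(cfg) - set(_SECTION_KEYS))
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {unknown}")
    for section in ("rwr", "screen", "fixture"):
        sub = cfg.get(section) or {}
        if not isinstance(sub, Mapping):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        bad = sorted(set(sub) - _SECTION_KEYS[section])
        if bad:
            raise ConfigError(f"{path}: unknown keys in {section!r}: {bad}")
    return dict(cfg)


def _fixture_config(cfg: Mapping[str, Any]) -> FixtureConfig:
    section = dict(cfg.get("fixture") or {})
    if "rng_seed" not in section:
        logger.info("fixture.rng_seed not given; defaulting to 0")
    try:
        return FixtureConfig(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid fixture section: {exc}") from exc


def simulate(cfg: Mapping[str, Any]) -> dict[str, Path]:
    """Generate fixture files under ``output_dir`` plus a ready run config.

    Returns the mapping of artifact names to paths; ``run_config`` points
    at a YAML that feeds the generated files straight back into ``run``.
    """
    from .synthetic import write_fixture

    out_dir = Path(cfg.get("output_dir", "fixture_out"))
    fixture_cfg = _fixture_config(cfg)
    bundle = generate_fixture(fixture_cfg)
    paths = write_fixture(bundle, out_dir)
    run_cfg = {
        "networks": {
            sp: str(paths[f"network_{sp}"]) for sp in bundle.networks
        },
        "deg_table": str(paths["deg_table"]),
        "secretome": str(paths["secretome"]),
        "ortholog_map": str(paths["ortholog_map"]),
        "output_dir": str(out_dir / "screen"),
        "rwr": dict(cfg.get("rwr") or {}),
        "screen": dict(cfg.get("screen") or {}),
    }
    run_cfg_path = out_dir / "run_config.yaml"
    run_cfg_path.write_text(yaml.safe_dump(run_cfg, sort_keys=True))
    paths["run_config"] = run_cfg_path
    logger.info("planted truth written to %s", paths["truth"])
    return paths


def _load_inputs(
    cfg: Mapping[str, Any]
) -> tuple[dict[str, PPINetwork], pd.DataFrame, tuple[str, ...]]:
    nets_cfg = cfg.get("networks")
    if not nets_cfg:
        raise ConfigError("config key 'networks' (species -> edge list path) is required")
    min_w = float(cfg.get("min_edge_weight", 0.0))
    mapping = {}
    if cfg.get("ortholog_map"):
        mapping = read_ortholog_map(cfg["ortholog_map"])
    networks = {}
    for species, path in nets_cfg.items():
        net = read_edge_list(path, min_weight=min_w)
        if mapping:
            net = net.relabel(mapping)
        networks[str(species).upper()] = net
    deg_table = read_deg_table(cfg["deg_table"])
    deg_table["species"] = deg_table["species"].str.upper()
    if mapping:
        deg_table = map_deg_genes(deg_table, mapping)
    secretome = read_gene_list(cfg["secretome"])
    if mapping:
        secretome = tuple(
            sorted({normalize_symbol(mapping.get(g, g)) for g in secretome})
        )
    return networks, deg_table, secretome


def run(
    cfg: Mapping[str, Any],
    overrides: Mapping[str, Any] | None = None,
) -> tuple[ScreenResult, dict[str, Path]]:
    """Execute the full screen and write its artifacts.

    Writes ``screen_result.tsv``, ``ahg_set.txt``, ``secretory_fraction.tsv``
    and ``run_log.txt`` under ``output_dir``. ``overrides`` may replace
    restart_prob, affinity_threshold or top_k (CLI flags beat config keys).
    """
    overrides = dict(overrides or {})
    out_dir = Path(cfg.get("output_dir", "screen_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ahgscreen")
    prior_level = root.level
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        rwr_section = dict(cfg.get("rwr") or {})
        if "restart_prob" in overrides and overrides["restart_prob"] is not None:
            rwr_section["restart_prob"] = overrides["restart_prob"]
        rwr_params = RWRParams(**rwr_section)
        screen_section = dict(cfg.get("screen") or {})
        for key in ("affinity_threshold", "top_k"):
            if overrides.get(key) is not None:
                screen_section[key] = overrides[key]
        screen_params = ScreenParams(**screen_section)
        logger.info("walk parameters: %s", rwr_params)
        logger.info("screen parameters: %s", screen_params)

        networks, deg_table, secretome = _load_inputs(cfg)
        profiles = score_contexts(networks, deg_table, rwr_params)
        for prof in profiles:
            if prof.dropped_seeds:
                logger.info(
                    "context %s: dropped off-network seeds %s",
                    prof.context,
                    list(prof.dropped_seeds),
                )
        result = run_screen(profiles, secretome, screen_params)
        logger.info("candidate category counts: %s", result.category_counts())
        logger.info("final hub-gene set (%d): %s", len(result.ahgs or ()), result.ahgs)

        paths = {
            "screen_result": out_dir / "screen_result.tsv",
            "ahg_set": out_dir / "ahg_set.txt",
            "secretory_fraction": out_dir / "secretory_fraction.tsv",
            "run_log": log_path,
        }
        write_screen_result(result, paths["screen_result"])
        write_ahg_set(result, paths["ahg_set"])
        frac = secretory_fraction(result)
        with paths["secretory_fraction"].open("w") as fh:
            fh.write("species\tsecretory_fraction\n")
            for species, value in frac.items():
                fh.write(f"{species}\t{'NA' if pd.isna(value) else f'{value:.6f}'}\n")
        return result, paths
    finally:
        root.removeHandler(handler)
        root.setLevel(prior_level)
        handler.close()


def evaluate_recovery(
    predicted: tuple[str, ...] | set[str], truth: tuple[str, ...] | set[str]
) -> dict[str, float | None]:
    """Precision and recall of the predicted hub set against the planted truth.

    Precision is undefined (None) for an empty prediction; recall is
    undefined for an empty truth set.
    """
    pred = {normalize_symbol(g) for g in predicted}
    true = {normalize_symbol(g) for g in truth}
    hits = len(pred & true)
    return {
        "n_predicted": len(pred),
        "n_truth": len(true),
        "n_hits": hits,
        "precision": hits / len(pred) if pred else None,
        "recall": hits / len(true) if true else None,
    }


def write_recovery_report(report: Mapping[str, Any], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in report.items():
            fh.write(f"{key}\t{'NA' if value is None else value}\n")
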
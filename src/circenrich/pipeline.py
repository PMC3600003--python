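"""End-to-end orchestration: simulate/load → annotate → nulls → model.

The pipeline is configured by a single YAML mapping (see
:data:`CONFIG_SCHEMA` for the recognized keys) and writes a result bundle:
enrichment TSVs for the permutation and sampling nulls for both SNP sets
(significant and suggestive, produced from one status assignment), a model
TSV, and a JSON run manifest recording the config snapshot, seeds, input
digests and per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (
    LdConfig,
    SnpCatalog,
    Status,
    StatusConfig,
    assign_association_status,
    read_annotation_bed,
    read_ld_pairs,
    read_snp_table,
    write_enrichment_table,
    write_snp_table,
)
from .model import fit_logistic, lr_deviance_test, pseudo_r2, stepwise_aic
from .overlap import compute_overlap_matrix
from .permutation import PermutationConfig, permutation_enrichment, run_permutations
from .sampling import SamplingConfig, run_sampling
from .simulate import SimConfig, TrackSpec, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["CONFIG_SCHEMA", "load_config", "run_pipeline"]

# recognized keys, their types, and defaults (None = required/optional input)
CONFIG_SCHEMA: dict[str, dict] = {
    "inputs": {
        "snp_table": str,
        "ld_pairs": str,
        "tracks": dict,  # name -> bed path
    },
    "simulate": {
        "n_chromosomes": int,
        "snps_per_chromosome": int,
        "chromosome_length": int,
        "n_assoc": int,
        "planted_or": dict,
        "tracks": list,  # of {name, target_coverage, mean_length, clustering}
        "seed": int,
    },
    "status": {
        "genomewide_threshold": float,
        "suggestive_upper": float,
        "excluded_chromosomes": list,
        "prune_suggestive_r2": float,
    },
    "ld": {"r2_threshold": float, "max_pair_distance": int},
    "permutation": {"n_permutations": int, "seed": int, "ci_mode": str, "tail_mode": str},
    "sampling": {"n_samples": int, "seed": int, "exclude_associated": bool},
    "model": {"enabled": bool, "blacklist": list, "platform_columns": bool},
    "report": {"bonferroni_alpha": float, "n_tests": int},
}


class ConfigError(ValueError):
    """Raised before any computation when the config violates the schema."""


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    for section, content in cfg.items():
        if section not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in content.items():
            if key not in CONFIG_SCHEMA[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            expected = CONFIG_SCHEMA[section][key]
            if expected is int and isinstance(value, bool):
                raise ConfigError(f"{section}.{key} must be {expected.__name__}")
            if expected is float and isinstance(value, int) and not isinstance(value, bool):
                continue
            if not isinstance(value, expected):
                raise ConfigError(f"{section}.{key} must be {expected.__name__}")
    if "inputs" in cfg and "simulate" in cfg:
        raise ConfigError("give either 'inputs' or 'simulate', not both")
    if "inputs" not in cfg and "simulate" not in cfg:
        raise ConfigError("config needs an 'inputs' or 'simulate' section")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _sim_config(section: dict) -> SimConfig:
    kwargs = dict(section)
    if "tracks" in kwargs:
        kwargs["tracks"] = tuple(TrackSpec(**t) for t in kwargs["tracks"])
    return SimConfig(**kwargs)


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute the configured pipeline; returns the manifest dict.

    Outputs land in ``outdir``: ``enrichment_{perm,sample}_{significant,
    suggestive}.tsv``, ``model.tsv``, ``catalog.tsv`` and
    ``manifest.json``.  A stage failure keeps earlier outputs and is noted
    in the manifest.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "circenrich",
        "version": __version__,
        "config": cfg,
        "inputs": {},
        "timings_s": {},
        "outputs": [],
        "failure": None,
    }
    ld_cfg = LdConfig(**cfg.get("ld", {}))
    status_cfg = StatusConfig(
        **{
            k: (frozenset(v) if k == "excluded_chromosomes" else v)
            for k, v in cfg.get("status", {}).items()
        }
    )
    t0 = time.perf_counter()
    if "simulate" in cfg:
        sim_cfg = _sim_config(cfg["simulate"])
        catalog, ld, tracks, matrix, status, truth = simulate_study(sim_cfg, ld_cfg)
        manifest["inputs"]["simulated"] = {"seed": sim_cfg.seed}
        manifest["ground_truth"] = {
            tr: {"table": vars(t)} for tr, t in truth.items()
        }
    else:
        inp = cfg["inputs"]
        catalog = read_snp_table(inp["snp_table"])
        ld = read_ld_pairs(inp["ld_pairs"], ld_cfg, catalog)
        tracks = [read_annotation_bed(p, name) for name, p in inp["tracks"].items()]
        catalog = assign_association_status(catalog, status_cfg, ld)
        matrix = compute_overlap_matrix(catalog, ld, tracks)
        for name, p in {"snp_table": inp["snp_table"], "ld_pairs": inp["ld_pairs"],
                        **inp["tracks"]}.items():
            manifest["inputs"][name] = _digest(Path(p))
    manifest["timings_s"]["annotate"] = round(time.perf_counter() - t0, 3)
    write_snp_table(catalog, outdir / "catalog.tsv")
    manifest["outputs"].append("catalog.tsv")

    report = cfg.get("report", {})
    alpha = report.get("bonferroni_alpha", 0.05)
    n_tests = report.get("n_tests", len(matrix.annotations))

    snp_sets = {"significant": catalog.status_array(Status.SIGNIFICANT)}
    sug = catalog.status_array(Status.SUGGESTIVE)
    if sug.any():
        snp_sets["suggestive"] = sug

    perm_cfg = PermutationConfig(**cfg.get("permutation", {}))
    samp_cfg = SamplingConfig(**cfg.get("sampling", {}))
    slices = catalog.chrom_slices()
    try:
        for set_name, mask in snp_sets.items():
            if not mask.any():
                continue
            t0 = time.perf_counter()
            nulls = run_permutations(matrix, mask, slices, perm_cfg)
            results = [permutation_enrichment(nd, perm_cfg) for nd in nulls]
            path = outdir / f"enrichment_perm_{set_name}.tsv"
            write_enrichment_table(results, path, bonferroni_alpha=alpha, n_tests=n_tests)
            manifest["outputs"].append(path.name)
            manifest["timings_s"][f"enrich_perm_{set_name}"] = round(
                time.perf_counter() - t0, 3
            )
            t0 = time.perf_counter()
            results = run_sampling(matrix, catalog, mask, samp_cfg)
            path = outdir / f"enrichment_sample_{set_name}.tsv"
            write_enrichment_table(results, path, bonferroni_alpha=alpha, n_tests=n_tests)
            manifest["outputs"].append(path.name)
            manifest["timings_s"][f"enrich_sample_{set_name}"] = round(
                time.perf_counter() - t0, 3
            )
        if cfg.get("model", {}).get("enabled", True):
            t0 = time.perf_counter()
            _run_model_stage(cfg, catalog, matrix, outdir, manifest)
            manifest["timings_s"]["model"] = round(time.perf_counter() - t0, 3)
    except Exception as e:  # keep partial outputs, note the failure
        logger.exception("pipeline stage failed")
        manifest["failure"] = f"{type(e).__name__}: {e}"
    manifest["seeds"] = {"permutation": perm_cfg.seed, "sampling": samp_cfg.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if manifest["failure"]:
        raise RuntimeError(f"pipeline failed after partial output: {manifest['failure']}")
    return manifest


def _run_model_stage(cfg, catalog: SnpCatalog, matrix, outdir: Path, manifest: dict) -> None:
    import pandas as pd

    status = catalog.status_array(Status.SIGNIFICANT)
    data = pd.DataFrame(
        {a: matrix.column(a).astype(float) for a in matrix.annotations}
    )
    forced = []
    if cfg.get("model", {}).get("platform_columns", True):
        groups = sorted({g for s in catalog.df["platform_groups"] for g in s})
        for g in groups:
            col = np.fromiter(
                (g in s for s in catalog.df["platform_groups"]), bool, len(catalog)
            ).astype(float)
            if 0 < col.mean() < 1:
                data[f"platform_{g}"] = col
                forced.append(f"platform_{g}")
    blacklist = set(cfg.get("model", {}).get("blacklist", []))
    step_log: list = []
    fit_full = stepwise_aic(status, data, forced, list(matrix.annotations),
                            blacklist=blacklist, step_log=step_log)
    fit_empty = fit_logistic(status, data[forced], forced_terms=forced)
    r2 = pseudo_r2(fit_empty, fit_full)
    comparison = (
        lr_deviance_test(fit_empty, fit_full)
        if len(fit_full.terms) > len(fit_empty.terms)
        else None
    )
    with open(outdir / "model.tsv", "w", encoding="utf-8") as fh:
        fh.write("term\testimate\tstd_error\tbeta_coefficient\tpvalue\tforced\n")
        for t in fit_full.terms:
            fh.write(
                f"{t.name}\t{t.estimate:.6g}\t{t.se:.6g}\t{t.beta_coefficient:.6g}"
                f"\t{t.pvalue:.6g}\t{t.name in fit_full.forced_terms}\n"
            )
    with open(outdir / "model_steps.tsv", "w", encoding="utf-8") as fh:
        fh.write("action\tterm\taic\n")
        for action, term, aic in step_log:
            fh.write(f"{action}\t{term or ''}\t{aic:.6g}\n")
    manifest["outputs"] += ["model.tsv", "model_steps.tsv"]
    manifest["model"] = {
        "aic": fit_full.aic,
        "mcfadden": r2.mcfadden,
        "mckelvey_zavoina": r2.mckelvey_zavoina,
        "deviance": comparison.deviance if comparison else 0.0,
        "deviance_p": comparison.pvalue if comparison else 1.0,
        "separation_flag": fit_full.separation_flag,
    }
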
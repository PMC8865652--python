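"""End-to-end orchestration: metrics -> screen -> PGLS -> report.

The analysis runs independently per taxon group: compute per-matrix
metrics and species means, screen the 14 metrics with the conditional
permutation-importance forest, then quantify the selected predictors'
effects on Red List rank with Pagel-lambda PGLS (starting from all
interactions and pruning the non-significant ones). When the screen
selects nothing the PGLS stage is skipped and reported as such.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import (
    build_species_table,
    coverage_summary,
    read_mpm_table,
    read_status_table,
)
from .mpm import METRIC_NAMES
from .pgls import (
    PGLSError,
    build_design,
    consensus_tree,
    phylo_covariance,
    prune_interactions,
    read_trees,
)
from .screen import ForestConfig, screen

logger = logging.getLogger("mpmrisk")

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run"]

#: Minimum number of assessed species required to attempt the analysis.
MIN_ASSESSED = 10


@dataclass
class PipelineConfig:
    matrix_table: str
    status_table: str
    trees: str  # newick file, one or more trees (samples) per line
    output_dir: str
    taxon_group: str | None = None  # None = all species pooled
    seed: int = 0
    n_trees: int = 1000
    mtry: int = 4
    min_node_size: int = 5
    conditional_threshold: float = 0.2
    pgls_method: str = "REML"
    alpha: float = 0.05
    lambda_bounds: tuple[float, float] = (0.0, 1.0)
    include_clonal_recruitment: bool = False
    log_level: str = "INFO"

    def forest_config(self) -> ForestConfig:
        return ForestConfig(
            n_trees=self.n_trees,
            mtry=self.mtry,
            min_node_size=self.min_node_size,
            conditional_threshold=self.conditional_threshold,
            seed=self.seed,
        )

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (not output paths)."""
        fields = {k: v for k, v in asdict(self).items()
                  if k not in ("output_dir", "log_level")}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _check_paths(config: PipelineConfig) -> None:
    for attr in ("matrix_table", "status_table", "trees"):
        p = Path(getattr(config, attr))
        if not p.exists():
            raise FileNotFoundError(f"{attr} file not found: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full per-taxon analysis and write the results bundle.

    Returns a dict with the species table, importance result, PGLS
    result (or None) and coverage summary; the same content is written
    to ``config.output_dir`` as CSV/JSON artifacts plus a manifest
    carrying the seed and a config hash.
    """
    logging.basicConfig(level=config.log_level)
    _check_paths(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(config.log_level)

    try:
        return _run(config, out)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    models, parse_log = read_mpm_table(config.matrix_table)
    statuses = read_status_table(config.status_table)
    trees = read_trees(config.trees)

    if config.taxon_group is not None:
        models = [m for m in models if m.taxon_group == config.taxon_group]

    species_table, exclusion_log = build_species_table(
        models,
        statuses,
        include_clonal_recruitment=config.include_clonal_recruitment,
    )
    coverage = coverage_summary(models, statuses)

    assessed = species_table.dropna(subset=["iucn_rank"])
    if len(assessed) < MIN_ASSESSED:
        raise PGLSError(
            f"only {len(assessed)} assessed species after filtering "
            f"(need at least {MIN_ASSESSED})"
        )

    X = assessed[list(METRIC_NAMES)]
    y = assessed["iucn_rank"]
    imp = screen(X.set_axis(assessed["species_id"]), y, config.forest_config())
    logger.info("screen selected: %s", imp.selected or "none")

    pgls_result = None
    pgls_species = []
    if imp.selected:
        complete = assessed[
            assessed[list(METRIC_NAMES)].notna().all(axis=1)
        ].reset_index(drop=True)
        tree = consensus_tree(trees)
        tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = sorted(set(complete["species_id"]) - tip_labels)
        if missing:
            raise PGLSError(
                f"species absent from the tree: {missing[:10]}"
                + (" ..." if len(missing) > 10 else "")
            )
        pgls_species = list(complete["species_id"])
        sub = tree.extract_tree_with_taxa_labels(pgls_species)
        C, labels = phylo_covariance(sub, pgls_species)
        design = build_design(complete, imp.selected)
        pgls_result = prune_interactions(
            design,
            complete["iucn_rank"].to_numpy(float),
            C,
            alpha=config.alpha,
            method=config.pgls_method,
        )

    bundle = {
        "species_table": species_table,
        "importance": imp,
        "pgls": pgls_result,
        "pgls_species": pgls_species,
        "coverage": coverage,
        "exclusions": exclusion_log + parse_log,
        "config": config,
    }
    _write_bundle(bundle, out)
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    config: PipelineConfig = bundle["config"]
    bundle["species_table"].to_csv(out / "species_metrics.csv", index=False)
    bundle["coverage"].to_csv(out / "coverage.csv", index=False)
    imp = bundle["importance"]
    imp.to_frame().to_csv(out / "importance.csv", index=False)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "selected": imp.selected,
        "importance_threshold": imp.threshold,
        "n_species_screen": imp.n_used,
        "n_dropped_screen": imp.n_dropped,
    }
    if bundle["pgls"] is not None:
        res = bundle["pgls"]
        res.coef_table().to_csv(out / "pgls_coefficients.csv", index=False)
        summary.update(
            {
                "pgls": {
                    "terms": res.terms,
                    "lambda_hat": res.lambda_hat,
                    "loglik": res.loglik,
                    "var_explained": res.var_explained,
                    "n": res.n,
                    "method": res.method,
                    "pruning_trace": res.pruning_trace,
                }
            }
        )
    else:
        summary["pgls"] = None
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(bundle["exclusions"], fh, indent=2)
    manifest = {
        "mpmrisk_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": asdict(config),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "report.md", "w") as fh:
        fh.write(summarize_run(bundle))


def summarize_run(bundle: dict) -> str:
    """Human-readable markdown report for one pipeline run."""
    config: PipelineConfig = bundle["config"]
    st = bundle["species_table"]
    imp = bundle["importance"]
    lines = [
        "# Extinction-risk correlates: run report",
        "",
        f"- seed: {config.seed}",
        f"- config hash: {config.digest()}",
        f"- taxon group: {config.taxon_group or 'all'}",
        "",
        "## Species per Red List rank",
        "",
    ]
    counts = (
        st.dropna(subset=["iucn_rank"])["iucn_rank"].astype(int).value_counts()
    )
    for rank in range(1, 6):
        lines.append(f"- rank {rank}: {int(counts.get(rank, 0))} species")
    lines.append(f"- unassessed: {int(st['iucn_rank'].isna().sum())} species")
    lines += ["", "## Importance screen", ""]
    if imp.selected:
        lines.append(
            f"Selected predictors (threshold {imp.threshold:.4g}): "
            + ", ".join(imp.selected)
        )
    else:
        lines.append("No significant predictors: the highest importance "
                     "value did not exceed twice the magnitude of the "
                     "largest negative value.")
    res = bundle["pgls"]
    lines += ["", "## PGLS", ""]
    if res is None:
        lines.append("Skipped (no predictors selected by the screen).")
    else:
        lines.append(res.coef_table().to_string(index=False))
        lines += [
            "",
            f"- Pagel's lambda: {res.lambda_hat:.3f}",
            f"- variance explained: {100 * res.var_explained:.1f}%",
            f"- n species: {res.n}",
        ]
    lines += ["", "## Assessment coverage", ""]
    lines.append(bundle["coverage"].to_string(index=False))
    lines.append("")
    return "\n".join(lines)
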
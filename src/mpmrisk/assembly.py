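"""Dataset assembly: matrix tables, retention rules and species records.

The analysis dataset joins three sources: a table of stage matrices
(one row per population matrix, COMPADRE/COMADRE style), an IUCN status
table, and a phylogeny. This module reads and writes the tabular
pieces, applies the retention and matrix-selection rules, averages
per-matrix metrics to species level, codes Red List status as an
ordinal rank, and tabulates assessment coverage per taxon group.

Retention rules: a matrix is kept only if it carries fecundity
information (F has a positive entry), splits validly into U/F/C, and
has an annual time step. Within a species, individual population
matrices are preferred; only when a species has none are mean matrices
used, and pooled matrices only as a last resort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mpm import (
    METRIC_NAMES,
    MPMError,
    StageMatrixModel,
    compute_metrics,
    validate_model,
)

__all__ = [
    "SpeciesRecord",
    "TAXON_GROUPS",
    "IUCN_RANKS",
    "iucn_rank",
    "read_mpm_table",
    "write_mpm_table",
    "read_status_table",
    "write_status_table",
    "select_matrices",
    "aggregate_species",
    "build_species_table",
    "coverage_summary",
]

TAXON_GROUPS = ("herb", "tree", "bird", "mammal")

#: Ordinal coding of the five modeled Red List categories.
IUCN_RANKS = {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5}

_KIND_PREFERENCE = ("individual", "mean", "pooled")

_FIELD_SEP = ";"


@dataclass
class SpeciesRecord:
    """Species-level mean metrics joined to taxon group and IUCN rank."""

    species_id: str
    taxon_group: str
    metrics: dict[str, float]
    n_matrices: int
    iucn_rank: int | None = None
    metric_missing_counts: dict[str, int] = field(default_factory=dict)


def iucn_rank(status: str) -> int | None:
    """Map a Red List token to its ordinal rank (LC=1 ... CR=5).

    Tokens outside the five modeled categories (DD, NE, EW, EX or
    anything unrecognized) return None: the species counts as
    unassessed for modeling but is retained for coverage reporting.
    """
    return IUCN_RANKS.get(str(status).strip().upper())


def _ser(M: np.ndarray) -> str:
    return _FIELD_SEP.join(repr(float(x)) for x in np.asarray(M).ravel())


def _deser(text: str, s: int) -> np.ndarray:
    vals = [float(x) for x in str(text).split(_FIELD_SEP)]
    if len(vals) != s * s:
        raise MPMError(f"expected {s * s} matrix entries, got {len(vals)}")
    return np.array(vals).reshape(s, s)


def write_mpm_table(models: list[StageMatrixModel], path) -> None:
    """Write models to CSV, one row per matrix (row-major U/F/C blocks)."""
    rows = []
    for m in models:
        rows.append(
            {
                "species_id": m.species_id,
                "taxon_group": m.taxon_group,
                "matrix_kind": m.matrix_kind,
                "annual": m.annual,
                "n_stages": m.n_stages,
                "stage_labels": _FIELD_SEP.join(m.stage_labels),
                "U": _ser(m.U),
                "F": _ser(m.F),
                "C": _ser(m.C),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mpm_table(path) -> tuple[list[StageMatrixModel], list[dict]]:
    """Read a matrix table; returns (valid models, per-row rejection log)."""
    df = pd.read_csv(path)
    required = {"species_id", "taxon_group", "matrix_kind", "annual",
                "n_stages", "stage_labels", "U", "F"}
    missing = required - set(df.columns)
    if missing:
        raise MPMError(f"matrix table missing columns: {sorted(missing)}")
    models: list[StageMatrixModel] = []
    log: list[dict] = []
    for idx, row in df.iterrows():
        try:
            if row["taxon_group"] not in TAXON_GROUPS:
                raise MPMError(f"unknown taxon group {row['taxon_group']!r}")
            if row["matrix_kind"] not in _KIND_PREFERENCE:
                raise MPMError(f"unknown matrix kind {row['matrix_kind']!r}")
            s = int(row["n_stages"])
            if pd.isna(row["F"]):
                raise MPMError("missing F block")
            C = None
            if "C" in df.columns and not pd.isna(row["C"]):
                C = _deser(row["C"], s)
            model = validate_model(
                _deser(row["U"], s),
                _deser(row["F"], s),
                C,
                str(row["stage_labels"]).split(_FIELD_SEP),
                species_id=str(row["species_id"]),
                taxon_group=str(row["taxon_group"]),
                matrix_kind=str(row["matrix_kind"]),
                annual=bool(row["annual"]),
            )
            models.append(model)
        except (MPMError, ValueError) as exc:
            log.append({"row": int(idx), "species_id": str(row.get("species_id", "")),
                        "reason": str(exc)})
    return models, log


def write_status_table(statuses: dict[str, str], path) -> None:
    pd.DataFrame(
        {"species_id": list(statuses), "status": list(statuses.values())}
    ).to_csv(path, index=False)


def read_status_table(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["species_id"].astype(str), df["status"].astype(str)))


def select_matrices(
    models: list[StageMatrixModel],
) -> tuple[dict[str, list[StageMatrixModel]], list[dict]]:
    """Apply the retention and matrix-kind selection rules.

    Matrices without fecundity information or with a non-annual time
    step are dropped with a logged reason. Within each species all
    individual matrices are kept when any exist; otherwise all mean
    matrices; otherwise all pooled ones. Species losing every matrix
    are excluded (logged). The result is sorted by species id and is
    independent of input order.
    """
    log: list[dict] = []
    kept: dict[str, list[StageMatrixModel]] = {}
    for m in models:
        if not m.has_fecundity:
            log.append({"species_id": m.species_id,
                        "reason": "no fecundity information"})
            continue
        if not m.annual:
            log.append({"species_id": m.species_id,
                        "reason": "non-annual transition time step"})
            continue
        kept.setdefault(m.species_id, []).append(m)

    selected: dict[str, list[StageMatrixModel]] = {}
    for sp in sorted(kept):
        group = kept[sp]
        for kind in _KIND_PREFERENCE:
            chosen = [m for m in group if m.matrix_kind == kind]
            if chosen:
                break
        for m in group:
            if m.matrix_kind != kind:
                log.append({"species_id": sp,
                            "reason": f"{m.matrix_kind} matrix superseded by "
                                      f"{kind} matrices"})
        selected[sp] = chosen
    return selected, log


def aggregate_species(
    species_id: str,
    taxon_group: str,
    metrics_list: list[dict[str, float]],
    iucn: int | None = None,
) -> SpeciesRecord:
    """Missing-aware arithmetic mean of per-matrix metrics.

    Each metric is averaged over the matrices where it is finite; it is
    missing (NaN) only if missing everywhere. The count of skipped
    matrices is recorded per metric.
    """
    if not metrics_list:
        raise MPMError("aggregate_species needs at least one matrix")
    means: dict[str, float] = {}
    miss: dict[str, int] = {}
    for name in METRIC_NAMES:
        vals = np.array([d.get(name, np.nan) for d in metrics_list], dtype=float)
        ok = np.isfinite(vals)
        means[name] = float(vals[ok].mean()) if ok.any() else float("nan")
        if (~ok).sum():
            miss[name] = int((~ok).sum())
    return SpeciesRecord(
        species_id=species_id,
        taxon_group=taxon_group,
        metrics=means,
        n_matrices=len(metrics_list),
        iucn_rank=iucn,
        metric_missing_counts=miss,
    )


def build_species_table(
    models: list[StageMatrixModel],
    statuses: dict[str, str] | None = None,
    *,
    include_clonal_recruitment: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Metrics pipeline: select matrices, compute metrics, average, join IUCN.

    Returns a species-level DataFrame (one row per retained species,
    columns: species_id, taxon_group, n_matrices, the 14 metrics,
    iucn_rank) and the exclusion log.
    """
    statuses = statuses or {}
    selected, log = select_matrices(models)
    rows = []
    for sp, group in selected.items():
        per_matrix = [
            compute_metrics(
                m, include_clonal_recruitment=include_clonal_recruitment
            ).as_dict()
            for m in group
        ]
        rank = iucn_rank(statuses[sp]) if sp in statuses else None
        rec = aggregate_species(sp, group[0].taxon_group, per_matrix, rank)
        row = {
            "species_id": rec.species_id,
            "taxon_group": rec.taxon_group,
            "n_matrices": rec.n_matrices,
            **rec.metrics,
            "iucn_rank": np.nan if rec.iucn_rank is None else rec.iucn_rank,
        }
        rows.append(row)
    cols = ["species_id", "taxon_group", "n_matrices", *METRIC_NAMES, "iucn_rank"]
    df = pd.DataFrame(rows, columns=cols)
    return df, log


def coverage_summary(
    models: list[StageMatrixModel], statuses: dict[str, str]
) -> pd.DataFrame:
    """Per-taxon counts of species with and without a usable IUCN status."""
    species: dict[str, str] = {}
    for m in models:
        species.setdefault(m.species_id, m.taxon_group)
    rows = []
    for taxon in TAXON_GROUPS:
        sp = [s for s, t in species.items() if t == taxon]
        assessed = [s for s in sp if iucn_rank(statuses.get(s, "")) is not None]
        total = len(sp)
        rows.append(
            {
                "taxon_group": taxon,
                "total_species": total,
                "assessed": len(assessed),
                "unassessed": total - len(assessed),
                "percent_unassessed": (
                    100.0 * (total - len(assessed)) / total if total else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
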
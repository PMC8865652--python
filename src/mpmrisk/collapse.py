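"""Juvenile/adult two-stage collapse of a stage-structured model.

Stage-specific survival and fecundity are hard to compare across models
with different stage structures. This module standardizes them by
collapsing every model to two classes: juveniles (all non-reproductive
stages before the first reproducing stage) and adults (the first
reproducing stage and everything after it). The collapse weights each
original stage by its share of the stable stage distribution, which
preserves the dominant eigenvalue of the projection matrix exactly.

From the collapsed model we read off juvenile survival ``sJ`` and adult
survival ``sA`` (column sums of the collapsed survival matrix), an
average adult fecundity ``fbar`` under a post-reproductive census, and
the elasticities of population growth to juvenile and adult survival.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mpm import (
    MPMError,
    StageMatrixModel,
    eigen_analysis,
    elasticity_matrix,
)

__all__ = [
    "StagePartition",
    "CollapsedModel",
    "classify_stages",
    "census_adjusted_fecundity",
    "collapse_matrix",
    "two_stage_vitals",
    "two_stage_elasticities",
    "collapse_model",
]


@dataclass(frozen=True)
class StagePartition:
    """Ordered juvenile and adult index sets (zero-based, disjoint)."""

    juvenile: tuple[int, ...]
    adult: tuple[int, ...]

    @property
    def degenerate(self) -> bool:
        """True when there is no juvenile class (first stage reproduces)."""
        return len(self.juvenile) == 0


@dataclass(frozen=True)
class CollapsedModel:
    """Two-stage summary of a full model (juvenile first, adult second)."""

    U2: np.ndarray
    F2: np.ndarray
    sJ: float
    sA: float
    fbar: float
    eJ: float
    eA: float


def classify_stages(F) -> StagePartition:
    """Split stages into juveniles and adults from the recruitment matrix.

    Stages are assumed developmentally ordered (the database
    convention): the adult class is every stage at or past the first
    one whose F column carries recruitment; juveniles are the rest.
    """
    F = np.asarray(F, dtype=float)
    repro_cols = np.flatnonzero(F.sum(axis=0) > 0)
    if repro_cols.size == 0:
        raise MPMError("no reproductive stage")
    first = int(repro_cols[0])
    s = F.shape[0]
    return StagePartition(
        juvenile=tuple(range(first)), adult=tuple(range(first, s))
    )


def census_adjusted_fecundity(U, F) -> np.ndarray:
    """Per-stage fecundity under a post-reproductive census.

    Recruitment elements of a post-reproductive-census matrix combine
    parental survival with offspring production, so per-stage fecundity
    is recovered as ``f_j = (sum_i F_ij) / sigma_j`` with ``sigma_j``
    the survival column sum. Columns without recruitment give zero; a
    reproducing column with zero parental survival is flagged NaN
    (reproduction without parental survival).
    """
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    recruit = F.sum(axis=0)
    sigma = U.sum(axis=0)
    f = np.zeros_like(recruit)
    live = sigma > 0
    f[live] = recruit[live] / sigma[live]
    f[(~live) & (recruit > 0)] = np.nan
    return f


def collapse_matrix(M, partition: StagePartition, w) -> np.ndarray:
    """Collapse an s-by-s matrix to 2-by-2 with stable-distribution weights.

    ``M2[I, J] = sum_{i in I, j in J} M_ij w_j / sum_{j in J} w_j``:
    each donor class is averaged with the weight its stages carry in
    the stable stage distribution ``w``. Applied to the projection
    matrix this collapse preserves the dominant eigenvalue, with
    collapsed stable distribution ``(sum_J w, sum_A w)``.
    """
    M = np.asarray(M, dtype=float)
    w = np.asarray(w, dtype=float)
    classes = [list(partition.juvenile), list(partition.adult)]
    if any(not c for c in classes):
        raise MPMError("cannot collapse onto an empty stage class")
    mass = [float(w[c].sum()) for c in classes]
    if any(m <= 0 for m in mass):
        raise MPMError("stable distribution carries no mass on a class")
    M2 = np.zeros((2, 2))
    for J, cj in enumerate(classes):
        for I, ci in enumerate(classes):
            M2[I, J] = M[np.ix_(ci, cj)].sum(axis=0) @ w[cj] / mass[J]
    return M2


def two_stage_vitals(
    model: StageMatrixModel,
    partition: StagePartition,
    w=None,
    recruitment=None,
) -> tuple[float, float, float]:
    """Juvenile survival, adult survival and average adult fecundity.

    Survival values are column sums of the stable-weighted collapse of
    U (stasis plus progression plus retrogression out of each class);
    ``fbar`` is the w-weighted mean of census-adjusted per-stage
    fecundities over the adult stages (NaN when any reproducing adult
    column has zero survival).
    """
    if partition.degenerate:
        raise MPMError("degenerate partition: no juvenile class")
    F = model.F if recruitment is None else np.asarray(recruitment, dtype=float)
    if w is None:
        w = eigen_analysis(model.A).w
    w = np.asarray(w, dtype=float)
    U2 = collapse_matrix(model.U, partition, w)
    sJ = float(U2[:, 0].sum())
    sA = float(U2[:, 1].sum())
    f = census_adjusted_fecundity(model.U, F)
    adult = list(partition.adult)
    wa = w[adult]
    if wa.sum() <= 0:
        raise MPMError("stable distribution carries no adult mass")
    fbar = float(f[adult] @ wa / wa.sum())
    return sJ, sA, fbar


def two_stage_elasticities(U2, F2) -> tuple[float, float]:
    """Elasticities of growth to juvenile and adult survival.

    The elasticity matrix of ``A2 = U2 + F2`` is computed and each
    element's elasticity is attributed to survival in proportion to the
    survival share ``U2_ij / A2_ij`` of that element. ``eJ`` collects
    the juvenile column (stasis plus maturation, both requiring a
    surviving juvenile); ``eA`` the adult column (stasis plus
    retrogression).
    """
    U2 = np.asarray(U2, dtype=float)
    F2 = np.asarray(F2, dtype=float)
    A2 = U2 + F2
    E = elasticity_matrix(A2)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(A2 > 0, U2 / np.where(A2 > 0, A2, 1.0), 0.0)
    Es = E * share
    eJ = float(Es[:, 0].sum())
    eA = float(Es[:, 1].sum())
    return eJ, eA


def collapse_model(model: StageMatrixModel, recruitment=None) -> CollapsedModel:
    """Full collapse pipeline for one model.

    Classifies stages from the recruitment matrix (``model.F`` unless a
    combined sexual-plus-clonal matrix is passed), collapses U and the
    recruitment matrix with stable-distribution weights from the full
    projection matrix, and derives the two-stage vital rates and
    survival elasticities.
    """
    F = model.F if recruitment is None else np.asarray(recruitment, dtype=float)
    partition = classify_stages(F)
    if partition.degenerate:
        raise MPMError("degenerate partition: no juvenile class")
    w = eigen_analysis(model.A).w
    U2 = collapse_matrix(model.U, partition, w)
    F2 = collapse_matrix(F, partition, w)
    sJ, sA, fbar = two_stage_vitals(model, partition, w=w, recruitment=F)
    eJ, eA = two_stage_elasticities(U2, F2)
    return CollapsedModel(U2=U2, F2=F2, sJ=sJ, sA=sA, fbar=fbar, eJ=eJ, eA=eA)
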
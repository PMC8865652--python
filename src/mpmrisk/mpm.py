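"""Core matrix-population-model (MPM) machinery.

A stage-classified population is projected one year at a time by the
matrix ``A = U + F + C`` where

* ``U`` holds survival-and-growth transition probabilities (column sums
  at most one),
* ``F`` holds per-capita sexual recruitment, and
* ``C`` holds per-capita clonal recruitment.

From a validated ``(U, F, C)`` triple this module derives the standard
life-history quantities used in comparative demography: the dominant
eigenvalue and its eigenvectors, the fundamental matrix, net
reproductive rate, generation time, age-from-stage survivorship and
fertility schedules, Keyfitz and Demetrius entropies, first-passage age
at maturity, mature life expectancy, per-stage vital-rate means and the
elasticity matrix of the projection matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MPMError",
    "StageMatrixModel",
    "EigenSummary",
    "AgeSchedules",
    "DemographicMetrics",
    "METRIC_NAMES",
    "validate_model",
    "eigen_analysis",
    "fundamental_matrix",
    "net_reproductive_rate",
    "generation_time",
    "age_schedules",
    "age_at_maturity",
    "mature_life_expectancy",
    "keyfitz_entropy",
    "demetrius_entropy",
    "vital_rate_means",
    "elasticity_matrix",
    "compute_metrics",
]

#: Column-sum slack allowed for survival probabilities.
U_COLSUM_TOL = 1e-6

#: Names (and canonical order) of the 14 per-matrix demographic metrics.
METRIC_NAMES = (
    "iteroparity",
    "survivorship_curve",
    "age_at_maturity",
    "mature_life_expectancy",
    "net_reproductive_rate",
    "generation_time",
    "mean_reproduction",
    "progressive_growth",
    "retrogressive_growth",
    "juvenile_survival",
    "adult_survival",
    "avg_fecundity",
    "elas_juvenile_survival",
    "elas_adult_survival",
)


class MPMError(ValueError):
    """Raised for structurally invalid matrix models."""


@dataclass(frozen=True)
class StageMatrixModel:
    """A validated per-population matrix model record."""

    U: np.ndarray
    F: np.ndarray
    C: np.ndarray
    stage_labels: tuple[str, ...]
    species_id: str = ""
    taxon_group: str = ""
    matrix_kind: str = "individual"  # individual | mean | pooled
    annual: bool = True

    @property
    def n_stages(self) -> int:
        return self.U.shape[0]

    @property
    def A(self) -> np.ndarray:
        """Projection matrix A = U + F + C."""
        return self.U + self.F + self.C

    @property
    def reproductive_stages(self) -> tuple[int, ...]:
        """Zero-based indices of stages whose F column has a positive entry."""
        return tuple(int(j) for j in np.flatnonzero(self.F.sum(axis=0) > 0))

    @property
    def has_fecundity(self) -> bool:
        """Whether any sexual recruitment is recorded (retention rule)."""
        return bool(np.any(self.F > 0))


@dataclass(frozen=True)
class EigenSummary:
    """Dominant eigen-quantities of a projection matrix.

    ``lam`` is the asymptotic annual growth rate, ``w`` the stable stage
    distribution (sums to one) and ``v`` the reproductive-value vector
    scaled so that ``v @ w == 1``.
    """

    lam: float
    w: np.ndarray
    v: np.ndarray


@dataclass(frozen=True)
class AgeSchedules:
    """Age-from-stage survivorship ``lx`` and fertility ``mx`` schedules."""

    lx: np.ndarray
    mx: np.ndarray
    horizon: int
    truncated_by: str = "horizon"  # "horizon" | "tol"


@dataclass
class DemographicMetrics:
    """The 14 per-matrix metric values; missing entries are NaN with a reason."""

    values: dict[str, float] = field(default_factory=dict)
    missing_reasons: dict[str, str] = field(default_factory=dict)

    def set(self, name: str, value: float) -> None:
        self.values[name] = float(value)

    def set_missing(self, name: str, reason: str) -> None:
        self.values[name] = float("nan")
        self.missing_reasons[name] = reason

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        return {k: self.values.get(k, float("nan")) for k in METRIC_NAMES}


def _as_matrix(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise MPMError(f"{name} must be a square matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise MPMError(f"{name} contains a non-finite entry")
    if np.any(M < 0):
        raise MPMError(f"{name} contains a negative entry")
    return M


def validate_model(
    U,
    F,
    C=None,
    stage_labels=None,
    *,
    species_id: str = "",
    taxon_group: str = "",
    matrix_kind: str = "individual",
    annual: bool = True,
) -> StageMatrixModel:
    """Validate a U/F/C split and return a :class:`StageMatrixModel`.

    Raises :class:`MPMError` on dimension mismatch, negative or
    non-finite entries, or a U column sum exceeding ``1 + 1e-6`` (a
    survival matrix must be sub-stochastic).
    """
    U = _as_matrix(U, "U")
    F = _as_matrix(F, "F")
    s = U.shape[0]
    if C is None:
        C = np.zeros_like(U)
    C = _as_matrix(C, "C")
    if F.shape != U.shape or C.shape != U.shape:
        raise MPMError(
            f"U, F, C must share dimensions: {U.shape}, {F.shape}, {C.shape}"
        )
    colsums = U.sum(axis=0)
    if np.any(colsums > 1.0 + U_COLSUM_TOL):
        j = int(np.argmax(colsums))
        raise MPMError(
            f"survival column exceeds 1: column {j} sums to {colsums[j]:.6g}"
        )
    if stage_labels is None:
        stage_labels = tuple(f"stage_{i + 1}" for i in range(s))
    else:
        stage_labels = tuple(str(x) for x in stage_labels)
        if len(stage_labels) != s:
            raise MPMError(
                f"{len(stage_labels)} stage labels for a {s}-stage model"
            )
    return StageMatrixModel(
        U=U,
        F=F,
        C=C,
        stage_labels=stage_labels,
        species_id=species_id,
        taxon_group=taxon_group,
        matrix_kind=matrix_kind,
        annual=annual,
    )


def eigen_analysis(A) -> EigenSummary:
    """Dominant eigenvalue and eigenvectors of a nonnegative matrix.

    By Perron-Frobenius the spectral radius of a nonnegative matrix is
    itself an eigenvalue with nonnegative right and left eigenvectors;
    we take the eigenvalue of largest modulus, require its imaginary
    part to be numerically zero, and normalize ``w`` to sum to one and
    ``v`` so that ``v @ w == 1``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MPMError("A must be square")
    if np.any(A < 0) or not np.all(np.isfinite(A)):
        raise MPMError("A must be finite and nonnegative")
    if not np.any(A > 0):
        raise MPMError("zero projection matrix")
    vals, vecs = np.linalg.eig(A)
    lvals, lvecs = np.linalg.eig(A.T)
    # imprimitive matrices carry several eigenvalues on the spectral
    # circle; the Perron root is the real nonnegative one among them
    radius = float(np.max(np.abs(vals)))
    on_circle = np.flatnonzero(np.abs(vals) >= radius * (1 - 1e-10))
    k = int(on_circle[np.argmax(vals[on_circle].real)])
    lam = vals[k]
    if abs(lam.imag) > 1e-8 * max(1.0, abs(lam.real)):
        raise MPMError("dominant eigenvalue is not real")
    lam = float(lam.real)
    w = np.real(vecs[:, k])
    # match the left eigenvector by eigenvalue
    kl = int(np.argmin(np.abs(lvals - lam)))
    v = np.real(lvecs[:, kl])
    # Perron vectors are single-signed; flip to nonnegative and clip
    # round-off negatives.
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v
    w = np.clip(w, 0.0, None)
    v = np.clip(v, 0.0, None)
    if w.sum() <= 0 or v @ w <= 0:
        raise MPMError("failed to extract nonnegative dominant eigenvectors")
    w = w / w.sum()
    v = v / (v @ w)
    return EigenSummary(lam=lam, w=w, v=v)


def fundamental_matrix(U) -> np.ndarray:
    """Fundamental matrix ``N = (I - U)^-1`` of the survival chain.

    ``N[i, j]`` is the expected number of yearly time steps spent in
    stage ``i`` by an individual now in stage ``j``, counting the
    current step; column sums are expected remaining lifetimes.
    """
    U = np.asarray(U, dtype=float)
    s = U.shape[0]
    if np.any(U > 0):
        rho = float(np.max(np.abs(np.linalg.eigvals(U))))
        if rho >= 1.0 - 1e-12:
            raise MPMError(
                f"non-absorbing survival matrix (spectral radius {rho:.6g})"
            )
    try:
        N = np.linalg.solve(np.eye(s) - U, np.eye(s))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise MPMError("non-absorbing survival matrix (singular I - U)") from exc
    return np.clip(N, 0.0, None)


def net_reproductive_rate(U, F) -> float:
    """Expected lifetime recruit production R0 = dominant eigenvalue of F N."""
    F = np.asarray(F, dtype=float)
    if not np.any(F > 0):
        return 0.0
    R = F @ fundamental_matrix(U)
    return float(np.max(np.abs(np.linalg.eigvals(R))))


def generation_time(U, F) -> float:
    """Generation time ``T = log(R0) / log(lambda)``.

    Returns NaN when R0 is zero or lambda is numerically one (the ratio
    is then indeterminate); callers treat NaN as a flagged missing value.
    """
    r0 = net_reproductive_rate(U, F)
    if r0 <= 0:
        return float("nan")
    F = np.asarray(F, dtype=float)
    lam = eigen_analysis(np.asarray(U, dtype=float) + F).lam
    if abs(lam - 1.0) < 1e-10 or lam <= 0:
        return float("nan")
    return float(np.log(r0) / np.log(lam))


def age_schedules(
    U,
    F,
    start=None,
    horizon: int = 1000,
    tol: float = 1e-7,
) -> AgeSchedules:
    """Age-from-stage survivorship and fertility schedules.

    The cohort ``n_x = U^x start`` gives ``lx(x) = sum(n_x)`` and
    ``mx(x) = (1' F n_x) / lx(x)``. The series is truncated at the
    first age with ``lx < tol`` or at ``horizon``, whichever comes
    first. The default starting distribution places the cohort in the
    first stage.
    """
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    s = U.shape[0]
    if horizon < 1:
        raise MPMError("horizon must be at least 1")
    if tol <= 0:
        raise MPMError("tol must be positive")
    if start is None:
        start = np.zeros(s)
        start[0] = 1.0
    start = np.asarray(start, dtype=float)
    if np.any(start < 0) or start.sum() <= 0:
        raise MPMError("start must be a nonnegative distribution")
    start = start / start.sum()

    lx = [1.0]
    mx = [float(F.sum(axis=0) @ start)]
    n = start.copy()
    truncated_by = "horizon"
    for _ in range(horizon):
        n = U @ n
        l = float(n.sum())
        if l < tol:
            truncated_by = "tol"
            break
        lx.append(l)
        mx.append(float(F.sum(axis=0) @ n) / l)
    return AgeSchedules(
        lx=np.array(lx), mx=np.array(mx), horizon=horizon, truncated_by=truncated_by
    )


def _maturity_chain(U, reproductive):
    """Absorbing-chain pieces for first passage into the reproductive set."""
    U = np.asarray(U, dtype=float)
    s = U.shape[0]
    repro = sorted(int(r) for r in reproductive)
    if not repro:
        raise MPMError("no reproductive stage")
    juv = [j for j in range(s) if j not in repro]
    Q = U[np.ix_(juv, juv)]  # juvenile -> juvenile
    R = U[np.ix_(repro, juv)]  # juvenile -> reproductive
    return juv, repro, Q, R


def age_at_maturity(U, reproductive, start=None) -> float:
    """Expected years to first enter a reproductive stage.

    The survival chain is made absorbing at the reproductive set and the
    expectation is taken conditional on ever maturing (Doob h-transform
    of the juvenile-to-juvenile block). A start already inside the
    reproductive set contributes zero waiting time. Returns NaN when no
    starting mass can ever mature.
    """
    U = np.asarray(U, dtype=float)
    s = U.shape[0]
    juv, repro, Q, R = _maturity_chain(U, reproductive)
    if start is None:
        start = np.zeros(s)
        start[0] = 1.0
    start = np.asarray(start, dtype=float) / np.sum(start)
    if not juv:
        return 0.0
    nj = len(juv)
    # h[j] = P(ever absorbed into the reproductive set | now in juvenile j);
    # U is column-stochastic (columns index the source stage), hence Q.T
    h = np.linalg.solve(np.eye(nj) - Q.T, R.sum(axis=0))
    pj = start[juv]
    pr = float(start[repro].sum())
    mass = float(pj @ h) + pr  # P(ever mature) under the start distribution
    if mass <= 1e-300:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        Qh = Q * h[:, None] / h[None, :]
    Qh = np.where(h[None, :] > 0, Qh, 0.0)
    # expected steps to absorption for the conditioned chain
    t = np.zeros(nj)
    ok = h > 0
    if np.any(ok):
        sub = np.ix_(ok, ok)
        t_ok = np.linalg.solve(
            np.eye(int(ok.sum())) - Qh[sub].T, np.ones(int(ok.sum()))
        )
        t[ok] = t_ok
    return float((pj * h) @ t / mass)


def _entry_distribution(U, reproductive, start=None) -> np.ndarray:
    """Distribution over reproductive stages at the moment of first entry."""
    U = np.asarray(U, dtype=float)
    s = U.shape[0]
    juv, repro, Q, R = _maturity_chain(U, reproductive)
    if start is None:
        start = np.zeros(s)
        start[0] = 1.0
    start = np.asarray(start, dtype=float) / np.sum(start)
    entry = np.array(start[repro], dtype=float)
    if juv:
        nj = len(juv)
        visits = np.linalg.solve(np.eye(nj) - Q, start[juv])
        entry = entry + R @ visits
    tot = entry.sum()
    if tot <= 1e-300:
        raise MPMError("no path to maturity")
    return entry / tot


def mature_life_expectancy(U, reproductive, start=None) -> float:
    """Expected remaining lifetime at first entry into the reproductive set.

    Remaining lifetime follows the column-sum convention of
    :func:`fundamental_matrix` (the entry year is counted, so survivors
    score at least one). Returns NaN when maturation is impossible.
    """
    try:
        entry = _entry_distribution(U, reproductive, start)
    except MPMError:
        return float("nan")
    N = fundamental_matrix(U)
    repro = sorted(int(r) for r in reproductive)
    life = N.sum(axis=0)[repro]
    return float(entry @ life)


def keyfitz_entropy(lx) -> float:
    """Keyfitz entropy H of a survivorship curve.

    ``H = -sum(lx * log lx) / sum(lx)`` over ages with ``lx > 0``. H
    near one indicates a Type II (constant-hazard) curve; H below one
    leans Type I, above one Type III.
    """
    lx = np.asarray(lx, dtype=float)
    if lx.size == 0 or np.all(lx <= 0):
        raise MPMError("empty or all-zero survivorship curve")
    pos = lx[lx > 0]
    return float(-(pos * np.log(pos)).sum() / pos.sum())


def demetrius_entropy(lx, mx) -> float:
    """Demetrius entropy S, the spread of reproduction over ages.

    ``S = -sum(p log p)`` with ``p`` the normalized net-fertility
    schedule ``lx * mx``. Zero for strict semelparity; larger values
    mean reproduction is spread over more of the lifespan. Returns NaN
    if the schedule contains no reproduction.
    """
    lx = np.asarray(lx, dtype=float)
    mx = np.asarray(mx, dtype=float)
    if lx.shape != mx.shape:
        raise MPMError("lx and mx must align")
    net = lx * mx
    tot = net.sum()
    if tot <= 0:
        return float("nan")
    p = net[net > 0] / tot
    return float(-(p * np.log(p)).sum())


def vital_rate_means(U, F) -> tuple[float, float, float]:
    """Mean sexual reproduction, progressive growth and retrogressive growth.

    * ``phi``: mean over all stage columns of the F column sums (mean
      per-capita recruits per stage per year).
    * ``gamma``: mean over columns 1..s-1 of the below-diagonal U mass
      (probability of advancing past the current stage).
    * ``rho``: mean over columns 2..s of the above-diagonal U mass
      (probability of reverting to an earlier stage).

    For a single-stage model gamma and rho are zero by convention.
    """
    U = np.asarray(U, dtype=float)
    F = np.asarray(F, dtype=float)
    s = U.shape[0]
    phi = float(F.sum(axis=0).mean())
    if s == 1:
        return phi, 0.0, 0.0
    lower = np.tril(U, -1).sum(axis=0)  # below-diagonal mass per column
    upper = np.triu(U, 1).sum(axis=0)  # above-diagonal mass per column
    gamma = float(lower[:-1].mean())
    rho = float(upper[1:].mean())
    return phi, gamma, rho


def elasticity_matrix(A) -> np.ndarray:
    """Elasticities of lambda to the elements of A.

    ``E_ij = (A_ij / lambda) * v_i w_j / (v @ w)``; the entries are the
    proportional sensitivities of the growth rate and sum to one.
    """
    A = np.asarray(A, dtype=float)
    eig = eigen_analysis(A)
    S = np.outer(eig.v, eig.w) / (eig.v @ eig.w)
    return A * S / eig.lam


def compute_metrics(
    model: StageMatrixModel,
    *,
    include_clonal_recruitment: bool = False,
    horizon: int = 1000,
    lx_tol: float = 1e-7,
) -> DemographicMetrics:
    """Compute all 14 demographic metrics for one matrix model.

    Recruitment-based metrics use the sexual matrix F by default;
    ``include_clonal_recruitment=True`` folds C into recruitment.
    Quantities whose preconditions fail (no reproduction, lambda equal
    to one, reproduction without parental survival, ...) come back as
    NaN with a reason code instead of raising.
    """
    from . import collapse as _collapse  # local import to avoid a cycle

    F = model.F + model.C if include_clonal_recruitment else model.F
    U = model.U
    A = model.A
    m = DemographicMetrics()

    repro = tuple(int(j) for j in np.flatnonzero(F.sum(axis=0) > 0))
    if not repro:
        for name in METRIC_NAMES:
            m.set_missing(name, "no fecundity information")
        return m

    sched = age_schedules(U, F, horizon=horizon, tol=lx_tol)
    S = demetrius_entropy(sched.lx, sched.mx)
    if np.isnan(S):
        m.set_missing("iteroparity", "no reproduction along the age schedule")
    else:
        m.set("iteroparity", S)
    m.set("survivorship_curve", keyfitz_entropy(sched.lx))

    la = age_at_maturity(U, repro)
    if np.isnan(la):
        m.set_missing("age_at_maturity", "maturation unreachable")
    else:
        m.set("age_at_maturity", la)
    mle = mature_life_expectancy(U, repro)
    if np.isnan(mle):
        m.set_missing("mature_life_expectancy", "maturation unreachable")
    else:
        m.set("mature_life_expectancy", mle)

    try:
        r0 = net_reproductive_rate(U, F)
        m.set("net_reproductive_rate", r0)
        T = generation_time(U, F)
        if np.isnan(T):
            m.set_missing("generation_time", "lambda at unity or R0 zero")
        else:
            m.set("generation_time", T)
    except MPMError as exc:
        m.set_missing("net_reproductive_rate", str(exc))
        m.set_missing("generation_time", str(exc))

    phi, gamma, rho = vital_rate_means(U, F)
    m.set("mean_reproduction", phi)
    m.set("progressive_growth", gamma)
    m.set("retrogressive_growth", rho)

    try:
        two = _collapse.collapse_model(model, recruitment=F)
        m.set("juvenile_survival", two.sJ)
        m.set("adult_survival", two.sA)
        if np.isnan(two.fbar):
            m.set_missing("avg_fecundity", "reproduction without parental survival")
        else:
            m.set("avg_fecundity", two.fbar)
        m.set("elas_juvenile_survival", two.eJ)
        m.set("elas_adult_survival", two.eA)
    except MPMError as exc:
        for name in (
            "juvenile_survival",
            "adult_survival",
            "avg_fecundity",
            "elas_juvenile_survival",
            "elas_adult_survival",
        ):
            m.set_missing(name, str(exc))
    return m
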
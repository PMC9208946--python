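"""Fuzzy C-means segmentation with particle-swarm-optimised initial centers.

Fuzzy C-means (FCM) assigns every pixel a graded membership ``u_ik`` to each
of C clusters and alternates two closed-form updates that minimise the
fuzzified within-cluster objective

    J_m = sum_i sum_k u_ik^m * ||x_k - c_i||^2,      m > 1,

namely the membership update ``u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1))`` and
the center update ``c_i = sum_k u_ik^m x_k / sum_k u_ik^m``.  Alternating
minimisation makes the objective trace non-increasing, but the fixed point
reached depends strongly on the initial centers.  The PSO initialiser treats
a candidate C-vector of centers as a particle, scores it with the FCM
objective under its implied memberships, and moves the swarm under inertia,
personal-best and global-best attraction; the global best seeds FCM.

Clustering operates on intensity alone (a 1D feature per pixel), matching
gray/white-matter segmentation of scalar MR images.  Segmentation quality
against a ground-truth mask is scored with the Jaccard similarity
``JS = |S1 ∩ S2| / |S1 ∪ S2|``.

Defaults follow the common choices m=2, at most T=100 iterations, and a
termination tolerance of 1e-4 on the maximum center displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FCMConfig",
    "PSOConfig",
    "MembershipMatrix",
    "ClusterModel",
    "PSOResult",
    "SegmentationResult",
    "fcm_objective",
    "update_membership",
    "update_centers",
    "pso_init_centers",
    "fcm_segment",
    "defuzzify",
    "jaccard_similarity",
    "per_class_jaccard",
]


@dataclass(frozen=True)
class FCMConfig:
    """FCM hyper-parameters.

    Parameters
    ----------
    n_clusters
        Number of clusters C (>= 2).
    m
        Fuzzifier exponent (> 1); larger values give softer memberships.
    max_iter
        Iteration cap T.
    tol
        Termination tolerance ε, applied to the quantity named by
        ``stop_on``.
    stop_on
        ``"center_shift"`` (default) stops when the maximum absolute center
        displacement falls below ε; ``"objective"`` uses |ΔJ| instead.
    zero_distance_eps
        A point within this distance of a center receives membership 1
        there (split equally over ties); guards the division by distance.
    """

    n_clusters: int = 3
    m: float = 2.0
    max_iter: int = 100
    tol: float = 1e-4
    stop_on: str = "center_shift"
    zero_distance_eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.stop_on not in ("center_shift", "objective"):
            raise ValueError("stop_on must be 'center_shift' or 'objective'")


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyper-parameters for the center initialiser.

    Defaults are the canonical constriction-equivalent values
    (w=0.72, c1=c2=1.49) with 20 particles and 50 iterations.
    """

    n_particles: int = 20
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    n_pso_iter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("inertia, cognitive and social weights must be > 0")
        if self.n_pso_iter < 1:
            raise ValueError("n_pso_iter must be >= 1")


@dataclass
class MembershipMatrix:
    """C × N fuzzy memberships; every column sums to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("membership matrix must be 2D (C, N)")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("memberships must lie in [0, 1]")
        col = self.values.sum(axis=0)
        if np.abs(col - 1.0).max() > 1e-9:
            raise ValueError("membership columns must sum to 1 within 1e-9")

    @property
    def n_clusters(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterModel:
    """Fitted centers with the per-iteration objective trace."""

    centers: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool


@dataclass
class PSOResult:
    """Outcome of the swarm search: best centers and the gbest fitness trace."""

    centers: np.ndarray
    gbest_trace: list[float]


@dataclass
class SegmentationResult:
    """Hard labels, memberships and the fitted model; clusters are renumbered
    by ascending center intensity (so CSF < GM < WM under the default
    phantom ordering)."""

    label_map: np.ndarray
    membership: MembershipMatrix
    model: ClusterModel


def _as_features(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if not np.isfinite(arr).all():
        raise ValueError("data must be finite")
    return arr


def _as_centers(centers: np.ndarray) -> np.ndarray:
    arr = np.asarray(centers, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def fcm_objective(data, centers, membership, m: float = 2.0) -> float:
    """The fuzzified within-cluster sum of squared distances J_m."""
    x = _as_features(data)
    c = _as_centers(centers)
    u = membership.values if isinstance(membership, MembershipMatrix) else np.asarray(membership, dtype=float)
    if u.shape != (c.shape[0], x.shape[0]):
        raise ValueError(
            f"membership shape {u.shape} inconsistent with "
            f"{c.shape[0]} centers and {x.shape[0]} points"
        )
    d2 = cdist(c, x, metric="sqeuclidean")
    return float(np.sum(u**m * d2))


def update_membership(data, centers, m: float = 2.0, zero_distance_eps: float = 1e-12) -> MembershipMatrix:
    """Closed-form membership update for fixed centers.

    Points within ``zero_distance_eps`` of one or more centers get their
    whole membership on those centers (split equally on ties); everywhere
    else ``u_ik ∝ d_ik^(-2/(m-1))`` normalised per point.
    """
    x = _as_features(data)
    c = _as_centers(centers)
    if c.shape[0] < 1:
        raise ValueError("need at least one center")
    if c.shape[0] > 1:
        pairwise = cdist(c, c)
        if pairwise[np.triu_indices(c.shape[0], 1)].max() <= zero_distance_eps:
            raise ValueError("all centers are identical; memberships undefined")
    d = cdist(c, x)  # (C, N)
    near = d <= zero_distance_eps
    with np.errstate(divide="ignore"):
        w = d ** (-2.0 / (m - 1.0))
    u = np.empty_like(d)
    snap = near.any(axis=0)
    if snap.any():
        hits = near[:, snap].astype(float)
        u[:, snap] = hits / hits.sum(axis=0)
    free = ~snap
    if free.any():
        u[:, free] = w[:, free] / w[:, free].sum(axis=0)
    return MembershipMatrix(u)


def update_centers(data, membership, m: float = 2.0) -> np.ndarray:
    """Closed-form center update: the u^m-weighted mean per cluster."""
    x = _as_features(data)
    u = membership.values if isinstance(membership, MembershipMatrix) else np.asarray(membership, dtype=float)
    um = u**m
    mass = um.sum(axis=1)
    if (mass == 0).any():
        dead = np.flatnonzero(mass == 0).tolist()
        raise ValueError(f"clusters {dead} have zero membership mass")
    return (um @ x) / mass[:, None]


def _implied_objective(x: np.ndarray, c: np.ndarray, m: float, eps: float) -> float:
    """J_m at centers ``c`` under the memberships those centers imply."""
    try:
        u = update_membership(x, c, m=m, zero_distance_eps=eps)
    except ValueError:  # degenerate particle (all centers coincide)
        return np.inf
    d2 = cdist(_as_centers(c), x, metric="sqeuclidean")
    return float(np.sum(u.values**m * d2))


def pso_init_centers(
    data,
    n_clusters: int,
    config: PSOConfig = PSOConfig(),
    m: float = 2.0,
    zero_distance_eps: float = 1e-12,
) -> PSOResult:
    """Choose FCM initial centers by particle swarm optimisation.

    Each particle is a candidate C-vector of centers in the data range;
    its fitness is the FCM objective under the memberships the candidate
    implies.  Velocities start small and random and follow
    ``v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)``.  The global-best
    fitness trace is
    non-increasing by construction, and equal seeds give equal outputs.
    """
    x = _as_features(data)
    uniq = np.unique(x, axis=0)
    if uniq.shape[0] < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} distinct data values, "
            f"found {uniq.shape[0]}"
        )
    rng = np.random.default_rng(config.seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    shape = (config.n_particles, n_clusters, x.shape[1])
    pos = rng.uniform(lo, hi, size=shape)
    # small random initial velocities keep swarm diversity early on
    vel = rng.uniform(-span / 4, span / 4, size=shape)

    fitness = np.array([_implied_objective(x, p, m, zero_distance_eps) for p in pos])
    pbest, pbest_fit = pos.copy(), fitness.copy()
    g = int(np.argmin(fitness))
    gbest, gbest_fit = pos[g].copy(), float(fitness[g])
    trace = [gbest_fit]

    for _ in range(config.n_pso_iter):
        r1 = rng.uniform(size=shape)
        r2 = rng.uniform(size=shape)
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest[None] - pos)
        )
        # no hard position clamp: the objective itself penalises positions
        # outside the data range, avoiding artificial boundary attractors
        pos = pos + vel
        fitness = np.array([_implied_objective(x, p, m, zero_distance_eps) for p in pos])
        improved = fitness < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fitness[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        trace.append(gbest_fit)

    return PSOResult(centers=gbest, gbest_trace=trace)


def fcm_segment(
    image,
    config: FCMConfig = FCMConfig(),
    init: str = "pso",
    pso_config: PSOConfig | None = None,
    initial_centers=None,
    seed: int | None = None,
) -> SegmentationResult:
    """Segment an intensity image by fuzzy C-means.

    Parameters
    ----------
    image
        Finite-valued array of any shape; pixels are clustered on intensity.
    init
        ``"pso"`` (swarm-optimised centers, the default), ``"random"``
        (C distinct intensities drawn at random), or ``"given"``
        (``initial_centers``).
    seed
        Seeds the random initialisation; also the PSO seed when no
        ``pso_config`` is supplied.

    Returns
    -------
    SegmentationResult
        With clusters renumbered by ascending center intensity, the label
        map equal to the per-pixel membership argmax, and the model carrying
        the (non-increasing) objective trace.
    """
    img = np.asarray(image, dtype=float)
    x = _as_features(img.ravel())
    C, m = config.n_clusters, config.m

    if init == "given":
        if initial_centers is None:
            raise ValueError("init='given' requires initial_centers")
        centers = _as_centers(initial_centers).astype(float).copy()
        if centers.shape[0] != C:
            raise ValueError(
                f"expected {C} initial centers, got {centers.shape[0]}"
            )
    elif init == "random":
        rng = np.random.default_rng(seed)
        uniq = np.unique(x, axis=0)
        if uniq.shape[0] < C:
            raise ValueError(
                f"need at least {C} distinct intensities, found {uniq.shape[0]}"
            )
        centers = uniq[rng.choice(uniq.shape[0], size=C, replace=False)]
    elif init == "pso":
        pcfg = pso_config or PSOConfig(seed=0 if seed is None else seed)
        centers = pso_init_centers(
            x, C, pcfg, m=m, zero_distance_eps=config.zero_distance_eps
        ).centers.copy()
    else:
        raise ValueError("init must be 'pso', 'random' or 'given'")

    trace: list[float] = []
    converged = False
    n_iter = 0
    u = None
    for n_iter in range(1, config.max_iter + 1):
        u = update_membership(x, centers, m=m, zero_distance_eps=config.zero_distance_eps)
        d2 = cdist(centers, x, metric="sqeuclidean")
        trace.append(float(np.sum(u.values**m * d2)))
        new_centers = update_centers(x, u, m=m)
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if config.stop_on == "center_shift":
            if shift < config.tol:
                converged = True
                break
        elif len(trace) >= 2 and abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break

    # Final memberships for the final centers, then canonical ordering by
    # ascending intensity so labels map to tissues deterministically.
    u = update_membership(x, centers, m=m, zero_distance_eps=config.zero_distance_eps)
    order = np.argsort(centers[:, 0], kind="stable")
    centers = centers[order]
    u = MembershipMatrix(u.values[order])
    labels = defuzzify(u).reshape(img.shape)

    model = ClusterModel(
        centers=centers[:, 0] if centers.shape[1] == 1 else centers,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
    )
    return SegmentationResult(label_map=labels, membership=u, model=model)


def defuzzify(membership) -> np.ndarray:
    """Per-element argmax of the membership columns; ties break toward the
    lowest cluster index."""
    u = membership.values if isinstance(membership, MembershipMatrix) else np.asarray(membership, dtype=float)
    return np.argmax(u, axis=0)


def jaccard_similarity(s1: np.ndarray, s2: np.ndarray) -> float:
    """Jaccard similarity |S1 ∩ S2| / |S1 ∪ S2| between two region masks.

    Two empty masks are identical regions and score 1.0 by convention.
    """
    a = np.asarray(s1, dtype=bool)
    b = np.asarray(s2, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def per_class_jaccard(
    predicted: np.ndarray, truth: np.ndarray, labels=None
) -> dict[int, float]:
    """Jaccard score of each class region against the ground truth.

    Classes default to the union of labels present in either map; relies on
    the canonical ascending-intensity cluster ordering for alignment.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("label maps must share a grid")
    if labels is None:
        labels = np.union1d(np.unique(predicted), np.unique(truth))
    return {
        int(lab): jaccard_similarity(predicted == lab, truth == lab)
        for lab in labels
    }
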
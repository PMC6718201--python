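"""Starting-point generation and the staged gradient-ascent maxima search.

The search for lattice-vector candidates runs in the real space of trial
vectors t.  Starting points fill a spherical search shell (either a broad
shell for an unknown cell, or thin shells at the known axis lengths), then
migrate uphill on the score function with an extended gradient rule that
adapts the step length from the previous step, the turn angle and the
current score, with an anti-zigzag correction.  A multi-stage schedule moves
from a smooth proximity function (large convergence radius) to sharp,
spurious-tolerant ones (precise maxima), with a sparse peak-finding step
that thins the point cloud to the best local maxima before the final polish.

Because even proximity functions make the score centrosymmetric, only one
point of each antipodal pair is kept (a fixed half-space through the
origin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .geometry import NodeSet
from .scoring import ProximityFunction, ScoreConfig, gradient_batch, score_batch

__all__ = [
    "SearchVolume",
    "SamplingPointSet",
    "DescentConfig",
    "DescentState",
    "StageSpec",
    "CandidatePeak",
    "HeuristicConfig",
    "default_stages",
    "generate_sphere_points",
    "build_starting_points",
    "descent_step",
    "run_stage",
    "sparse_peak_find",
    "find_lattice_vector_candidates",
]


@dataclass(frozen=True)
class SearchVolume:
    """Real-space search region for lattice vectors.

    ``unknown_cell``: a shell r_min <= |t| <= r_max (Angstrom).
    ``known_cell``: thin shells of the given half-width around each radius
    (the real-cell axis lengths, optionally plus the face-diagonal lengths).
    """

    mode: str = "unknown_cell"
    r_min: float = 20.0
    r_max: float = 300.0
    shell_radii: tuple[float, ...] = ()
    half_width: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("unknown_cell", "known_cell"):
            raise ValueError("mode must be 'unknown_cell' or 'known_cell'")
        if self.mode == "unknown_cell":
            if not (0 < self.r_min < self.r_max):
                raise ValueError("need 0 < r_min < r_max")
        else:
            if not self.shell_radii or any(r <= 0 for r in self.shell_radii):
                raise ValueError("shell_radii must be positive")
            if not self.half_width > 0:
                raise ValueError("half_width must be > 0")


@dataclass
class SamplingPointSet:
    """Migrating sampling points with their per-point descent state."""

    positions: np.ndarray  # (M, 3) Angstrom
    prev_dir: np.ndarray  # (M, 3) unit step directions (zero before first step)
    prev_len: np.ndarray  # (M,) previous step lengths, Angstrom
    scores: np.ndarray  # (M,)
    inliers: np.ndarray  # (M,) int

    @classmethod
    def from_positions(cls, pos: np.ndarray, init_step: float = 1.0):
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        m = len(pos)
        return cls(
            positions=pos.copy(),
            prev_dir=np.zeros((m, 3)),
            prev_len=np.full(m, init_step),
            scores=np.full(m, -np.inf),
            inliers=np.zeros(m, dtype=int),
        )

    def __len__(self) -> int:
        return len(self.positions)

    def copy(self) -> "SamplingPointSet":
        return SamplingPointSet(
            self.positions.copy(),
            self.prev_dir.copy(),
            self.prev_len.copy(),
            self.scores.copy(),
            self.inliers.copy(),
        )

    def select(self, idx) -> "SamplingPointSet":
        return SamplingPointSet(
            self.positions[idx],
            self.prev_dir[idx],
            self.prev_len[idx],
            self.scores[idx],
            self.inliers[idx],
        )


@dataclass(frozen=True)
class DescentConfig:
    """Extended gradient-ascent parameters.

    gamma scales the score-dependent step boost; steps are clipped to
    [min_step, max_step] (Angstrom).  A proposed direction turning back on
    the previous one by more than zigzag_cos_threshold triggers the
    anti-zigzag correction.  A point whose clipped step falls below
    convergence_tol stops moving (0 disables the check).
    """

    gamma: float = 1.0
    min_step: float = 0.01
    max_step: float = 2.0
    zigzag_cos_threshold: float = -0.8
    convergence_tol: float = 0.0
    init_step: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_step <= self.max_step):
            raise ValueError("need 0 < min_step <= max_step")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not (-1.0 < self.zigzag_cos_threshold < 0.0):
            raise ValueError("zigzag_cos_threshold must be in (-1, 0)")


@dataclass
class DescentState:
    """Per-point state for the scalar descent_step interface."""

    position: np.ndarray
    prev_dir: np.ndarray = field(default_factory=lambda: np.zeros(3))
    prev_len: float = 1.0


@dataclass(frozen=True)
class StageSpec:
    """One stage of the maxima-search heuristic."""

    proximity: str
    mode: str = "plain"  # 'plain' (bounded score) or 'tolerant'
    weighting: str = "unity"  # 'unity' or 'inverse_radial'
    n_steps: int = 20
    point_budget: int | None = None
    epsilon: float = 0.15

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.mode not in ("plain", "tolerant"):
            raise ValueError("mode must be 'plain' or 'tolerant'")
        if self.weighting not in ("unity", "inverse_radial"):
            raise ValueError("weighting must be 'unity' or 'inverse_radial'")

    def score_config(self, nodes: NodeSet) -> ScoreConfig:
        weights = None
        if self.weighting == "inverse_radial":
            norms = nodes.norms
            if np.any(norms == 0):
                raise ValueError("inverse-radial weighting needs |q| > 0")
            weights = 1.0 / norms
        return ScoreConfig(
            proximity=ProximityFunction(self.proximity),
            weights=weights,
            epsilon=self.epsilon,
            use_tolerance=(self.mode == "tolerant"),
        )


@dataclass(frozen=True)
class CandidatePeak:
    """A locally maximal sampling point: a candidate lattice vector."""

    position: np.ndarray
    score: float
    inliers: int


def default_stages(profile: str = "fast", epsilon: float = 0.15) -> list[StageSpec]:
    """Stage schedule: smooth first, sharp and tolerant later.

    The last stage runs after sparse peak finding, on the surviving peaks
    only.
    """
    if profile == "fast":
        steps = (40, 20, 8, 30)
    elif profile == "precise":
        steps = (60, 30, 12, 60)
    else:
        raise ValueError("profile must be 'fast' or 'precise'")
    return [
        StageSpec("cosine", "plain", "inverse_radial", steps[0], epsilon=epsilon),
        StageSpec("sharp_b", "tolerant", "unity", steps[1], epsilon=epsilon),
        StageSpec("sharp_a", "tolerant", "unity", steps[2], epsilon=epsilon),
        StageSpec("sharp_a", "tolerant", "unity", steps[3], epsilon=epsilon),
    ]


@dataclass
class HeuristicConfig:
    """Bundle of the maxima-search knobs."""

    budget: int = 5000
    environment_radius: float = 2.0
    max_keep: int = 50
    descent: DescentConfig = field(default_factory=DescentConfig)
    stages: list[StageSpec] = field(default_factory=default_stages)

    @classmethod
    def from_profile(cls, profile: str = "fast", epsilon: float = 0.15, **kw):
        budget = 5000 if profile == "fast" else 50000
        return cls(budget=budget, stages=default_stages(profile, epsilon), **kw)


# ---------------------------------------------------------------------------
# Starting points
# ---------------------------------------------------------------------------


def generate_sphere_points(n: int, seed: int | None = None) -> np.ndarray:
    """n approximately equally spaced unit vectors (Fibonacci spiral).

    Nearest-neighbour angular spacing is uniform to within a factor ~2 of
    the ideal (4 pi / n)^0.5.  A seeded random rotation decorrelates the
    spiral axis between calls; the output is deterministic under the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        pts = np.array([[0.0, 0.0, 1.0]])
    elif n == 2:
        pts = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
    else:
        i = np.arange(n)
        phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle increments
        z = 1.0 - (2.0 * i + 1.0) / n
        r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if seed is not None:
        rot = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
        pts = pts @ rot.T
    return pts


def _half_space_mask(pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Keep one point of each antipodal pair: z > 0 with lexicographic ties."""
    z, y, x = pts[:, 2], pts[:, 1], pts[:, 0]
    return (z > tol) | (
        (np.abs(z) <= tol) & ((y > tol) | ((np.abs(y) <= tol) & (x > 0)))
    )


def _solve_points_per_sphere(budget: int, n_spheres_of_n) -> int:
    """Largest per-sphere count n with n * n_spheres(n) <= budget."""
    n = max(1, budget)
    for _ in range(60):
        n_sph = max(1, n_spheres_of_n(n))
        n_new = max(1, budget // n_sph)
        if n_new == n:
            break
        n = n_new
    return n


def build_starting_points(
    vol: SearchVolume,
    budget: int,
    seed: int | None = None,
    descent: DescentConfig | None = None,
) -> SamplingPointSet:
    """Fill the search volume with concentric, randomly rotated spheres.

    The radial increment between neighbouring spheres equals the average
    angular spacing of the points on the sphere, so the cloud is roughly
    isotropic.  Each sphere receives an independent random rotation, and only
    one point of each antipodal pair is kept (score centrosymmetry).  The
    number of generated points (before halving) does not exceed ``budget``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    spheres: list[tuple[float, int]] = []  # (radius, n points)

    if vol.mode == "unknown_cell":
        span = vol.r_max / vol.r_min

        def n_spheres(n):
            delta = math.sqrt(4.0 * math.pi / n)
            return max(1, int(math.log(span) / math.log1p(delta)) + 1)

        n = _solve_points_per_sphere(budget, n_spheres)
        delta = math.sqrt(4.0 * math.pi / n)
        r = vol.r_min
        while r <= vol.r_max * (1 + 1e-12) and len(spheres) < n_spheres(n):
            spheres.append((r, n))
            r *= 1.0 + delta
    else:
        radii = sorted(vol.shell_radii)

        def n_spheres(n):
            delta = math.sqrt(4.0 * math.pi / n)
            return sum(
                max(1, int(2.0 * vol.half_width / (delta * r)) + 1) for r in radii
            )

        n = _solve_points_per_sphere(budget, n_spheres)
        delta = math.sqrt(4.0 * math.pi / n)
        for r0 in radii:
            m = max(1, int(2.0 * vol.half_width / (delta * r0)) + 1)
            for r in (
                [r0] if m == 1 else np.linspace(r0 - vol.half_width, r0 + vol.half_width, m)
            ):
                spheres.append((float(r), n))

    if not spheres or spheres[0][1] < 1:
        raise ValueError("budget too small to place a single sphere")

    base = generate_sphere_points(spheres[0][1])
    chunks = []
    for r, _ in spheres:
        rot = Rotation.random(random_state=rng).as_matrix()
        chunks.append(r * (base @ rot.T))
    pts = np.concatenate(chunks, axis=0)
    pts = pts[_half_space_mask(pts)]
    init = (descent or DescentConfig()).init_step
    return SamplingPointSet.from_positions(pts, init_step=init)


# ---------------------------------------------------------------------------
# Extended gradient ascent
# ---------------------------------------------------------------------------


def _orthogonal_unit(u: np.ndarray) -> np.ndarray:
    """Deterministic unit vector orthogonal to u."""
    e = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = e - np.dot(e, u) * u
    return v / np.linalg.norm(v)


def _step_batch(
    pts: SamplingPointSet,
    grads: np.ndarray,
    scores: np.ndarray,
    cfg: DescentConfig,
    active: np.ndarray,
) -> None:
    """Advance all active points one extended-ascent step, in place."""
    gn = np.linalg.norm(grads, axis=1)
    moving = active & (gn > 1e-14)
    stuck = active & ~ (gn > 1e-14)
    pts.prev_len[stuck] = cfg.min_step  # zero gradient: stay put, reset step

    if not np.any(moving):
        return
    d = grads[moving] / gn[moving, None]
    prev = pts.prev_dir[moving]
    cos0 = np.einsum("ij,ij->i", d, prev)

    zig = cos0 < cfg.zigzag_cos_threshold
    if np.any(zig):
        s = d[zig] + prev[zig]
        sn = np.linalg.norm(s, axis=1)
        ok = sn > 1e-12
        fixed = np.empty_like(s)
        fixed[ok] = s[ok] / sn[ok, None]
        for i in np.nonzero(~ok)[0]:  # exactly antipodal: deterministic fallback
            fixed[i] = _orthogonal_unit(prev[zig][i])
        d[zig] = fixed

    factor = np.where(cos0 > 0.7, 1.5, np.where(cos0 < 0.0, 0.5, 1.0))
    boost = 1.0 + cfg.gamma * (1.0 - scores[moving]) / 2.0
    length = np.clip(pts.prev_len[moving] * factor * boost, cfg.min_step, cfg.max_step)

    pts.positions[moving] += d * length[:, None]
    pts.prev_dir[moving] = d
    pts.prev_len[moving] = length
    if cfg.convergence_tol > 0:
        idx = np.nonzero(moving)[0]
        active[idx[length < cfg.convergence_tol]] = False


def descent_step(
    state: DescentState,
    gradient: np.ndarray,
    score_now: float,
    inliers_now: int,
    cfg: DescentConfig,
) -> DescentState:
    """Single-point extended gradient-ascent step (scalar interface).

    The step direction is the normalized gradient unless it turns back on
    the previous step (anti-zigzag sum of unit directions; exactly antipodal
    falls back to a deterministic orthogonal direction).  The step length is
    the previous length scaled by a turn factor and a score-dependent boost,
    clipped to [min_step, max_step].  ``inliers_now`` is carried in the
    signature for rule variants but unused by the default rule.
    """
    pts = SamplingPointSet(
        positions=np.atleast_2d(np.asarray(state.position, dtype=float)).copy(),
        prev_dir=np.atleast_2d(np.asarray(state.prev_dir, dtype=float)).copy(),
        prev_len=np.array([float(state.prev_len)]),
        scores=np.array([float(score_now)]),
        inliers=np.array([int(inliers_now)]),
    )
    active = np.array([True])
    _step_batch(pts, np.atleast_2d(np.asarray(gradient, dtype=float)), pts.scores, cfg, active)
    return DescentState(
        position=pts.positions[0],
        prev_dir=pts.prev_dir[0],
        prev_len=float(pts.prev_len[0]),
    )


def run_stage(
    points: SamplingPointSet,
    nodes: NodeSet,
    stage: StageSpec,
    cfg: DescentConfig,
) -> SamplingPointSet:
    """Run one heuristic stage: n_steps ascent steps under the stage's score.

    Per-point score and inlier-count state are refreshed under the stage's
    score mode on return.  With a point budget, only the best-scoring points
    (under this stage's score) are advanced.
    """
    pts = points.copy()
    scfg = stage.score_config(nodes)
    if stage.point_budget is not None and len(pts) > stage.point_budget:
        s, _ = score_batch(pts.positions, nodes, scfg)
        keep = np.argsort(s)[::-1][: stage.point_budget]
        pts = pts.select(np.sort(keep))
    active = np.ones(len(pts), dtype=bool)
    for _ in range(stage.n_steps):
        if not np.any(active):
            break
        s, _ = score_batch(pts.positions, nodes, scfg)
        g = gradient_batch(pts.positions, nodes, scfg)
        _step_batch(pts, g, s, cfg, active)
    s, n_in = score_batch(pts.positions, nodes, scfg)
    pts.scores = s
    pts.inliers = n_in.astype(int)
    return pts


def sparse_peak_find(
    points: SamplingPointSet,
    environment_radius: float,
    max_keep: int = 50,
) -> list[CandidatePeak]:
    """Keep only points that score highest within their local environment.

    A point survives iff no other point within ``environment_radius`` has a
    strictly higher score (score ties broken by index, so a cluster of
    identical points yields exactly one peak).  At most ``max_keep`` peaks
    are returned, ordered by descending score.
    """
    if environment_radius <= 0:
        raise ValueError("environment_radius must be > 0")
    m = len(points)
    if m == 0:
        return []
    pos, sc = points.positions, points.scores
    keep = np.ones(m, dtype=bool)
    # chunked O(n^2) neighbourhood comparison
    chunk = max(1, int(2e7) // max(m, 1))
    idx = np.arange(m)
    for start in range(0, m, chunk):
        stop = min(m, start + chunk)
        d = cdist(pos[start:stop], pos)
        near = d <= environment_radius
        s_block = sc[start:stop, None]
        beaten = near & (
            (sc[None, :] > s_block)
            | ((sc[None, :] == s_block) & (idx[None, :] < idx[start:stop, None]))
        )
        keep[start:stop] = ~beaten.any(axis=1)
    order = np.nonzero(keep)[0]
    order = order[np.argsort(sc[order])[::-1]][:max_keep]
    return [
        CandidatePeak(position=pos[i].copy(), score=float(sc[i]), inliers=int(points.inliers[i]))
        for i in order
    ]


def find_lattice_vector_candidates(
    nodes: NodeSet,
    vol: SearchVolume,
    config: HeuristicConfig,
    seed: int | None = None,
) -> list[CandidatePeak]:
    """Full maxima-search heuristic: staged ascent, thinning, final polish.

    Runs all but the last stage on the full starting-point cloud, thins the
    cloud by sparse peak finding, then polishes the surviving peaks with the
    last stage.  Returns at most ``config.max_keep`` candidate lattice
    vectors ordered by descending final score.  Deterministic under seed.
    """
    if nodes.K < 3:
        raise ValueError("need at least 3 nodes to span a 3D lattice")
    if not config.stages:
        raise ValueError("at least one stage is required")
    pts = build_starting_points(vol, config.budget, seed=seed, descent=config.descent)
    for stage in config.stages[:-1]:
        pts = run_stage(pts, nodes, stage, config.descent)
    peaks = sparse_peak_find(pts, config.environment_radius, config.max_keep)
    if not peaks:
        return []
    final = config.stages[-1]
    polish = SamplingPointSet.from_positions(
        np.array([p.position for p in peaks]), init_step=config.descent.min_step * 4
    )
    polish = run_stage(polish, nodes, final, config.descent)
    order = np.argsort(polish.scores)[::-1]
    return [
        CandidatePeak(
            position=polish.positions[i].copy(),
            score=float(polish.scores[i]),
            inliers=int(polish.inliers[i]),
        )
        for i in order
    ]
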
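"""Lattice bases: formation, reduction, selection, refinement, indexing.

A real-space lattice basis is stored as a 3x3 matrix whose *rows* are the
basis vectors a, b, c (Angstrom).  In the crystallographic convention used
throughout, the fractional Miller indices of a node q are simply

    (h, k, l) = (a . q, b . q, c . q),

integers exactly when q lies on the reciprocal lattice of the basis.  The
node position predicted for integer indices h is q_pred = h . inv(B)^T.

Candidate bases are assembled from the score-function peaks (candidate
lattice vectors), filtered by how many nodes they predict, reduced to their
shortest-vector form, ranked by two defect statistics (mean reciprocal-space
distance and mean fractional-index deviation), and accepted greedily so
that each accepted lattice explains nodes no other accepted lattice does —
the native one-pass multi-lattice mode.  Accepted bases are refined against
their inlier nodes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import NodeSet
from .scoring import wrap_offset
from .search import (
    CandidatePeak,
    HeuristicConfig,
    SearchVolume,
    find_lattice_vector_candidates,
)

log = logging.getLogger(__name__)

__all__ = [
    "LatticeBasis",
    "MillerAssignment",
    "DefectReport",
    "IndexingSolution",
    "CandidateBasis",
    "SelectionConfig",
    "RefineConfig",
    "IndexingConfig",
    "fractional_indices",
    "count_predicted",
    "enumerate_candidate_bases",
    "reduce_basis",
    "compute_defects",
    "select_lattices",
    "refine_basis",
    "index",
]


@dataclass(frozen=True)
class LatticeBasis:
    """Three real-space lattice vectors (rows a, b, c of ``matrix``, Angstrom)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or not np.all(np.isfinite(m)):
            raise ValueError("basis matrix must be a finite 3x3 array")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_parameters(
        cls, a: float, b: float, c: float, alpha: float, beta: float, gamma: float
    ) -> "LatticeBasis":
        """Canonical basis from cell lengths (Angstrom) and angles (degrees)."""
        al, be, ga = np.radians([alpha, beta, gamma])
        va = np.array([a, 0.0, 0.0])
        vb = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
        cx = np.cos(be)
        cy = (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz2 = 1.0 - cx * cx - cy * cy
        if cz2 <= 0:
            raise ValueError("invalid cell angles")
        vc = np.array([c * cx, c * cy, c * np.sqrt(cz2)])
        return cls(np.array([va, vb, vc]))

    @property
    def a(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def b(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def c(self) -> np.ndarray:
        return self.matrix[2]

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.matrix, axis=1)

    @property
    def angles(self) -> np.ndarray:
        """Cell angles (alpha, beta, gamma) in degrees."""
        a, b, c = self.matrix
        la, lb, lc = self.lengths

        def ang(u, v, lu, lv):
            return np.degrees(np.arccos(np.clip(np.dot(u, v) / (lu * lv), -1, 1)))

        return np.array([ang(b, c, lb, lc), ang(a, c, la, lc), ang(a, b, la, lb)])

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def reciprocal_rows(self) -> np.ndarray:
        """Rows are the reciprocal basis vectors a*, b*, c* (a* . a = 1)."""
        return np.linalg.inv(self.matrix).T

    def sorted_by_length(self) -> "LatticeBasis":
        order = np.argsort(self.lengths)
        m = self.matrix[order]
        if np.linalg.det(m) < 0:
            m = m * np.array([[1.0], [1.0], [-1.0]])
        return LatticeBasis(m)


@dataclass
class MillerAssignment:
    """Per-node integer Miller triples (where assigned) and predicted positions."""

    hkl: np.ndarray  # (K, 3) int
    assigned: np.ndarray  # (K,) bool
    predicted_q: np.ndarray  # (K, 3); rows meaningful only where assigned


@dataclass(frozen=True)
class DefectReport:
    """Fit-quality statistics of a basis against a node set.

    absolute_defect: mean |q_obs - q_pred| over predicted nodes (1/Angstrom).
    relative_defect: mean Euclidean distance between fractional and rounded
    integer Miller indices over predicted nodes (dimensionless).
    """

    absolute_defect: float
    relative_defect: float
    n_predicted: int


@dataclass
class IndexingSolution:
    """An accepted lattice: reduced/refined basis, assignments, defects."""

    basis: LatticeBasis
    assignment: MillerAssignment
    defects: DefectReport
    lattice_id: int = 0
    score: float = 0.0


@dataclass(frozen=True)
class CandidateBasis:
    """An unreduced candidate basis with its summed peak score."""

    basis: LatticeBasis
    score: float


@dataclass
class SelectionConfig:
    """Candidate filtering and greedy lattice-selection parameters."""

    relative_tol: float = 0.15  # max-norm fractional residual to count a node
    min_predicted: int = 5
    # a lattice must also explain this fraction of the pattern's nodes;
    # guards against chance fits on pure-noise patterns (with tol 0.15 a
    # random node lands within tolerance of ANY basis with p ~ 0.027, and
    # maximizing over thousands of candidate triples finds >= 5 such nodes)
    min_predicted_fraction: float = 0.25
    # chance inliers are uniform in the tolerance cube, giving a mean
    # fractional residual close to relative_tol itself; a genuine lattice
    # fits its nodes far better.  None resolves to relative_tol / 3,
    # enforced on refined solutions (candidates are screened at twice the
    # value, since unrefined defects carry the peak-position noise).
    max_relative_defect: float | None = None

    def resolve_max_relative_defect(self) -> float:
        if self.max_relative_defect is not None:
            return self.max_relative_defect
        return self.relative_tol / 3.0
    det_rel_floor: float = 0.2  # |det| >= floor * |a||b||c|
    det_abs_floor: float = 1000.0  # Angstrom^3
    max_candidates: int = 500
    shortlist_by_score: int = 15
    shortlist_by_defect: int = 50
    defect_improvement: float = 0.7  # 'significantly smaller' relative defect
    overlap_fraction: float = 0.8  # node-set overlap defining 'same lattice'
    known_cell: tuple[float, float, float, float, float, float] | None = None
    cell_length_tol: float = 0.05  # relative
    cell_angle_tol: float = 2.5  # degrees


@dataclass
class RefineConfig:
    relative_tol: float = 0.15
    max_iterations: int = 100
    min_improvement: float = 1e-8  # 1/Angstrom


def fractional_indices(basis: LatticeBasis, q: np.ndarray) -> np.ndarray:
    """Real-valued Miller indices (a.q, b.q, c.q) of node(s) q under a basis."""
    if abs(basis.determinant) < 1e-12:
        raise ValueError("singular basis")
    q = np.asarray(q, dtype=float)
    return q @ basis.matrix.T


def count_predicted(
    basis: LatticeBasis, nodes: NodeSet, relative_tol: float
) -> tuple[int, MillerAssignment]:
    """Count nodes whose fractional indices round to integers within tolerance.

    A node is predicted when the max-component distance of its fractional
    indices to the nearest integer triple is <= relative_tol.
    """
    F = fractional_indices(basis, nodes.q)
    H = np.round(F)
    resid = np.abs(F - H)
    assigned = resid.max(axis=1) <= relative_tol
    pred_q = H @ basis.reciprocal_rows
    return int(assigned.sum()), MillerAssignment(
        hkl=H.astype(int), assigned=assigned, predicted_q=pred_q
    )


def _predicted_mask(basis: LatticeBasis, nodes: NodeSet, tol: float) -> np.ndarray:
    F = nodes.q @ basis.matrix.T
    return np.abs(F - np.round(F)).max(axis=1) <= tol


def compute_defects(
    basis: LatticeBasis, nodes: NodeSet, relative_tol: float
) -> DefectReport:
    """Absolute and relative defects of a basis over its predicted nodes."""
    n, asg = count_predicted(basis, nodes, relative_tol)
    if n == 0:
        return DefectReport(np.inf, np.inf, 0)
    sel = asg.assigned
    dq = np.linalg.norm(nodes.q[sel] - asg.predicted_q[sel], axis=1)
    F = fractional_indices(basis, nodes.q[sel])
    dh = np.linalg.norm(F - np.round(F), axis=1)
    return DefectReport(float(dq.mean()), float(dh.mean()), n)


# ---------------------------------------------------------------------------
# Basis reduction (shortest vectors)
# ---------------------------------------------------------------------------


def reduce_basis(basis: LatticeBasis) -> LatticeBasis:
    """Reduce a basis to the shortest vectors generating the same lattice.

    Iterated pairwise Lagrange-Gauss size reduction over the three vector
    pairs, plus +-1 cross-corrections combining all three vectors, until no
    vector norm decreases.  In three dimensions this greedy scheme yields
    vector norms equal to the successive minima of the lattice.  The
    transform is unimodular, so |det| is preserved; the output is sorted
    |a| <= |b| <= |c| with det > 0.
    """
    B = np.array(basis.matrix, dtype=float)
    if abs(np.linalg.det(B)) < 1e-12:
        raise ValueError("singular basis cannot be reduced")
    shrink = 1.0 - 1e-12
    for _ in range(200):
        changed = False
        # pairwise size reduction
        for j in range(3):
            for i in range(3):
                if i == j:
                    continue
                denom = np.dot(B[i], B[i])
                mu = round(np.dot(B[j], B[i]) / denom)
                if mu != 0:
                    cand = B[j] - mu * B[i]
                    if np.dot(cand, cand) < np.dot(B[j], B[j]) * shrink:
                        B[j] = cand
                        changed = True
        # +-1 corrections with both other vectors
        for j in range(3):
            i, k = [m for m in range(3) if m != j]
            best = np.dot(B[j], B[j])
            best_vec = None
            for ei in (-1, 0, 1):
                for ek in (-1, 0, 1):
                    if ei == 0 and ek == 0:
                        continue
                    cand = B[j] + ei * B[i] + ek * B[k]
                    n2 = np.dot(cand, cand)
                    if n2 < best * shrink:
                        best = n2
                        best_vec = cand
            if best_vec is not None:
                B[j] = best_vec
                changed = True
        if not changed:
            break
    return LatticeBasis(B).sorted_by_length()


# ---------------------------------------------------------------------------
# Candidate-basis enumeration
# ---------------------------------------------------------------------------


def _cell_matches(
    basis: LatticeBasis, cfg: SelectionConfig
) -> bool:
    """Compare a reduced basis against the known-cell prior (sorted params)."""
    assert cfg.known_cell is not None
    prior = reduce_basis(LatticeBasis.from_parameters(*cfg.known_cell))
    ls, lp = np.sort(basis.lengths), np.sort(prior.lengths)
    if np.any(np.abs(ls - lp) > cfg.cell_length_tol * lp):
        return False
    fold = lambda a: np.minimum(a, 180.0 - a)  # sign-flip ambiguity of reduction
    ang_s = np.sort(fold(basis.angles))
    ang_p = np.sort(fold(prior.angles))
    return bool(np.all(np.abs(ang_s - ang_p) <= cfg.cell_angle_tol))


def enumerate_candidate_bases(
    peaks: list[CandidatePeak],
    nodes: NodeSet,
    config: SelectionConfig | None = None,
) -> list[CandidateBasis]:
    """Form candidate bases from peak triples, with pruning filters.

    Pipeline: (1) drop peak vectors individually predicting fewer than
    min_predicted nodes (single-plane-family count); (2) prune vector pairs
    by their joint predicted count; (3) form triples, rejecting small
    determinants (angle-degeneracy guard and absolute floor); (4) require
    the triple's joint predicted count; (5) known-cell filter when a prior
    is set; (6) rank by summed peak scores and keep at most max_candidates.

    Fewer than three surviving peaks yields an empty list (a no-solution
    outcome, not an error).
    """
    cfg = config or SelectionConfig()
    if len(peaks) < 3:
        return []
    T = np.array([p.position for p in peaks])
    scores = np.array([p.score for p in peaks])
    X = wrap_offset(nodes.q @ T.T)  # (K, N) per-vector fractional offsets
    M = (np.abs(X) <= cfg.relative_tol).T  # (N, K) inlier masks
    good = M.sum(axis=1) >= cfg.min_predicted
    T, scores, M = T[good], scores[good], M[good]
    n = len(T)
    if n < 3:
        return []
    norms = np.linalg.norm(T, axis=1)
    Mi = M.astype(np.int32)
    pair_counts = Mi @ Mi.T
    out: list[tuple[float, np.ndarray]] = []
    for i, j in itertools.combinations(range(n), 2):
        if pair_counts[i, j] < cfg.min_predicted:
            continue
        cross = np.cross(T[i], T[j])
        ls = np.arange(j + 1, n)
        if len(ls) == 0:
            continue
        dets = np.abs(T[ls] @ cross)
        det_floor = np.maximum(
            cfg.det_abs_floor, cfg.det_rel_floor * norms[i] * norms[j] * norms[ls]
        )
        cnt3 = ((M[i] & M[j])[None, :] & M[ls]).sum(axis=1)
        ok = (dets >= det_floor) & (cnt3 >= cfg.min_predicted)
        ok &= pair_counts[i, ls] >= cfg.min_predicted
        ok &= pair_counts[j, ls] >= cfg.min_predicted
        for l in ls[ok]:
            out.append((scores[i] + scores[j] + scores[l], np.array([T[i], T[j], T[l]])))
    if cfg.known_cell is not None:
        out = [
            (s, m)
            for s, m in out
            if _cell_matches(reduce_basis(LatticeBasis(m)), cfg)
        ]
    out.sort(key=lambda sm: -sm[0])
    return [
        CandidateBasis(basis=LatticeBasis(m), score=float(s))
        for s, m in out[: cfg.max_candidates]
    ]


# ---------------------------------------------------------------------------
# Selection and refinement
# ---------------------------------------------------------------------------


@dataclass
class _Evaluated:
    basis: LatticeBasis
    score: float
    n_predicted: int
    assignment: MillerAssignment
    defects: DefectReport
    mask: np.ndarray


def _min_count(nodes: NodeSet, cfg: SelectionConfig) -> int:
    return max(cfg.min_predicted, int(np.ceil(cfg.min_predicted_fraction * nodes.K)))


def _evaluate(cand: CandidateBasis, nodes: NodeSet, cfg: SelectionConfig):
    red = reduce_basis(cand.basis)
    n, asg = count_predicted(red, nodes, cfg.relative_tol)
    if n < _min_count(nodes, cfg):
        return None
    defects = compute_defects(red, nodes, cfg.relative_tol)
    if defects.relative_defect > 2.0 * cfg.resolve_max_relative_defect():
        return None
    return _Evaluated(red, cand.score, n, asg, defects, asg.assigned.copy())


def select_lattices(
    candidates: list[CandidateBasis],
    nodes: NodeSet,
    config: SelectionConfig | None = None,
) -> list[IndexingSolution]:
    """Shortlist and greedily accept lattices from the candidate bases.

    Candidates are reduced and evaluated; the shortlist is the union of the
    top ``shortlist_by_score`` by summed peak score and the top
    ``shortlist_by_defect`` by smallest relative defect.  Sorted by
    descending predicted-node count (ties: smaller |det| first — supercell
    avoidance — then smaller relative defect), a candidate is accepted if it
    predicts at least ``min_predicted`` nodes claimed by no accepted lattice,
    or replaces an accepted lattice covering essentially the same nodes when
    its relative defect is significantly smaller.
    """
    cfg = config or SelectionConfig()
    evaluated = [e for c in candidates if (e := _evaluate(c, nodes, cfg)) is not None]
    # drop duplicates: candidates reducing to the same cell keep the best score
    unique: dict[tuple, _Evaluated] = {}
    for e in evaluated:
        key = (
            tuple(np.round(np.sort(e.basis.lengths), 2)),
            tuple(np.round(np.sort(np.minimum(e.basis.angles, 180 - e.basis.angles)), 1)),
        )
        held = unique.get(key)
        if held is None or e.score > held.score:
            unique[key] = e
    evaluated = list(unique.values())
    if not evaluated:
        return []
    by_score = sorted(range(len(evaluated)), key=lambda i: -evaluated[i].score)
    # near-equal defects (differences below the candidate-position noise)
    # prefer the smaller cell, so primitive bases are not crowded out of the
    # shortlist by their supercells
    def defect_key(i):
        e = evaluated[i]
        return (
            round(e.defects.relative_defect / 0.02),
            abs(e.basis.determinant),
            e.defects.relative_defect,
        )

    by_defect = sorted(range(len(evaluated)), key=defect_key)
    shortlist_idx = sorted(
        set(by_score[: cfg.shortlist_by_score]) | set(by_defect[: cfg.shortlist_by_defect])
    )
    shortlist = [evaluated[i] for i in shortlist_idx]
    shortlist.sort(
        key=lambda e: (
            -e.n_predicted,
            abs(e.basis.determinant),
            e.defects.relative_defect,
        )
    )
    accepted: list[_Evaluated] = []
    for cand in shortlist:
        claimed = np.zeros(nodes.K, dtype=bool)
        for a in accepted:
            claimed |= a.mask
        new_nodes = int((cand.mask & ~claimed).sum())
        if new_nodes >= cfg.min_predicted:
            accepted.append(cand)
            continue
        # replacement: same node set, significantly smaller defects
        for i, a in enumerate(accepted):
            overlap = int((cand.mask & a.mask).sum())
            denom = max(int(cand.mask.sum()), int(a.mask.sum()))
            if denom == 0 or overlap / denom < cfg.overlap_fraction:
                continue
            if (
                cand.defects.relative_defect
                < cfg.defect_improvement * a.defects.relative_defect
                # a better fit to the same nodes never grows the cell
                # (supercells of the incumbent are not an improvement)
                and abs(cand.basis.determinant) <= 1.05 * abs(a.basis.determinant)
            ):
                accepted[i] = cand
            break
    return [
        IndexingSolution(
            basis=a.basis,
            assignment=a.assignment,
            defects=a.defects,
            lattice_id=k,
            score=a.score,
        )
        for k, a in enumerate(accepted)
    ]


def refine_basis(
    basis: LatticeBasis,
    nodes: NodeSet,
    config: RefineConfig | None = None,
) -> LatticeBasis:
    """Refine a basis to minimize the mean distance to its inlier nodes.

    Alternates {assign inlier nodes -> least-squares update of the
    reciprocal matrix over the inliers}, accepting an update only when the
    mean Euclidean distance between observed and predicted nodes decreases,
    so the objective is non-increasing across iterations.  Stops when the
    decrease falls below ``min_improvement`` or after ``max_iterations``;
    aborts (returning the last valid basis, with a warning) if the inlier
    count drops below five.
    """
    cfg = config or RefineConfig()

    def objective(b: LatticeBasis):
        n, asg = count_predicted(b, nodes, cfg.relative_tol)
        if n == 0:
            return np.inf, n, asg
        sel = asg.assigned
        return (
            float(np.linalg.norm(nodes.q[sel] - asg.predicted_q[sel], axis=1).mean()),
            n,
            asg,
        )

    best = basis
    obj, n, asg = objective(best)
    if n < 5:
        log.warning("refinement skipped: only %d inlier nodes", n)
        return best
    for _ in range(cfg.max_iterations):
        sel = asg.assigned
        H = asg.hkl[sel].astype(float)
        if np.linalg.matrix_rank(H) < 3:
            break
        # q_pred = h . R with R rows = reciprocal vectors; LSQ for R
        R, *_ = np.linalg.lstsq(H, nodes.q[sel], rcond=None)
        try:
            new_basis = LatticeBasis(np.linalg.inv(R).T)
        except np.linalg.LinAlgError:
            break
        new_obj, new_n, new_asg = objective(new_basis)
        if new_n < 5:
            log.warning("refinement aborted: inlier count fell to %d", new_n)
            break
        if not (new_obj < obj):
            break
        improved = obj - new_obj
        best, obj, asg = new_basis, new_obj, new_asg
        if improved < cfg.min_improvement:
            break
    return best


# ---------------------------------------------------------------------------
# Top-level indexing
# ---------------------------------------------------------------------------


@dataclass
class IndexingConfig:
    """End-to-end indexing configuration."""

    profile: str = "fast"
    volume: SearchVolume | None = None
    known_cell: tuple[float, float, float, float, float, float] | None = None
    extended_search: bool = False  # add 110/011/101 diagonal shells
    heuristic: HeuristicConfig | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    mode: str = "one_pass"  # or 'delete_and_retry'
    max_rounds: int = 5
    epsilon: float = 0.15
    filter_cell: bool = True  # apply the known cell as a candidate filter

    def resolve_heuristic(self) -> HeuristicConfig:
        return self.heuristic or HeuristicConfig.from_profile(
            self.profile, epsilon=self.epsilon
        )

    def resolve_volume(self) -> SearchVolume:
        if self.volume is not None:
            return self.volume
        if self.known_cell is not None:
            basis = LatticeBasis.from_parameters(*self.known_cell)
            radii = list(basis.lengths)
            if self.extended_search:
                a, b, c = basis.matrix
                radii += [
                    float(np.linalg.norm(a + b)),
                    float(np.linalg.norm(b + c)),
                    float(np.linalg.norm(a + c)),
                ]
            return SearchVolume(mode="known_cell", shell_radii=tuple(radii))
        return SearchVolume(mode="unknown_cell")

    def resolve_selection(self) -> SelectionConfig:
        sel = self.selection
        if self.known_cell is not None and self.filter_cell and sel.known_cell is None:
            sel = SelectionConfig(**{**sel.__dict__, "known_cell": self.known_cell})
        return sel


def _index_once(
    nodes: NodeSet, cfg: IndexingConfig, seed: int | None
) -> list[IndexingSolution]:
    heur = cfg.resolve_heuristic()
    vol = cfg.resolve_volume()
    sel = cfg.resolve_selection()
    peaks = find_lattice_vector_candidates(nodes, vol, heur, seed=seed)
    candidates = enumerate_candidate_bases(peaks, nodes, sel)
    solutions = select_lattices(candidates, nodes, sel)
    refined: list[IndexingSolution] = []
    for sol in solutions:
        b = refine_basis(sol.basis, nodes, cfg.refine)
        b = reduce_basis(b)
        n, asg = count_predicted(b, nodes, sel.relative_tol)
        defects = compute_defects(b, nodes, sel.relative_tol)
        # final significance check on the refined fit
        if n < _min_count(nodes, sel):
            continue
        if defects.relative_defect > sel.resolve_max_relative_defect():
            continue
        refined.append(
            IndexingSolution(
                basis=b,
                assignment=asg,
                defects=defects,
                lattice_id=len(refined),
                score=sol.score,
            )
        )
    return refined


def index(
    nodes: NodeSet,
    config: IndexingConfig | None = None,
    seed: int | None = None,
) -> list[IndexingSolution]:
    """Index a node set: returns the accepted lattices (possibly empty).

    Fewer than five nodes is a no-solution outcome, not an error.  In
    ``one_pass`` mode all lattices are taken from a single run; in
    ``delete_and_retry`` mode the strongest lattice's predicted nodes are
    removed and indexing re-runs (at most ``max_rounds`` times).
    """
    cfg = config or IndexingConfig()
    if nodes.K < 5:
        return []
    if cfg.mode == "one_pass":
        return _index_once(nodes, cfg, seed)
    if cfg.mode != "delete_and_retry":
        raise ValueError("mode must be 'one_pass' or 'delete_and_retry'")
    remaining = np.arange(nodes.K)
    solutions: list[IndexingSolution] = []
    rng = np.random.default_rng(seed)
    for round_no in range(cfg.max_rounds):
        sub = nodes.subset(remaining)
        if sub.K < 5:
            break
        round_seed = int(rng.integers(2**31 - 1)) if seed is not None else None
        found = _index_once(sub, cfg, round_seed)
        if not found:
            break
        strongest = max(found, key=lambda s: s.defects.n_predicted)
        # lift the assignment back to the original node indexing
        full_hkl = np.zeros((nodes.K, 3), dtype=int)
        full_assigned = np.zeros(nodes.K, dtype=bool)
        full_pred = np.zeros((nodes.K, 3))
        full_hkl[remaining] = strongest.assignment.hkl
        full_assigned[remaining] = strongest.assignment.assigned
        full_pred[remaining] = strongest.assignment.predicted_q
        strongest.assignment = MillerAssignment(full_hkl, full_assigned, full_pred)
        strongest.lattice_id = round_no
        solutions.append(strongest)
        remaining = remaining[~strongest.assignment.assigned[remaining]]
    return solutions
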
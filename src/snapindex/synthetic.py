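"""Ground-truth synthetic diffraction scenes and solution evaluation.

A scene draws one to three independently oriented lattices of a given unit
cell, samples reciprocal-lattice points within a resolution limit
(restricted to a thin shell around the Ewald sphere in ``ewald_mode``, which
mimics still-image geometry), perturbs them with isotropic Gaussian noise,
and appends spurious nodes that belong to no lattice.  Per-node truth
labels are kept, so indexing solutions can be scored against the generating
bases.

Correctness of a recovered basis is judged by the rotation angle (Kabsch
superposition) needed to bring it into coincidence with a ground-truth
basis, minimized over the 48 signed axis permutations with matching cell
lengths; a solution within 3 degrees counts as correct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import NodeSet
from .lattice import IndexingConfig, IndexingSolution, LatticeBasis, index, reduce_basis

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "TrialResult",
    "DEFAULT_CELL",
    "simulate_scene",
    "kabsch_rotation_angle",
    "bases_equivalent",
    "success_rate",
]

# Default triclinic test cell: low symmetry avoids accidental degeneracies
# that would confound basis-equivalence checks.
DEFAULT_CELL = (35.0, 45.0, 60.0, 85.0, 95.0, 100.0)


@dataclass(frozen=True)
class SceneParams:
    """Synthetic-scene generation parameters.

    noise_sigma is the isotropic Gaussian positional noise in 1/Angstrom
    (use :meth:`with_noise_fraction` to express it as a fraction of the
    smallest reciprocal basis-vector length).  n_spurious nodes are sampled
    uniformly in the resolution ball (on the Ewald shell in ewald_mode).
    """

    cell: tuple[float, float, float, float, float, float] = DEFAULT_CELL
    n_lattices: int = 1
    n_nodes: int = 25
    noise_sigma: float = 0.0
    n_spurious: int = 0
    q_max: float = 0.25  # 1/Angstrom resolution limit
    ewald_mode: bool = True
    wavelength: float = 1.0  # Angstrom, used in ewald_mode
    shell_half_thickness: float = 0.002  # 1/Angstrom

    def with_noise_fraction(self, fraction: float) -> "SceneParams":
        """Set noise_sigma to a fraction of the smallest reciprocal spacing."""
        basis = LatticeBasis.from_parameters(*self.cell)
        smallest = float(np.linalg.norm(basis.reciprocal_rows, axis=1).min())
        return replace(self, noise_sigma=fraction * smallest)


@dataclass
class SyntheticScene:
    """A generated scene: true bases, nodes and per-node truth labels."""

    true_bases: list[LatticeBasis]
    nodes: NodeSet
    labels: np.ndarray  # (K,) int; lattice index or -1 for spurious
    params: SceneParams
    seed: int | None = None


@dataclass
class TrialResult:
    """Outcome of indexing one synthetic scene against its ground truth."""

    recovered: bool
    kabsch_angle_deg: float  # best angle over solutions vs any true basis
    n_lattices_found: int
    per_lattice_recovered: list[bool] = field(default_factory=list)
    cell_length_error: float = np.nan  # max relative length error of best match


def _ewald_shell_mask(q: np.ndarray, wavelength: float, half_thickness: float):
    centre = np.array([0.0, 0.0, -1.0 / wavelength])
    return (
        np.abs(np.linalg.norm(q - centre, axis=1) - 1.0 / wavelength) <= half_thickness
    )


def _truncated_gaussian(rng, shape, sigma, cap=5.0):
    """Isotropic Gaussian noise with rejection beyond cap*sigma."""
    out = sigma * rng.standard_normal(shape)
    for _ in range(100):
        bad = np.linalg.norm(out, axis=-1) > cap * sigma
        if not bad.any():
            break
        out[bad] = sigma * rng.standard_normal((int(bad.sum()), shape[-1]))
    return out


def simulate_scene(params: SceneParams, seed: int | None = None) -> SyntheticScene:
    """Generate a synthetic scene; deterministic under seed."""
    rng = np.random.default_rng(seed)
    base = LatticeBasis.from_parameters(*params.cell)
    hmax = np.ceil(base.lengths * params.q_max).astype(int) + 1
    grid = np.array(
        list(
            itertools.product(
                range(-hmax[0], hmax[0] + 1),
                range(-hmax[1], hmax[1] + 1),
                range(-hmax[2], hmax[2] + 1),
            )
        ),
        dtype=float,
    )
    grid = grid[np.any(grid != 0, axis=1)]

    all_q: list[np.ndarray] = []
    labels: list[int] = []
    true_bases: list[LatticeBasis] = []
    for lat in range(params.n_lattices):
        rot = Rotation.random(random_state=rng).as_matrix()
        basis = LatticeBasis(base.matrix @ rot.T)
        true_bases.append(basis)
        q_all = grid @ basis.reciprocal_rows
        mask = np.linalg.norm(q_all, axis=1) <= params.q_max
        if params.ewald_mode:
            mask &= _ewald_shell_mask(
                q_all, params.wavelength, params.shell_half_thickness
            )
        reachable = q_all[mask]
        if len(reachable) < params.n_nodes:
            raise ValueError(
                f"only {len(reachable)} reciprocal points reachable; "
                f"increase q_max or shell thickness"
            )
        pick = rng.choice(len(reachable), size=params.n_nodes, replace=False)
        q = reachable[pick]
        if params.noise_sigma > 0:
            q = q + _truncated_gaussian(rng, q.shape, params.noise_sigma)
        all_q.append(q)
        labels += [lat] * params.n_nodes

    if params.n_spurious > 0:
        if params.ewald_mode:
            # spurious detector peaks still map onto the Ewald sphere
            centre = np.array([0.0, 0.0, -1.0 / params.wavelength])
            sp = []
            while len(sp) < params.n_spurious:
                v = rng.standard_normal(3)
                v = centre + v / np.linalg.norm(v) / params.wavelength
                if 0 < np.linalg.norm(v) <= params.q_max:
                    sp.append(v)
            sp = np.array(sp)
        else:
            u = rng.random(params.n_spurious) ** (1.0 / 3.0)
            d = rng.standard_normal((params.n_spurious, 3))
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            sp = params.q_max * u[:, None] * d
        all_q.append(sp)
        labels += [-1] * params.n_spurious

    q = np.concatenate(all_q, axis=0)
    labels_arr = np.array(labels, dtype=int)
    perm = rng.permutation(len(q))
    source = np.where(labels_arr[perm] < 0, "spurious-synthetic", "synthetic").astype(
        object
    )
    return SyntheticScene(
        true_bases=true_bases,
        nodes=NodeSet(q[perm], source=source),
        labels=labels_arr[perm],
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Solution evaluation
# ---------------------------------------------------------------------------


def kabsch_rotation_angle(basis_a: LatticeBasis, basis_b: LatticeBasis) -> float:
    """Angle (degrees) of the proper rotation best superposing two triads.

    The rotation minimizes the RMSD over the three paired basis vectors
    (det R = +1 enforced); the result is invariant under a joint rotation of
    both bases.
    """
    for b in (basis_a, basis_b):
        if abs(b.determinant) < 1e-12:
            raise ValueError("singular basis")
    rot, _ = Rotation.align_vectors(basis_a.matrix, basis_b.matrix)
    return float(np.degrees(rot.magnitude()))


def _signed_permutations():
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1.0, -1.0), repeat=3):
            m = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            mats.append(m)
    return mats


_SIGNED_PERMS = _signed_permutations()


def bases_equivalent(
    solution_basis: LatticeBasis,
    true_basis: LatticeBasis,
    angle_tol_deg: float = 3.0,
    length_tol: float = 0.05,
) -> bool:
    """True when the two bases describe the same lattice orientation.

    Both bases are reduced; the Kabsch angle is minimized over the 48 signed
    axis permutations whose per-row cell lengths match within ``length_tol``.
    """
    return (
        min_equivalence_angle(solution_basis, true_basis, length_tol) <= angle_tol_deg
    )


def min_equivalence_angle(
    solution_basis: LatticeBasis,
    true_basis: LatticeBasis,
    length_tol: float = 0.05,
) -> float:
    """Smallest Kabsch angle over length-matching signed axis relabelings."""
    ra = reduce_basis(solution_basis)
    rb = reduce_basis(true_basis)
    best = np.inf
    lb = rb.lengths
    for P in _SIGNED_PERMS:
        m = P @ ra.matrix
        lengths = np.linalg.norm(m, axis=1)
        if np.any(np.abs(lengths - lb) > length_tol * lb):
            continue
        rot, _ = Rotation.align_vectors(rb.matrix, m)
        best = min(best, float(np.degrees(rot.magnitude())))
    return best


def _best_match(
    solutions: list[IndexingSolution], truth: LatticeBasis
) -> tuple[float, float]:
    """(min angle, cell length error) of the best solution for one true basis."""
    best_angle, best_len = np.inf, np.nan
    rt = reduce_basis(truth)
    for sol in solutions:
        ang = min_equivalence_angle(sol.basis, truth)
        if ang < best_angle:
            best_angle = ang
            rs = reduce_basis(sol.basis)
            best_len = float(
                np.max(np.abs(np.sort(rs.lengths) - np.sort(rt.lengths)) / np.sort(rt.lengths))
            )
    return best_angle, best_len


def evaluate_solutions(
    solutions: list[IndexingSolution],
    scene: SyntheticScene,
    angle_tol_deg: float = 3.0,
) -> TrialResult:
    """Score a solution list against a scene's ground truth."""
    per_lattice = []
    best_angle, best_len = np.inf, np.nan
    for truth in scene.true_bases:
        ang, lerr = _best_match(solutions, truth)
        per_lattice.append(bool(ang <= angle_tol_deg))
        if ang < best_angle:
            best_angle, best_len = ang, lerr
    return TrialResult(
        recovered=any(per_lattice),
        kabsch_angle_deg=float(min(best_angle, 180.0)),
        n_lattices_found=len(solutions),
        per_lattice_recovered=per_lattice,
        cell_length_error=best_len,
    )


def success_rate(
    scene_params: SceneParams,
    n_trials: int,
    seeds: list[int] | None = None,
    indexing_config: IndexingConfig | None = None,
    angle_tol_deg: float = 3.0,
) -> tuple[float, list[TrialResult]]:
    """Index n_trials seeded scenes; success = any true basis recovered.

    Returns the success fraction and the per-trial details.  Exactly
    reproducible under a fixed seed list.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seeds is None:
        seeds = list(range(n_trials))
    if len(seeds) != n_trials:
        raise ValueError("need one seed per trial")
    results = []
    for s in seeds:
        scene = simulate_scene(scene_params, seed=s)
        sols = index(scene.nodes, indexing_config, seed=s)
        results.append(evaluate_solutions(sols, scene, angle_tol_deg))
    rate = sum(r.recovered for r in results) / n_trials
    return rate, results
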
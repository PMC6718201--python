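"""Periodic proximity functions and the lattice-vector score function.

Every node q defines the real-space plane family {t : q . t integer}.  A
*proximity function* c is a periodic (period 1), even function on
[-0.5, 0.5] that equals 1 on the planes, -1 midway between planes, and is
non-increasing away from a plane.  The score of a trial real-space vector t
against K nodes is the normalized weighted sum

    S(t) = sum_k w_k c(x_k) / sum_k w_k,        x_k = wrap(q_k . t),

whose maxima are candidate lattice vectors.  With the cosine proximity and
unit weights, S is the real part of the Fourier transform of the node
arrangement evaluated at t.

A tolerant variant excludes nodes whose nearest plane is farther than a
fractional tolerance eps from t:

    S_eps(t) = sum_{k : |x_k| <= eps} w_k c(x_k / (2 eps)) / sum_k w_k,

which confers robustness to spurious nodes at the cost of discontinuities.
The denominator runs over *all* node weights so that vectors explaining few
nodes are penalized; an empty inclusion set scores -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Node, NodeSet

__all__ = [
    "ProximityFunction",
    "PROXIMITY_KINDS",
    "ScoreConfig",
    "wrap_offset",
    "fractional_offset",
    "score",
    "score_tolerant",
    "score_gradient",
    "score_batch",
    "gradient_batch",
]

_SIGMA_A = 0.1  # width of the narrow-Gaussian proximity bump
_HALF_B = 0.15  # half-width of the narrow-triangle proximity bump


def _cos_val(x):
    return np.cos(2.0 * np.pi * x)


def _cos_der(x):
    return -2.0 * np.pi * np.sin(2.0 * np.pi * x)


def _tri_val(x):
    return 1.0 - 4.0 * np.abs(x)


def _tri_der(x):
    return -4.0 * np.sign(x)


# Narrow Gaussian bump, affinely rescaled so that c(0)=1 and c(+/-0.5)=-1.
_G0 = 1.0  # 2*exp(0) - 1
_G5 = 2.0 * np.exp(-(0.5 / _SIGMA_A) ** 2) - 1.0


def _sharp_a_val(x):
    g = 2.0 * np.exp(-((x / _SIGMA_A) ** 2)) - 1.0
    return -1.0 + 2.0 * (g - _G5) / (_G0 - _G5)


def _sharp_a_der(x):
    dg = 2.0 * np.exp(-((x / _SIGMA_A) ** 2)) * (-2.0 * x / _SIGMA_A**2)
    return 2.0 * dg / (_G0 - _G5)


def _sharp_b_val(x):
    return 2.0 * np.maximum(0.0, 1.0 - np.abs(x) / _HALF_B) - 1.0


def _sharp_b_der(x):
    inside = np.abs(x) < _HALF_B
    return np.where(inside, -2.0 / _HALF_B * np.sign(x), 0.0)


_FAMILY = {
    "cosine": (_cos_val, _cos_der),
    "triangle": (_tri_val, _tri_der),
    "sharp_a": (_sharp_a_val, _sharp_a_der),
    "sharp_b": (_sharp_b_val, _sharp_b_der),
}

PROXIMITY_KINDS = tuple(_FAMILY)


@dataclass(frozen=True)
class ProximityFunction:
    """A named member of the proximity-function family.

    ``value`` maps [-0.5, 0.5] -> [-1, 1] with value(0)=1, value(+-0.5)=-1,
    even and non-increasing on [0, 0.5]; ``derivative`` is its derivative
    (one-sided at kinks of the piecewise-linear members).
    """

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _FAMILY:
            raise ValueError(
                f"unknown proximity kind {self.kind!r}; choose from {PROXIMITY_KINDS}"
            )

    def value(self, x):
        return _FAMILY[self.kind][0](np.asarray(x, dtype=float))

    def derivative(self, x):
        return _FAMILY[self.kind][1](np.asarray(x, dtype=float))

    @classmethod
    def get(cls, kind) -> "ProximityFunction":
        return kind if isinstance(kind, cls) else cls(kind)


@dataclass
class ScoreConfig:
    """Configuration of the score function.

    weights : per-node non-negative weights (None = unity).
    epsilon : fractional-distance tolerance in (0, 0.5] for the tolerant mode.
    use_tolerance : select the tolerant (discontinuous) score.
    """

    proximity: ProximityFunction = field(
        default_factory=lambda: ProximityFunction("cosine")
    )
    weights: np.ndarray | None = None
    epsilon: float = 0.15
    use_tolerance: bool = False

    def __post_init__(self) -> None:
        self.proximity = ProximityFunction.get(self.proximity)
        if not (0.0 < self.epsilon <= 0.5):
            raise ValueError("epsilon must be in (0, 0.5]")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            self.weights = w

    def node_weights(self, nodes: NodeSet) -> np.ndarray:
        if self.weights is None:
            return np.ones(nodes.K)
        if self.weights.shape != (nodes.K,):
            raise ValueError("weights length must match node count")
        return self.weights


def wrap_offset(x):
    """Wrap to (-0.5, 0.5] with the midpoint tie broken toward +0.5."""
    x = np.asarray(x, dtype=float)
    return x - np.ceil(x - 0.5)


def fractional_offset(node: Node | np.ndarray, t: np.ndarray):
    """Signed fractional distance of t from the nearest plane of a node.

    Returns x = q.t - round(q.t) in (-0.5, 0.5]; |x| measures the distance in
    units of the plane spacing 1/|q|.
    """
    q = node.q if isinstance(node, Node) else np.asarray(node, dtype=float)
    return wrap_offset(float(np.dot(q, t)))


def _check_nodes(nodes: NodeSet) -> None:
    if nodes.K == 0:
        raise ValueError("score requires at least one node")


def score_batch(T: np.ndarray, nodes: NodeSet, cfg: ScoreConfig):
    """Vectorized score of M trial vectors: returns (scores, inlier counts).

    Inlier counts are the number of nodes within cfg.epsilon of a plane,
    reported in both modes.
    """
    _check_nodes(nodes)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    w = cfg.node_weights(nodes)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("sum of node weights must be positive")
    F = wrap_offset(T @ nodes.q.T)  # (M, K)
    inl = np.abs(F) <= cfg.epsilon
    n_in = inl.sum(axis=1)
    if cfg.use_tolerance:
        vals = cfg.proximity.value(F / (2.0 * cfg.epsilon))
        s = (np.where(inl, vals, 0.0) @ w) / wsum
        s = np.where(n_in == 0, -1.0, s)
    else:
        s = (cfg.proximity.value(F) @ w) / wsum
    return s, n_in


def gradient_batch(T: np.ndarray, nodes: NodeSet, cfg: ScoreConfig) -> np.ndarray:
    """Vectorized analytic gradient of the score at M trial vectors."""
    _check_nodes(nodes)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    w = cfg.node_weights(nodes)
    wsum = w.sum()
    F = wrap_offset(T @ nodes.q.T)
    if cfg.use_tolerance:
        inl = np.abs(F) <= cfg.epsilon
        ders = cfg.proximity.derivative(F / (2.0 * cfg.epsilon)) / (2.0 * cfg.epsilon)
        coef = np.where(inl, ders, 0.0) * w
    else:
        coef = cfg.proximity.derivative(F) * w
    return (coef @ nodes.q) / wsum


def score(t: np.ndarray, nodes: NodeSet, cfg: ScoreConfig) -> float:
    """Score S(t) of a single trial vector (plain, bounded in [-1, 1])."""
    s, _ = score_batch(t, nodes, cfg)
    return float(s[0])


def score_tolerant(t: np.ndarray, nodes: NodeSet, cfg: ScoreConfig):
    """Tolerant score S_eps(t); returns (score, inlier count)."""
    tol_cfg = ScoreConfig(
        proximity=cfg.proximity,
        weights=cfg.weights,
        epsilon=cfg.epsilon,
        use_tolerance=True,
    )
    s, n = score_batch(t, nodes, tol_cfg)
    return float(s[0]), int(n[0])


def score_gradient(t: np.ndarray, nodes: NodeSet, cfg: ScoreConfig) -> np.ndarray:
    """Analytic gradient of the (plain or tolerant) score at t."""
    return gradient_batch(t, nodes, cfg)[0]
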
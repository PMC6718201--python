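"""Detector geometry and reciprocal-space mapping.

A Bragg peak observed at detector coordinates (fs, ss) is mapped to its
momentum-transfer vector

    q = (s_hat - s0_hat) / lambda,

where ``s0_hat`` is the unit incident-beam direction and ``s_hat`` the unit
vector from the sample to the peak's position in the lab frame.  We call the
resulting 3-vector a *node*: a noisy sample of a reciprocal-lattice point.
Crystallographic convention is used throughout (no 2*pi factor), so q has
units of 1/Angstrom and q . t is an integer whenever t is a real-space
lattice vector.

Lab-frame conventions: the beam travels along +z; the (flat, single-panel)
detector plane is normal to the beam at z = detector_distance; the fs/ss
detector axes map to lab x/y.  An optional tilt rotation can be applied to
the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "DetectorGeometry",
    "PeakObservation",
    "Node",
    "NodeSet",
    "map_peak_to_node",
    "node_to_peak",
    "peaks_to_nodes",
    "plane_spacing",
    "ewald_residual",
    "read_geometry",
    "read_peak_list",
    "read_node_list",
    "write_node_list",
]

_BEAM = np.array([0.0, 0.0, 1.0])  # unit incident-beam direction s0_hat


@dataclass(frozen=True)
class DetectorGeometry:
    """Single flat-panel experiment geometry.

    Parameters
    ----------
    wavelength : float
        Incident wavelength in Angstrom.
    detector_distance : float
        Sample-to-detector distance in mm.
    pixel_size : float
        Pixel edge length in mm (square pixels).
    beam_center : tuple of float
        Beam centre on the panel in pixels, (fs, ss).
    tilt : ndarray, optional
        3x3 rotation applied to the panel; identity by default.
    """

    wavelength: float
    detector_distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    tilt: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise ValueError("wavelength must be > 0")
        if not (self.detector_distance > 0):
            raise ValueError("detector_distance must be > 0")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")
        t = np.asarray(self.tilt, dtype=float)
        if t.shape != (3, 3) or not np.allclose(t @ t.T, np.eye(3), atol=1e-8):
            raise ValueError("tilt must be a 3x3 rotation matrix")
        object.__setattr__(self, "tilt", t)


@dataclass(frozen=True)
class PeakObservation:
    """One detected Bragg spot: detector position (pixels) and intensity."""

    fs_px: float
    ss_px: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fs_px) and np.isfinite(self.ss_px)):
            raise ValueError("peak coordinates must be finite")
        if not (np.isfinite(self.intensity) and self.intensity >= 0):
            raise ValueError("intensity must be finite and >= 0")


@dataclass(frozen=True)
class Node:
    """A reciprocal-space node: q in 1/Angstrom, with a weight and a source tag.

    A node with |q| = 0 (zero scattering angle) is unusable; it is flagged by
    ``usable`` and dropped, with a warning, when building a :class:`NodeSet`.
    """

    q: np.ndarray
    weight: float = 1.0
    source: str = "observed"

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (3,) or not np.all(np.isfinite(q)):
            raise ValueError("q must be a finite 3-vector")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        object.__setattr__(self, "q", q)

    @property
    def usable(self) -> bool:
        return bool(np.linalg.norm(self.q) > 0)


class NodeSet:
    """Ordered collection of nodes, stored as a (K, 3) array of q vectors."""

    def __init__(
        self,
        q: np.ndarray,
        weights: np.ndarray | None = None,
        source: np.ndarray | None = None,
    ) -> None:
        q = np.atleast_2d(np.asarray(q, dtype=float))
        if q.ndim != 2 or q.shape[1] != 3:
            raise ValueError("q must be a (K, 3) array")
        self.q = q
        self.weights = (
            np.ones(len(q)) if weights is None else np.asarray(weights, dtype=float)
        )
        if self.weights.shape != (len(q),) or np.any(self.weights < 0):
            raise ValueError("weights must be a non-negative (K,) array")
        self.source = (
            np.full(len(q), "observed", dtype=object)
            if source is None
            else np.asarray(source, dtype=object)
        )

    @classmethod
    def from_nodes(cls, nodes: list[Node]) -> "NodeSet":
        if not nodes:
            return cls(np.empty((0, 3)))
        return cls(
            np.array([n.q for n in nodes]),
            np.array([n.weight for n in nodes]),
            np.array([n.source for n in nodes], dtype=object),
        )

    @property
    def K(self) -> int:
        return len(self.q)

    def __len__(self) -> int:
        return len(self.q)

    @property
    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.q, axis=1)

    def subset(self, mask: np.ndarray) -> "NodeSet":
        return NodeSet(self.q[mask], self.weights[mask], self.source[mask])


def map_peak_to_node(peak: PeakObservation, geom: DetectorGeometry) -> Node:
    """Map one detector peak to its reciprocal-space node.

    The returned q lies on the Ewald sphere of radius 1/lambda centred at
    -s0_hat/lambda and satisfies |q| = 2 sin(theta)/lambda.  A peak at the
    beam centre maps to q = 0 and is flagged unusable (weight 0).

    Raises
    ------
    ValueError
        If the peak's lab-frame position lies behind the sample plane
        (possible with a tilted panel).
    """
    cx, cy = geom.beam_center
    panel = np.array(
        [
            (peak.fs_px - cx) * geom.pixel_size,
            (peak.ss_px - cy) * geom.pixel_size,
            geom.detector_distance,
        ]
    )
    lab = geom.tilt @ panel
    if lab[2] <= 0:
        raise ValueError(
            f"peak ({peak.fs_px}, {peak.ss_px}) maps behind the sample plane"
        )
    s_hat = lab / np.linalg.norm(lab)
    q = (s_hat - _BEAM) / geom.wavelength
    if not np.all(np.isfinite(q)):  # pragma: no cover - defensive
        raise ValueError("non-finite node from peak mapping")
    if np.linalg.norm(q) == 0.0:
        return Node(q=np.zeros(3), weight=0.0, source="observed")
    return Node(q=q, weight=max(peak.intensity, 0.0) or 1.0, source="observed")


def node_to_peak(node: Node, geom: DetectorGeometry) -> PeakObservation:
    """Project a node on the Ewald sphere back to detector coordinates.

    Inverse of :func:`map_peak_to_node` for nodes that satisfy the Ewald
    condition; the scattered direction is renormalized so that small
    off-sphere deviations are tolerated.
    """
    v = geom.wavelength * node.q + _BEAM
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("back-scattering node cannot be projected")
    s_hat = v / n
    lab = geom.tilt.T @ s_hat
    if lab[2] <= 0:
        raise ValueError("node scatters away from the detector")
    panel = lab * (geom.detector_distance / lab[2])
    cx, cy = geom.beam_center
    return PeakObservation(
        fs_px=panel[0] / geom.pixel_size + cx,
        ss_px=panel[1] / geom.pixel_size + cy,
        intensity=max(node.weight, 0.0),
    )


def peaks_to_nodes(
    peaks: list[PeakObservation],
    geom: DetectorGeometry,
    weighting: str = "unity",
) -> NodeSet:
    """Map a peak list to a NodeSet, dropping unusable (q = 0) peaks.

    ``weighting`` selects the per-node weight carried along: ``"unity"``
    (default, the implemented heuristic ignores intensities) or
    ``"intensity"``.
    """
    nodes = []
    for i, p in enumerate(peaks):
        node = map_peak_to_node(p, geom)
        if not node.usable:
            log.warning("dropping peak %d at the beam centre (q = 0)", i)
            continue
        w = p.intensity if weighting == "intensity" else 1.0
        nodes.append(Node(q=node.q, weight=w, source="observed"))
    return NodeSet.from_nodes(nodes)


def plane_spacing(node: Node) -> float:
    """Spacing (Angstrom) of the real-space plane family generated by a node.

    Each node q defines the plane family {t : q . t integer}, orthogonal to q
    with spacing 1/|q|.
    """
    n = np.linalg.norm(node.q)
    if n == 0:
        raise ValueError("degenerate node: |q| = 0 has no plane family")
    return 1.0 / n


def ewald_residual(node: Node, geom: DetectorGeometry) -> float:
    """Distance (1/Angstrom) of a node from the Ewald sphere surface."""
    centre = -_BEAM / geom.wavelength
    return abs(np.linalg.norm(node.q - centre) - 1.0 / geom.wavelength)


# ---------------------------------------------------------------------------
# File I/O: geometry config, peak lists, node lists
# ---------------------------------------------------------------------------


def read_geometry(path) -> DetectorGeometry:
    """Read a flat key-value (YAML) geometry file.

    Required keys: wavelength_A, detector_distance_mm, pixel_size_mm,
    beam_center_px (two values).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: geometry file must be a key-value mapping")
    try:
        bc = data["beam_center_px"]
        return DetectorGeometry(
            wavelength=float(data["wavelength_A"]),
            detector_distance=float(data["detector_distance_mm"]),
            pixel_size=float(data["pixel_size_mm"]),
            beam_center=(float(bc[0]), float(bc[1])),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing geometry key {exc}") from exc


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def _is_header(fields: list[str]) -> bool:
    try:
        float(fields[0])
        return False
    except ValueError:
        return True


def read_peak_list(path) -> list[PeakObservation]:
    """Read a TSV peak list with columns fs_px, ss_px, intensity.

    Comment lines starting with '#' and an optional header row are skipped.
    Malformed rows raise ValueError naming the offending line.
    """
    peaks: list[PeakObservation] = []
    first = True
    for lineno, fields in _data_lines(path):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
        try:
            fs, ss = float(fields[0]), float(fields[1])
            inten = float(fields[2]) if len(fields) > 2 else 0.0
            peaks.append(PeakObservation(fs_px=fs, ss_px=ss, intensity=inten))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def read_node_list(path) -> NodeSet:
    """Read a TSV node list with columns qx, qy, qz (1/Angstrom)."""
    rows = []
    first = True
    for lineno, fields in _data_lines(path):
        if first and _is_header(fields):
            first = False
            continue
        first = False
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns (qx qy qz)")
        try:
            rows.append([float(fields[0]), float(fields[1]), float(fields[2])])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return NodeSet(np.array(rows) if rows else np.empty((0, 3)))


def write_node_list(path, nodes: NodeSet) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("qx\tqy\tqz\n")
        for q in nodes.q:
            fh.write(f"{q[0]:.10g}\t{q[1]:.10g}\t{q[2]:.10g}\n")
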
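"""Synthetic resizable head geometry, 10-20 landmarks, and cortical ROI masks.

The head is modelled as an ovoid (triaxial ellipsoid) scalp surface with a
cortical node shell at a configurable depth below it.  Coordinates are in mm,
right-handed, origin at the head centre: +x toward the right ear, +y toward
the nasion, +z toward the vertex.  The midsagittal plane is x = 0 and the
node sets are constructed to be exactly mirror-symmetric about it, so that a
left-hemisphere region of interest always has a right-hemisphere mirror
partner of identical cardinality (used as the noise-only null region).

The 10-20 landmarks are placed by the standard proportional fractions: Fpz
at 10% of the nasion->Cz->inion arc from the nasion, T7/T8 at 10% of the
LPA->Cz->RPA arc from the pre-auricular points, Cz at the vertex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special
from scipy.spatial import cKDTree

__all__ = [
    "HeadModel",
    "ROIMask",
    "make_synthetic_head",
    "resize_head",
    "select_spherical_roi",
    "mirror_roi",
    "cortical_depth",
    "select_second_roi",
    "save_head",
    "load_head",
    "head_from_meshes",
]

#: cortical depth (mm) beyond which fNIRS light does not reach; used for
#: reporting/classification only, sensitivities are still computed.
REACHABLE_DEPTH_MM = 40.0

# Ovoid axis ratios (x : y : z) for the default synthetic head.  The head is
# longer front-to-back than side-to-side and the vertex sits slightly below
# the half-length; the absolute scale is set by the requested circumference.
_AXIS_RATIO_Y = 1.25
_AXIS_RATIO_Z = 1.15


@dataclass(frozen=True)
class ROIMask:
    """0/1 indicator over cortex nodes defining a spherical region of interest."""

    indicator: np.ndarray  # (n_cortex,) int8, values 0 or 1
    center_node: int
    radius: float  # mm

    @property
    def node_ids(self) -> np.ndarray:
        return np.flatnonzero(self.indicator)

    @property
    def size(self) -> int:
        return int(self.indicator.sum())


@dataclass
class HeadModel:
    """Scalp + cortex node sets with 10-20 landmarks, resizable by circumference.

    ``semi_axes`` holds the analytic ellipsoid (a, b, c) for synthetic heads;
    mesh-loaded heads leave it ``None`` and fall back to node-based geometry.
    """

    scalp_nodes: np.ndarray  # (n_scalp, 3) mm
    cortex_nodes: np.ndarray  # (n_cortex, 3) mm
    landmarks: dict[str, np.ndarray]  # 10-20 label -> scalp point
    circumference: float  # mm
    node_spacing: float  # mm, nominal inter-node distance
    semi_axes: tuple[float, float, float] | None = None
    _scalp_tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _mirror_pairs: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- geometry helpers ---------------------------------------------------

    @property
    def mesh_tolerance(self) -> float:
        """Positional tolerance implied by the node discretisation."""
        return 0.5 * self.node_spacing

    @property
    def scalp_tree(self) -> cKDTree:
        if self._scalp_tree is None:
            self._scalp_tree = cKDTree(self.scalp_nodes)
        return self._scalp_tree

    def mirror_point(self, points: np.ndarray) -> np.ndarray:
        """Reflect points across the midsagittal plane x = 0."""
        points = np.atleast_2d(np.asarray(points, float))
        out = points.copy()
        out[:, 0] = -out[:, 0]
        return out

    def mirror_pairs(self) -> np.ndarray:
        """Index i -> index of the mirror partner of cortex node i.

        Raises ``ValueError`` if any node lacks a partner within the mesh
        tolerance (possible for externally loaded meshes).
        """
        if self._mirror_pairs is None:
            tree = cKDTree(self.cortex_nodes)
            dist, idx = tree.query(self.mirror_point(self.cortex_nodes))
            if np.any(dist > self.mesh_tolerance):
                raise ValueError(
                    "head is not mirror-symmetric within tolerance "
                    f"(max pairing distance {dist.max():.2f} mm)"
                )
            self._mirror_pairs = idx
        return self._mirror_pairs

    def project_to_scalp(self, points: np.ndarray) -> np.ndarray:
        """Project points onto the scalp surface.

        For synthetic (ellipsoid) heads the projection is radial from the
        head centre, which is a good approximation of nearest-point
        projection for points already close to the surface; for mesh heads
        the nearest scalp node is returned.
        """
        points = np.atleast_2d(np.asarray(points, float))
        if self.semi_axes is not None:
            axes = np.asarray(self.semi_axes)
            s = np.sqrt(np.sum((points / axes) ** 2, axis=1))
            s = np.where(s == 0, 1.0, s)
            return points / s[:, None]
        _, idx = self.scalp_tree.query(points)
        return self.scalp_nodes[idx]

    def surface_normal(self, points: np.ndarray, *, outward: bool = True) -> np.ndarray:
        """Unit surface normal at (the projection of) each point."""
        points = np.atleast_2d(np.asarray(points, float))
        if self.semi_axes is not None:
            axes2 = np.asarray(self.semi_axes) ** 2
            n = self.project_to_scalp(points) / axes2
        else:
            # node-based fallback: radial direction from the centroid
            n = points - self.scalp_nodes.mean(axis=0)
        n = n / np.linalg.norm(n, axis=1, keepdims=True)
        return n if outward else -n

    def scalp_point(self, azimuth: float | np.ndarray, elevation: float | np.ndarray) -> np.ndarray:
        """Analytic scalp point at (azimuth, elevation) for synthetic heads.

        Azimuth 0 faces the nasion (+y) and increases toward the right ear
        (+x); elevation pi/2 is the vertex.
        """
        if self.semi_axes is None:
            raise ValueError("analytic parametrisation requires a synthetic head")
        a, b, c = self.semi_axes
        az = np.asarray(azimuth, float)
        el = np.asarray(elevation, float)
        return np.stack(
            [a * np.cos(el) * np.sin(az), b * np.cos(el) * np.cos(az), c * np.sin(el)],
            axis=-1,
        )

    def measured_circumference(self) -> float:
        """Head circumference measured along the 10-20 ring through Fpz.

        Clinically the circumference is taken about 10% above the
        nasion-LPA-inion-RPA contour, i.e. along the ring through Fpz and
        Oz; for the ellipsoid that contour is the horizontal cross-section
        at Fpz's elevation.
        """
        if self.semi_axes is not None:
            a, b, c = self.semi_axes
            z_ring = self.landmarks["Fpz"][2] if "Fpz" in self.landmarks else 0.0
            shrink = np.sqrt(max(1.0 - (z_ring / c) ** 2, 0.0))
            return shrink * _ellipse_perimeter(a, b)
        z_ring = self.landmarks["Fpz"][2] if "Fpz" in self.landmarks else 0.0
        ring = self.scalp_nodes[
            np.abs(self.scalp_nodes[:, 2] - z_ring) < self.node_spacing
        ]
        ang = np.arctan2(ring[:, 0], ring[:, 1])
        order = np.argsort(ang)
        ring = ring[order]
        seg = np.diff(np.vstack([ring, ring[:1]]), axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())


def _ellipse_perimeter(a: float, b: float) -> float:
    big, small = max(a, b), min(a, b)
    m = 1.0 - (small / big) ** 2
    return float(4.0 * big * special.ellipe(m))


# -- construction -----------------------------------------------------------


def default_depth_profile(unit_point: np.ndarray) -> float:
    """Default cortical depth (mm): smoothly varying shell, 13-35 mm, plus a
    deep posterior patch.

    Real cortex sits at a highly variable depth below the scalp (gyral
    crowns shallow, sulcal banks deep), and channel sensitivity decays
    roughly exponentially with depth — this variation is what turns some
    regions into near-blind spots and is the main source of difficulty for
    ROI detection.  The default profile emulates it with a smooth,
    mirror-symmetric undulation (even in azimuth, so left/right symmetry is
    preserved) spanning the gyrus-to-sulcus depth range, and a posterior
    patch at 48 mm, beyond the 40-mm reachability cutoff.  ``unit_point``
    is the scalp point divided by the semi-axes (on the unit sphere).
    """
    x, y, z = unit_point
    if y < -0.55:
        return 48.0
    az = np.arctan2(x, y)
    el = np.arcsin(np.clip(z, -1.0, 1.0))
    return 24.0 + 11.0 * np.cos(2.2 * az) * np.cos(1.5 * el)


def make_synthetic_head(
    circumference: float = 420.0,
    cortical_depth_profile: float | Callable[[np.ndarray], float] | None = None,
    node_spacing: float = 8.0,
) -> HeadModel:
    """Build the synthetic ovoid head used in place of an anatomical atlas.

    Parameters
    ----------
    circumference : mm, horizontal scalp contour circumference.
    cortical_depth_profile : constant depth in mm, or a callable mapping the
        unit-sphere scalp direction to a depth; default 15 mm plus a deep
        (>40 mm) posterior patch.
    node_spacing : mm, nominal spacing of scalp and cortex nodes.
    """
    if circumference <= 0:
        raise ValueError("circumference must be positive")
    if node_spacing <= 0:
        raise ValueError("node_spacing must be positive")

    if cortical_depth_profile is None:
        depth_fn = default_depth_profile
    elif callable(cortical_depth_profile):
        depth_fn = cortical_depth_profile
    else:
        const = float(cortical_depth_profile)
        if const <= 0:
            raise ValueError("cortical depth must be positive")
        depth_fn = lambda _p: const  # noqa: E731

    # Scale the unit ovoid so the 10-20 ring (the horizontal contour at
    # Fpz's elevation, where head circumference is conventionally measured)
    # has the requested circumference.
    _, sz = _arc_fraction_point((_AXIS_RATIO_Y, _AXIS_RATIO_Z), 0.10)
    ring_shrink = np.sqrt(1.0 - sz**2)
    unit_perimeter = ring_shrink * _ellipse_perimeter(1.0, _AXIS_RATIO_Y)
    a = circumference / unit_perimeter
    b = _AXIS_RATIO_Y * a
    c = _AXIS_RATIO_Z * a
    axes = np.array([a, b, c])

    scalp = _sample_ovoid(axes, node_spacing, elevation_min=-0.35)
    cortex_list = []
    for p in _sample_ovoid(axes, node_spacing, elevation_min=-0.25):
        unit = p / axes
        n = p / axes**2
        n /= np.linalg.norm(n)
        d = float(depth_fn(unit))
        cortex_list.append(p - d * n)
    cortex = np.array(cortex_list)

    head = HeadModel(
        scalp_nodes=scalp,
        cortex_nodes=cortex,
        landmarks={},
        circumference=circumference,
        node_spacing=node_spacing,
        semi_axes=(a, b, c),
    )
    head.landmarks = _place_landmarks(head)
    return head


def _sample_ovoid(axes: np.ndarray, spacing: float, elevation_min: float) -> np.ndarray:
    """Sample an ellipsoid surface on elevation rings with even point counts.

    Even per-ring counts with azimuths symmetric about 0 make the node set
    exactly mirror-symmetric in x, which downstream mirroring relies on.
    """
    a, b, c = axes
    r_mean = 0.5 * (a + b)
    n_rings = max(3, int(np.ceil((np.pi / 2 - elevation_min) * c / spacing)))
    elevations = np.linspace(elevation_min, np.pi / 2, n_rings + 1)[:-1]
    pts = []
    for el in elevations:
        ring_r = r_mean * np.cos(el)
        n_az = max(4, 2 * int(np.ceil(np.pi * ring_r / spacing)))
        az = -np.pi + 2 * np.pi * np.arange(n_az) / n_az
        pts.append(
            np.stack(
                [
                    a * np.cos(el) * np.sin(az),
                    b * np.cos(el) * np.cos(az),
                    np.full(n_az, c * np.sin(el)),
                ],
                axis=1,
            )
        )
    pts.append(np.array([[0.0, 0.0, c]]))  # vertex
    return np.vstack(pts)


def _arc_fraction_point(
    axes_2d: tuple[float, float], fraction: float
) -> tuple[float, float]:
    """Point on a quarter ellipse at a given fraction of the half arc.

    The ellipse has semi-axes (u, v); parameter t runs from 0 (on the u axis,
    elevation 0) to pi/2 (top).  ``fraction`` is measured along the *full*
    front-over-top-to-back arc, so 0.5 is the top.
    """
    u, v = axes_2d

    def arc(t: float) -> float:
        val, _ = integrate.quad(
            lambda s: np.hypot(u * np.sin(s), v * np.cos(s)), 0.0, t
        )
        return val

    half = arc(np.pi / 2)
    target = fraction * 2.0 * half
    if target > half:  # past the top: mirror into the back quarter
        t = optimize.brentq(lambda s: arc(s) - (2 * half - target), 0, np.pi / 2)
        return (-np.cos(t), np.sin(t))
    t = optimize.brentq(lambda s: arc(s) - target, 0, np.pi / 2)
    return (np.cos(t), np.sin(t))


def _place_landmarks(head: HeadModel) -> dict[str, np.ndarray]:
    a, b, c = head.semi_axes
    marks: dict[str, np.ndarray] = {
        "Nasion": np.array([0.0, b, 0.0]),
        "Inion": np.array([0.0, -b, 0.0]),
        "LPA": np.array([-a, 0.0, 0.0]),
        "RPA": np.array([a, 0.0, 0.0]),
        "Cz": np.array([0.0, 0.0, c]),
    }
    # Fpz/Oz: 10% of the nasion->Cz->inion arc from either end (midsagittal)
    cy, cz = _arc_fraction_point((b, c), 0.10)
    marks["Fpz"] = np.array([0.0, b * cy, c * cz])
    marks["Oz"] = np.array([0.0, -b * cy, c * cz])
    # T7/T8: 10% of the LPA->Cz->RPA arc from the pre-auricular points
    cx, cz = _arc_fraction_point((a, c), 0.10)
    marks["T8"] = np.array([a * cx, 0.0, c * cz])
    marks["T7"] = np.array([-a * cx, 0.0, c * cz])
    return marks


# -- operations -------------------------------------------------------------


def resize_head(head: HeadModel, new_circumference: float) -> HeadModel:
    """Proportionally rescale every coordinate by the circumference ratio.

    Node indices are preserved, so an ROI defined by node ids on the original
    head selects the anatomically analogous (scaled) region on the resized
    head — the ROI's relative portion of the cortex is unchanged.
    """
    if new_circumference <= 0:
        raise ValueError("circumference must be positive")
    ratio = new_circumference / head.circumference
    return HeadModel(
        scalp_nodes=head.scalp_nodes * ratio,
        cortex_nodes=head.cortex_nodes * ratio,
        landmarks={k: v * ratio for k, v in head.landmarks.items()},
        circumference=new_circumference,
        node_spacing=head.node_spacing * ratio,
        semi_axes=None
        if head.semi_axes is None
        else tuple(ratio * np.asarray(head.semi_axes)),
    )


def select_spherical_roi(head: HeadModel, center_node: int, radius: float) -> ROIMask:
    """All cortex nodes within ``radius`` of the given node's coordinates."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(head.cortex_nodes)
    if not (0 <= center_node < n):
        raise KeyError(f"unknown cortex node id {center_node}")
    center = head.cortex_nodes[center_node]
    dist = np.linalg.norm(head.cortex_nodes - center, axis=1)
    return ROIMask(
        indicator=(dist <= radius).astype(np.int8),
        center_node=int(center_node),
        radius=float(radius),
    )


def mirror_roi(head: HeadModel, roi: ROIMask) -> ROIMask:
    """Reflect an ROI across the midsagittal plane; cardinality is preserved."""
    pairs = head.mirror_pairs()
    indicator = np.zeros_like(roi.indicator)
    indicator[pairs[roi.node_ids]] = 1
    return ROIMask(
        indicator=indicator,
        center_node=int(pairs[roi.center_node]),
        radius=roi.radius,
    )


def cortical_depth(head: HeadModel, node: int) -> float:
    """Minimum distance (mm) from a cortex node to the scalp surface."""
    point = head.cortex_nodes[node]
    d_node, _ = head.scalp_tree.query(point)
    if head.semi_axes is None:
        return float(d_node)
    # refine with the analytic surface: distance to the radial projection,
    # capped by the nearest-node distance
    proj = head.project_to_scalp(point[None, :])[0]
    return float(min(d_node, np.linalg.norm(point - proj)))


def reachable(head: HeadModel, node: int) -> bool:
    """Whether the node is shallow enough (<= 40 mm) to be seen by fNIRS."""
    return cortical_depth(head, node) <= REACHABLE_DEPTH_MM


def select_second_roi(
    head: HeadModel,
    first: ROIMask,
    separation: float,
    radius: float,
    rng: np.random.Generator,
    tolerance: float | None = None,
) -> ROIMask:
    """Random same-radius ROI whose centre is ``separation`` from the first.

    Candidate centres are all cortex nodes whose distance to the first ROI's
    centre lies within ``tolerance`` (default: one node spacing) of the
    requested separation; one is drawn uniformly with ``rng``.
    """
    if tolerance is None:
        tolerance = head.node_spacing
    if separation == 0:
        return select_spherical_roi(head, first.center_node, radius)
    center = head.cortex_nodes[first.center_node]
    dist = np.linalg.norm(head.cortex_nodes - center, axis=1)
    candidates = np.flatnonzero(np.abs(dist - separation) <= tolerance)
    if len(candidates) == 0:
        raise ValueError(
            f"no cortex node at separation {separation}±{tolerance} mm from node "
            f"{first.center_node}"
        )
    choice = int(candidates[rng.integers(len(candidates))])
    return select_spherical_roi(head, choice, radius)


# -- serialization ----------------------------------------------------------


def save_head(head: HeadModel, directory: str | Path) -> None:
    """Write a head as plain-text node tables plus a JSON metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for tag, nodes in (("scalp", head.scalp_nodes), ("cortex", head.cortex_nodes)):
        for i, (x, y, z) in enumerate(nodes):
            rows.append(f"{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{tag}")
    (directory / "nodes.tsv").write_text(
        "id\tx\ty\tz\tsurface\n" + "\n".join(rows) + "\n"
    )
    meta = {
        "circumference": head.circumference,
        "node_spacing": head.node_spacing,
        "semi_axes": None if head.semi_axes is None else list(head.semi_axes),
        "landmarks": {k: list(map(float, v)) for k, v in head.landmarks.items()},
    }
    (directory / "head.json").write_text(json.dumps(meta, indent=2))


def load_head(directory: str | Path) -> HeadModel:
    directory = Path(directory)
    meta = json.loads((directory / "head.json").read_text())
    scalp, cortex = [], []
    with open(directory / "nodes.tsv") as fh:
        next(fh)
        for line in fh:
            _, x, y, z, tag = line.split("\t")
            (scalp if tag.strip() == "scalp" else cortex).append(
                [float(x), float(y), float(z)]
            )
    return HeadModel(
        scalp_nodes=np.array(scalp),
        cortex_nodes=np.array(cortex),
        landmarks={k: np.array(v) for k, v in meta["landmarks"].items()},
        circumference=meta["circumference"],
        node_spacing=meta["node_spacing"],
        semi_axes=None if meta["semi_axes"] is None else tuple(meta["semi_axes"]),
    )


def head_from_meshes(
    scalp_mesh: str | Path,
    cortex_mesh: str | Path,
    landmarks: dict[str, np.ndarray],
    circumference: float,
    node_spacing: float,
) -> HeadModel:
    """Load scalp/cortex surfaces from PLY/OBJ meshes (extension point).

    Requires ``trimesh``; landmarks and circumference must be supplied since
    generic meshes carry no 10-20 information.
    """
    import trimesh  # local import: optional dependency

    scalp = np.asarray(trimesh.load(str(scalp_mesh), force="mesh").vertices, float)
    cortex = np.asarray(trimesh.load(str(cortex_mesh), force="mesh").vertices, float)
    return HeadModel(
        scalp_nodes=scalp,
        cortex_nodes=cortex,
        landmarks={k: np.asarray(v, float) for k, v in landmarks.items()},
        circumference=float(circumference),
        node_spacing=float(node_spacing),
        semi_axes=None,
    )
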
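"""Probe layouts, anchor/attractor registration, and the placement error model.

Two standard layouts are provided:

* a low-density probe: an alternating source-detector chain of 9 sources and
  8 detectors at 25-mm pitch (16 nearest-pair channels), anchored at Fpz with
  attractors pulling its axes toward T7, T8 and Cz;
* a high-density probe: 30 sources and 36 detectors on interleaved square
  lattices of pitch 13*sqrt(2) mm, measuring the first- to fourth-nearest
  source-detector pairs (nominal separations 13, 30, 40 and 48 mm; 460
  channels in total).

Registration places the flat 2-D layout onto the scalp surface by iterative
least squares: the anchor point is pinned to its 10-20 landmark (a hard
constraint), inter-optode distances are held near their 2-D layout values,
and attractor points are softly pulled toward surface targets constructed by
walking along the scalp from the anchor in the direction of their bound
landmarks — the attractors therefore orient the probe axes without
constraining distances.  Head-size and placement uncertainty follow a simple
random model: circumference ~ N(420, 50^2) mm and independent N(0, 10^2) mm
displacements of the anchor/attractor binding points along the layout axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from .head import HeadModel

__all__ = [
    "ProbeLayout",
    "RegisteredProbe",
    "RegistrationError",
    "build_low_density_probe",
    "build_high_density_probe",
    "register_probe",
    "sample_registration_error",
    "save_layout",
    "load_layout",
]

HD_PITCH = 13.0 * np.sqrt(2.0)  # same-type optode spacing, mm
HD_SEPARATION_CLASSES = (13.0, 13.0 * np.sqrt(5.0), 39.0, 13.0 * np.sqrt(13.0))


@dataclass(frozen=True)
class ProbeLayout:
    """Flat 2-D probe description: optodes, channels, and 10-20 bindings."""

    optode_labels: tuple[str, ...]
    optode_positions: np.ndarray  # (n, 2) mm
    channels: tuple[tuple[str, str], ...]  # (source label, detector label)
    anchors: tuple[tuple[tuple[float, float], str], ...]  # ((x, y), 10-20 label)
    attractors: tuple[tuple[tuple[float, float], str], ...]

    def __post_init__(self):
        labels = set(self.optode_labels)
        for s, d in self.channels:
            if s not in labels or d not in labels:
                raise ValueError(f"channel ({s}, {d}) references unknown optode")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def position_of(self, label: str) -> np.ndarray:
        return self.optode_positions[self.optode_labels.index(label)]

    def channel_distances_2d(self) -> np.ndarray:
        out = np.empty(len(self.channels))
        for i, (s, d) in enumerate(self.channels):
            out[i] = np.linalg.norm(self.position_of(s) - self.position_of(d))
        return out


@dataclass(frozen=True)
class RegistrationError:
    """Random head size and 2-D binding-point displacements for one subject."""

    anchor_displacement: np.ndarray  # (2,) mm in the layout frame
    attractor_displacements: np.ndarray  # (n_attractors, 2) mm
    circumference: float  # mm


@dataclass
class RegisteredProbe:
    """3-D optode/channel geometry on a specific head after registration."""

    layout: ProbeLayout
    head: HeadModel
    optode_positions: np.ndarray  # (n, 3) mm, on the scalp
    n_iterations: int
    final_cost: float
    _chan_idx: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        labels = list(self.layout.optode_labels)
        self._chan_idx = np.array(
            [(labels.index(s), labels.index(d)) for s, d in self.layout.channels]
        )

    @property
    def channels(self) -> tuple[tuple[str, str], ...]:
        return self.layout.channels

    @property
    def source_positions(self) -> np.ndarray:
        return self.optode_positions[self._chan_idx[:, 0]]

    @property
    def detector_positions(self) -> np.ndarray:
        return self.optode_positions[self._chan_idx[:, 1]]

    @property
    def sd_distances(self) -> np.ndarray:
        """Per-channel 3-D source-detector chord distance, mm."""
        return np.linalg.norm(self.source_positions - self.detector_positions, axis=1)

    @property
    def channel_midpoints(self) -> np.ndarray:
        return 0.5 * (self.source_positions + self.detector_positions)

    def position_of(self, label: str) -> np.ndarray:
        return self.optode_positions[self.layout.optode_labels.index(label)]


# -- layouts ----------------------------------------------------------------


def build_low_density_probe() -> ProbeLayout:
    """Alternating S-D chain: 9 sources, 8 detectors, 16 channels at 25 mm."""
    labels, positions = [], []
    for k in range(17):
        x = (k - 8) * 25.0
        if k % 2 == 0:
            labels.append(f"S{k // 2 + 1}")
        else:
            labels.append(f"D{(k + 1) // 2}")
        positions.append((x, 0.0))
    channels = []
    for i in range(1, 9):  # S1:D1, S2:D1, S2:D2, S3:D2, ...
        channels.append((f"S{i}", f"D{i}"))
        channels.append((f"S{i + 1}", f"D{i}"))
    return ProbeLayout(
        optode_labels=tuple(labels),
        optode_positions=np.array(positions),
        channels=tuple(channels),
        anchors=(((0.0, 0.0), "Fpz"),),
        attractors=(
            ((-200.0, 0.0), "T7"),
            ((200.0, 0.0), "T8"),
            ((0.0, 100.0), "Cz"),
        ),
    )


def build_high_density_probe() -> ProbeLayout:
    """Interleaved-lattice probe: 30 sources, 36 detectors, 460 channels.

    Detectors sit on a 9 x 4 square lattice of pitch 13*sqrt(2) mm and
    sources on a 10 x 3 lattice offset by half a cell in both axes; this is
    the smallest interleaved arrangement realising the 30/36 optode counts
    with exactly 460 channels in the four nominal separation classes.
    """
    g = HD_PITCH
    labels, positions = [], []
    n_d = 0
    for j in range(4):
        for i in range(9):
            n_d += 1
            labels.append(f"D{n_d}")
            positions.append(((i - 4.0) * g, (j - 1.5) * g))
    n_s = 0
    for j in range(3):
        for i in range(10):
            n_s += 1
            labels.append(f"S{n_s}")
            positions.append(((i - 4.5) * g, (j - 1.0) * g))
    positions = np.array(positions)
    # channels: every S-D pair whose 2-D distance matches a nominal class
    channels = []
    src = [(k, l) for k, l in enumerate(labels) if l.startswith("S")]
    det = [(k, l) for k, l in enumerate(labels) if l.startswith("D")]
    for ks, ls in src:
        for kd, ld in det:
            dist = np.linalg.norm(positions[ks] - positions[kd])
            if any(abs(dist - c) < 0.5 for c in HD_SEPARATION_CLASSES):
                channels.append((ls, ld))
    return ProbeLayout(
        optode_labels=tuple(labels),
        optode_positions=positions,
        channels=tuple(channels),
        anchors=(((0.0, 0.0), "Fpz"),),
        attractors=(
            ((-200.0, 0.0), "T7"),
            ((200.0, 0.0), "T8"),
            ((0.0, 100.0), "Cz"),
        ),
    )


# -- error model ------------------------------------------------------------


def sample_registration_error(
    head_mean: float = 420.0,
    head_sd: float = 50.0,
    disp_sd: float = 10.0,
    rng: np.random.Generator | None = None,
    n_attractors: int = 3,
    circumference_floor: float = 250.0,
) -> RegistrationError:
    """Draw a subject's head circumference and binding-point displacements.

    Circumference ~ N(head_mean, head_sd^2), redrawn below a positive floor
    (250 mm) to exclude degenerate heads; each anchor/attractor displacement
    component ~ N(0, disp_sd^2) in the 2-D layout frame.
    """
    if head_sd < 0 or disp_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    rng = np.random.default_rng() if rng is None else rng
    circumference = float(rng.normal(head_mean, head_sd)) if head_sd > 0 else head_mean
    while circumference < circumference_floor:
        circumference = float(rng.normal(head_mean, head_sd))
    anchor = rng.normal(0.0, disp_sd, size=2) if disp_sd > 0 else np.zeros(2)
    attractors = (
        rng.normal(0.0, disp_sd, size=(n_attractors, 2))
        if disp_sd > 0
        else np.zeros((n_attractors, 2))
    )
    return RegistrationError(
        anchor_displacement=anchor,
        attractor_displacements=attractors,
        circumference=circumference,
    )


# -- registration -----------------------------------------------------------


def _angles_of(head: HeadModel, point: np.ndarray) -> tuple[float, float]:
    a, b, c = head.semi_axes
    el = np.arcsin(np.clip(point[2] / c, -1, 1))
    az = np.arctan2(point[0] / a, point[1] / b)
    return float(az), float(el)


def _wrap_map(head: HeadModel, anchor_pos: np.ndarray, rel2d: np.ndarray) -> np.ndarray:
    """Map layout offsets (mm) to scalp points by exact arc-length walking.

    The layout +x axis walks along the azimuthal ring through the anchor
    (toward the right ear) and +y then climbs the local meridian toward the
    vertex, both by true arc length on the ellipsoid.  This is the
    initialisation (and the attractor target construction) for the
    least-squares registration; because it preserves arc lengths, it is
    already nearly distance-consistent.
    """
    a, b, c = head.semi_axes
    az0, el0 = _angles_of(head, anchor_pos)
    rel2d = np.atleast_2d(rel2d)

    # elevation first: climb the anchor meridian by dy, integrating
    # d(el)/ds = 1 / sqrt(r^2 sin^2 el + c^2 cos^2 el) with RK2 steps
    r_az0 = np.sqrt((a * np.sin(az0)) ** 2 + (b * np.cos(az0)) ** 2)
    el = np.full(len(rel2d), el0)
    n_steps = 64
    h = rel2d[:, 1] / n_steps

    def speed(e):
        return np.sqrt((r_az0 * np.sin(e)) ** 2 + (c * np.cos(e)) ** 2)

    for _ in range(n_steps):
        k1 = 1.0 / speed(el)
        k2 = 1.0 / speed(el + 0.5 * h * k1)
        el = el + h * k2
    el = np.clip(el, -0.45, np.pi / 2 - 1e-6)

    # azimuth along each point's own ring: the horizontal contour at
    # elevation el is the equator ellipse scaled by cos(el), so its arc
    # length is cos(el) times the equatorial arc
    az_grid = az0 + np.linspace(-1.6 * np.pi, 1.6 * np.pi, 3001)
    ds = np.sqrt((a * np.cos(az_grid)) ** 2 + (b * np.sin(az_grid)) ** 2)
    s_grid = np.concatenate(
        [[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(az_grid))]
    )
    s_grid -= np.interp(az0, az_grid, s_grid)
    az = np.interp(rel2d[:, 0] / np.cos(el), s_grid, az_grid)
    return head.scalp_point(az, el)


def register_probe(
    layout: ProbeLayout,
    head: HeadModel,
    error: RegistrationError | None = None,
    *,
    distance_weight: float = 1.0,
    attractor_weight: float = 0.1,
    pair_cutoff: float = 60.0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> RegisteredProbe:
    """Place a 2-D probe layout onto the scalp by iterative least squares.

    The displaced anchor binding point is pinned at its landmark (hard
    constraint), pairwise geodesic distances between nearby layout points
    are held at their 2-D layout values (via arc-consistent chord targets),
    and attractor bindings orient the layout axes: a displaced attractor
    rotates the centreline or its arm of the probe, and weak direction
    springs pin that orientation during the relaxation.  Every least-squares
    step is solved in the points' scalp tangent planes and projected back
    onto the surface (damped Gauss-Newton).  With ``error`` given, the
    binding points are displaced in the 2-D layout frame, which shifts and
    tilts the whole probe as a misplaced cap would.
    """
    if head.semi_axes is None:
        raise ValueError("registration requires an analytic (synthetic) head")
    (anchor_xy, anchor_label), = layout.anchors
    for _, lab in layout.anchors + layout.attractors:
        if lab not in head.landmarks:
            raise KeyError(f"head lacks 10-20 landmark {lab!r}")

    n_opt = len(layout.optode_labels)
    pts2d = [np.asarray(p, float) for p in layout.optode_positions]
    anchor_disp = np.zeros(2)
    att_disp = np.zeros((len(layout.attractors), 2))
    if error is not None:
        anchor_disp = np.asarray(error.anchor_displacement, float)
        att_disp = np.asarray(error.attractor_displacements, float)

    # extended 2-D point set: optodes plus (if distinct) the anchor binding
    def _find_or_add(xy: np.ndarray) -> int:
        for i, p in enumerate(pts2d):
            if np.linalg.norm(p - xy) < 1e-9:
                return i
        pts2d.append(xy)
        return len(pts2d) - 1

    anchor_bind = np.asarray(anchor_xy, float) + anchor_disp
    anchor_idx = _find_or_add(anchor_bind)
    pts2d = np.array(pts2d)
    n_pts = len(pts2d)

    # Attractor direction terms: each displaced attractor binding changes
    # the direction of the probe axis it defines.  Attractors along the
    # layout y axis rotate the whole layout (the centreline); attractors on
    # the left/right additionally rotate that arm about the centreline.
    # This is exactly the misorientation geometry of a displaced cap.
    delta_axis, delta_left, delta_right = 0.0, 0.0, 0.0
    n_axis = 0
    for k, (xy, _) in enumerate(layout.attractors):
        v0 = np.asarray(xy, float) - np.asarray(anchor_xy, float)
        v1 = np.asarray(xy, float) + att_disp[k] - anchor_bind
        if np.linalg.norm(v0) == 0 or np.linalg.norm(v1) == 0:
            continue
        d_k = float(np.arctan2(v0[0] * v1[1] - v0[1] * v1[0], np.dot(v0, v1)))
        if abs(v0[1]) >= abs(v0[0]):
            delta_axis += d_k
            n_axis += 1
        elif v0[0] < 0:
            delta_left += d_k
        else:
            delta_right += d_k
    if n_axis:
        delta_axis /= n_axis

    def _rot(theta: float) -> np.ndarray:
        return np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )

    rel = pts2d - anchor_bind
    rel_rot = rel @ _rot(delta_axis).T
    left = rel[:, 0] < -1e-9
    right = rel[:, 0] > 1e-9
    rel_rot[left] = rel[left] @ _rot(delta_axis + delta_left).T
    rel_rot[right] = rel[right] @ _rot(delta_axis + delta_right).T

    anchor_target = head.landmarks[anchor_label]
    wrap = _wrap_map(head, anchor_target, rel_rot)
    wrap[anchor_idx] = anchor_target

    # pair graph: all pairs within the cutoff, plus 4 nearest neighbours
    # each.  Targets are the 2-D layout distances; a flat layout cannot be
    # embedded isometrically in a curved scalp, so the relaxation finds the
    # least-squares compromise, with the wrap (below) as the starting point
    # and orientation prior.
    d2 = np.linalg.norm(pts2d[:, None, :] - pts2d[None, :, :], axis=2)
    pairs = set()
    for i in range(n_pts):
        near = np.flatnonzero((d2[i] <= pair_cutoff) & (np.arange(n_pts) != i))
        order = np.argsort(d2[i])
        near = set(near.tolist()) | set(order[1:5].tolist())
        for j in near:
            pairs.add((min(i, int(j)), max(i, int(j))))
    pairs = np.array(sorted(pairs))
    pair_target = d2[pairs[:, 0], pairs[:, 1]]
    pair_w = np.full(len(pairs), np.sqrt(distance_weight))

    init = wrap.copy()

    free = np.array([i for i in range(n_pts) if i != anchor_idx])
    col_of = np.full(n_pts, -1)
    col_of[free] = np.arange(len(free))
    axes = np.asarray(head.semi_axes)
    w_att = np.sqrt(attractor_weight)
    pair_free_i = col_of[pairs[:, 0]]
    pair_free_j = col_of[pairs[:, 1]]
    # weak springs carry the attractor-oriented wrap directions into the
    # relaxation (they pin the rotational degree of freedom about the anchor)
    att_idx = free
    att_targets = wrap[free]
    att_free = col_of[att_idx]

    def cost_of(pts: np.ndarray) -> tuple[float, np.ndarray]:
        diff = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        r_dist = pair_w * (np.linalg.norm(diff, axis=1) - pair_target)
        r_att = w_att * (pts[att_idx] - att_targets).ravel()
        r = np.concatenate([r_dist, r_att])
        return float(r @ r), r

    def tangent_bases(pts: np.ndarray) -> np.ndarray:
        """Orthonormal tangent-plane basis (n_free, 3, 2) at each free point."""
        n = pts[free] / axes**2
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        ref = np.zeros_like(n)
        ref[:, np.argmin(np.abs(n).mean(axis=0))] = 1.0
        # fall back per-point if the reference axis is nearly parallel
        bad = np.abs(np.sum(n * ref, axis=1)) > 0.9
        ref[bad] = 0.0
        ref[bad, np.argmin(np.abs(n[bad]), axis=1)] = 1.0
        t1 = np.cross(n, ref)
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(n, t1)
        return np.stack([t1, t2], axis=2)

    # Gauss-Newton on the scalp: each step is solved in the points' tangent
    # planes (2 dof per free point) and the result is projected back onto
    # the surface, i.e. nearest-point projection after every least-squares
    # step.  Levenberg damping keeps the step well-behaved.
    pts = init.copy()
    cost, _ = cost_of(pts)
    lam = 1e-3
    n_free = len(free)
    n_outer = 0
    converged = False
    for n_outer in range(1, max_iter + 1):
        T = tangent_bases(pts)  # (n_free, 3, 2)
        diff = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        norm = np.linalg.norm(diff, axis=1)
        norm = np.where(norm == 0, 1.0, norm)
        unit = pair_w[:, None] * diff / norm[:, None]
        n_res = len(pairs) + 3 * len(att_idx)
        J = np.zeros((n_res, 2 * n_free))
        rows = np.arange(len(pairs))
        for sgn, idx in ((1.0, pair_free_i), (-1.0, pair_free_j)):
            ok = idx >= 0
            # chain rule: d r / d t = unit . T
            proj = np.einsum("rk,rkt->rt", unit[ok], T[idx[ok]])
            J[np.repeat(rows[ok], 2), (2 * idx[ok][:, None] + np.arange(2)).ravel()] += (
                sgn * proj
            ).ravel()
        off = len(pairs)
        for k in range(len(att_idx)):
            c = att_free[k]
            if c >= 0:
                J[off + 3 * k : off + 3 * k + 3, 2 * c : 2 * c + 2] = w_att * T[c]
        _, r = cost_of(pts)
        g = J.T @ r
        H = J.T @ J
        for _ in range(8):  # adaptive damping
            try:
                step = np.linalg.solve(H + lam * np.eye(2 * n_free), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = pts.copy()
            trial[free] = head.project_to_scalp(
                pts[free] + np.einsum("nkt,nt->nk", T, step.reshape(-1, 2))
            )
            new_cost, _ = cost_of(trial)
            if new_cost <= cost:
                lam = max(lam * 0.3, 1e-8)
                break
            lam *= 4.0
        else:
            converged = True  # damping exhausted: no descent left
            break
        rel_change = (cost - new_cost) / max(cost, 1e-12)
        moved = float(np.max(np.abs(trial[free] - pts[free])))
        pts, cost = trial, new_cost
        if rel_change <= tol or moved < 1e-4:
            converged = True
            break
    if not converged:
        raise RuntimeError("probe registration did not converge")

    final = pts
    return RegisteredProbe(
        layout=layout,
        head=head,
        optode_positions=final[:n_opt],
        n_iterations=n_outer,
        final_cost=cost,
    )


# -- plain-text layout serialization ---------------------------------------


def save_layout(layout: ProbeLayout, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    opt = ["label\tx\ty"]
    for lab, (x, y) in zip(layout.optode_labels, layout.optode_positions):
        opt.append(f"{lab}\t{x:.6f}\t{y:.6f}")
    (directory / "optodes.tsv").write_text("\n".join(opt) + "\n")
    chan = ["source\tdetector"] + [f"{s}\t{d}" for s, d in layout.channels]
    (directory / "channels.tsv").write_text("\n".join(chan) + "\n")
    meta = {
        "anchors": [[list(p), lab] for p, lab in layout.anchors],
        "attractors": [[list(p), lab] for p, lab in layout.attractors],
    }
    (directory / "bindings.json").write_text(json.dumps(meta, indent=2))


def load_layout(directory: str | Path) -> ProbeLayout:
    directory = Path(directory)
    labels, positions = [], []
    with open(directory / "optodes.tsv") as fh:
        next(fh)
        for line in fh:
            lab, x, y = line.split("\t")
            labels.append(lab)
            positions.append([float(x), float(y)])
    channels = []
    with open(directory / "channels.tsv") as fh:
        next(fh)
        for line in fh:
            s, d = line.split("\t")
            channels.append((s.strip(), d.strip()))
    meta = json.loads((directory / "bindings.json").read_text())
    return ProbeLayout(
        optode_labels=tuple(labels),
        optode_positions=np.array(positions),
        channels=tuple(channels),
        anchors=tuple((tuple(p), lab) for p, lab in meta["anchors"]),
        attractors=tuple((tuple(p), lab) for p, lab in meta["attractors"]),
    )
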
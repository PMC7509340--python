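"""Approximate semi-infinite-slab photon-diffusion forward model.

The sensitivity of an fNIRS source-detector channel to an absorption change
at a cortical location is computed from closed-form diffusion-theory Green's
functions for a homogeneous semi-infinite medium with an extrapolated
boundary:

* the two-point function ``G(s, r)`` describes light travelling from a
  surface point ``s`` to a volume point ``r`` — an isotropic point source
  buried one transport mean free path below the surface plus a negative
  image source above the extrapolated boundary;
* the three-point function combines two obliquely oriented two-point
  functions through the volume point and normalises by the surface-to-
  surface two-point function (Rytov form):
  ``S(s, d, r) = G(s, r) G(r, d) / G(s, d)``.

Each optode carries its own local slab frame: depth is measured along the
scalp normal at the optode position, which is how the two slab solutions
become "obliquely oriented" on a curved head.  The model is evaluated at a
single wavelength (808 nm by default): the contrast pipeline normalises the
projected weights, so extinction-coefficient scaling cancels and no coupled
two-wavelength treatment is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .head import HeadModel
from .probe import RegisteredProbe

__all__ = [
    "OpticalProperties",
    "SensitivityMatrix",
    "two_point_green",
    "three_point_sensitivity",
    "compute_forward_matrix",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Tissue optical properties at a single wavelength.

    Defaults are typical adult-head values at 808 nm: absorption
    mu_a = 0.0191 /mm, reduced scattering mu_s' = 0.66 /mm, and a
    tissue/air refractive-index ratio of 1.45.
    """

    wavelength: float = 808.0  # nm
    mua: float = 0.0191  # 1/mm
    musp: float = 0.66  # 1/mm
    n_rel: float = 1.45  # tissue/air refractive-index ratio

    def __post_init__(self):
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError("optical coefficients must be positive")
        if not (600.0 < self.wavelength < 1000.0):
            raise ValueError("wavelength must lie in the NIR window (600, 1000) nm")

    @property
    def diffusion(self) -> float:
        """Diffusion coefficient D = 1/(3 (mu_a + mu_s')), mm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mueff(self) -> float:
        """Effective attenuation sqrt(mu_a / D), 1/mm."""
        return np.sqrt(self.mua / self.diffusion)

    @property
    def z0(self) -> float:
        """Depth of the buried isotropic source, one transport mfp, mm."""
        return 1.0 / self.musp

    @property
    def zb(self) -> float:
        """Extrapolated boundary distance 2 A D, mm (Groenhuis A(n))."""
        n = self.n_rel
        A = 1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        return 2.0 * A * self.diffusion


@dataclass
class SensitivityMatrix:
    """Channel x cortex-node sensitivities (dimensionless, Rytov form)."""

    values: np.ndarray  # (n_channels, n_nodes), all >= 0
    channels: tuple[tuple[str, str], ...]
    n_nodes: int

    def __post_init__(self):
        if self.values.shape != (len(self.channels), self.n_nodes):
            raise ValueError("sensitivity matrix shape mismatch")


def two_point_green(
    surface_point: np.ndarray,
    volume_point: np.ndarray,
    props: OpticalProperties,
    inward_normal: np.ndarray = (0.0, 0.0, -1.0),
) -> float | np.ndarray:
    """Semi-infinite-medium fluence Green's function, image-source form.

    The slab frame is local to ``surface_point``: ``inward_normal`` defines
    the depth axis (default: surface at z = 0, medium below).  The true
    source sits one transport mean free path inside the medium and a
    negative image source mirrors it across the extrapolated boundary.
    Raises ``ValueError`` if any volume point lies above the local tangent
    plane.
    """
    s = np.asarray(surface_point, float)
    r = np.atleast_2d(np.asarray(volume_point, float))
    n_in = np.asarray(inward_normal, float)
    n_in = n_in / np.linalg.norm(n_in)
    depth = (r - s) @ n_in
    if np.any(depth < -1e-9):
        raise ValueError("volume point lies above the local surface plane")
    src_real = s + props.z0 * n_in
    src_image = s - (props.z0 + 2.0 * props.zb) * n_in
    r1 = np.linalg.norm(r - src_real, axis=1)
    r2 = np.linalg.norm(r - src_image, axis=1)
    r1 = np.maximum(r1, 1e-9)
    r2 = np.maximum(r2, 1e-9)
    mu = props.mueff
    phi = (np.exp(-mu * r1) / r1 - np.exp(-mu * r2) / r2) / (
        4.0 * np.pi * props.diffusion
    )
    phi = np.maximum(phi, 0.0)
    return phi if phi.size > 1 else float(phi[0])


def three_point_sensitivity(
    source: np.ndarray,
    detector: np.ndarray,
    node: np.ndarray,
    props: OpticalProperties,
    source_normal: np.ndarray = (0.0, 0.0, -1.0),
    detector_normal: np.ndarray = (0.0, 0.0, -1.0),
    normalized: bool = True,
) -> float | np.ndarray:
    """Channel sensitivity to an absorber at ``node`` (banana-path weight).

    Product of the source->node and node->detector two-point functions,
    divided (Rytov normalisation, the default) by the source->detector
    two-point function.  Symmetric under source/detector exchange.
    """
    source = np.asarray(source, float)
    detector = np.asarray(detector, float)
    if np.linalg.norm(source - detector) < 1e-9:
        raise ValueError("degenerate channel: source equals detector")
    g_sr = two_point_green(source, node, props, source_normal)
    g_rd = two_point_green(detector, node, props, detector_normal)
    out = np.asarray(g_sr) * np.asarray(g_rd)
    if normalized:
        g_sd = two_point_green(source, detector + 0.0, props, source_normal)
        out = out / max(float(np.asarray(g_sd)), 1e-300)
    return out if out.size > 1 else float(out)


def compute_forward_matrix(
    probe: RegisteredProbe,
    head: HeadModel,
    props: OpticalProperties | None = None,
    normalized: bool = True,
) -> SensitivityMatrix:
    """Sensitivity matrix L: channels x cortex nodes (deterministic).

    Entry (channel, node) is the three-point sensitivity of that channel's
    source/detector pair to an absorption change at the node, using each
    optode's local scalp normal as its slab depth axis.  Entries for nodes
    deeper than the 40-mm reachability cutoff are computed, not zeroed.
    """
    if probe.head is not head and len(probe.head.cortex_nodes) != len(
        head.cortex_nodes
    ):
        raise ValueError("probe was registered on an incompatible head")
    if props is None:
        props = OpticalProperties()
    nodes = head.cortex_nodes
    src = probe.source_positions
    det = probe.detector_positions
    n_src = -head.surface_normal(src)  # inward
    n_det = -head.surface_normal(det)
    L = np.empty((len(src), len(nodes)))
    for k in range(len(src)):
        g_sr = two_point_green(src[k], nodes, props, n_src[k])
        g_rd = two_point_green(det[k], nodes, props, n_det[k])
        row = np.asarray(g_sr) * np.asarray(g_rd)
        if normalized:
            g_sd = two_point_green(src[k], det[k][None, :], props, n_src[k])
            row = row / max(float(np.asarray(g_sd)), 1e-300)
        L[k] = row
    return SensitivityMatrix(values=L, channels=probe.channels, n_nodes=len(nodes))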
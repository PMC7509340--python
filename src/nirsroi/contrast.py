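"""Contrast vectors over fNIRS channels: tapered, uniform, difference, Kron.

A contrast vector assigns a weight to every channel (and optionally to every
task condition) and defines the linear null hypothesis ``c . beta = 0`` on
the first-level GLM coefficients.  The tapered contrast projects a cortical
ROI mask through the optical forward model, so its weight peaks on the
channel most sensitive to the region and tapers with relative sensitivity;
the conventional uniform contrast puts equal weight on the few channels
nearest the region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .head import HeadModel, ROIMask
from .forward import SensitivityMatrix
from .probe import RegisteredProbe

__all__ = [
    "ContrastVector",
    "tapered_contrast",
    "uniform_contrast",
    "difference_contrast",
    "condition_kron",
    "contrast_to_frame",
    "save_contrast",
]


class BlindSpotError(ValueError):
    """The ROI projects to (numerically) zero sensitivity on every channel."""


@dataclass(frozen=True)
class ContrastVector:
    """Channel weights (spatial part) with optional condition weights."""

    weights: np.ndarray  # (n_channels,)
    channels: tuple[tuple[str, str], ...]
    condition_weights: np.ndarray | None = None

    def __post_init__(self):
        if len(self.weights) != len(self.channels):
            raise ValueError("one weight per channel required")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def combined(self) -> np.ndarray:
        """Weights per (channel, condition); channel-major Kronecker order."""
        if self.condition_weights is None:
            return self.weights
        return np.kron(self.weights, self.condition_weights)

    def same_basis(self, other: "ContrastVector") -> bool:
        return self.channels == other.channels


def tapered_contrast(
    L: SensitivityMatrix, roi: ROIMask, floor: float = 1e-300
) -> ContrastVector:
    """Forward-model projection of an ROI mask, normalised to sum to one.

    The weight of each channel is the sum of its sensitivities over the
    masked cortex nodes.  Raises :class:`BlindSpotError` if the region is
    invisible to the probe (all-zero projection) rather than returning
    silent zeros.
    """
    mask = np.asarray(roi.indicator, float)
    if mask.shape[0] != L.n_nodes:
        raise ValueError("mask node order does not match the forward matrix")
    raw = L.values @ mask
    total = raw.sum()
    if not np.isfinite(total) or total <= floor:
        raise BlindSpotError("ROI is not visible to any channel of this probe")
    return ContrastVector(weights=raw / total, channels=L.channels)


def uniform_contrast(
    probe: RegisteredProbe,
    roi: ROIMask,
    head: HeadModel,
    n_channels: int | None = None,
) -> ContrastVector:
    """Equal weight on the channels nearest the ROI centroid.

    ``n_channels`` defaults to 4 for sparse probes and to a quarter of the
    channels for dense ones (>100 channels).  "Nearest" is the 3-D Euclidean
    distance from the channel's source-detector midpoint to the centroid of
    the masked cortex nodes; ties break deterministically by channel index.
    """
    n_total = len(probe.channels)
    if n_channels is None:
        n_channels = 4 if n_total <= 100 else int(round(n_total / 4))
    if not (1 <= n_channels <= n_total):
        raise ValueError("n_channels out of range")
    centroid = head.cortex_nodes[roi.node_ids].mean(axis=0)
    dist = np.linalg.norm(probe.channel_midpoints - centroid, axis=1)
    nearest = np.argsort(dist, kind="stable")[:n_channels]
    weights = np.zeros(n_total)
    weights[nearest] = 1.0 / n_channels
    return ContrastVector(weights=weights, channels=probe.channels)


def difference_contrast(c1: ContrastVector, c2: ContrastVector) -> ContrastVector:
    """Elementwise c1 - c2 (sums to zero when both inputs are normalised).

    An all-zero result (possible when two nearby ROIs select identical
    uniform channel sets) is returned as-is; the t-test maps it to t = 0,
    p = 1 downstream.
    """
    if not c1.same_basis(c2):
        raise ValueError("contrast vectors are on different channel bases")
    return ContrastVector(weights=c1.weights - c2.weights, channels=c1.channels)


def condition_kron(
    c_roi: ContrastVector, c_cond: np.ndarray
) -> ContrastVector:
    """Expand a spatial contrast over task conditions (Kronecker product)."""
    c_cond = np.asarray(c_cond, float)
    if c_cond.size == 0:
        raise ValueError("condition weights must be nonempty")
    return ContrastVector(
        weights=c_roi.weights, channels=c_roi.channels, condition_weights=c_cond
    )


def contrast_to_frame(c: ContrastVector, name: str = "weight") -> pd.DataFrame:
    """Tidy per-channel table (source, detector, condition, weight)."""
    rows = []
    conds = (
        [None] if c.condition_weights is None else range(len(c.condition_weights))
    )
    for j in conds:
        for (s, d), w in zip(c.channels, c.weights):
            rows.append(
                {
                    "source": s,
                    "detector": d,
                    "condition": 0 if j is None else j,
                    name: w if j is None else w * c.condition_weights[j],
                }
            )
    return pd.DataFrame(rows)


def save_contrast(c: ContrastVector, path: str | Path) -> None:
    contrast_to_frame(c).to_csv(path, index=False)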
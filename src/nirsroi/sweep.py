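"""Group-level analysis drivers and the simulation sweep.

``analyze_single_roi`` / ``analyze_two_roi`` run one simulated group through
the four analysis conditions of the study design — tapered vs uniform
contrast weighting, each with the probe registration treated as known
(per-subject true registration) or unknown (average 420-mm head, no
placement error) — and return the group-level p-values for the active test
and its mirrored null.  The sweep runners repeat this over grids of ROI
radius (and separation, in two-ROI mode) and summarise each cell with the
ROC AUC, the empirical false-positive rate at alpha = 0.05, and the DeLong
comparison of the two weighting methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contrast import (
    BlindSpotError,
    ContrastVector,
    difference_contrast,
    tapered_contrast,
    uniform_contrast,
)
from .evaluate import delong_compare, roc_from_pvalues
from .forward import OpticalProperties, compute_forward_matrix
from .glm import ROITestResult, build_design, fit_glm, group_combine
from .head import make_synthetic_head
from .probe import build_high_density_probe, build_low_density_probe
from .simulate import SimulatedDataset, SimulationConfig, simulate_group

__all__ = [
    "SweepSpec",
    "analyze_single_roi",
    "analyze_two_roi",
    "run_single_roi_sweep",
    "run_two_roi_sweep",
]

METHODS = ("tapered", "uniform")
MODES = ("known", "unknown")


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition for the simulation study."""

    radii: tuple = tuple(range(10, 37, 2))  # mm, 14 values
    separations: tuple = tuple(range(20, 81, 5))  # mm, 13 values (two-ROI)
    probe: str = "low"
    modes: tuple = MODES
    reps: int = 100
    seed: int = 0
    config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if not self.radii or self.reps < 1:
            raise ValueError("sweep needs at least one radius and one rep")


def _fit_subject_glms(dataset: SimulatedDataset, noise_model: str = "ar"):
    """Fit each subject's GLM once per chromophore (shared by all methods)."""
    fits = []
    for subj in dataset.subjects:
        n_samples = next(iter(subj.ts.values())).n_samples
        X, names = build_design(
            subj.onsets,
            dataset.config.stim_duration,
            n_samples,
            dataset.config.fs,
        )
        fits.append(
            {
                name: fit_glm(ts, X, noise_model=noise_model, design_names=names)
                for name, ts in subj.ts.items()
            }
        )
    return fits


def _contrast_for(
    dataset: SimulatedDataset,
    subj_index: int,
    roi,
    method: str,
    mode: str,
    props: OpticalProperties,
) -> ContrastVector | None:
    """Contrast vector for one subject/ROI under a method and mode.

    Returns ``None`` when the tapered projection sees nothing (blind spot).
    """
    if mode == "known":
        subj = dataset.subjects[subj_index]
        registered, head, L = subj.registered, subj.head, subj.sensitivity
    else:
        registered, head = dataset.standard_registration, dataset.base_head
        L = _standard_sensitivity(dataset, props)
    if method == "tapered":
        try:
            return tapered_contrast(L, roi)
        except BlindSpotError:
            return None
    return uniform_contrast(registered, roi, head)


def _standard_sensitivity(dataset: SimulatedDataset, props: OpticalProperties):
    if not hasattr(dataset, "_std_L"):
        dataset._std_L = compute_forward_matrix(
            dataset.standard_registration, dataset.base_head, props
        )
    return dataset._std_L


def _group_p(results: list[ROITestResult | None]) -> float:
    """Combine subject results; degenerate/blind subjects carry no evidence."""
    valid = [
        r for r in results if r is not None and r.se > 0 and np.isfinite(r.t)
    ]
    if not valid:
        return 1.0
    return group_combine(valid).p


def analyze_single_roi(
    dataset: SimulatedDataset,
    props: OpticalProperties | None = None,
    chromophores: tuple | None = None,
    glm_fits=None,
) -> pd.DataFrame:
    """All four analysis conditions for the single-ROI test on one group.

    Returns a tidy frame with one row per (method, mode, chromophore):
    group p-value for the active ROI and for its mirrored null ROI.
    """
    props = props or OpticalProperties()
    fits = glm_fits if glm_fits is not None else _fit_subject_glms(dataset)
    chromos = chromophores or tuple(name for name, _ in dataset.config.chromophores)
    rows = []
    for method in METHODS:
        for mode in MODES:
            contrasts = {
                roi_name: [
                    _contrast_for(dataset, i, roi, method, mode, props)
                    for i in range(len(dataset.subjects))
                ]
                for roi_name, roi in (
                    ("active", dataset.active_roi),
                    ("null", dataset.null_roi),
                )
            }
            for chromo in chromos:
                p = {}
                for roi_name, per_subj in contrasts.items():
                    res = [
                        None if c is None else fits[i][chromo].t_contrast(c)
                        for i, c in enumerate(per_subj)
                    ]
                    p[roi_name] = _group_p(res)
                rows.append(
                    {
                        "method": method,
                        "mode": mode,
                        "chromophore": chromo,
                        "p_active": p["active"],
                        "p_null": p["null"],
                    }
                )
    return pd.DataFrame(rows)


def analyze_two_roi(
    dataset: SimulatedDataset,
    props: OpticalProperties | None = None,
    chromophores: tuple | None = None,
    glm_fits=None,
) -> pd.DataFrame:
    """Difference-contrast analysis of the two-ROI test on one group.

    Activity was generated in the first ROI only; the active hypothesis is
    the difference (ROI1 - ROI2) and the null is the difference of the two
    mirrored right-hemisphere regions.  A degenerate all-zero difference
    (identical uniform channel sets) yields p = 1 by construction.
    """
    if dataset.second_roi is None:
        raise ValueError("dataset was not simulated in two-ROI mode")
    props = props or OpticalProperties()
    fits = glm_fits if glm_fits is not None else _fit_subject_glms(dataset)
    chromos = chromophores or tuple(name for name, _ in dataset.config.chromophores)
    pairs = {
        "active": (dataset.active_roi, dataset.second_roi),
        "null": (dataset.null_roi, dataset.second_null_roi),
    }
    rows = []
    for method in METHODS:
        for mode in MODES:
            diff_contrasts = {}
            for name, (roi1, roi2) in pairs.items():
                per_subj = []
                for i in range(len(dataset.subjects)):
                    c1 = _contrast_for(dataset, i, roi1, method, mode, props)
                    c2 = _contrast_for(dataset, i, roi2, method, mode, props)
                    if c1 is None or c2 is None:
                        per_subj.append(None)
                    else:
                        per_subj.append(difference_contrast(c1, c2))
                diff_contrasts[name] = per_subj
            for chromo in chromos:
                row = {"method": method, "mode": mode, "chromophore": chromo}
                for name, per_subj in diff_contrasts.items():
                    res = []
                    for i, c in enumerate(per_subj):
                        if c is None:
                            res.append(None)
                        else:
                            r = fits[i][chromo].t_contrast(c)
                            # keep the degenerate p=1 outcome as evidence
                            res.append(r)
                    degen = [r for r in res if r is not None and r.se == 0.0]
                    valid = [r for r in res if r is not None and r.se > 0]
                    if valid:
                        row[f"p_{name}"] = group_combine(valid).p
                    else:
                        row[f"p_{name}"] = 1.0
                    row[f"degenerate_{name}"] = len(degen)
                rows.append(row)
    return pd.DataFrame(rows)


def _summarise_cell(frame: pd.DataFrame, cell_keys: dict) -> tuple[list, list]:
    """ROC/FPR summary rows and DeLong comparisons for one sweep cell."""
    rows, comparisons = [], []
    for mode in frame["mode"].unique():
        for chromo in frame["chromophore"].unique():
            per_method = {}
            for method in METHODS:
                sub = frame[
                    (frame["method"] == method)
                    & (frame["mode"] == mode)
                    & (frame["chromophore"] == chromo)
                ]
                roc = roc_from_pvalues(sub["p_active"].values, sub["p_null"].values)
                fpr05 = float((sub["p_null"].values <= 0.05).mean())
                per_method[method] = sub
                rows.append(
                    {
                        **cell_keys,
                        "mode": mode,
                        "chromophore": chromo,
                        "method": method,
                        "auc": roc.auc,
                        "fpr_at_05": fpr05,
                        "n_reps": len(sub),
                    }
                )
            cmp = delong_compare(
                per_method["tapered"]["p_active"].values,
                per_method["tapered"]["p_null"].values,
                per_method["uniform"]["p_active"].values,
                per_method["uniform"]["p_null"].values,
                paired=True,
            )
            comparisons.append(
                {
                    **cell_keys,
                    "mode": mode,
                    "chromophore": chromo,
                    "auc_tapered": cmp.auc1,
                    "auc_uniform": cmp.auc2,
                    "z": cmp.z,
                    "p": cmp.p,
                }
            )
    return rows, comparisons


def _run_sweep(spec: SweepSpec, two_roi: bool):
    base_head = make_synthetic_head(spec.config.head_mean)
    layout = (
        build_low_density_probe() if spec.probe == "low"
        else build_high_density_probe()
    )
    seeds = np.random.SeedSequence(spec.seed)
    rows, comparisons = [], []
    cells = (
        [(r, s) for r in spec.radii for s in spec.separations]
        if two_roi
        else [(r, None) for r in spec.radii]
    )
    cell_seeds = seeds.spawn(len(cells))
    for (radius, separation), cell_seed in zip(cells, cell_seeds):
        cfg = replace(
            spec.config,
            probe=spec.probe,
            roi_radius=float(radius),
            roi_separation=None if separation is None else float(separation),
        )
        cell_frames = []
        for rep, child in enumerate(cell_seed.spawn(spec.reps)):
            rng = np.random.default_rng(child)
            dataset = simulate_group(cfg, base_head=base_head, layout=layout, rng=rng)
            frame = (
                analyze_two_roi(dataset) if two_roi else analyze_single_roi(dataset)
            )
            frame["rep"] = rep
            cell_frames.append(frame)
        cell = pd.concat(cell_frames, ignore_index=True)
        keys = {"probe": spec.probe, "radius": radius}
        if two_roi:
            keys["separation"] = separation
        r, c = _summarise_cell(cell, keys)
        rows.extend(r)
        comparisons.extend(c)
    return pd.DataFrame(rows), pd.DataFrame(comparisons)


def run_single_roi_sweep(spec: SweepSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-ROI sweep over radii; returns (summary, DeLong comparisons)."""
    return _run_sweep(spec, two_roi=False)


def run_two_roi_sweep(spec: SweepSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-ROI sweep over radius x separation; returns (summary, comparisons)."""
    return _run_sweep(spec, two_roi=True)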
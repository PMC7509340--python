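"""Channel-space first-level GLM and the ROI contrast t-test.

The statistical core follows the standard mass-univariate fNIRS analysis:
raw intensities are converted to optical-density changes, optionally to
hemoglobin concentration changes via the modified Beer-Lambert law, and
each channel's time series is regressed on a design matrix of canonical
hemodynamic responses.  Channels are modelled as independent, so the
coefficient covariance is block-diagonal across channels, and any linear
hypothesis over (channel, condition) coefficients is tested with

    t = (c . beta) / sqrt(c' cov_beta c)

where ``c`` is a contrast vector.  The model/results split mirrors
statsmodels: :class:`ChannelGLM` holds data and design, ``fit()`` returns a
:class:`ChannelGLMResults` carrying estimates, covariances and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.regression.linear_model import yule_walker

from .contrast import ContrastVector

__all__ = [
    "ChannelTimeSeries",
    "BeerLambertParams",
    "ROITestResult",
    "ChannelGLM",
    "ChannelGLMResults",
    "intensity_to_od",
    "mbll",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "roi_t_statistic",
    "group_combine",
]


@dataclass
class ChannelTimeSeries:
    """Samples x channels data with a sampling rate and a unit tag."""

    data: np.ndarray  # (n_samples, n_channels)
    fs: float  # Hz
    unit: str = "intensity"  # intensity | od | hb
    channel_names: tuple | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.unit not in ("intensity", "od", "hb"):
            raise ValueError(f"unknown unit tag {self.unit!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class BeerLambertParams:
    """Per-wavelength pathlength and extinction parameters (2 wavelengths).

    ``extinction`` rows are wavelengths, columns are (HbO, HbR), in
    1/(mM mm); ``distance`` is the source-detector separation l in mm and
    ``dpf`` the differential pathlength factor per wavelength.
    """

    distance: float
    dpf: tuple[float, float]
    extinction: np.ndarray  # (2, 2): [[eps_HbO(l1), eps_HbR(l1)], [l2 ...]]

    def __post_init__(self):
        if self.distance <= 0 or min(self.dpf) <= 0:
            raise ValueError("distance and DPF must be positive")
        if abs(np.linalg.det(np.asarray(self.extinction))) < 1e-12:
            raise ValueError("extinction matrix is singular")


@dataclass(frozen=True)
class ROITestResult:
    """Effect, uncertainty and two-sided p for one contrast hypothesis."""

    effect: float
    se: float
    t: float
    dof: float
    p: float


def intensity_to_od(
    ts: ChannelTimeSeries, baseline: str | np.ndarray = "mean"
) -> ChannelTimeSeries:
    """Optical-density change -ln(I / I0) per channel.

    ``baseline`` is either "mean" (I0 = per-channel scan mean, the usual
    convention) or an explicit per-channel I0 array.
    """
    if np.any(ts.data <= 0):
        raise ValueError("intensities must be positive")
    if isinstance(baseline, str):
        if baseline != "mean":
            raise ValueError("baseline must be 'mean' or an array")
        i0 = ts.data.mean(axis=0)
    else:
        i0 = np.asarray(baseline, float)
        if np.any(i0 <= 0):
            raise ValueError("baseline intensities must be positive")
    od = -np.log(ts.data / i0)
    return ChannelTimeSeries(od, ts.fs, unit="od", channel_names=ts.channel_names)


def mbll(
    od_w1: ChannelTimeSeries,
    od_w2: ChannelTimeSeries,
    params: BeerLambertParams,
) -> tuple[ChannelTimeSeries, ChannelTimeSeries]:
    """Invert the modified Beer-Lambert law for (dHbO, dHbR), mM.

    Solves, per time point and channel, the 2x2 linear system
    ``OD_l = l DPF_l (eps_HbO_l dHbO + eps_HbR_l dHbR)``.
    """
    eps = np.asarray(params.extinction, float)
    lpath = params.distance * np.asarray(params.dpf)  # effective path per wl
    A = lpath[:, None] * eps  # (2 wavelengths, 2 chromophores)
    od = np.stack([od_w1.data, od_w2.data])  # (2, T, C)
    sol = np.linalg.solve(A, od.reshape(2, -1)).reshape(od.shape)
    hbo = ChannelTimeSeries(sol[0], od_w1.fs, unit="hb", channel_names=od_w1.channel_names)
    hbr = ChannelTimeSeries(sol[1], od_w1.fs, unit="hb", channel_names=od_w1.channel_names)
    return hbo, hbr


def canonical_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma canonical hemodynamic response, peak normalised to 1."""
    t = np.asarray(t, float)
    h = stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    h = h - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay / dispersion, scale=dispersion
    )
    peak = h.max()
    return h / peak if peak > 0 else h


def build_design(
    onsets: np.ndarray | dict[str, np.ndarray],
    duration: float,
    n_samples: int,
    fs: float,
    hrf_kwargs: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Boxcar-at-onsets convolved with the canonical HRF, plus an intercept.

    ``onsets`` is an array of event times (s) for a single condition or a
    mapping of condition name to onset array.  Returns the (n_samples, k)
    design matrix and its column names; the intercept is the last column.
    """
    if not isinstance(onsets, dict):
        onsets = {"task": np.asarray(onsets, float)}
    # conditions without any event would give an all-zero (rank-deficient)
    # column; drop them — with no events at all the design is intercept-only
    onsets = {k: np.asarray(v, float) for k, v in onsets.items() if len(v)}
    hrf_kwargs = hrf_kwargs or {}
    t_hrf = np.arange(0, 32.0, 1.0 / fs)
    hrf = canonical_hrf(t_hrf, **hrf_kwargs)
    cols, names = [], []
    for name, times in onsets.items():
        box = np.zeros(n_samples)
        for t0 in times:
            i0 = int(np.floor(t0 * fs))
            i1 = int(np.round((t0 + duration) * fs))
            if i0 >= n_samples:
                continue
            box[i0 : min(max(i1, i0 + 1), n_samples)] = 1.0
        reg = signal.fftconvolve(box, hrf)[:n_samples]
        cols.append(reg)
        names.append(name)
    cols.append(np.ones(n_samples))
    names.append("intercept")
    return np.column_stack(cols), names


def _ar_filter(x: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Prewhiten columns of x with AR coefficients rho (drops first p rows)."""
    p = len(rho)
    coeff = np.concatenate([[1.0], -rho])
    out = signal.lfilter(coeff, [1.0], x, axis=0)
    return out[p:]


class ChannelGLM:
    """Mass-univariate linear model Y = X beta + eps over fNIRS channels.

    Parameters
    ----------
    ts : ChannelTimeSeries (or raw samples x channels array)
    design : (n_samples, k) design matrix
    noise_model : "ar" (default, AR(p) prewhitening per channel via
        Yule-Walker on OLS residuals) or "iid"
    ar_order : order of the AR noise model (default 5)
    """

    def __init__(
        self,
        ts: ChannelTimeSeries | np.ndarray,
        design: np.ndarray,
        design_names: list[str] | None = None,
        noise_model: str = "ar",
        ar_order: int = 5,
    ):
        self.Y = ts.data if isinstance(ts, ChannelTimeSeries) else np.atleast_2d(ts)
        self.X = np.asarray(design, float)
        if self.X.ndim != 2 or self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("design matrix does not match the data")
        if self.X.shape[0] < self.X.shape[1]:
            raise ValueError("more regressors than samples")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        if noise_model not in ("ar", "iid"):
            raise ValueError("noise_model must be 'ar' or 'iid'")
        self.noise_model = noise_model
        self.ar_order = int(ar_order)
        self.design_names = design_names or [
            f"x{j}" for j in range(self.X.shape[1])
        ]

    def fit(self) -> "ChannelGLMResults":
        Y, X = self.Y, self.X
        n, k = X.shape
        n_chan = Y.shape[1]
        beta = np.empty((n_chan, k))
        cov = np.empty((n_chan, k, k))
        ar_coefs = []
        pinv = np.linalg.pinv(X)
        b_ols = (pinv @ Y).T  # (channels, k)
        resid = Y - X @ b_ols.T
        if self.noise_model == "iid":
            dof = n - k
            xtx_inv = np.linalg.inv(X.T @ X)
            for c in range(n_chan):
                s2 = float(resid[:, c] @ resid[:, c]) / dof
                beta[c] = b_ols[c]
                cov[c] = s2 * xtx_inv
                ar_coefs.append(np.zeros(0))
        else:
            p = self.ar_order
            dof = (n - p) - k
            for c in range(n_chan):
                rho, _ = yule_walker(resid[:, c], order=p, method="mle")
                Xw = _ar_filter(X, rho)
                yw = _ar_filter(Y[:, c : c + 1], rho)[:, 0]
                xtx_inv = np.linalg.inv(Xw.T @ Xw)
                b = xtx_inv @ Xw.T @ yw
                rw = yw - Xw @ b
                s2 = float(rw @ rw) / dof
                beta[c] = b
                cov[c] = s2 * xtx_inv
                ar_coefs.append(rho)
        return ChannelGLMResults(
            model=self, beta=beta, cov_beta=cov, dof=float(dof), ar_coefs=ar_coefs
        )


@dataclass
class ChannelGLMResults:
    """Per-channel coefficients, covariances and contrast tests."""

    model: ChannelGLM
    beta: np.ndarray  # (n_channels, k)
    cov_beta: np.ndarray  # (n_channels, k, k) block diagonal across channels
    dof: float
    ar_coefs: list = field(default_factory=list)

    @property
    def condition_names(self) -> list[str]:
        return [n for n in self.model.design_names if n != "intercept"]

    def _condition_index(self) -> np.ndarray:
        return np.array(
            [j for j, n in enumerate(self.model.design_names) if n != "intercept"]
        )

    def flat_beta(self) -> np.ndarray:
        """Task coefficients stacked channel-major: (channel, condition)."""
        return self.beta[:, self._condition_index()].ravel()

    def t_contrast(self, c: ContrastVector | np.ndarray) -> ROITestResult:
        """Test the linear hypothesis c . beta = 0 (two-sided).

        An all-zero contrast (e.g. the difference of two identical uniform
        contrasts) is degenerate by construction and returns t = 0, p = 1.
        """
        weights = c.combined if isinstance(c, ContrastVector) else np.asarray(c, float)
        idx = self._condition_index()
        n_cond = len(idx)
        n_chan = self.beta.shape[0]
        if weights.size == n_chan and n_cond > 1:
            weights = np.kron(weights, np.ones(n_cond))
        if weights.size != n_chan * n_cond:
            raise ValueError("contrast dimension does not match the model")
        if np.all(weights == 0):
            return ROITestResult(effect=0.0, se=0.0, t=0.0, dof=self.dof, p=1.0)
        w = weights.reshape(n_chan, n_cond)
        effect = float(np.sum(w * self.beta[:, idx]))
        var = 0.0
        for ch in range(n_chan):
            sub = self.cov_beta[ch][np.ix_(idx, idx)]
            var += float(w[ch] @ sub @ w[ch])
        if var < -1e-12:
            raise ValueError("coefficient covariance is not positive semidefinite")
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            t = np.inf if effect != 0 else 0.0
        else:
            t = effect / se
        p = float(2.0 * stats.t.sf(abs(t), self.dof)) if np.isfinite(t) else 0.0
        return ROITestResult(effect=effect, se=se, t=float(t), dof=self.dof, p=p)

    def summary(self) -> pd.DataFrame:
        """Per-(channel, condition) coefficient table with t and p."""
        idx = self._condition_index()
        rows = []
        for ch in range(self.beta.shape[0]):
            for j_pos, j in enumerate(idx):
                b = self.beta[ch, j]
                se = float(np.sqrt(self.cov_beta[ch, j, j]))
                t = b / se if se > 0 else np.inf
                rows.append(
                    {
                        "channel": ch,
                        "condition": self.condition_names[j_pos],
                        "beta": b,
                        "se": se,
                        "t": t,
                        "dof": self.dof,
                        "p": float(2.0 * stats.t.sf(abs(t), self.dof)),
                    }
                )
        return pd.DataFrame(rows)


def fit_glm(
    ts: ChannelTimeSeries | np.ndarray,
    design: np.ndarray,
    noise_model: str = "ar",
    ar_order: int = 5,
    design_names: list[str] | None = None,
) -> ChannelGLMResults:
    """Convenience wrapper: build a :class:`ChannelGLM` and fit it."""
    return ChannelGLM(
        ts, design, design_names=design_names, noise_model=noise_model,
        ar_order=ar_order,
    ).fit()


def roi_t_statistic(
    res: ChannelGLMResults, c: ContrastVector | np.ndarray
) -> ROITestResult:
    """ROI t-test of the contrast hypothesis on fitted GLM results."""
    return res.t_contrast(c)


def group_combine(
    subject_results: list[ROITestResult | tuple],
    method: str = "fixed",
) -> ROITestResult:
    """Combine per-subject effects across a group.

    ``fixed`` (default) is the inverse-variance-weighted fixed-effects
    estimate with pooled degrees of freedom; ``random`` adds a
    DerSimonian-Laird between-subject variance component.
    """
    if not subject_results:
        raise ValueError("at least one subject required")
    eff = np.array([r.effect if isinstance(r, ROITestResult) else r[0] for r in subject_results])
    se = np.array([r.se if isinstance(r, ROITestResult) else r[1] for r in subject_results])
    dof = np.array([r.dof if isinstance(r, ROITestResult) else r[2] for r in subject_results])
    if np.any(se <= 0):
        raise ValueError("zero-variance subject result")
    v = se**2
    if method == "random" and len(eff) > 1:
        w = 1.0 / v
        mu_fe = np.sum(w * eff) / np.sum(w)
        q = float(np.sum(w * (eff - mu_fe) ** 2))
        tau2 = max(0.0, (q - (len(eff) - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        v = v + tau2
    w = 1.0 / v
    effect = float(np.sum(w * eff) / np.sum(w))
    se_comb = float(1.0 / np.sqrt(np.sum(w)))
    dof_comb = float(np.sum(dof))
    t = effect / se_comb
    p = float(2.0 * stats.t.sf(abs(t), dof_comb))
    return ROITestResult(effect=effect, se=se_comb, t=t, dof=dof_comb, p=p)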
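"""Image-restoration quality metrics: NRMSE, SSIM, and SNR.

Predicted and ground-truth stacks are first brought onto the ground truth's
dynamic range by percentile normalization (0.3 / 99.7 by default), then
compared with NRMSE and SSIM.  SSIM for a hyperspectral stack is computed
per spectral plane and averaged, since spatial structure and spectral
structure carry different physical correlations.

SNR here is the ratio of the mean intensity over a signal region to the
standard deviation over a background region, both taken at a single spectral
channel.  This matches how single SNR numbers are quoted for raw SRS frames
(e.g. a cell region at 1650 cm^-1 against empty background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "MetricReport",
    "range_normalize_pair",
    "nrmse",
    "ssim",
    "snr_measure",
    "evaluate_pair",
]


@dataclass(frozen=True)
class MetricReport:
    nrmse: float
    ssim: float
    snr: float | None = None
    per_channel_ssim: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {"nrmse": self.nrmse, "ssim": self.ssim}
        if self.snr is not None:
            out["snr"] = self.snr
        return out


def _percentiles(x: np.ndarray, lo_pct: float, hi_pct: float) -> tuple[float, float]:
    lo = float(np.percentile(x, lo_pct))
    hi = float(np.percentile(x, hi_pct))
    if hi <= lo:
        raise ValueError(
            "degenerate dynamic range: high percentile does not exceed low percentile"
        )
    return lo, hi


def range_normalize_pair(
    pred: np.ndarray,
    gt: np.ndarray,
    lo_pct: float = 0.3,
    hi_pct: float = 99.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale both images to the ground truth's percentile dynamic range.

    Both arrays are mapped by ``x -> (x - lo) / (hi - lo)`` where ``lo`` and
    ``hi`` are the ground truth's percentiles, putting prediction and ground
    truth on one common scale while excluding rare hot pixels from it.
    """
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth must share a shape")
    lo, hi = _percentiles(gt, lo_pct, hi_pct)
    return (pred - lo) / (hi - lo), (gt - lo) / (hi - lo)


def nrmse(pred: np.ndarray, gt: np.ndarray, fit_affine: bool = False) -> float:
    """Root-mean-square error normalized by the RMS of the ground truth.

    With ``fit_affine=True`` the prediction is first mapped through the
    least-squares affine transform ``a * pred + b`` minimizing the error,
    making the metric invariant to global gain/offset differences.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    gt = np.asarray(gt, dtype=float).ravel()
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth must share a shape")
    denom = float(np.sqrt(np.mean(gt**2)))
    if denom == 0.0:
        raise ValueError("ground truth has zero energy; NRMSE undefined")
    if fit_affine:
        A = np.stack([pred, np.ones_like(pred)], axis=1)
        coef, *_ = np.linalg.lstsq(A, gt, rcond=None)
        pred = A @ coef
    return float(np.sqrt(np.mean((pred - gt) ** 2)) / denom)


def ssim(
    pred: np.ndarray,
    gt: np.ndarray,
    window: int = 7,
    data_range: float | None = None,
) -> float:
    """Mean structural similarity, per spectral plane for rank-3 stacks.

    Uses the standard stabilizing constants (k1=0.01, k2=0.03) and a uniform
    ``window`` x ``window`` local window.  ``data_range`` defaults to the
    ground truth's full intensity range.
    """
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth must share a shape")
    if data_range is None:
        data_range = float(gt.max() - gt.min())
        if data_range == 0.0:
            raise ValueError("constant ground truth: supply data_range explicitly")
    if pred.ndim == 2:
        planes = [(pred, gt)]
    elif pred.ndim == 3:
        planes = [(pred[k], gt[k]) for k in range(pred.shape[0])]
    else:
        raise ValueError("ssim expects a 2-D image or a rank-3 (lambda, y, x) stack")
    if min(planes[0][0].shape) < window:
        raise ValueError("SSIM window larger than the image")
    vals = [
        structural_similarity(p, g, win_size=window, data_range=data_range,
                              gaussian_weights=False)
        for p, g in planes
    ]
    return float(np.mean(vals))


def snr_measure(
    stack: np.ndarray,
    channel: int,
    signal_mask: np.ndarray,
    background_mask: np.ndarray,
) -> float:
    """Signal-to-noise ratio at one spectral channel.

    Mean intensity over ``signal_mask`` divided by the standard deviation over
    ``background_mask``, both in the image plane of the given channel.
    """
    data = np.asarray(stack, dtype=float)
    if data.ndim == 3:
        plane = data[channel]
    elif data.ndim == 2:
        plane = data
    else:
        raise ValueError("expected a 2-D image or rank-3 stack")
    sig = np.asarray(signal_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if not sig.any() or not bg.any():
        raise ValueError("signal and background masks must be non-empty")
    if np.any(sig & bg):
        raise ValueError("signal and background masks must be disjoint")
    noise = float(plane[bg].std())
    if noise == 0.0:
        raise ValueError("zero background standard deviation: SNR undefined")
    return float(plane[sig].mean() / noise)


def evaluate_pair(
    pred: np.ndarray,
    gt: np.ndarray,
    lo_pct: float = 0.3,
    hi_pct: float = 99.7,
    ssim_window: int = 7,
) -> MetricReport:
    """Normalize a prediction/ground-truth pair and report NRMSE and SSIM."""
    p, g = range_normalize_pair(pred, gt, lo_pct=lo_pct, hi_pct=hi_pct)
    data_range = float(g.max() - g.min())
    per_channel = None
    if p.ndim == 3:
        per_channel = np.array(
            [ssim(p[k], g[k], window=ssim_window, data_range=data_range)
             for k in range(p.shape[0])]
        )
    return MetricReport(
        nrmse=nrmse(p, g),
        ssim=ssim(p, g, window=ssim_window, data_range=data_range),
        per_channel_ssim=per_channel,
    )
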
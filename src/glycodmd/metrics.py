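"""Fit-quality metrics for traces and frames, and the Fourier baseline.

Trace metrics: the L2 error measures point-wise distance between data and
model output, the Pearson coefficient their correlation, and the R2 score
the fraction of data variance the model explains.  Frame metrics are the
mean squared error and the structural similarity index (SSIM).  The
Fourier low-pass filter serves as the traditional smoothing baseline a
modal decomposition is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["FitMetrics", "trace_fit_metrics", "image_quality",
           "fourier_lowpass"]


@dataclass(frozen=True)
class FitMetrics:
    l2_error: float
    rmse: float
    pearson_r: float    # NaN when the data have zero variance
    r2: float           # NaN when the data have zero variance

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.pearson_r) or np.isnan(self.r2))


def trace_fit_metrics(data, model_output) -> FitMetrics:
    """L2 error, RMSE, Pearson r and R2 between a trace and its model.

    Zero-variance data leave Pearson/R2 as NaN sentinels (undefined).
    """
    x = np.asarray(data, dtype=float).ravel()
    y = np.asarray(model_output, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    diff = y - x
    l2 = float(np.linalg.norm(diff))
    rmse = l2 / np.sqrt(x.size)
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0:
        return FitMetrics(l2, rmse, float("nan"), float("nan"))
    r2 = 1.0 - float(np.sum(diff ** 2)) / ss_tot
    sy = y.std()
    pearson = (float(np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * sy))
               if sy > 0 else float("nan"))
    return FitMetrics(l2, rmse, pearson, r2)


def image_quality(frame_a, frame_b) -> dict:
    """MSE and SSIM between two single-channel frames.

    SSIM uses a 7-pixel window and the standard stabilizing constants; the
    data range is taken from the joint range of the frame pair.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("frames must be 2-D single-channel")
    mse = float(np.mean((a - b) ** 2))
    data_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if data_range == 0:
        return {"mse": mse, "ssim": 1.0 if mse == 0 else -1.0}
    ssim = float(structural_similarity(a, b, win_size=7,
                                       data_range=data_range))
    return {"mse": mse, "ssim": ssim}


def fourier_lowpass(trace, n_keep: int) -> np.ndarray:
    """Keep the ``n_keep`` largest-magnitude frequency components.

    Components are selected among the nonnegative-frequency (rfft) bins by
    magnitude; conjugate symmetry is preserved by construction, so the
    output is real.  ``n_keep`` equal to the number of bins reproduces the
    input.
    """
    x = np.asarray(trace, dtype=float).ravel()
    spec = np.fft.rfft(x)
    if not 1 <= n_keep <= spec.size:
        raise ValueError(
            f"n_keep must be in [1, {spec.size}] for {x.size} samples")
    order = np.argsort(np.abs(spec))[::-1]
    mask = np.zeros(spec.size, dtype=bool)
    mask[order[:n_keep]] = True
    return np.fft.irfft(np.where(mask, spec, 0.0), n=x.size)
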
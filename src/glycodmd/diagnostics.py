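"""Spectral validation: eigenpair residuals and analytic-spectrum comparison.

A finite-rank approximation of the Koopman operator can suffer spectral
pollution: eigenvalues of the reduced operator that do not correspond to
any dynamics present in the data.  Following the residual-DMD idea, each
eigenpair is assigned the relative data-space residual

    res_j = || X2 w_j - lambda_j X1 w_j || / || X1 w_j ||

where ``w_j`` is the eigenvector expressed in the snapshot (column) basis
of ``X1``.  Exactly-linear noiseless data give residuals at machine
precision; spurious eigenvalues give residuals of order one.  The second
diagnostic compares the unit-circle phases of the DMD eigenvalues with the
phases of the analytically linearized oscillator spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import TraceMatrix
from .dmd import DMDModel, build_hankel, fit_exact_dmd, reconstruct
from .errors import EmbeddingError
from .metrics import trace_fit_metrics
from .oscillators import AnalyticSpectrum

__all__ = [
    "ResidualSpectrum",
    "SpectrumComparison",
    "eigenpair_residuals",
    "compare_to_analytic",
    "embedding_scan",
]

DEFAULT_RESIDUAL_THRESHOLD = 0.5


@dataclass
class ResidualSpectrum:
    residuals: np.ndarray      # (r,) nonnegative; NaN where undefined
    threshold: float
    accepted: np.ndarray       # (r,) bool, residual <= threshold
    undefined: np.ndarray      # (r,) bool, ||X1 w_j|| == 0

    @property
    def spurious(self) -> np.ndarray:
        return ~self.accepted & ~self.undefined

    @property
    def accepted_fraction(self) -> float:
        ok = ~self.undefined
        return float(self.accepted[ok].mean()) if ok.any() else float("nan")


@dataclass
class SpectrumComparison:
    distances: np.ndarray        # (r,) angular distances, radians, in [0, pi]
    nearest_phase: np.ndarray    # (r,) complex analytic phase matched
    mean: float = field(init=False)
    median: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean = float(np.mean(self.distances))
        self.median = float(np.median(self.distances))


def eigenpair_residuals(
    X1: np.ndarray,
    X2: np.ndarray,
    model: DMDModel,
    threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
) -> ResidualSpectrum:
    """Relative data-space residual of every model eigenpair.

    ``X1``/``X2`` must be the (augmented) snapshot matrices the model was
    fitted on.  Residuals are invariant to rescaling the whole dataset.
    """
    if model.mode_coeffs is None:
        raise ValueError("model carries no snapshot-basis eigenvectors")
    W = model.mode_coeffs
    lam = model.eigenvalues
    A1 = X1 @ W
    A2 = X2 @ W
    norms = np.linalg.norm(A1, axis=0)
    undefined = norms == 0
    residuals = np.full(lam.shape, np.nan)
    ok = ~undefined
    residuals[ok] = (np.linalg.norm(A2[:, ok] - A1[:, ok] * lam[ok][None, :],
                                    axis=0) / norms[ok])
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} eigenpair(s) have zero data-space "
            "norm; residual undefined", UserWarning, stacklevel=2)
    accepted = np.zeros(lam.shape, dtype=bool)
    accepted[ok] = residuals[ok] <= threshold
    return ResidualSpectrum(residuals=residuals, threshold=threshold,
                            accepted=accepted, undefined=undefined)


def _angular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise |wrapped phase difference| in [0, pi]: (len(a), len(b))."""
    diff = a[:, None] - b[None, :]
    return np.abs(np.angle(np.exp(1j * diff)))


def compare_to_analytic(model: DMDModel, analytic: AnalyticSpectrum
                        ) -> SpectrumComparison:
    """Nearest analytic phase for each DMD eigenvalue, on the unit circle.

    Matching is greedy nearest-neighbour per DMD eigenvalue (adequate for
    the ranks used here, r <= 50); eigenvalues at the origin are skipped.
    """
    lam = model.eigenvalues
    keep = np.abs(lam) > 0
    if not keep.any() or analytic.flat_phases.size == 0:
        raise ValueError("empty spectrum")
    dmd_phase = np.angle(lam[keep])
    ana_phase = np.angle(analytic.flat_phases)
    dist = _angular_distance(dmd_phase, ana_phase)
    j = dist.argmin(axis=1)
    return SpectrumComparison(distances=dist[np.arange(len(j)), j],
                              nearest_phase=analytic.flat_phases[j])


def embedding_scan(
    traces: TraceMatrix,
    d_list,
    r: int,
    l: int = 1,
    analytic: AnalyticSpectrum | None = None,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
    center: bool = True,
) -> list[dict]:
    """Fit Hankel DMD over a grid of embedding depths.

    By default traces are centered per cell first: the analytic spectrum
    describes deviations from the steady state, and centering keeps the
    rank budget from being spent on the static offsets.  For each feasible
    ``d`` the record contains the training-window reconstruction RMSE
    (scored over the Hankel column range the regression actually fits),
    the eigenvalues, a residual summary and (when the analytic spectrum is
    given) the mean angular phase distance to it.  Infeasible depths are
    skipped with a warning.
    """
    data = traces.data
    if center:
        data = data - data.mean(axis=1, keepdims=True)
    records = []
    for d in d_list:
        try:
            emb = build_hankel(data, d=int(d), l=l, dt=traces.dt)
        except EmbeddingError as err:
            warnings.warn(f"skipping d = {d}: {err}", UserWarning,
                          stacklevel=2)
            continue
        model = fit_exact_dmd(emb, r=r)
        cols = emb.H.shape[1]
        recon = reconstruct(model, np.arange(cols))
        fit = trace_fit_metrics(data[:, :cols].ravel(), recon.ravel())
        res = eigenpair_residuals(emb.H[:, :-1], emb.H[:, 1:], model,
                                  threshold=residual_threshold)
        record = {
            "d": int(d),
            "l": l,
            "r": model.rank,
            "rmse": fit.rmse,
            "r2": fit.r2,
            "eigenvalues": model.eigenvalues.copy(),
            "residuals": res.residuals.copy(),
            "accepted_fraction": res.accepted_fraction,
            "model": model,
        }
        if analytic is not None:
            record["phase_distance_mean"] = compare_to_analytic(
                model, analytic).mean
        records.append(record)
    return records
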
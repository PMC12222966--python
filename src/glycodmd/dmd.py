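"""Exact DMD, Hankel/time-delay embedding and higher-order DMD.

Dynamic mode decomposition approximates the one-step evolution of a
sequence of snapshots ``x_1 ... x_m`` by a best-fit linear operator ``A``
(``X2 ~= A X1`` in the Frobenius norm), computed through a rank-``r``
truncated SVD of ``X1``.  The eigen-decomposition of the reduced operator
yields discrete eigenvalues ``lambda_j``, modes ``phi_j`` and amplitudes
``b_j`` such that

    x_k  ~=  sum_j  phi_j * lambda_j**(k-1) * b_j

Continuous growth/frequency rates follow as ``omega = ln(lambda) / dt``.

Time-delay embedding stacks ``d`` extra time-shifted copies of every data
row into a Hankel-structured augmented matrix (shift offsets ``0, l, 2l,
..., d*l``); DMD on the augmented matrix is the Hankel/TDE variant used
throughout this package.  Higher-order DMD (multi-lag Koopman assumption,
companion-structured operator) is algebraically DMD on the same stacked
snapshot vectors, and is implemented that way: ``fit_hodmd`` with ``d``
stacked blocks equals exact DMD on a Hankel embedding with ``d - 1`` extra
shifts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateDataError,
    EmbeddingError,
    RankTruncationWarning,
    UnstableModeWarning,
)

__all__ = [
    "SnapshotPair",
    "HankelEmbedding",
    "DMDModel",
    "ForecastResult",
    "build_hankel",
    "fit_exact_dmd",
    "fit_hodmd",
    "to_continuous_rates",
    "solve_amplitudes",
    "reconstruct",
    "predict",
    "cell_mode_amplitude_features",
]

_ZERO_EIG_TOL = 1e-14


@dataclass
class SnapshotPair:
    """Time-shifted snapshot matrices X1 = [x_1..x_{m-1}], X2 = [x_2..x_m]."""

    X1: np.ndarray
    X2: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        if self.X1.shape != self.X2.shape:
            raise ValueError("X1 and X2 must have identical shape")
        if not (np.isfinite(self.X1).all() and np.isfinite(self.X2).all()):
            raise ValueError("snapshots must be finite")

    @classmethod
    def from_matrix(cls, data: np.ndarray, dt: float = 1.0) -> "SnapshotPair":
        data = np.asarray(data, dtype=float)
        if data.shape[1] < 2:
            raise ValueError("need at least two snapshots")
        return cls(X1=data[:, :-1], X2=data[:, 1:], dt=dt)


@dataclass
class HankelEmbedding:
    """Augmented (block-Hankel) matrix: one block of rows per time shift.

    Block ``s`` (s = 0..d) contains every original row shifted by ``s*l``
    samples, so ``H`` has ``m*(d+1)`` rows and ``n - d*l`` columns.
    """

    H: np.ndarray
    d: int          # number of extra shifted blocks
    l: int          # delay step length, samples
    m: int          # original row count
    n: int          # original timepoint count
    dt: float = 1.0

    def __post_init__(self) -> None:
        expect = (self.m * (self.d + 1), self.n - self.d * self.l)
        if self.H.shape != expect:
            raise ValueError(f"H has shape {self.H.shape}, expected {expect}")


def build_hankel(data, d: int, l: int = 1, dt: float | None = None
                 ) -> HankelEmbedding:
    """Stack ``d`` extra time-shifted copies of each row below the data.

    ``data`` may be a 2-D array (rows = cells or pixels, columns =
    timepoints) or a :class:`~glycodmd.containers.TraceMatrix`.  ``d = 0``
    returns the data unchanged (as a single block).
    """
    from .containers import TraceMatrix  # local import to avoid cycle

    if isinstance(data, TraceMatrix):
        if dt is None:
            dt = data.dt
        data = data.data
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    if dt is None:
        dt = 1.0
    m, n = data.shape
    if d < 0 or l < 1:
        raise ValueError("need d >= 0 and l >= 1")
    if n <= d * l + 1:
        d_max = (n - 2) // l
        raise EmbeddingError(
            f"embedding too deep: n = {n} timepoints support at most "
            f"d = {d_max} extra shifts at step l = {l}")
    cols = n - d * l
    H = np.empty((m * (d + 1), cols))
    for s in range(d + 1):
        H[s * m:(s + 1) * m] = data[:, s * l:s * l + cols]
    return HankelEmbedding(H=H, d=d, l=l, m=m, n=n, dt=dt)


@dataclass
class DMDModel:
    """Fitted spectral decomposition of (possibly delay-embedded) data.

    ``modes`` live in the augmented space; the first ``m_rows`` rows are
    the shift-0 block and are used for de-embedded reconstruction.
    ``mode_coeffs`` are the eigenvector coordinates in the snapshot
    (column) basis of X1, kept for residual diagnostics.
    """

    rank: int
    eigenvalues: np.ndarray        # (r,) complex, discrete
    modes: np.ndarray              # (aug_dim, r) complex
    amplitudes: np.ndarray         # (r,) complex
    dt: float
    d: int = 0
    l: int = 1
    m_rows: int = 0                # rows of the un-embedded data
    n_times: int = 0               # original training timepoints
    basis: np.ndarray | None = None        # (aug_dim, r) left singular vecs
    mode_coeffs: np.ndarray | None = None  # (cols-1, r) snapshot basis
    singular_values: np.ndarray | None = None
    amplitude_residual: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = self.rank
        if not (len(self.eigenvalues) == self.modes.shape[1]
                == len(self.amplitudes) == r):
            raise ValueError("rank and decomposition sizes disagree")

    @property
    def omegas(self) -> np.ndarray:
        """Continuous complex rates, 1/time."""
        return to_continuous_rates(self.eigenvalues, self.dt)

    # -------------------------------------------------------------- I/O

    def to_json(self, path: str | Path | None = None) -> str:
        def c2l(arr):
            arr = np.asarray(arr)
            return np.stack([arr.real, arr.imag], axis=-1).tolist()

        payload = {
            "rank": self.rank, "d": self.d, "l": self.l, "dt": self.dt,
            "m_rows": self.m_rows, "n_times": self.n_times,
            "eigenvalues": c2l(self.eigenvalues),
            "modes": c2l(self.modes),
            "amplitudes": c2l(self.amplitudes),
            "amplitude_residual": self.amplitude_residual,
            "meta": self.meta,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DMDModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        obj = json.loads(text)

        def l2c(lst):
            arr = np.asarray(lst, dtype=float)
            return arr[..., 0] + 1j * arr[..., 1]

        return cls(
            rank=obj["rank"], d=obj["d"], l=obj["l"], dt=obj["dt"],
            m_rows=obj["m_rows"], n_times=obj["n_times"],
            eigenvalues=l2c(obj["eigenvalues"]),
            modes=l2c(obj["modes"]),
            amplitudes=l2c(obj["amplitudes"]),
            amplitude_residual=obj.get("amplitude_residual", 0.0),
            meta=obj.get("meta", {}),
        )


@dataclass
class ForecastResult:
    """Training-window reconstruction plus extrapolation beyond it."""

    fitted: np.ndarray       # (m_rows, split_index)
    forecast: np.ndarray     # (m_rows, horizon)
    split_index: int
    dt: float
    metrics: dict = field(default_factory=dict)


# -------------------------------------------------------------- fitting


def _as_pair(data, dt: float | None):
    """Normalize input to (X1, X2, dt, d, l, m_rows, n_times)."""
    if isinstance(data, SnapshotPair):
        use_dt = dt if dt is not None else data.dt
        return (data.X1, data.X2, use_dt, 0, 1,
                data.X1.shape[0], data.X1.shape[1] + 1)
    if isinstance(data, HankelEmbedding):
        use_dt = dt if dt is not None else data.dt
        H = data.H
        return H[:, :-1], H[:, 1:], use_dt, data.d, data.l, data.m, data.n
    from .containers import TraceMatrix
    if isinstance(data, TraceMatrix):
        use_dt = dt if dt is not None else data.dt
        arr = data.data
    else:
        arr = np.asarray(data, dtype=float)
        use_dt = dt if dt is not None else 1.0
    if arr.ndim == 1:
        arr = arr[None, :]
    return (arr[:, :-1], arr[:, 1:], use_dt, 0, 1,
            arr.shape[0], arr.shape[1])


def fit_exact_dmd(data, r: int, dt: float | None = None) -> DMDModel:
    """Exact DMD of snapshots, optionally delay-embedded.

    ``data`` may be a 2-D matrix (rows observables, columns snapshots), a
    :class:`SnapshotPair`, a :class:`HankelEmbedding` or a ``TraceMatrix``.
    ``r`` is the SVD truncation rank; if it exceeds the numerical rank of
    X1 a warning is issued and the rank is truncated.
    """
    X1, X2, use_dt, d, l, m_rows, n_times = _as_pair(data, dt)
    if r < 1:
        raise ValueError("rank r must be >= 1")
    if r > min(X1.shape):
        raise ValueError(
            f"rank r = {r} exceeds min(rows, cols-1) = {min(X1.shape)}")
    U, s, Vh = np.linalg.svd(X1, full_matrices=False)
    if s[0] == 0:
        raise DegenerateDataError("all-zero snapshot matrix")
    tol = np.finfo(float).eps * max(X1.shape) * s[0]
    num_rank = int(np.sum(s > tol))
    if r > num_rank:
        warnings.warn(
            f"requested rank {r} exceeds numerical rank {num_rank}; "
            "truncating", RankTruncationWarning, stacklevel=2)
        r = num_rank
    Ur = U[:, :r]
    sr = s[:r]
    Vr = Vh[:r].conj().T
    B = X2 @ (Vr / sr)                     # = X2 V S^-1, (aug_dim, r)
    A_tilde = Ur.conj().T @ B
    eigvals, W = np.linalg.eig(A_tilde)
    # Exact DMD modes; projected modes as fallback for (near-)zero eigenvalues
    modes = B @ W
    coeffs = (Vr / sr) @ W                 # snapshot-basis coefficients
    zero = np.abs(eigvals) < _ZERO_EIG_TOL
    if zero.any():
        modes[:, zero] = (Ur @ W)[:, zero]
    model = DMDModel(
        rank=r, eigenvalues=eigvals, modes=modes,
        amplitudes=np.zeros(r, dtype=complex), dt=use_dt, d=d, l=l,
        m_rows=m_rows, n_times=n_times, basis=Ur, mode_coeffs=coeffs,
        singular_values=s,
    )
    b, resid = solve_amplitudes(model, X1[:, 0])
    model.amplitudes = b
    model.amplitude_residual = resid
    _sort_modes(model)
    return model


def _sort_modes(model: DMDModel) -> None:
    """Order triplets by energy |b_j| * ||phi_j||, ties by |lambda_j|."""
    energy = np.abs(model.amplitudes) * np.linalg.norm(model.modes, axis=0)
    order = np.lexsort((-np.abs(model.eigenvalues), -energy))
    model.eigenvalues = model.eigenvalues[order]
    model.modes = model.modes[:, order]
    model.amplitudes = model.amplitudes[order]
    if model.mode_coeffs is not None:
        model.mode_coeffs = model.mode_coeffs[:, order]


def fit_hodmd(snapshots, d: int, r: int, dt: float | None = None) -> DMDModel:
    """Higher-order DMD: DMD under a ``d``-lag evolution assumption.

    Stacks ``d`` consecutive snapshot vectors (``d = 1`` is plain exact
    DMD) and proceeds as exact DMD on the stacked matrix; accepts flattened
    image frames as snapshot columns.
    """
    if d < 1:
        raise ValueError("HoDMD stacking order d must be >= 1")
    emb = build_hankel(snapshots, d=d - 1, l=1, dt=dt)
    model = fit_exact_dmd(emb, r=r, dt=dt)
    model.meta["hodmd_order"] = d
    return model


# ---------------------------------------------------------- decomposition


def to_continuous_rates(eigenvalues, dt: float) -> np.ndarray:
    """Map discrete eigenvalues to continuous rates, omega = ln(lambda)/dt.

    The principal branch is used; ``exp(omega * dt)`` reproduces ``lambda``
    to machine precision.  A zero eigenvalue maps to the infinite-decay
    sentinel ``-inf`` (excluded from any reconstruction).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam = np.asarray(eigenvalues, dtype=complex)
    omega = np.full(lam.shape, -np.inf + 0j, dtype=complex)
    nz = np.abs(lam) >= _ZERO_EIG_TOL
    omega[nz] = np.log(lam[nz]) / dt
    return omega


def solve_amplitudes(model: DMDModel, first_snapshot: np.ndarray
                     ) -> tuple[np.ndarray, float]:
    """Least-squares mode amplitudes from the first augmented snapshot.

    Returns ``(b, residual_norm)`` with ``Phi @ b ~= x_1``; a
    rank-deficient mode matrix yields the minimum-norm solution (with a
    warning).
    """
    x1 = np.asarray(first_snapshot, dtype=complex).ravel()
    if x1.size != model.modes.shape[0]:
        raise ValueError(
            f"first snapshot has dim {x1.size}, expected "
            f"{model.modes.shape[0]} (augmented space)")
    b, _, rank, _ = np.linalg.lstsq(model.modes, x1, rcond=None)
    if rank < model.rank:
        warnings.warn(
            "mode matrix is rank-deficient; minimum-norm amplitudes",
            RankTruncationWarning, stacklevel=2)
    resid = float(np.linalg.norm(model.modes @ b - x1))
    return b, resid


def _modal_sum(model: DMDModel, k_range: np.ndarray) -> np.ndarray:
    """Evaluate sum_j phi0_j lambda_j^k b_j over the shift-0 block rows."""
    lam = model.eigenvalues
    keep = np.abs(lam) >= _ZERO_EIG_TOL
    phi0 = model.modes[:model.m_rows or model.modes.shape[0], keep]
    weights = model.amplitudes[keep]
    lam = lam[keep]
    if (np.abs(lam) > 1.0 + 1e-9).any() and k_range.max(initial=0) > 0:
        warnings.warn(
            "eigenvalues outside the unit circle; forecast values grow "
            "exponentially (overflow-guarded)", UnstableModeWarning,
            stacklevel=3)
    # guard overflow: cap |lambda|^k at ~1e150
    with np.errstate(over="ignore", invalid="ignore"):
        log_mag = np.log(np.abs(lam))[:, None] * k_range[None, :]
        log_mag = np.minimum(log_mag, 345.0)
        phase = np.angle(lam)[:, None] * k_range[None, :]
        vander = np.exp(log_mag + 1j * phase)
    return phi0 @ (weights[:, None] * vander)


def reconstruct(model: DMDModel, k_range=None, imag_tol: float = 1e-6
                ) -> np.ndarray:
    """De-embedded modal reconstruction at the requested time steps.

    ``k_range`` are integer step indices relative to the training start
    (default: the full original training window ``0 .. n_times-1``); the
    shift-0 block of the augmented modes is read out, so rows correspond
    one-to-one to the input rows.  The real part is returned; the relative
    imaginary residue is reported in ``model.meta`` and must stay below
    ``imag_tol`` for conjugate-closed spectra.
    """
    if k_range is None:
        k_range = np.arange(model.n_times)
    k_range = np.asarray(k_range)
    if (k_range < 0).any():
        raise ValueError("requested steps precede the training start")
    out = _modal_sum(model, k_range.astype(float))
    signal = np.linalg.norm(out.real)
    residue = np.linalg.norm(out.imag) / signal if signal > 0 else 0.0
    model.meta["imag_residue"] = float(residue)
    if residue > imag_tol and _conjugate_closed(model.eigenvalues):
        warnings.warn(
            f"imaginary residue {residue:.2e} exceeds {imag_tol:g}",
            UserWarning, stacklevel=2)
    return out.real


def _conjugate_closed(lam: np.ndarray, tol: float = 1e-10) -> bool:
    lam = np.asarray(lam)
    remaining = list(lam)
    for value in lam:
        if abs(value.imag) < tol:
            continue
        if not any(abs(other - value.conjugate()) < tol * max(1, abs(value))
                   for other in remaining):
            return False
    return True


def predict(model: DMDModel, horizon: int) -> ForecastResult:
    """Evaluate the modal sum beyond the training window.

    Returns the reconstruction over the training window (``fitted``) and
    the extrapolation over the next ``horizon`` steps (``forecast``),
    separated at ``split_index = n_times``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    split = model.n_times
    full = reconstruct(model, np.arange(split + horizon))
    return ForecastResult(fitted=full[:, :split], forecast=full[:, split:],
                          split_index=split, dt=model.dt)


def cell_mode_amplitude_features(model: DMDModel) -> np.ndarray:
    """Per-cell DMD amplitude features: cells x rank, nonnegative.

    Feature ``(i, j)`` is the modulus (root of summed squared real and
    imaginary parts) of the shift-0 mode entry of cell ``i`` in mode ``j``
    weighted by the mode amplitude ``b_j``; invariant to a global phase
    rotation of any mode/amplitude pair.
    """
    phi0 = model.modes[:model.m_rows]
    return np.abs(phi0 * model.amplitudes[None, :])
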
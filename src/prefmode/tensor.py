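"""Population tensors, mode unfoldings, SVD bases and rank-k reconstruction.

A trial-averaged population recording is a third-order array
``X ∈ R^{N×C×T}`` indexed by neuron, condition and time.  The two analysis
modes correspond to the two matrix unfoldings

* neuron mode (mode 1):    ``X_(1) ∈ R^{N×(C·T)}`` — one row per neuron;
* condition mode (mode 2): ``X_(2) ∈ R^{C×(N·T)}`` — one row per condition.

Truncated SVD of an unfolding yields *basis-neurons* (C×T patterns) or
*basis-conditions* (N×T patterns); the normalized squared error of the
rank-k reconstruction is the central quantity of the preferred-mode
analysis.  Columns of the unfoldings are laid out in time-major blocks
``[X(1) X(2) … X(T)]`` where ``X(t)`` is the N×C slice at time t; within a
block columns run over conditions (mode 1) or neurons (mode 2).  Column
order does not affect singular values or reconstruction errors, but a fixed
order keeps coefficient matrices reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.linalg

from .exceptions import DegenerateDataError, InvalidInputError

Mode = Literal["neuron", "condition"]

_MODES = ("neuron", "condition")


def _check_mode(mode: str) -> str:
    if mode not in _MODES:
        raise InvalidInputError(f"mode must be one of {_MODES}, got {mode!r}")
    return mode


@dataclass
class PopulationTensor:
    """An N×C×T array of firing rates with axis labels.

    Parameters
    ----------
    values
        Real array of shape (n_neurons, n_conditions, n_timepoints), in
        spikes/s for raw data or arbitrary units after soft normalization.
    neuron_ids, condition_ids
        Axis labels; lengths must match the array shape.
    time_ms
        Strictly increasing, uniformly spaced sample times in milliseconds.
    units_flag
        ``"raw"`` or ``"soft_normalized"``.
    centered_flag
        True once the cross-condition mean has been removed.
    meta
        Free-form provenance (e.g. which neurons/conditions were kept by
        count equalization).
    """

    values: np.ndarray
    neuron_ids: list[str]
    condition_ids: list[str]
    time_ms: np.ndarray
    units_flag: str = "raw"
    centered_flag: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.values.ndim != 3:
            raise InvalidInputError(
                f"values must be a 3-mode array, got ndim={self.values.ndim}"
            )
        if min(self.values.shape) == 0:
            raise InvalidInputError(
                f"degenerate tensor: shape {self.values.shape} has an empty mode"
            )
        self.neuron_ids = [str(s) for s in self.neuron_ids]
        self.condition_ids = [str(s) for s in self.condition_ids]
        n, c, t = self.values.shape
        if len(self.neuron_ids) != n or len(self.condition_ids) != c:
            raise InvalidInputError(
                "label lengths do not match array shape: "
                f"{len(self.neuron_ids)} neuron_ids, {len(self.condition_ids)} "
                f"condition_ids for shape {self.values.shape}"
            )
        if self.time_ms.shape != (t,):
            raise InvalidInputError(
                f"time_ms has length {self.time_ms.size}, expected {t}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("tensor values must be finite")
        if t > 1:
            steps = np.diff(self.time_ms)
            if np.any(steps <= 0):
                raise InvalidInputError("time_ms must be strictly increasing")
            if np.any(np.abs(steps - steps[0]) > 1e-9 * abs(steps[0])):
                raise InvalidInputError("time_ms must be uniformly spaced")
        if self.units_flag not in ("raw", "soft_normalized"):
            raise InvalidInputError(
                f"units_flag must be 'raw' or 'soft_normalized', got {self.units_flag!r}"
            )

    # -- conveniences -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def step_ms(self) -> float:
        if self.n_timepoints < 2:
            return float("nan")
        return float(self.time_ms[1] - self.time_ms[0])

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        time_ms: np.ndarray | None = None,
        **kwargs,
    ) -> "PopulationTensor":
        """Wrap a bare array, generating default labels and time axis."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise InvalidInputError("values must be a 3-mode array")
        n, c, t = values.shape
        if time_ms is None:
            time_ms = np.arange(t, dtype=float)
        return cls(
            values=values,
            neuron_ids=[f"n{i}" for i in range(n)],
            condition_ids=[f"c{i}" for i in range(c)],
            time_ms=np.asarray(time_ms, dtype=float),
            **kwargs,
        )

    def replace_values(self, values: np.ndarray, **updates) -> "PopulationTensor":
        """Copy of this tensor with new values (labels/axis unchanged)."""
        fields = dict(
            values=values,
            neuron_ids=list(self.neuron_ids),
            condition_ids=list(self.condition_ids),
            time_ms=self.time_ms.copy(),
            units_flag=self.units_flag,
            centered_flag=self.centered_flag,
            meta=dict(self.meta),
        )
        fields.update(updates)
        return PopulationTensor(**fields)

    def window(self, start: int, stop: int) -> "PopulationTensor":
        """Sub-tensor over time indices ``start..stop`` inclusive."""
        if not (0 <= start <= stop < self.n_timepoints):
            raise InvalidInputError(
                f"window [{start}, {stop}] out of range for T={self.n_timepoints}"
            )
        return self.replace_values(
            self.values[:, :, start : stop + 1],
            time_ms=self.time_ms[start : stop + 1].copy(),
        )


@dataclass
class UnfoldedMatrix:
    """A mode unfolding of a population tensor.

    ``column_order`` documents the column layout: ``"time-major"`` means
    column ``t*K + j`` holds time t and condition/neuron j (0-based).
    """

    values: np.ndarray
    mode: Mode
    source_shape: tuple[int, int, int]
    column_order: str = "time-major"


@dataclass
class BasisSet:
    """Top-k mode basis with the full singular spectrum.

    ``elements`` has shape (k, C, T) for basis-neurons or (k, N, T) for
    basis-conditions; elements are orthonormal under the Frobenius inner
    product but are defined only up to sign (and up to rotation within
    degenerate singular subspaces).  ``coefficients`` (rows × k) reproduce
    the rank-k SVD truncation: row r of the unfolding ≈
    ``coefficients[r] @ vec(elements)``.
    """

    mode: Mode
    k: int
    elements: np.ndarray
    singular_values: np.ndarray
    coefficients: np.ndarray


@dataclass
class ReconstructionResult:
    """Normalized squared error of a rank-k mode reconstruction.

    ``total_error`` is ‖X − X̂‖²_F / ‖X‖²_F ∈ [0, 1].  ``per_condition_errors``
    and ``per_neuron_errors`` use per-slice normalization by default (each
    slice's residual over that slice's sum of squares); see
    :func:`reconstruct_rank_k`.
    """

    mode: Mode
    k: int
    total_error: float
    per_condition_errors: np.ndarray
    per_neuron_errors: np.ndarray
    sem_across_conditions: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def unfold(tensor: PopulationTensor, mode: Mode) -> UnfoldedMatrix:
    """Unfold an N×C×T tensor into its mode-1 (neuron) or mode-2 (condition) matrix.

    Row n of the neuron-mode unfolding is neuron n's C×T slice flattened
    time-major; row c of the condition-mode unfolding is condition c's N×T
    slice flattened time-major.  The rearrangement preserves the total sum
    of squares.
    """
    _check_mode(mode)
    n, c, t = tensor.shape
    if mode == "neuron":
        # column t*C + c'  <-  values[n, c', t]
        mat = np.transpose(tensor.values, (0, 2, 1)).reshape(n, t * c)
    else:
        # column t*N + n'  <-  values[n', c, t]
        mat = np.transpose(tensor.values, (1, 2, 0)).reshape(c, t * n)
    return UnfoldedMatrix(values=mat, mode=mode, source_shape=(n, c, t))


def fold(matrix: np.ndarray, mode: Mode, source_shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the N×C×T array from an unfolding."""
    _check_mode(mode)
    n, c, t = source_shape
    if mode == "neuron":
        return np.transpose(matrix.reshape(n, t, c), (0, 2, 1))
    return np.transpose(matrix.reshape(c, t, n), (2, 0, 1))


def _svd(mat: np.ndarray):
    return scipy.linalg.svd(mat, full_matrices=False)


def _check_k(k: int, rows: int, cols: int) -> int:
    kmax = min(rows, cols)
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= kmax):
        raise InvalidInputError(
            f"k must be an integer in [1, {kmax}] for a {rows}×{cols} unfolding, got {k!r}"
        )
    return int(k)


def mode_basis(tensor: PopulationTensor, mode: Mode, k: int) -> BasisSet:
    """Top-k basis-neurons (C×T) or basis-conditions (N×T) of a tensor.

    The elements are the top-k right singular vectors of the mode's
    unfolding, reshaped; the full singular spectrum is retained.
    """
    unf = unfold(tensor, mode)
    rows, cols = unf.values.shape
    k = _check_k(k, rows, cols)
    u, s, vt = _svd(unf.values)
    n, c, t = tensor.shape
    slice_rows = c if mode == "neuron" else n
    # right singular vector of length t*slice_rows, index t*K + j -> (j, t)
    elements = vt[:k].reshape(k, t, slice_rows).transpose(0, 2, 1)
    coefficients = u[:, :k] * s[:k]
    return BasisSet(
        mode=mode,
        k=k,
        elements=elements,
        singular_values=s.copy(),
        coefficients=coefficients,
    )


def reconstruct_rank_k(
    tensor: PopulationTensor,
    mode: Mode,
    k: int,
    per_slice_norm: bool = True,
) -> ReconstructionResult:
    """Rank-k truncated-SVD reconstruction error along one mode.

    ``total_error = ‖X − X̂‖²_F / ‖X‖²_F`` where X̂ refolds the rank-k
    truncation of the mode's unfolding; by the Eckart–Young theorem this
    equals ``1 − Σ_{i≤k} s_i² / Σ_i s_i²``.

    Parameters
    ----------
    per_slice_norm
        If True (default), each condition's (neuron's) error is its squared
        residual divided by that slice's sum of squares; if False, slices
        are normalized by the global sum of squares divided by the slice
        count, so the per-slice errors average to ``total_error``.
    """
    unf = unfold(tensor, mode)
    rows, cols = unf.values.shape
    k = _check_k(k, rows, cols)
    total_ss = float(np.sum(unf.values**2))
    if total_ss == 0.0:
        raise DegenerateDataError(
            "all-zero tensor: normalized reconstruction error is undefined"
        )
    u, s, vt = _svd(unf.values)
    recon = (u[:, :k] * s[:k]) @ vt[:k]
    resid = fold(unf.values - recon, mode, tensor.shape)
    total_error = float(np.sum(resid**2) / total_ss)
    total_error = min(max(total_error, 0.0), 1.0)

    resid_cond = np.sum(resid**2, axis=(0, 2))  # length C
    resid_neuron = np.sum(resid**2, axis=(1, 2))  # length N
    ss_cond = np.sum(tensor.values**2, axis=(0, 2))
    ss_neuron = np.sum(tensor.values**2, axis=(1, 2))
    n, c, _ = tensor.shape
    if per_slice_norm:
        with np.errstate(invalid="ignore", divide="ignore"):
            per_condition = np.where(ss_cond > 0, resid_cond / np.maximum(ss_cond, 1e-300), 0.0)
            per_neuron = np.where(ss_neuron > 0, resid_neuron / np.maximum(ss_neuron, 1e-300), 0.0)
    else:
        per_condition = resid_cond / (total_ss / c)
        per_neuron = resid_neuron / (total_ss / n)
    sem = float(np.std(per_condition, ddof=1) / np.sqrt(c)) if c > 1 else 0.0
    return ReconstructionResult(
        mode=mode,
        k=k,
        total_error=total_error,
        per_condition_errors=per_condition,
        per_neuron_errors=per_neuron,
        sem_across_conditions=sem,
    )


def reconstruction_error_curve(tensor: PopulationTensor, mode: Mode) -> np.ndarray:
    """Normalized error ``1 − Σ_{i≤k} s_i²/Σ s_i²`` for every k ≥ 1.

    Cheap singular-value route to the full error-vs-k curve; entry ``j``
    is the error at ``k = j + 1``.
    """
    unf = unfold(tensor, mode)
    s = scipy.linalg.svdvals(unf.values)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise DegenerateDataError(
            "all-zero tensor: normalized reconstruction error is undefined"
        )
    err = 1.0 - np.cumsum(s**2) / total
    return np.clip(err, 0.0, 1.0)


def numerical_rank(matrix: np.ndarray, rel_tol: float = 1e-8) -> int:
    """Count of singular values above ``rel_tol`` times the largest.

    Measured unfoldings of noisy data are always full rank in the exact
    sense; a thresholded rank is the usable surrogate.  A zero matrix has
    rank 0.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise InvalidInputError("matrix must be finite")
    if rel_tol <= 0:
        raise InvalidInputError(f"rel_tol must be positive, got {rel_tol}")
    if matrix.size == 0:
        return 0
    s = scipy.linalg.svdvals(matrix)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > rel_tol * s[0]))
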
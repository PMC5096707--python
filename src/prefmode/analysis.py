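"""The preferred-mode procedure: k-selection, sweeps, and the verdict.

Workflow on a preprocessed N×C×T tensor (typically with N = C):

1. :func:`select_k` — at the single central timepoint (where row rank equals
   column rank, so neither mode is preferred) find the smallest k whose
   rank-k reconstruction error is within a threshold (default 5%).
2. :func:`timespan_sweep` — with k fixed, reconstruct both modes on
   symmetrically expanding time windows around the central timepoint, up to
   the full tensor, tracking per-condition errors for uncertainty.
3. :func:`basis_count_sweep` — at the full timespan, the difference
   (condition-mode error − neuron-mode error) as a function of k; positive
   values indicate neuron-preferred structure.
4. :func:`preferred_mode_verdict` — a paired two-sided test across
   conditions on the full-timespan error difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .exceptions import DegenerateDataError, InvalidInputError
from .tensor import (
    Mode,
    PopulationTensor,
    reconstruct_rank_k,
    reconstruction_error_curve,
)

logger = logging.getLogger(__name__)

#: Mean error differences below this are treated as exact ties: the verdict
#: is "none" regardless of the test's p-value.
TIE_TOLERANCE = 1e-12


@dataclass
class SweepResult:
    """Reconstruction-error curves versus timespan for both modes.

    ``timespans[i]`` is the window length T_i (in timepoints);
    ``window_bounds[i]`` the inclusive (start, stop) time indices.
    ``neuron_per_condition`` and ``condition_per_condition`` are
    (n_timespans × C) matrices of per-condition errors, from which the
    standard errors across conditions (``neuron_sem``, ``condition_sem``)
    are derived.
    """

    k: int
    timespans: np.ndarray
    neuron_errors: np.ndarray
    condition_errors: np.ndarray
    neuron_sem: np.ndarray
    condition_sem: np.ndarray
    window_bounds: list[tuple[int, int]]
    neuron_per_condition: np.ndarray
    condition_per_condition: np.ndarray
    step_ms: float = float("nan")

    @property
    def timespans_ms(self) -> np.ndarray:
        return self.timespans * self.step_ms


@dataclass
class DiffCurve:
    """Fig-7-style normalized error difference versus basis count.

    ``diffs[i]`` = (condition-mode error − neuron-mode error) at full
    timespan for ``k = k_values[i]``, divided by ``normalizer`` (the smaller
    of the two full-timespan errors at the reference k).  Positive values
    indicate neuron-preferred structure.
    """

    k_values: np.ndarray
    diffs: np.ndarray
    normalizer: float
    reference_k: int


@dataclass
class Verdict:
    """Outcome of the paired preferred-mode test.

    ``effect`` is the signed relative error difference at full timespan,
    (condition error − neuron error) / min(both); positive means the neuron
    mode is preferred.
    """

    preferred: str  # "neuron" | "condition" | "none"
    p_value: float
    effect: float
    alpha: float = 0.05
    test: str = "wilcoxon"
    n_conditions: int = 0
    mean_difference: float = float("nan")


def central_index(n_timepoints: int) -> int:
    """0-based index of the central timepoint, round(T/2) with half-up
    rounding on 1-based indexing (T=91 → 1-based 46)."""
    if n_timepoints < 1:
        raise InvalidInputError("need at least one timepoint")
    return int(np.floor(n_timepoints / 2 + 0.5)) - 1


def select_k(tensor: PopulationTensor, threshold: float = 0.05) -> int:
    """Smallest k reconstructing the central N×C slice to within ``threshold``.

    Because the central slice is a matrix, the value is identical for both
    modes (row rank equals column rank).  The comparison is
    ``error ≤ threshold`` (within float tolerance): with equal singular
    values the residual hits the threshold exactly and that k is accepted.
    """
    if not (0.0 < threshold < 1.0):
        raise InvalidInputError(f"threshold must lie in (0, 1), got {threshold}")
    t_half = central_index(tensor.n_timepoints)
    central = tensor.window(t_half, t_half)
    if not np.any(central.values):
        raise DegenerateDataError("central time slice is all zero; cannot select k")
    err = reconstruction_error_curve(central, "neuron")
    ok = np.nonzero(err <= threshold + 1e-12)[0]
    return int(ok[0]) + 1


def _expanding_windows(n_timepoints: int) -> list[tuple[int, int]]:
    """Inclusive (start, stop) windows growing symmetrically from the
    central index, clamped at the boundaries, ending with the full range."""
    lo = hi = central_index(n_timepoints)
    bounds = [(lo, hi)]
    while lo > 0 or hi < n_timepoints - 1:
        lo = max(lo - 1, 0)
        hi = min(hi + 1, n_timepoints - 1)
        bounds.append((lo, hi))
    return bounds


def timespan_sweep(
    tensor: PopulationTensor,
    k: int,
    per_slice_norm: bool = True,
) -> SweepResult:
    """Both modes' reconstruction errors on expanding time windows.

    Windows expand one step per side per iteration around the central
    timepoint (lengths 1, 3, 5, … for odd T), clamped at the array
    boundaries, until the full tensor is covered.  The same k is used for
    both modes at every window.  Per-condition errors supply the standard
    errors across conditions.
    """
    n, c, t = tensor.shape
    if not (1 <= k <= min(n, c)):
        raise InvalidInputError(f"k must lie in [1, {min(n, c)}], got {k}")
    bounds = _expanding_windows(t)
    n_win = len(bounds)
    neuron_err = np.empty(n_win)
    condition_err = np.empty(n_win)
    neuron_sem = np.empty(n_win)
    condition_sem = np.empty(n_win)
    neuron_pc = np.empty((n_win, c))
    condition_pc = np.empty((n_win, c))
    for i, (lo, hi) in enumerate(bounds):
        sub = tensor.window(lo, hi)
        rn = reconstruct_rank_k(sub, "neuron", k, per_slice_norm=per_slice_norm)
        rc = reconstruct_rank_k(sub, "condition", k, per_slice_norm=per_slice_norm)
        neuron_err[i] = rn.total_error
        condition_err[i] = rc.total_error
        neuron_sem[i] = rn.sem_across_conditions
        condition_sem[i] = rc.sem_across_conditions
        neuron_pc[i] = rn.per_condition_errors
        condition_pc[i] = rc.per_condition_errors
    return SweepResult(
        k=k,
        timespans=np.array([hi - lo + 1 for lo, hi in bounds]),
        neuron_errors=neuron_err,
        condition_errors=condition_err,
        neuron_sem=neuron_sem,
        condition_sem=condition_sem,
        window_bounds=bounds,
        neuron_per_condition=neuron_pc,
        condition_per_condition=condition_pc,
        step_ms=tensor.step_ms,
    )


def basis_count_sweep(
    tensor: PopulationTensor,
    k_max: int | None = None,
    reference_k: int | None = None,
    threshold: float = 0.05,
) -> DiffCurve:
    """Normalized (condition − neuron) error difference versus basis count.

    The full-timespan tensor is reconstructed at every k in 1..k_max for
    both modes.  Differences are normalized by the smaller of the two
    full-timespan errors at ``reference_k`` (default: :func:`select_k`'s
    choice).  The difference is necessarily zero at k = N = C.
    """
    n, c, _ = tensor.shape
    limit = min(n, c)
    if k_max is None:
        k_max = min(20, limit)
    if k_max < 1:
        raise InvalidInputError(f"k_max must be positive, got {k_max}")
    if k_max > limit:
        logger.warning("k_max=%d exceeds min(N, C)=%d; clamping", k_max, limit)
        warnings.warn(f"k_max={k_max} exceeds min(N, C)={limit}; clamping", stacklevel=2)
        k_max = limit
    if reference_k is None:
        reference_k = select_k(tensor, threshold=threshold)
    if not (1 <= reference_k <= limit):
        raise InvalidInputError(
            f"reference_k must lie in [1, {limit}], got {reference_k}"
        )
    err_n = reconstruction_error_curve(tensor, "neuron")
    err_c = reconstruction_error_curve(tensor, "condition")
    # error at k beyond the spectrum length is 0 (full-rank reconstruction)
    def _at(curve: np.ndarray, k: int) -> float:
        return float(curve[k - 1]) if k <= curve.size else 0.0

    normalizer = min(_at(err_n, reference_k), _at(err_c, reference_k))
    if normalizer <= 0.0:
        raise DegenerateDataError(
            "reference reconstruction error is zero; the normalized difference "
            "curve is undefined (data are exactly low-rank at the reference k)"
        )
    k_values = np.arange(1, k_max + 1)
    diffs = np.array([(_at(err_c, k) - _at(err_n, k)) / normalizer for k in k_values])
    return DiffCurve(
        k_values=k_values,
        diffs=diffs,
        normalizer=normalizer,
        reference_k=int(reference_k),
    )


def _paired_verdict(
    neuron_pc: np.ndarray,
    condition_pc: np.ndarray,
    neuron_total: float,
    condition_total: float,
    alpha: float,
    test: str,
) -> Verdict:
    c = neuron_pc.size
    if c < 5:
        raise InvalidInputError(
            f"preferred-mode test needs at least 5 conditions, got {c}"
        )
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    d = condition_pc - neuron_pc
    mean_d = float(np.mean(d))
    denom = min(neuron_total, condition_total)
    effect = (condition_total - neuron_total) / denom if denom > 0 else 0.0
    if abs(mean_d) < TIE_TOLERANCE:
        return Verdict(
            preferred="none",
            p_value=1.0,
            effect=float(effect),
            alpha=alpha,
            test=test,
            n_conditions=c,
            mean_difference=mean_d,
        )
    if test == "wilcoxon":
        stat = scipy.stats.wilcoxon(d, alternative="two-sided")
        p = float(stat.pvalue)
    elif test == "ttest":
        stat = scipy.stats.ttest_1samp(d, 0.0)
        p = float(stat.pvalue)
    else:
        raise InvalidInputError(f"unknown test {test!r}; use 'wilcoxon' or 'ttest'")
    if p < alpha:
        preferred = "neuron" if mean_d > 0 else "condition"
    else:
        preferred = "none"
    return Verdict(
        preferred=preferred,
        p_value=p,
        effect=float(effect),
        alpha=alpha,
        test=test,
        n_conditions=c,
        mean_difference=mean_d,
    )


def preferred_mode_verdict(
    sweep: SweepResult,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> Verdict:
    """Paired two-sided test across conditions at the full timespan.

    The per-condition error difference (condition-mode − neuron-mode) at
    the longest window determines the label: significantly positive →
    neuron-preferred, significantly negative → condition-preferred,
    otherwise (or on an exact tie) → none.
    """
    neuron_pc = sweep.neuron_per_condition[-1]
    condition_pc = sweep.condition_per_condition[-1]
    return _paired_verdict(
        neuron_pc,
        condition_pc,
        float(sweep.neuron_errors[-1]),
        float(sweep.condition_errors[-1]),
        alpha,
        test,
    )


def mode_preference(
    tensor: PopulationTensor,
    k: int,
    alpha: float = 0.05,
    test: str = "wilcoxon",
    per_slice_norm: bool = True,
) -> Verdict:
    """Full-timespan verdict without the expanding-window sweep.

    Equivalent to the final entry of :func:`timespan_sweep` followed by
    :func:`preferred_mode_verdict`; useful when only the verdict is needed
    (e.g. null-calibration replicates).
    """
    rn = reconstruct_rank_k(tensor, "neuron", k, per_slice_norm=per_slice_norm)
    rc = reconstruct_rank_k(tensor, "condition", k, per_slice_norm=per_slice_norm)
    return _paired_verdict(
        rn.per_condition_errors,
        rc.per_condition_errors,
        rn.total_error,
        rc.total_error,
        alpha,
        test,
    )
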
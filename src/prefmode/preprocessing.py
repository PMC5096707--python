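"""Spike trains to analysis-ready population tensors.

Pipeline (the order is enforced and recorded): per-trial Gaussian smoothing
of spike trains into firing rates, trial averaging, neuron/condition count
equalization, soft normalization, and cross-condition mean removal.

Soft normalization divides each neuron's response by (constant + its
firing-rate range over all conditions and times), with default constant 5
spikes/s: a neuron with a 100 spikes/s range maps to a range near 1, a
neuron with a 5 spikes/s range maps to 0.5.  This keeps squared-error
analyses from being dominated by high-rate neurons without exploding
sampling noise in low-rate neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, InvalidInputError
from .tensor import PopulationTensor


@dataclass
class SpikePopulation:
    """Trial-resolved spike-event times.

    ``spike_times[n][c][r]`` is an array of event times in ms for neuron n,
    condition c, trial r; all events must lie within ``recording_window``
    (start_ms, end_ms).  Trial counts may differ across (neuron, condition)
    pairs but every analyzed pair needs at least one trial.
    """

    spike_times: list[list[list[np.ndarray]]]
    neuron_ids: list[str]
    condition_ids: list[str]
    recording_window: tuple[float, float]

    def __post_init__(self) -> None:
        start, end = self.recording_window
        if not end > start:
            raise InvalidInputError(
                f"empty recording window ({start}, {end})"
            )
        if len(self.spike_times) != len(self.neuron_ids):
            raise InvalidInputError("spike_times outer length must match neuron_ids")
        for n, per_neuron in enumerate(self.spike_times):
            if len(per_neuron) != len(self.condition_ids):
                raise InvalidInputError(
                    f"neuron {n} has {len(per_neuron)} condition entries, "
                    f"expected {len(self.condition_ids)}"
                )
            for c, trials in enumerate(per_neuron):
                if len(trials) < 1:
                    raise InvalidInputError(
                        f"(neuron {n}, condition {c}) has no trials"
                    )
                for r, ev in enumerate(trials):
                    ev = np.asarray(ev, dtype=float)
                    self.spike_times[n][c][r] = ev
                    if ev.size and (ev.min() < start or ev.max() > end):
                        raise InvalidInputError(
                            f"spike outside recording window in (neuron {n}, "
                            f"condition {c}, trial {r})"
                        )

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def trial_counts(self) -> np.ndarray:
        return np.array(
            [[len(trials) for trials in per_neuron] for per_neuron in self.spike_times]
        )


@dataclass
class PreprocessConfig:
    """Preprocessing constants.

    ``kernel_sd_ms``: Gaussian smoothing kernel standard deviation (20 ms
    default); ``step_ms``: output sampling period (10 ms default);
    ``soft_norm_constant``: the additive constant of soft normalization
    (5 spikes/s default); ``remove_mean`` / ``equalize`` toggle the
    cross-condition mean subtraction and the N=C down-selection.
    """

    kernel_sd_ms: float = 20.0
    step_ms: float = 10.0
    soft_norm_constant: float = 5.0
    remove_mean: bool = True
    equalize: bool = True

    def __post_init__(self) -> None:
        if self.kernel_sd_ms <= 0:
            raise InvalidInputError("kernel_sd_ms must be positive")
        if self.step_ms <= 0:
            raise InvalidInputError("step_ms must be positive")
        if self.soft_norm_constant < 0:
            raise InvalidInputError("soft_norm_constant must be nonnegative")


_BIN_MS = 1.0  # spike binning resolution before convolution


def _smoothing_kernel(sd_ms: float) -> np.ndarray:
    """Gaussian kernel on the 1 ms grid, truncated at ±4 sd, unit mass."""
    half = max(int(np.ceil(4.0 * sd_ms / _BIN_MS)), 1)
    x = np.arange(-half, half + 1) * _BIN_MS
    k = np.exp(-0.5 * (x / sd_ms) ** 2)
    return k / k.sum()


def rates_from_spikes(
    spikes: SpikePopulation, config: PreprocessConfig | None = None
) -> PopulationTensor:
    """Smoothed, trial-averaged firing rates on a uniform grid.

    Spikes are binned at 1 ms, convolved with a Gaussian kernel (truncated
    at ±4 sd; near the window edges the kernel is renormalized by its
    in-window mass so rates are not biased downward), converted to
    spikes/s, averaged across trials, and sampled every ``step_ms`` by
    linear interpolation between bin centers.
    """
    config = config or PreprocessConfig()
    start, end = spikes.recording_window
    n_bins = int(np.round((end - start) / _BIN_MS))
    if n_bins < 1:
        raise InvalidInputError("recording window shorter than the 1 ms bin")
    edges = start + np.arange(n_bins + 1) * _BIN_MS
    centers = edges[:-1] + _BIN_MS / 2.0
    kernel = _smoothing_kernel(config.kernel_sd_ms)
    # in-window kernel mass at each bin, for edge renormalization
    mass = np.convolve(np.ones(n_bins), kernel, mode="same")

    sample_times = start + np.arange(int(np.floor((end - start) / config.step_ms)) + 1) * config.step_ms
    out = np.empty((spikes.n_neurons, spikes.n_conditions, sample_times.size))
    for i in range(spikes.n_neurons):
        for j in range(spikes.n_conditions):
            trials = spikes.spike_times[i][j]
            counts = np.zeros(n_bins)
            for ev in trials:
                counts += np.histogram(ev, bins=edges)[0]
            counts /= len(trials)
            smoothed = np.convolve(counts, kernel, mode="same") / mass
            rate = smoothed / (_BIN_MS / 1000.0)  # spikes/s
            out[i, j] = np.interp(sample_times, centers, rate)
    return PopulationTensor(
        values=out,
        neuron_ids=list(spikes.neuron_ids),
        condition_ids=list(spikes.condition_ids),
        time_ms=sample_times,
        units_flag="raw",
        meta={"kernel_sd_ms": config.kernel_sd_ms, "step_ms": config.step_ms},
    )


def soft_normalize(tensor: PopulationTensor, constant: float = 5.0) -> PopulationTensor:
    """Divide each neuron by (constant + its range over conditions and times).

    The range is max − min of the neuron's firing rate across all
    conditions and times; a constant-rate neuron (range 0) is divided by
    the constant alone.  Output ranges are strictly below 1 for a positive
    constant.
    """
    if constant < 0:
        raise InvalidInputError("soft-normalization constant must be nonnegative")
    if tensor.units_flag != "raw":
        raise InvalidInputError(
            f"soft_normalize expects raw rates, got units_flag={tensor.units_flag!r}"
        )
    ranges = tensor.values.max(axis=(1, 2)) - tensor.values.min(axis=(1, 2))
    denom = constant + ranges
    if np.any(denom == 0):
        raise DegenerateDataError(
            "zero normalization denominator (constant 0 and a constant-rate neuron)"
        )
    out = tensor.replace_values(
        tensor.values / denom[:, None, None], units_flag="soft_normalized"
    )
    out.meta["soft_norm_constant"] = constant
    return out


def remove_cross_condition_mean(tensor: PopulationTensor) -> PopulationTensor:
    """Subtract the condition-averaged N×T response from every condition.

    Removes structure identical across conditions (e.g. a stimulus-locked
    rate elevation shared by all conditions); idempotent.  Requires C ≥ 2.
    """
    if tensor.n_conditions < 2:
        raise InvalidInputError("cross-condition mean removal requires C >= 2")
    mean = tensor.values.mean(axis=1, keepdims=True)
    return tensor.replace_values(tensor.values - mean, centered_flag=True)


def snr_scores(
    tensor: PopulationTensor, noise_estimates: np.ndarray | None = None
) -> np.ndarray:
    """Per-neuron signal-to-noise score used for neuron down-selection.

    With ``noise_estimates`` (per-neuron noise variances of the
    trial-averaged rate): variance of the neuron's response over conditions
    and times divided by its noise estimate.  Without them, falls back to
    the response range (max − min), a monotone proxy when noise is
    comparable across neurons.
    """
    if noise_estimates is not None:
        noise = np.asarray(noise_estimates, dtype=float)
        if noise.shape != (tensor.n_neurons,) or np.any(noise < 0):
            raise InvalidInputError(
                "noise_estimates must be a nonnegative vector of length N"
            )
        signal = tensor.values.var(axis=(1, 2))
        with np.errstate(divide="ignore"):
            return np.where(noise > 0, signal / np.maximum(noise, 1e-300), np.inf)
    return tensor.values.max(axis=(1, 2)) - tensor.values.min(axis=(1, 2))


def equalize_counts(
    tensor: PopulationTensor, noise_estimates: np.ndarray | None = None
) -> PopulationTensor:
    """Down-select neurons or conditions so that N = C.

    When N > C, keeps the C neurons with the highest signal-to-noise score
    (:func:`snr_scores`); when C > N, keeps the N conditions with the
    largest response standard deviation across neurons and times.  Ties
    break by original index (stable sort).  Kept labels are recorded in
    ``meta``; an already-square tensor passes through unchanged.
    """
    n, c, _ = tensor.shape
    if n == c:
        return tensor
    if n > c:
        scores = snr_scores(tensor, noise_estimates)
        order = np.argsort(-scores, kind="stable")
        keep = np.sort(order[:c])
        out = PopulationTensor(
            values=tensor.values[keep].copy(),
            neuron_ids=[tensor.neuron_ids[i] for i in keep],
            condition_ids=list(tensor.condition_ids),
            time_ms=tensor.time_ms.copy(),
            units_flag=tensor.units_flag,
            centered_flag=tensor.centered_flag,
            meta=dict(tensor.meta),
        )
        out.meta["equalize_kept_neurons"] = out.neuron_ids
        return out
    scores = tensor.values.std(axis=(0, 2))
    order = np.argsort(-scores, kind="stable")
    keep = np.sort(order[:n])
    out = PopulationTensor(
        values=tensor.values[:, keep, :].copy(),
        neuron_ids=list(tensor.neuron_ids),
        condition_ids=[tensor.condition_ids[i] for i in keep],
        time_ms=tensor.time_ms.copy(),
        units_flag=tensor.units_flag,
        centered_flag=tensor.centered_flag,
        meta=dict(tensor.meta),
    )
    out.meta["equalize_kept_conditions"] = out.condition_ids
    return out


def preprocess(
    tensor: PopulationTensor, config: PreprocessConfig | None = None
) -> PopulationTensor:
    """Standard pipeline on a raw rate tensor.

    Order: equalize counts → soft normalization → cross-condition mean
    removal (normalization must precede mean removal; swapping would
    change the result).  Steps are toggled by the config.
    """
    config = config or PreprocessConfig()
    out = tensor
    if config.equalize:
        out = equalize_counts(out)
    if out.units_flag == "raw":
        out = soft_normalize(out, config.soft_norm_constant)
    if config.remove_mean and not out.centered_flag:
        out = remove_cross_condition_mean(out)
    return out


def filter_width_sweep(
    spikes: SpikePopulation,
    widths_ms: tuple[float, ...] = (10.0, 20.0, 100.0),
    k: int | str = "auto",
    threshold: float = 0.05,
    alpha: float = 0.05,
    config: PreprocessConfig | None = None,
):
    """Preferred-mode verdict as a function of smoothing kernel width.

    For each width, runs the full pipeline (rates → equalize → normalize →
    center), chooses k (``"auto"`` = threshold rule at the central
    timepoint, or a fixed integer), and computes the full-timespan verdict.
    Returns a list of (width_ms, Verdict).  The verdict should not depend
    on the filter width: the preferred mode reflects structure across
    neurons versus conditions, not temporal frequency content.
    """
    from .analysis import mode_preference, select_k  # local import, avoids cycle

    base = config or PreprocessConfig()
    results = []
    for w in widths_ms:
        if w <= 0:
            raise InvalidInputError(f"filter width must be positive, got {w}")
        cfg = PreprocessConfig(
            kernel_sd_ms=w,
            step_ms=base.step_ms,
            soft_norm_constant=base.soft_norm_constant,
            remove_mean=base.remove_mean,
            equalize=base.equalize,
        )
        tensor = preprocess(rates_from_spikes(spikes, cfg), cfg)
        k_used = select_k(tensor, threshold) if k == "auto" else int(k)
        verdict = mode_preference(tensor, k_used, alpha=alpha)
        results.append((w, verdict))
    return results
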
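"""Synthetic population tensors with known ground truth.

The generator is the discrete-time linear system

    x(t+1, c) = a·A x(t, c) + b·B u(t+1, c)

with orthogonal dynamics A (eigenvalues on the unit circle, rotation angles
clustered near 0 so trajectories are smooth), B with orthonormal columns,
M-dimensional inputs u built from randomly weighted sinusoids that are
unconstrained across conditions, and initial states spanning a proper
subspace of state space.  The strengths a, b interpolate between a pure
tuning model (a=0: x(t) = b·B u(t) at every time; responses are a static
readout of external variables) and a pure autonomous dynamical system
(b=0: x(t) = A^{t-1} x(1)).  Four presets mirror the canonical settings
(a, b) ∈ {(0, 1), (0.98, 0.05), (0.99, 0.03), (1, 0)}.

Also here: diagonal partial observation y = C_obs x, the control
manipulation that collapses one mode's basis to a few summed groups,
condition subsampling with a diversity heuristic, and an inhomogeneous
Poisson spike generator for end-to-end preprocessing tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DegenerateDataError, InvalidInputError
from .preprocessing import SpikePopulation
from .tensor import Mode, PopulationTensor, fold, mode_basis, unfold, _check_mode

#: Default maximum rotation angle per step: at most 6 (mean ~3) oscillation
#: cycles over the default T=300 steps, comparable to cortical data.
DEFAULT_MAX_ROTATION = 2.0 * np.pi * 6.0 / 300.0

#: The four canonical (a, b) strength settings: pure tuning, input-dominated,
#: dynamics-dominated, pure dynamics.
PRESETS: dict[str, tuple[float, float]] = {
    "fig8a": (0.0, 1.0),
    "fig8b": (0.98, 0.05),
    "fig8c": (0.99, 0.03),
    "fig8d": (1.0, 0.0),
}


@dataclass
class LDSConfig:
    """Full parameterization of the linear-system simulator.

    ``a`` and ``b`` are the dynamics and input strengths in [0, 1];
    ``n_inputs`` (M) the input dimensionality; ``init_state_rank`` the
    dimension of the subspace spanned by the per-condition initial states;
    ``max_rotation_angle`` bounds the rotation angle per step of the
    orthogonal dynamics matrix (radians).  All randomness flows from
    ``seed`` through a fixed splitting scheme (one child stream each for A,
    B, inputs, initial states, in that order).

    Scale convention: input channels are normalized to unit temporal RMS
    per condition, and initial-state columns to ``init_state_scale`` RMS
    per neuron (column norm ``init_state_scale·√N``).  The source method
    states neither scale; this convention balances the two structure
    sources so the canonical mixed presets land on opposite sides of the
    tuning/dynamics boundary under the default preset seed.
    """

    n_neurons: int = 20
    n_conditions: int = 20
    n_timepoints: int = 300
    n_inputs: int = 10
    a: float = 1.0
    b: float = 0.0
    max_rotation_angle: float = DEFAULT_MAX_ROTATION
    n_sinusoids: int = 20
    init_state_rank: int = 10
    seed: int = 0
    time_varying: bool = False
    step_ms: float = 10.0
    init_state_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_neurons, self.n_conditions, self.n_timepoints) < 1:
            raise InvalidInputError("tensor dimensions must be positive")
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.b <= 1.0):
            raise InvalidInputError("strengths a, b must lie in [0, 1]")
        if self.a == 0.0 and self.b == 0.0:
            raise DegenerateDataError("a=0 and b=0 would produce an all-zero tensor")
        if self.n_inputs > self.n_neurons:
            raise InvalidInputError("n_inputs (M) must not exceed n_neurons (N)")
        if self.init_state_rank > self.n_neurons:
            raise InvalidInputError("init_state_rank must not exceed n_neurons")
        if self.max_rotation_angle <= 0:
            raise InvalidInputError("max_rotation_angle must be positive")
        if self.n_sinusoids < 1:
            raise InvalidInputError("n_sinusoids must be at least 1")
        # low-rank preconditions under which the mode preference is identified
        if self.a == 0.0:
            if not (self.n_neurons > self.n_inputs and self.n_conditions > self.n_inputs):
                raise InvalidInputError(
                    "pure tuning run requires N > M and C > M "
                    f"(got N={self.n_neurons}, C={self.n_conditions}, M={self.n_inputs})"
                )
        if self.b == 0.0 and self.init_state_rank >= self.n_neurons:
            raise InvalidInputError(
                "pure dynamics run requires initial states spanning a proper "
                f"subspace: init_state_rank={self.init_state_rank} must be < "
                f"N={self.n_neurons}"
            )

    @property
    def generator_class(self) -> str:
        if self.a == 0.0:
            return "tuning"
        if self.b == 0.0:
            return "dynamics"
        return "mixed"


@dataclass
class ObservationConfig:
    """Diagonal 0/1 observation y = C_obs x keeping the first
    ``observed_dims`` state coordinates."""

    observed_dims: int

    def matrix(self, n: int) -> np.ndarray:
        if not (1 <= self.observed_dims <= n):
            raise InvalidInputError(
                f"observed_dims must lie in [1, {n}], got {self.observed_dims}"
            )
        return np.diag((np.arange(n) < self.observed_dims).astype(float))


@dataclass
class GroundTruth:
    """Generator internals for a simulated tensor."""

    A: np.ndarray | None
    B: np.ndarray
    inputs: np.ndarray  # (M, C, T)
    initial_states: np.ndarray  # (N, C)
    observation_matrix: np.ndarray | None
    generator_class: str
    config: LDSConfig | None = None
    A_sequence: list[np.ndarray] | None = None  # for time-varying dynamics


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def _draw_angles(n: int, max_angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation angles / angular frequencies, uniform on (0, max_angle]."""
    return max_angle * (1.0 - rng.random(n))


def make_dynamics_matrix(
    n: int,
    max_rotation_angle: float = DEFAULT_MAX_ROTATION,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random orthogonal dynamics matrix with eigenvalues clustered near 1.

    Block-diagonal 2×2 rotations with angles drawn uniformly on
    (0, max_rotation_angle], conjugated by a random orthogonal matrix; odd
    n gets one unit eigenvalue.  All eigenvalues lie on the unit circle, so
    trajectories neither decay nor blow up.
    """
    if max_rotation_angle <= 0:
        raise InvalidInputError("max_rotation_angle must be positive")
    if n < 1:
        raise InvalidInputError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = _draw_angles(n // 2, max_rotation_angle, rng)
    blocks = np.zeros((n, n))
    for i, th in enumerate(angles):
        c, s = np.cos(th), np.sin(th)
        blocks[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = [[c, -s], [s, c]]
    if n % 2:
        blocks[-1, -1] = 1.0
    q = _random_orthogonal(n, rng)
    return q @ blocks @ q.T


def make_inputs(
    n_inputs: int,
    n_conditions: int,
    n_timepoints: int,
    n_sinusoids: int = 20,
    max_rotation_angle: float = DEFAULT_MAX_ROTATION,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Inputs U (M×C×T): each channel a randomly weighted sum of sinusoids.

    Angular frequencies are drawn by the same sampler as the dynamics
    matrix's rotation angles (so inputs and dynamics share frequency
    content); frequencies and phases are per (channel, sinusoid) and the
    weights are drawn independently per condition, leaving the inputs
    unconstrained across conditions.
    """
    if n_sinusoids < 1:
        raise InvalidInputError("n_sinusoids must be at least 1")
    if min(n_inputs, n_conditions, n_timepoints) < 1:
        raise InvalidInputError("input dimensions must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = _draw_angles(n_inputs * n_sinusoids, max_rotation_angle, rng).reshape(
        n_inputs, n_sinusoids
    )
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_inputs, n_sinusoids))
    weights = rng.standard_normal((n_inputs, n_conditions, n_sinusoids)) / np.sqrt(
        n_sinusoids
    )
    t = np.arange(n_timepoints)
    # (M, J, T) sinusoid bank shared across conditions
    bank = np.sin(freqs[:, :, None] * t[None, None, :] + phases[:, :, None])
    return np.einsum("mcj,mjt->mct", weights, bank)


def simulate_lds(config: LDSConfig) -> tuple[PopulationTensor, GroundTruth]:
    """Simulate the linear system and return the rate tensor and ground truth.

    For ``a == 0`` the system is the static tuning model: x(t) = b·B u(t)
    at every time (initial states are not part of the data).  Otherwise the
    recursion starts from the rank-constrained initial states, with the
    input applied at the target step, so ``b == 0`` gives
    x(t) = A^{t-1} x(1) exactly.  ``time_varying`` draws a fresh A(t) per
    step (shared across conditions).
    """
    n, c, t, m = (
        config.n_neurons,
        config.n_conditions,
        config.n_timepoints,
        config.n_inputs,
    )
    rng_a, rng_b, rng_u, rng_x0 = _child_rngs(config.seed, 4)

    a_seq: list[np.ndarray] | None = None
    if config.time_varying:
        a_seq = [
            make_dynamics_matrix(n, config.max_rotation_angle, rng_a)
            for _ in range(t - 1)
        ]
        a_mat = None
    else:
        a_mat = make_dynamics_matrix(n, config.max_rotation_angle, rng_a)

    b_mat = _random_orthogonal(n, rng_b)[:, :m]  # orthonormal columns
    u = make_inputs(
        m, c, t, config.n_sinusoids, config.max_rotation_angle, rng_u
    )
    # unit temporal RMS per (channel, condition)
    rms = np.sqrt((u**2).mean(axis=2, keepdims=True))
    u = u / np.maximum(rms, 1e-12)

    # initial states: Gaussian, projected onto a random init_state_rank-dim
    # subspace, columns scaled to init_state_scale RMS per neuron
    r = config.init_state_rank
    p = _random_orthogonal(n, rng_x0)[:, :r]
    z = rng_x0.standard_normal((r, c))
    x0 = p @ z
    norms = np.linalg.norm(x0, axis=0)
    norms[norms == 0] = 1.0
    x0 = x0 * (config.init_state_scale * np.sqrt(n) / norms)

    x = np.empty((n, c, t))
    if config.a == 0.0:
        x = config.b * np.einsum("nm,mct->nct", b_mat, u)
        x0 = x[:, :, 0].copy()
    else:
        x[:, :, 0] = x0
        for step in range(1, t):
            a_now = a_seq[step - 1] if config.time_varying else a_mat
            x[:, :, step] = (
                config.a * (a_now @ x[:, :, step - 1])
                + config.b * (b_mat @ u[:, :, step])
            )
    if not np.any(x):
        raise DegenerateDataError("simulation produced an all-zero tensor")

    tensor = PopulationTensor.from_values(
        x,
        time_ms=np.arange(t) * config.step_ms,
        meta={
            "generator_class": config.generator_class,
            "seed": config.seed,
            "a": config.a,
            "b": config.b,
        },
    )
    truth = GroundTruth(
        A=a_mat,
        B=b_mat,
        inputs=u,
        initial_states=x0,
        observation_matrix=None,
        generator_class=config.generator_class,
        config=config,
        A_sequence=a_seq,
    )
    return tensor, truth


def preset_config(name: str, seed: int = 0, **overrides) -> LDSConfig:
    """Config for one of the canonical presets (``fig8a`` … ``fig8d``)."""
    if name not in PRESETS:
        raise InvalidInputError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    a, b = PRESETS[name]
    return LDSConfig(a=a, b=b, seed=seed, **overrides)


def apply_observation(
    tensor: PopulationTensor, obs: ObservationConfig | int
) -> PopulationTensor:
    """Partial observation y = C_obs x: zero all but the first
    ``observed_dims`` neuron coordinates.  ``observed_dims = N`` is the
    identity."""
    if isinstance(obs, int):
        obs = ObservationConfig(observed_dims=obs)
    c_obs = obs.matrix(tensor.n_neurons)
    y = np.einsum("ij,jct->ict", c_obs, tensor.values)
    out = tensor.replace_values(y)
    out.meta["observed_dims"] = obs.observed_dims
    out.meta["generator_class"] = "observed_" + str(
        tensor.meta.get("generator_class", "unknown")
    )
    return out


def make_control_dataset(
    tensor: PopulationTensor,
    collapse_mode: Mode,
    n_keep_basis: int,
    n_groups: int,
    seed: int = 0,
) -> PopulationTensor:
    """Collapse one mode's basis into a few summed groups and refit.

    Extracts the top ``n_keep_basis`` basis elements along
    ``collapse_mode``, randomly partitions them into ``n_groups`` groups of
    equal size, sums the elements within each group, and least-squares
    refits every slice of the tensor onto the collapsed basis (equivalently:
    projects the rows of the collapse-mode unfolding onto the span of the
    collapsed elements).  The output keeps surface-level features of the
    original data but has rank ≤ n_groups along the collapsed mode, which
    flips the preferred mode of a dataset preferred along the other mode.
    """
    _check_mode(collapse_mode)
    if n_groups < 1 or n_keep_basis % n_groups != 0:
        raise InvalidInputError(
            f"n_keep_basis={n_keep_basis} must be a positive multiple of "
            f"n_groups={n_groups}"
        )
    basis = mode_basis(tensor, collapse_mode, n_keep_basis)
    k, rows, t = basis.elements.shape
    vecs = basis.elements.reshape(k, rows * t)  # orthonormal rows
    rng = np.random.default_rng(seed)
    perm = rng.permutation(k)
    group_size = k // n_groups
    collapsed = np.stack(
        [
            vecs[perm[g * group_size : (g + 1) * group_size]].sum(axis=0)
            for g in range(n_groups)
        ]
    )
    # groups are disjoint subsets of an orthonormal set -> mutually orthogonal
    q = collapsed / np.linalg.norm(collapsed, axis=1, keepdims=True)
    unf = unfold(tensor, collapse_mode)
    # vecs were reshaped from (rows, T) element matrices; unfolding columns are
    # time-major, so express the basis in unfolding column order
    q_cols = q.reshape(n_groups, rows, t).transpose(0, 2, 1).reshape(n_groups, t * rows)
    proj = (unf.values @ q_cols.T) @ q_cols
    out = tensor.replace_values(fold(proj, collapse_mode, tensor.shape))
    out.meta["control"] = {
        "collapse_mode": collapse_mode,
        "n_keep_basis": n_keep_basis,
        "n_groups": n_groups,
        "seed": seed,
    }
    return out


def subsample_conditions(
    tensor: PopulationTensor,
    n: int,
    seed: int = 0,
    diversity: bool = True,
) -> PopulationTensor:
    """Keep n conditions, optionally enforcing diversity.

    With ``diversity=True`` conditions are chosen by greedy farthest-point
    sampling on the Frobenius distance between condition slices, starting
    from a random condition — a stand-in for "randomly selected but
    sufficiently different".  With ``diversity=False`` the draw is uniform
    without replacement.  ``n = C`` returns all conditions in the original
    order.
    """
    c = tensor.n_conditions
    if not (1 <= n <= c):
        raise InvalidInputError(f"n must lie in [1, {c}], got {n}")
    if n == c:
        return tensor.replace_values(tensor.values.copy())
    rng = np.random.default_rng(seed)
    if diversity:
        slices = tensor.values.transpose(1, 0, 2).reshape(c, -1)
        chosen = [int(rng.integers(c))]
        d2 = np.sum((slices - slices[chosen[0]]) ** 2, axis=1)
        while len(chosen) < n:
            d2[chosen] = -1.0
            nxt = int(np.argmax(d2))
            chosen.append(nxt)
            d2 = np.minimum(d2, np.sum((slices - slices[nxt]) ** 2, axis=1))
        idx = sorted(chosen)
    else:
        idx = sorted(rng.choice(c, size=n, replace=False).tolist())
    out = PopulationTensor(
        values=tensor.values[:, idx, :].copy(),
        neuron_ids=list(tensor.neuron_ids),
        condition_ids=[tensor.condition_ids[i] for i in idx],
        time_ms=tensor.time_ms.copy(),
        units_flag=tensor.units_flag,
        centered_flag=tensor.centered_flag,
        meta=dict(tensor.meta),
    )
    out.meta["subsampled_conditions"] = [tensor.condition_ids[i] for i in idx]
    return out


def simulate_spikes(
    rates: PopulationTensor, n_trials: int, seed: int = 0
) -> SpikePopulation:
    """Inhomogeneous Poisson spikes from a nonnegative rate tensor.

    Events are generated by thinning: per (neuron, condition, trial) a
    homogeneous Poisson stream at the slice's peak rate is thinned by the
    ratio of the linearly interpolated rate (spikes/s, over ``time_ms``) to
    the peak.  Reproducible for a fixed seed.
    """
    if n_trials < 1:
        raise InvalidInputError("n_trials must be at least 1")
    if np.any(rates.values < 0):
        raise InvalidInputError("rates must be nonnegative for Poisson emission")
    rng = np.random.default_rng(seed)
    t0, t1 = float(rates.time_ms[0]), float(rates.time_ms[-1])
    duration_s = max(t1 - t0, 0.0) / 1000.0
    spike_times: list[list[list[np.ndarray]]] = []
    for i in range(rates.n_neurons):
        per_neuron = []
        for j in range(rates.n_conditions):
            lam = rates.values[i, j]
            lam_max = float(lam.max())
            per_cond = []
            for _ in range(n_trials):
                if lam_max == 0.0 or duration_s == 0.0:
                    per_cond.append(np.empty(0))
                    continue
                n_cand = rng.poisson(lam_max * duration_s)
                cand = np.sort(rng.uniform(t0, t1, size=n_cand))
                lam_at = np.interp(cand, rates.time_ms, lam)
                keep = rng.random(n_cand) < lam_at / lam_max
                per_cond.append(cand[keep])
            per_neuron.append(per_cond)
        spike_times.append(per_neuron)
    return SpikePopulation(
        spike_times=spike_times,
        neuron_ids=list(rates.neuron_ids),
        condition_ids=list(rates.condition_ids),
        recording_window=(t0, t1),
    )
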
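"""Serialization: HDF5 tensors and spikes, CSV curves, JSON reports.

HDF5 tensor layout (schema version 1): datasets ``/data`` (float64,
N×C×T), ``/neuron_ids`` and ``/condition_ids`` (UTF-8 strings),
``/time_ms`` (float64); root attributes ``units_flag``, ``centered_flag``,
``schema_version``.  Spike files hold one float64 dataset per trial under
``/spikes/n{i}/c{j}/trial{k}`` plus ``window_start_ms`` / ``window_end_ms``
root attributes.  Datasets are written with ``track_times=False`` so
identical inputs produce bit-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .analysis import DiffCurve, SweepResult, Verdict
from .exceptions import FormatError, InvalidInputError
from .preprocessing import SpikePopulation
from .tensor import PopulationTensor

SCHEMA_VERSION = 1
REPORT_SCHEMA_VERSION = 1

_DS_OPTS = dict(track_times=False)


def save_tensor(tensor: PopulationTensor, path: str | Path) -> None:
    """Write a tensor to the documented HDF5 layout (bit-exact roundtrip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tensor.values, dtype="f8", **_DS_OPTS)
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("neuron_ids", data=tensor.neuron_ids, dtype=str_dt, **_DS_OPTS)
        f.create_dataset(
            "condition_ids", data=tensor.condition_ids, dtype=str_dt, **_DS_OPTS
        )
        f.create_dataset("time_ms", data=tensor.time_ms, dtype="f8", **_DS_OPTS)
        f.attrs["units_flag"] = tensor.units_flag
        f.attrs["centered_flag"] = bool(tensor.centered_flag)
        f.attrs["schema_version"] = SCHEMA_VERSION


def load_tensor(path: str | Path) -> PopulationTensor:
    """Read a tensor from the HDF5 layout, validating the schema."""
    with h5py.File(path, "r") as f:
        for name in ("data", "neuron_ids", "condition_ids", "time_ms"):
            if name not in f:
                raise FormatError(f"tensor file {path} is missing dataset /{name}")
        values = f["data"][()]
        if values.ndim != 3:
            raise FormatError(
                f"/data must be 3-dimensional, got shape {values.shape}"
            )
        neuron_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["neuron_ids"][()]]
        condition_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["condition_ids"][()]]
        time_ms = f["time_ms"][()]
        if len(neuron_ids) != values.shape[0]:
            raise FormatError("/neuron_ids length does not match /data shape")
        if len(condition_ids) != values.shape[1]:
            raise FormatError("/condition_ids length does not match /data shape")
        if time_ms.shape != (values.shape[2],):
            raise FormatError("/time_ms length does not match /data shape")
        return PopulationTensor(
            values=values,
            neuron_ids=neuron_ids,
            condition_ids=condition_ids,
            time_ms=time_ms,
            units_flag=str(f.attrs.get("units_flag", "raw")),
            centered_flag=bool(f.attrs.get("centered_flag", False)),
        )


def tensor_from_csv(path: str | Path) -> PopulationTensor:
    """Import a small tensor from tidy CSV.

    Columns: ``neuron_id, condition_id, time_ms, rate``; every
    (neuron, condition, time) combination must appear exactly once.
    """
    df = pd.read_csv(path)
    required = {"neuron_id", "condition_id", "time_ms", "rate"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"CSV must have columns {sorted(required)}, got {sorted(df.columns)}"
        )
    neuron_ids = list(dict.fromkeys(df["neuron_id"].astype(str)))
    condition_ids = list(dict.fromkeys(df["condition_id"].astype(str)))
    time_ms = np.array(sorted(df["time_ms"].unique()), dtype=float)
    pivot = df.pivot_table(
        index=["neuron_id", "condition_id"], columns="time_ms", values="rate"
    )
    if pivot.isna().any().any() or len(df) != len(neuron_ids) * len(condition_ids) * len(time_ms):
        raise FormatError("CSV does not contain a complete neuron×condition×time grid")
    values = np.empty((len(neuron_ids), len(condition_ids), len(time_ms)))
    for i, nid in enumerate(neuron_ids):
        for j, cid in enumerate(condition_ids):
            values[i, j] = pivot.loc[(nid, cid)].to_numpy()
    return PopulationTensor(
        values=values,
        neuron_ids=neuron_ids,
        condition_ids=condition_ids,
        time_ms=time_ms,
    )


def tensor_to_csv(tensor: PopulationTensor, path: str | Path) -> None:
    """Export a tensor to the tidy CSV layout of :func:`tensor_from_csv`."""
    n, c, t = tensor.shape
    df = pd.DataFrame(
        {
            "neuron_id": np.repeat(tensor.neuron_ids, c * t),
            "condition_id": np.tile(np.repeat(tensor.condition_ids, t), n),
            "time_ms": np.tile(tensor.time_ms, n * c),
            "rate": tensor.values.ravel(),
        }
    )
    df.to_csv(path, index=False)


def save_spikes(spikes: SpikePopulation, path: str | Path) -> None:
    """Write a spike population (lossless 64-bit event times)."""
    with h5py.File(path, "w") as f:
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("neuron_ids", data=spikes.neuron_ids, dtype=str_dt, **_DS_OPTS)
        f.create_dataset(
            "condition_ids", data=spikes.condition_ids, dtype=str_dt, **_DS_OPTS
        )
        f.attrs["window_start_ms"] = spikes.recording_window[0]
        f.attrs["window_end_ms"] = spikes.recording_window[1]
        f.attrs["schema_version"] = SCHEMA_VERSION
        grp = f.create_group("spikes")
        for i, per_neuron in enumerate(spikes.spike_times):
            for j, trials in enumerate(per_neuron):
                g = grp.create_group(f"n{i}/c{j}")
                g.attrs["n_trials"] = len(trials)
                for r, ev in enumerate(trials):
                    g.create_dataset(
                        f"trial{r}", data=np.asarray(ev, dtype="f8"), **_DS_OPTS
                    )


def load_spikes(path: str | Path) -> SpikePopulation:
    """Read a spike population; events outside the window raise a
    validation error (via the container invariant)."""
    with h5py.File(path, "r") as f:
        for name in ("neuron_ids", "condition_ids", "spikes"):
            if name not in f:
                raise FormatError(f"spike file {path} is missing /{name}")
        neuron_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["neuron_ids"][()]]
        condition_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["condition_ids"][()]]
        window = (
            float(f.attrs["window_start_ms"]),
            float(f.attrs["window_end_ms"]),
        )
        spike_times = []
        for i in range(len(neuron_ids)):
            per_neuron = []
            for j in range(len(condition_ids)):
                g = f[f"spikes/n{i}/c{j}"]
                n_trials = int(g.attrs["n_trials"])
                per_neuron.append(
                    [g[f"trial{r}"][()] for r in range(n_trials)]
                )
            spike_times.append(per_neuron)
    return SpikePopulation(
        spike_times=spike_times,
        neuron_ids=neuron_ids,
        condition_ids=condition_ids,
        recording_window=window,
    )


# ---------------------------------------------------------------------------
# analysis report
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AnalysisReport:
    """Structured, JSON-serializable record of one full analysis run."""

    dataset: dict
    k: int
    k_policy: str
    sweep: SweepResult
    diff_curve: DiffCurve
    verdict: Verdict
    preprocessing: dict = dataclasses.field(default_factory=dict)
    seed_registry: dict = dataclasses.field(default_factory=dict)
    software_version: str = __version__
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a).tolist()

        return {
            "schema_version": self.schema_version,
            "software_version": self.software_version,
            "dataset": self.dataset,
            "k": int(self.k),
            "k_policy": self.k_policy,
            "preprocessing": self.preprocessing,
            "seed_registry": self.seed_registry,
            "sweep": {
                "k": int(self.sweep.k),
                "timespans": arr(self.sweep.timespans),
                "neuron_errors": arr(self.sweep.neuron_errors),
                "condition_errors": arr(self.sweep.condition_errors),
                "neuron_sem": arr(self.sweep.neuron_sem),
                "condition_sem": arr(self.sweep.condition_sem),
                "window_bounds": [list(b) for b in self.sweep.window_bounds],
                "neuron_per_condition": arr(self.sweep.neuron_per_condition),
                "condition_per_condition": arr(self.sweep.condition_per_condition),
                "step_ms": float(self.sweep.step_ms),
            },
            "diff_curve": {
                "k_values": arr(self.diff_curve.k_values),
                "diffs": arr(self.diff_curve.diffs),
                "normalizer": float(self.diff_curve.normalizer),
                "reference_k": int(self.diff_curve.reference_k),
            },
            "verdict": {
                "preferred": self.verdict.preferred,
                "p_value": float(self.verdict.p_value),
                "effect": float(self.verdict.effect),
                "alpha": float(self.verdict.alpha),
                "test": self.verdict.test,
                "n_conditions": int(self.verdict.n_conditions),
                "mean_difference": float(self.verdict.mean_difference),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        sw = d["sweep"]
        sweep = SweepResult(
            k=int(sw["k"]),
            timespans=np.asarray(sw["timespans"]),
            neuron_errors=np.asarray(sw["neuron_errors"]),
            condition_errors=np.asarray(sw["condition_errors"]),
            neuron_sem=np.asarray(sw["neuron_sem"]),
            condition_sem=np.asarray(sw["condition_sem"]),
            window_bounds=[tuple(b) for b in sw["window_bounds"]],
            neuron_per_condition=np.asarray(sw["neuron_per_condition"]),
            condition_per_condition=np.asarray(sw["condition_per_condition"]),
            step_ms=float(sw["step_ms"]),
        )
        dc = d["diff_curve"]
        diff = DiffCurve(
            k_values=np.asarray(dc["k_values"]),
            diffs=np.asarray(dc["diffs"]),
            normalizer=float(dc["normalizer"]),
            reference_k=int(dc["reference_k"]),
        )
        v = d["verdict"]
        verdict = Verdict(
            preferred=v["preferred"],
            p_value=float(v["p_value"]),
            effect=float(v["effect"]),
            alpha=float(v["alpha"]),
            test=v["test"],
            n_conditions=int(v["n_conditions"]),
            mean_difference=float(v["mean_difference"]),
        )
        return cls(
            dataset=d["dataset"],
            k=int(d["k"]),
            k_policy=d["k_policy"],
            sweep=sweep,
            diff_curve=diff,
            verdict=verdict,
            preprocessing=d.get("preprocessing", {}),
            seed_registry=d.get("seed_registry", {}),
            software_version=d.get("software_version", __version__),
            schema_version=int(d.get("schema_version", REPORT_SCHEMA_VERSION)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def curves_to_csv(sweep: SweepResult, path: str | Path) -> None:
    """Export the timespan sweep as tidy CSV:
    (timespan, timespan_ms, mode, k, error, sem)."""
    rows = []
    for mode, err, sem in (
        ("neuron", sweep.neuron_errors, sweep.neuron_sem),
        ("condition", sweep.condition_errors, sweep.condition_sem),
    ):
        for i, ts in enumerate(sweep.timespans):
            rows.append(
                {
                    "timespan": int(ts),
                    "timespan_ms": float(ts * sweep.step_ms)
                    if np.isfinite(sweep.step_ms)
                    else float("nan"),
                    "mode": mode,
                    "k": int(sweep.k),
                    "error": float(err[i]),
                    "sem": float(sem[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def diff_curve_to_csv(curve: DiffCurve, path: str | Path) -> None:
    """Export the basis-count sweep as tidy CSV: (k, normalized_diff)."""
    pd.DataFrame(
        {"k": curve.k_values.astype(int), "normalized_diff": curve.diffs}
    ).to_csv(path, index=False)
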
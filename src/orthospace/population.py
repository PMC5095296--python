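"""Domain containers and preprocessing for trial-averaged population recordings.

The analyses in this package operate on trial-averaged firing-rate tensors
(neurons x conditions x time, sampled every 10 ms) recorded around a delayed
reach: a target appears, a go cue follows, and the movement begins shortly
after.  Two 300 ms epochs anchor everything downstream:

* the *preparatory* epoch, starting 150 ms after target onset, and
* the *movement* epoch, starting 50 ms before movement onset.

Preprocessing follows the standard population-dynamics recipe: Gaussian
smoothing of spike trains, trial averaging, soft normalization (divide each
neuron by its firing-rate range plus 5 spikes/s) and cross-condition mean
centering at every timepoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.stats import norm

TIME_STEP_MS = 10.0

EVENT_NAMES = ("target_onset_ms", "go_cue_ms", "move_onset_ms")


class SchemaError(ValueError):
    """A dataset on disk does not match the expected layout."""


@dataclass
class EpochDef:
    """A fixed-length analysis window anchored to a task event."""

    name: str
    anchor_event: str
    start_offset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.anchor_event not in EVENT_NAMES:
            raise ValueError(f"unknown anchor event {self.anchor_event!r}")
        if self.duration_ms <= 0:
            raise ValueError(f"epoch duration must be positive, got {self.duration_ms}")


#: 300 ms beginning 150 ms after target onset.
PREPARATORY_EPOCH = EpochDef("preparatory", "target_onset_ms", 150.0, 300.0)
#: 300 ms beginning 50 ms before movement onset.
MOVEMENT_EPOCH = EpochDef("movement", "move_onset_ms", -50.0, 300.0)


@dataclass
class PopulationResponse:
    """Trial-averaged firing rates for N neurons, C conditions, T timepoints.

    ``rates`` is in spikes/s unless ``normalized`` is set.  Rates may be
    negative only after normalization/centering (or for the linear latent
    readout of the simulator, which is cross-condition zero-mean by
    construction and is flagged ``centered``).
    """

    rates: np.ndarray
    time_ms: np.ndarray
    events: dict
    neuron_ids: list = None
    normalized: bool = False
    centered: bool = False

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be a 3-d (neurons, conditions, time) array")
        n, _, t = self.rates.shape
        if self.time_ms.shape != (t,):
            raise ValueError("time_ms length must match the rates time axis")
        steps = np.diff(self.time_ms)
        if t > 1 and not np.allclose(steps, TIME_STEP_MS, atol=1e-9):
            raise ValueError("time_ms must increase in constant 10 ms steps")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates contain non-finite values")
        if not (self.normalized or self.centered) and np.any(self.rates < 0):
            raise ValueError("raw firing rates must be non-negative")
        missing = [e for e in EVENT_NAMES if e not in self.events]
        if missing:
            raise SchemaError(f"events missing fields: {missing}")
        lo, hi = self.time_ms[0], self.time_ms[-1]
        for name in EVENT_NAMES:
            if not (lo <= self.events[name] <= hi):
                raise ValueError(
                    f"event {name}={self.events[name]} outside recorded range [{lo}, {hi}]"
                )
        if self.neuron_ids is None:
            self.neuron_ids = [f"n{i}" for i in range(n)]
        if len(self.neuron_ids) != n:
            raise ValueError("neuron_ids length must match the neuron axis")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.rates.shape[1]

    def copy(self, **changes) -> "PopulationResponse":
        fields = dict(
            rates=self.rates.copy(),
            time_ms=self.time_ms.copy(),
            events=dict(self.events),
            neuron_ids=list(self.neuron_ids),
            normalized=self.normalized,
            centered=self.centered,
        )
        fields.update(changes)
        return PopulationResponse(**fields)


@dataclass
class EpochMatrix:
    """Neurons x (conditions * times) unfolding of one epoch.

    Columns are ordered condition-major, time-minor.  ``covariance`` treats
    each neuron (row) as a variable: rows are centered over columns and the
    divisor is C*T - 1.  ``singular_values`` are the covariance eigenvalues
    in descending order.
    """

    data: np.ndarray
    epoch: EpochDef
    n_conditions: int
    n_times: int
    covariance: np.ndarray = field(default=None)
    singular_values: np.ndarray = field(default=None)
    zero_rate_neurons: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-d")
        if self.data.shape[1] != self.n_conditions * self.n_times:
            raise ValueError("column count must equal conditions * times")
        if self.covariance is None:
            centered = self.data - self.data.mean(axis=1, keepdims=True)
            self.covariance = centered @ centered.T / (self.data.shape[1] - 1)
            self.covariance = 0.5 * (self.covariance + self.covariance.T)
        if self.singular_values is None:
            vals = np.linalg.eigvalsh(self.covariance)
            self.singular_values = np.clip(vals[::-1], 0.0, None)
        if self.zero_rate_neurons is None:
            self.zero_rate_neurons = np.where(np.all(self.data == 0.0, axis=1))[0]


@dataclass
class SpikeTrains:
    """Per-(neuron, condition) lists of trial spike-time arrays, in ms."""

    trials: dict
    window_ms: tuple
    n_neurons: int
    n_conditions: int

    def __post_init__(self) -> None:
        t0, t1 = self.window_ms
        if not t1 > t0:
            raise ValueError("spike window must be non-empty")
        for (i, c), trial_list in self.trials.items():
            for times in trial_list:
                times = np.asarray(times, dtype=float)
                if times.size and (times.min() < t0 or times.max() > t1):
                    raise ValueError(
                        f"spike times for neuron {i}, condition {c} fall outside "
                        f"the trial window [{t0}, {t1}]"
                    )


def smooth_and_average(
    spikes: SpikeTrains, kernel_sd_ms: float = 20.0, grid: np.ndarray = None, events: dict = None
) -> PopulationResponse:
    """Gaussian-smooth spike trains and average across trials into a PSTH.

    The kernel has unit area, so integrated rate per trial equals spike
    count.  Near the window edges the kernel mass falling outside the trial
    is renormalized away (truncated-kernel renormalization), preventing the
    rate droop a plain convolution would show.
    """
    if kernel_sd_ms <= 0:
        raise ValueError("kernel_sd_ms must be positive")
    t0, t1 = spikes.window_ms
    if grid is None:
        grid = np.arange(t0, t1 + TIME_STEP_MS / 2, TIME_STEP_MS)
    grid = np.asarray(grid, dtype=float)
    if events is None:
        events = {
            "target_onset_ms": grid[0],
            "go_cue_ms": grid[0],
            "move_onset_ms": grid[0],
        }
    # mass of the kernel that remains inside the trial window, per grid point
    inside = norm.cdf((t1 - grid) / kernel_sd_ms) - norm.cdf((t0 - grid) / kernel_sd_ms)
    rates = np.zeros((spikes.n_neurons, spikes.n_conditions, grid.size))
    for i in range(spikes.n_neurons):
        for c in range(spikes.n_conditions):
            trial_list = spikes.trials.get((i, c))
            if not trial_list:
                raise ValueError(f"no trials for neuron {i}, condition {c}")
            acc = np.zeros(grid.size)
            for times in trial_list:
                times = np.asarray(times, dtype=float)
                if times.size:
                    z = (grid[:, None] - times[None, :]) / kernel_sd_ms
                    acc += np.exp(-0.5 * z**2).sum(axis=1) / (
                        kernel_sd_ms * np.sqrt(2 * np.pi)
                    )
            # 1/ms -> spikes/s, trial average, edge renormalization
            rates[i, c] = 1000.0 * acc / len(trial_list) / inside
    return PopulationResponse(rates=rates, time_ms=grid, events=dict(events))


def soft_normalize(resp: PopulationResponse, offset: float = 5.0) -> PopulationResponse:
    """Divide each neuron's trace by (its rate range over all conditions and
    times) + ``offset``, bounding strong responders near unity range."""
    if offset < 0:
        raise ValueError("soft-normalization offset must be non-negative")
    if resp.normalized:
        raise ValueError("response is already soft-normalized")
    ranges = resp.rates.max(axis=(1, 2)) - resp.rates.min(axis=(1, 2))
    factors = ranges + offset
    if np.any(factors == 0):
        raise ValueError("zero normalization factor (range 0 and offset 0)")
    out = resp.copy(normalized=True)
    out.rates = resp.rates / factors[:, None, None]
    return out


def mean_center(resp: PopulationResponse) -> PopulationResponse:
    """Subtract, per neuron and timepoint, the mean across conditions."""
    out = resp.copy(centered=True)
    out.rates = resp.rates - resp.rates.mean(axis=1, keepdims=True)
    return out


def preprocess(resp: PopulationResponse, offset: float = 5.0) -> PopulationResponse:
    """Soft-normalize then mean-center (the standard preprocessing chain)."""
    return mean_center(soft_normalize(resp, offset=offset))


def resolve_epoch_times(resp: PopulationResponse, epoch: EpochDef) -> np.ndarray:
    """Indices of the samples inside an epoch window (start inclusive)."""
    anchor = resp.events[epoch.anchor_event]
    start = anchor + epoch.start_offset_ms
    stop = start + epoch.duration_ms
    idx = np.where((resp.time_ms >= start - 1e-9) & (resp.time_ms < stop - 1e-9))[0]
    expected = int(round(epoch.duration_ms / TIME_STEP_MS))
    if idx.size != expected:
        raise ValueError(
            f"epoch {epoch.name!r} window [{start}, {stop}) ms not fully covered by "
            f"recorded times [{resp.time_ms[0]}, {resp.time_ms[-1]}]"
        )
    return idx


def extract_epoch(resp: PopulationResponse, epoch: EpochDef) -> EpochMatrix:
    """Unfold one epoch into an N x (C*T) matrix, condition-major/time-minor."""
    if not (resp.normalized and resp.centered):
        raise ValueError("extract_epoch expects a soft-normalized, mean-centered response")
    idx = resolve_epoch_times(resp, epoch)
    block = resp.rates[:, :, idx]  # (N, C, Tw)
    n, c, tw = block.shape
    return EpochMatrix(
        data=block.reshape(n, c * tw), epoch=epoch, n_conditions=c, n_times=tw
    )


# ---------------------------------------------------------------------------
# File I/O: HDF5 (primary) and long-format CSV (alternative)
# ---------------------------------------------------------------------------

def write_dataset(resp: PopulationResponse, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv(resp, path)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=resp.rates)
        f.create_dataset("time_ms", data=resp.time_ms)
        f.create_dataset(
            "neuron_ids", data=np.array([str(s) for s in resp.neuron_ids], dtype="S")
        )
        g = f.create_group("events")
        for k in EVENT_NAMES:
            g.attrs[k] = float(resp.events[k])
        f.attrs["normalized"] = bool(resp.normalized)
        f.attrs["centered"] = bool(resp.centered)


def read_dataset(path) -> PopulationResponse:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    with h5py.File(path, "r") as f:
        for key in ("rates", "time_ms", "neuron_ids"):
            if key not in f:
                raise SchemaError(f"HDF5 file missing dataset /{key}")
        if "events" not in f:
            raise SchemaError("HDF5 file missing group /events")
        events = {}
        for k in EVENT_NAMES:
            if k not in f["events"].attrs:
                raise SchemaError(f"/events missing attribute {k}")
            events[k] = float(f["events"].attrs[k])
        return PopulationResponse(
            rates=f["rates"][()],
            time_ms=f["time_ms"][()],
            events=events,
            neuron_ids=[s.decode() for s in f["neuron_ids"][()]],
            normalized=bool(f.attrs.get("normalized", False)),
            centered=bool(f.attrs.get("centered", False)),
        )


def _write_csv(resp: PopulationResponse, path: Path) -> None:
    n, c, t = resp.rates.shape
    meta = {
        "events": {k: float(resp.events[k]) for k in EVENT_NAMES},
        "normalized": bool(resp.normalized),
        "centered": bool(resp.centered),
        "neuron_ids": [str(s) for s in resp.neuron_ids],
    }
    neuron = np.repeat(np.arange(n), c * t)
    condition = np.tile(np.repeat(np.arange(c), t), n)
    time = np.tile(resp.time_ms, n * c)
    df = pd.DataFrame(
        {
            "neuron": neuron,
            "condition": condition,
            "time_ms": time,
            "rate": resp.rates.reshape(-1),
        }
    )
    with open(path, "w") as fh:
        fh.write("# orthospace-population " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path) -> PopulationResponse:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# orthospace-population "):
            raise SchemaError("CSV missing '# orthospace-population' metadata header")
        meta = json.loads(header[len("# orthospace-population ") :])
        df = pd.read_csv(fh, float_precision="round_trip")
    for col in ("neuron", "condition", "time_ms", "rate"):
        if col not in df.columns:
            raise SchemaError(f"CSV missing column {col!r}")
    if "events" not in meta:
        raise SchemaError("CSV metadata missing 'events'")
    n = int(df["neuron"].max()) + 1
    c = int(df["condition"].max()) + 1
    time_ms = np.unique(df["time_ms"].to_numpy())
    t = time_ms.size
    df = df.sort_values(["neuron", "condition", "time_ms"], kind="stable")
    rates = df["rate"].to_numpy().reshape(n, c, t)
    return PopulationResponse(
        rates=rates,
        time_ms=time_ms,
        events=meta["events"],
        neuron_ids=meta.get("neuron_ids"),
        normalized=meta.get("normalized", False),
        centered=meta.get("centered", False),
    )
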
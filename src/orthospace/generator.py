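"""Gated feed-forward latent dynamical model of preparation and movement.

A two-stage linear system generates population activity in which preparatory
and movement computations occupy separate latent planes linked by a gated
feed-forward transfer:

    d/dt [x_prep]   [ J_prep      0     ] [x_prep]   [(1 - g_t) B u(c, t)]
         [x_move] = [ g_t J_FF  J_move  ] [x_move] +  [        0          ]

``J_prep`` is a leaky integrator: the target input ``u*(c)`` (the reach
target position of condition c) creates a fixed point to which the
preparatory state decays.  ``J_move`` is an oscillatory pattern generator.
The gate ``g_t`` is 0 before the go cue and rises smoothly (a step smoothed
with a 20 ms s.d. Gaussian kernel) to 1 just before movement onset; it
switches the input off and the feed-forward transfer on, so the late
preparatory state sets the amplitude and phase of the movement oscillation.

Firing rates are a random linear readout of the latents: r = L x, with
loading entries i.i.d. zero-mean Gaussian (s.d. 50).  Because the radial
targets sum to zero and the dynamics are linear, r is cross-condition
zero-mean by construction; the returned response is flagged ``centered``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .population import TIME_STEP_MS, PopulationResponse, SpikeTrains

SCENARIOS = ("orthogonal_linked", "overlapping", "independent")


@dataclass
class Timeline:
    """Task event times for a simulated trial, ms."""

    target_onset_ms: float = 0.0
    go_cue_ms: float = 500.0
    move_onset_ms: float = 650.0
    end_ms: float = 950.0

    def events(self) -> dict:
        return {
            "target_onset_ms": self.target_onset_ms,
            "go_cue_ms": self.go_cue_ms,
            "move_onset_ms": self.move_onset_ms,
        }


def make_targets(n_conditions: int = 8, radius_mm: float = 130.0) -> np.ndarray:
    """Reach-target positions: C points equally spaced on a circle.

    Returns an array of shape (2, C); column c is u*(c).
    """
    if n_conditions <= 0:
        raise ValueError("need at least one condition")
    angles = 2 * np.pi * np.arange(n_conditions) / n_conditions
    return radius_mm * np.vstack([np.cos(angles), np.sin(angles)])


def _default_j_prep() -> np.ndarray:
    # leaky integrator, 100 ms time constant
    return -np.eye(2) / 100.0


def _default_j_move() -> np.ndarray:
    # pure rotation at 2.5 Hz (one cycle per 400 ms)
    w = 2 * np.pi * 2.5 / 1000.0  # rad/ms
    return w * np.array([[0.0, 1.0], [-1.0, 0.0]])


def _default_j_ff() -> np.ndarray:
    return np.eye(2) / 50.0


@dataclass
class GeneratorParams:
    """All matrices and signals of the feed-forward generator model.

    Units: dynamics matrices are in 1/ms; targets in mm; the gate and input
    ramp are dimensionless in [0, 1].
    """

    seed: int
    n_neurons: int = 127
    d_prep: int = 2
    d_move: int = 2
    J_prep: np.ndarray = field(default_factory=_default_j_prep)
    J_move: np.ndarray = field(default_factory=_default_j_move)
    J_FF: np.ndarray = field(default_factory=_default_j_ff)
    loading_sd: float = 50.0
    gate_center_ms: float = 575.0
    gate_sd_ms: float = 20.0
    input_center_offset_ms: float = 60.0
    input_sd_ms: float = 20.0
    targets: np.ndarray = field(default_factory=make_targets)
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        self.J_prep = np.asarray(self.J_prep, dtype=float)
        self.J_move = np.asarray(self.J_move, dtype=float)
        self.J_FF = np.asarray(self.J_FF, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.J_prep.shape != (self.d_prep, self.d_prep):
            raise ValueError("J_prep shape must be (d_prep, d_prep)")
        if self.J_move.shape != (self.d_move, self.d_move):
            raise ValueError("J_move shape must be (d_move, d_move)")
        if self.J_FF.shape != (self.d_move, self.d_prep):
            raise ValueError("J_FF shape must be (d_move, d_prep)")
        if np.any(np.linalg.eigvals(self.J_prep).real >= 0):
            raise ValueError("J_prep must be leaky (eigenvalues with negative real part)")
        if self.targets.shape[0] != self.d_prep:
            raise ValueError("targets must have d_prep rows")

    @property
    def n_conditions(self) -> int:
        return self.targets.shape[1]


@dataclass
class LatentTrajectories:
    """Latent states on the 10 ms grid: x has shape (d_prep+d_move, C, T)."""

    x: np.ndarray
    time_ms: np.ndarray
    prep_idx: np.ndarray
    move_idx: np.ndarray
    timeline: Timeline

    @property
    def x_prep(self) -> np.ndarray:
        return self.x[self.prep_idx]

    @property
    def x_move(self) -> np.ndarray:
        return self.x[self.move_idx]


def gate_signal(t_ms: np.ndarray, params: GeneratorParams, timeline: Timeline) -> np.ndarray:
    """Go-signal gate: 0 before the go cue, smoothed step to 1 before movement."""
    g = norm.cdf((t_ms - params.gate_center_ms) / params.gate_sd_ms)
    return np.where(t_ms < timeline.go_cue_ms, 0.0, g)


def input_ramp(t_ms: np.ndarray, params: GeneratorParams, timeline: Timeline) -> np.ndarray:
    """Input onset: 0 before target onset, smoothed step to 1 right after it."""
    center = timeline.target_onset_ms + params.input_center_offset_ms
    a = norm.cdf((t_ms - center) / params.input_sd_ms)
    return np.where(t_ms < timeline.target_onset_ms, 0.0, a)


def simulate_latents(params: GeneratorParams, timeline: Timeline = None) -> LatentTrajectories:
    """Integrate the gated two-stage linear system by forward Euler.

    Integrates at ``params.dt_ms`` from target onset to the end of the
    timeline and decimates to the 10 ms sampling grid.
    """
    if timeline is None:
        timeline = Timeline()
    if params.dt_ms > 1.0 + 1e-12:
        raise ValueError("dt_ms must be <= 1 ms for a faithful Euler integration")
    dp, dm = params.d_prep, params.d_move
    c = params.n_conditions
    t_fine = np.arange(timeline.target_onset_ms, timeline.end_ms + params.dt_ms / 2, params.dt_ms)
    g = gate_signal(t_fine, params, timeline)
    a = input_ramp(t_fine, params, timeline)
    x = np.zeros((dp + dm, c))
    keep = np.isclose((t_fine - timeline.target_onset_ms) % TIME_STEP_MS, 0.0) | np.isclose(
        (t_fine - timeline.target_onset_ms) % TIME_STEP_MS, TIME_STEP_MS
    )
    out = np.zeros((dp + dm, c, int(keep.sum())))
    k = 0
    for i, t in enumerate(t_fine):
        if keep[i]:
            out[:, :, k] = x
            k += 1
        dx_prep = params.J_prep @ x[:dp] + (1.0 - g[i]) * a[i] * params.targets
        dx_move = g[i] * (params.J_FF @ x[:dp]) + params.J_move @ x[dp:]
        x = x + params.dt_ms * np.vstack([dx_prep, dx_move])
        if np.any(np.abs(x) > 1e9):
            raise FloatingPointError(
                "latent integration diverged (|x| > 1e9); use a smaller dt_ms"
            )
    time_ms = t_fine[keep]
    return LatentTrajectories(
        x=out,
        time_ms=time_ms,
        prep_idx=np.arange(dp),
        move_idx=np.arange(dp, dp + dm),
        timeline=timeline,
    )


def make_loading(params: GeneratorParams, rng: np.random.Generator = None) -> np.ndarray:
    """N x (d_prep+d_move) readout matrix, entries i.i.d. N(0, loading_sd^2)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return params.loading_sd * rng.standard_normal(
        (params.n_neurons, params.d_prep + params.d_move)
    )


def emit_rates(
    latents: LatentTrajectories,
    params: GeneratorParams,
    loading: np.ndarray = None,
    baseline: float = None,
    rectify: bool = False,
) -> PopulationResponse:
    """Read latent trajectories out into simulated firing rates r = L x.

    Without a baseline the readout is the raw (signed) linear projection,
    which is cross-condition zero-mean whenever the target set is balanced;
    the response is flagged ``centered`` accordingly.  With ``baseline`` and
    ``rectify`` (used only when spike emission is requested) rates are
    shifted and clipped at zero.
    """
    if loading is None:
        loading = make_loading(params)
    loading = np.asarray(loading, dtype=float)
    if loading.shape[1] != latents.x.shape[0]:
        raise ValueError(
            f"loading has {loading.shape[1]} columns but there are "
            f"{latents.x.shape[0]} latents"
        )
    rates = np.einsum("nd,dct->nct", loading, latents.x)
    centered = True
    if baseline is not None:
        rates = rates + baseline
        centered = False
    if rectify:
        rates = np.clip(rates, 0.0, None)
        centered = False
    return PopulationResponse(
        rates=rates,
        time_ms=latents.time_ms,
        events=latents.timeline.events(),
        centered=centered,
    )


def emit_spikes(resp: PopulationResponse, n_trials: int, seed: int) -> SpikeTrains:
    """Inhomogeneous Poisson spike trains from a non-negative rate response.

    Rates are linearly interpolated to 1 ms bins; counts per bin are Poisson
    with mean rate * 0.001 and spike times are placed uniformly in the bin.
    """
    if np.any(resp.rates < 0):
        raise ValueError("spike emission requires non-negative rates")
    rng = np.random.default_rng(seed)
    t0, t1 = resp.time_ms[0], resp.time_ms[-1]
    fine = np.arange(t0, t1, 1.0)
    trials = {}
    for i in range(resp.n_neurons):
        for c in range(resp.n_conditions):
            lam = np.interp(fine + 0.5, resp.time_ms, resp.rates[i, c]) * 1e-3
            trial_list = []
            for _ in range(n_trials):
                counts = rng.poisson(lam)
                times = np.repeat(fine, counts) + rng.random(int(counts.sum()))
                trial_list.append(np.sort(times))
            trials[(i, c)] = trial_list
    return SpikeTrains(
        trials=trials, window_ms=(t0, t1), n_neurons=resp.n_neurons,
        n_conditions=resp.n_conditions,
    )


def _orthogonalize_blocks(loading: np.ndarray, d_prep: int) -> np.ndarray:
    """Project the movement loading columns out of the preparatory plane, so
    the two readout planes are exactly orthogonal (planted ground truth)."""
    lp = loading[:, :d_prep]
    qp, _ = np.linalg.qr(lp)
    lm = loading[:, d_prep:]
    return np.hstack([lp, lm - qp @ (qp.T @ lm)])


def _orthonormal_span(a: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(a)
    return q


def make_scenario(
    kind: str,
    params: GeneratorParams,
    timeline: Timeline = None,
    orthogonalize: bool = True,
):
    """Simulate one of the three hypothetical population structures.

    * ``orthogonal_linked`` — the generator model itself: preparation and
      movement occupy orthogonal neuron-space planes, linked through the
      gated feed-forward transfer.
    * ``overlapping`` — movement latents are read out through the *same*
      neuron-space plane as the preparatory latents; the condition ordering
      is cyclically shifted, so states change but the subspace does not.
    * ``independent`` — orthogonal planes as above, but the condition-to-
      state assignment of the movement latents is randomly permuted, erasing
      the lawful preparatory-to-movement relationship.

    Returns ``(response, truth)`` where ``truth`` holds the planted
    orthonormal bases ``Q_prep``/``Q_move`` (in neuron space) and scenario
    metadata.  ``orthogonalize`` makes the planted planes exactly orthogonal
    (movement loading columns projected off the preparatory plane); with
    ``False`` the raw Gaussian loading is used and the planes are only
    near-orthogonal, as in the unmodified generator model.
    """
    if kind not in SCENARIOS:
        raise ValueError(f"unknown scenario {kind!r}; expected one of {SCENARIOS}")
    if timeline is None:
        timeline = Timeline()
    rng = np.random.default_rng(params.seed)
    latents = simulate_latents(params, timeline)
    loading = make_loading(params, rng)
    dp = params.d_prep
    c = params.n_conditions

    if kind == "overlapping":
        # shared readout plane: move latents re-expressed through the prep
        # columns; lawful (cyclic) reordering of condition states
        shift = 1 if c > 1 else 0
        x = latents.x.copy()
        x[dp:] = np.roll(x[dp:], shift, axis=1)
        shared = np.hstack([loading[:, :dp], loading[:, :dp]])
        rates = np.einsum("nd,dct->nct", shared, x)
        q = _orthonormal_span(loading[:, :dp])
        truth = {"kind": kind, "Q_prep": q, "Q_move": q.copy(), "condition_shift": shift}
    else:
        if orthogonalize:
            loading = _orthogonalize_blocks(loading, dp)
        x = latents.x.copy()
        perm = np.arange(c)
        if kind == "independent":
            perm = rng.permutation(c)
            x[dp:] = x[dp:][:, perm]
        rates = np.einsum("nd,dct->nct", loading, x)
        q_prep = _orthonormal_span(loading[:, :dp])
        lm = loading[:, dp:]
        if not orthogonalize:
            # the recoverable move plane is the move loading with its
            # (small, random) preparatory-plane component removed
            lm = lm - q_prep @ (q_prep.T @ lm)
        truth = {
            "kind": kind,
            "Q_prep": q_prep,
            "Q_move": _orthonormal_span(lm),
            "condition_permutation": perm,
        }
    resp = PopulationResponse(
        rates=rates, time_ms=latents.time_ms, events=timeline.events(), centered=True
    )
    return resp, truth


def simulate_response(params: GeneratorParams, timeline: Timeline = None) -> PopulationResponse:
    """Convenience: simulate latents and read them out with the seeded loading."""
    if timeline is None:
        timeline = Timeline()
    latents = simulate_latents(params, timeline)
    return emit_rates(latents, params)
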
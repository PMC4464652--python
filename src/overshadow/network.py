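"""Recurrent interactive network core.

Three peripheral layers (retinotopic 4200, visual image 4200, verbal 6) are
bidirectionally connected through a single hidden layer (20 units); there are
no direct peripheral-peripheral or hidden-hidden connections.  Unit dynamics
are time-averaged:

    s[i,t] = s[i,t-1] + r * (sum_j w[j,i] a[j,t-1] + b[i] - s[i,t-1])
    a[i,t] = 1 / (1 + exp(-s[i,t]))

with integration rate r = 0.1, so under a constant summed input x the net
input converges geometrically to x with ratio (1 - r) per cycle.  External
inputs either hard-clamp a layer (activations pinned to the input, used for
the retinotopic layer) or soft-clamp it, blending the internally computed
output with the external value by a fixed gain g = 0.5:

    a <- a + g * (external - a)

Peripheral units whose external input / target value never varies across the
stimulus set are disconnected (sparse connectivity), which removes most of
the 8400 image units from the weight matrices.

Training uses backpropagation through time on a cross-entropy loss: a trial
phase stops early once every target-layer unit is within 0.5 of its target
(tested from the phase's first eligible cycle), error is injected at the
phase's stop cycle, and units already within the zero-error radius (0.1) of
their target contribute no gradient.  Gaussian noise (SD 0.2) is added to
the hidden layer's summed input during training to push hidden activations
toward the sigmoid asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from scipy.special import expit

from .stimuli import StimulusSet

__all__ = [
    "NetworkParams",
    "ConnectivityMask",
    "WeightSet",
    "ClampSpec",
    "Phase",
    "TrialSpec",
    "Trajectory",
    "NonFiniteStateError",
    "derive_connectivity",
    "init_network",
    "step_activations",
    "run_trial",
    "compute_error",
    "bptt_gradients",
    "apply_bptt_update",
]

LAYERS = ("retinotopic", "visual", "verbal")


class NonFiniteStateError(FloatingPointError):
    """Network state or gradient became non-finite; carries the cycle index."""

    def __init__(self, what: str, cycle: int):
        super().__init__(f"non-finite {what} at cycle {cycle}")
        self.cycle = cycle


@dataclass(frozen=True)
class NetworkParams:
    """All fixed hyperparameters of the dynamics and of training."""

    n_retinotopic: int = 4200
    n_visual: int = 4200
    n_verbal: int = 6
    n_hidden: int = 20
    integration_rate: float = 0.1
    clamp_gain: float = 0.5
    cycles_per_phase: int = 10
    early_stop_threshold: float = 0.5
    #: earliest cycle (within a phase) at which the early-stop test can end
    #: the phase.  External input reaches the output layers only after two
    #: cycles (input -> hidden -> output), so testing before cycle 3 would
    #: stop trials on input-independent activity and, during training, ask
    #: the network to hit targets the input cannot yet have produced.
    early_stop_min_cycle: int = 3
    zero_error_radius: float = 0.1
    learning_rate: float = 0.05
    weight_decay: float = 1e-8
    momentum: float = 0.0
    batch_size: int = 1
    hidden_input_noise_sd: float = 0.2
    init_weight_range: float = 0.1
    #: where along a target phase cross-entropy error is injected:
    #: "final_cycle" applies it at the phase's stop cycle only; "every_cycle"
    #: at every cycle from the phase's first cycle through its stop cycle;
    #: "on_failure" only at the last cycle of phases that never met the
    #: early-stop criterion.  The output-target comparison that triggers
    #: early stopping always runs from the first cycle.  Per-cycle injection
    #: demands saturation within one integration step (unreachable at rate
    #: 0.1) and destabilizes training; on_failure stops training pressure at
    #: barely-correct outputs and never polarizes them; the stop-cycle
    #: schedule is the default.
    error_schedule: str = "final_cycle"
    eps: float = 1e-7

    def __post_init__(self):
        if self.cycles_per_phase < 1:
            raise ValueError("cycles_per_phase must be >= 1")
        for name in (
            "integration_rate",
            "clamp_gain",
            "hidden_input_noise_sd",
            "zero_error_radius",
            "init_weight_range",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def layer_size(self, layer: str) -> int:
        return {"retinotopic": self.n_retinotopic, "visual": self.n_visual, "verbal": self.n_verbal}[layer]


@dataclass
class ConnectivityMask:
    """Which peripheral units are wired to the hidden layer.

    A unit is connected iff its external input / target value varies across
    the item set it was derived from.
    """

    retinotopic: np.ndarray  # bool
    visual: np.ndarray
    verbal: np.ndarray

    def mask_for(self, layer: str) -> np.ndarray:
        return getattr(self, layer)

    @property
    def n_connected(self) -> int:
        return int(self.retinotopic.sum() + self.visual.sum() + self.verbal.sum())


def derive_connectivity(stimuli: StimulusSet) -> ConnectivityMask:
    """Connect only peripheral units whose value varies across items.

    Retinotopic/visual units constant over the whole set (e.g. always-white
    background pixels) are left out; all six verbal units vary by design and
    stay connected.
    """
    retino = np.ptp(stimuli.retinotopic, axis=0) > 0
    visual = np.ptp(stimuli.images, axis=0) > 0
    verbal = np.ones(stimuli.verbal.shape[1], dtype=bool)
    return ConnectivityMask(retinotopic=retino, visual=visual, verbal=verbal)


class WeightSet:
    """Sparse bidirectional weights and biases.

    Connected peripheral units are packed into one vector ``P`` in layer
    order (retinotopic, visual, verbal); ``W_ph`` maps P -> hidden and
    ``W_hp`` hidden -> P.  Biases sit on hidden and connected peripheral
    units.
    """

    def __init__(self, params: NetworkParams, mask: ConnectivityMask):
        self.params = params
        self.mask = mask
        n_r = int(mask.retinotopic.sum())
        n_v = int(mask.visual.sum())
        n_l = int(mask.verbal.sum())
        self.n_p = n_r + n_v + n_l
        self.n_h = params.n_hidden
        self.slices = {
            "retinotopic": slice(0, n_r),
            "visual": slice(n_r, n_r + n_v),
            "verbal": slice(n_r + n_v, self.n_p),
        }
        self.W_ph = np.zeros((self.n_p, self.n_h))
        self.W_hp = np.zeros((self.n_h, self.n_p))
        self.b_h = np.zeros(self.n_h)
        self.b_p = np.zeros(self.n_p)
        self._velocity = None  # allocated only if momentum > 0

    # -- packing helpers ----------------------------------------------------

    def pack(self, layer: str, full_vector: np.ndarray) -> np.ndarray:
        """Restrict a full-layer vector to its connected units."""
        return np.asarray(full_vector, dtype=np.float64)[self.mask.mask_for(layer)]

    def unpack(self, layer: str, packed: np.ndarray, fill: float = 0.5) -> np.ndarray:
        """Expand connected-unit values back to full layer width."""
        full = np.full(self.params.layer_size(layer), fill, dtype=np.float64)
        full[self.mask.mask_for(layer)] = packed
        return full

    def copy(self) -> "WeightSet":
        other = WeightSet(self.params, self.mask)
        other.W_ph = self.W_ph.copy()
        other.W_hp = self.W_hp.copy()
        other.b_h = self.b_h.copy()
        other.b_p = self.b_p.copy()
        return other

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Bit-exact checkpoint: .npz matrix bundle plus a JSON header."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path,
            W_ph=self.W_ph,
            W_hp=self.W_hp,
            b_h=self.b_h,
            b_p=self.b_p,
            mask_retinotopic=self.mask.retinotopic,
            mask_visual=self.mask.visual,
            mask_verbal=self.mask.verbal,
        )
        header = {
            "params": {k: getattr(self.params, k) for k in NetworkParams.__dataclass_fields__},
            "shapes": {"W_ph": list(self.W_ph.shape), "W_hp": list(self.W_hp.shape)},
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "WeightSet":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        params = NetworkParams(**header["params"])
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        mask = ConnectivityMask(
            retinotopic=data["mask_retinotopic"],
            visual=data["mask_visual"],
            verbal=data["mask_verbal"],
        )
        ws = cls(params, mask)
        ws.W_ph = data["W_ph"]
        ws.W_hp = data["W_hp"]
        ws.b_h = data["b_h"]
        ws.b_p = data["b_p"]
        return ws


def init_network(params: NetworkParams, mask: ConnectivityMask, seed: int) -> WeightSet:
    """i.i.d. uniform weights in +/- init_weight_range, deterministic per seed."""
    rng = np.random.default_rng(seed)
    ws = WeightSet(params, mask)
    r = params.init_weight_range
    ws.W_ph = rng.uniform(-r, r, size=ws.W_ph.shape)
    ws.W_hp = rng.uniform(-r, r, size=ws.W_hp.shape)
    ws.b_h = rng.uniform(-r, r, size=ws.b_h.shape)
    ws.b_p = rng.uniform(-r, r, size=ws.b_p.shape)
    return ws


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class ClampSpec:
    """External input to one layer during one phase.

    ``values`` is in full layer coordinates.  ``unit_mask`` restricts the
    clamp to a subset of units (used for verbal clamps, where only the
    externally described labels receive input); by default every unit of the
    layer is clamped.  Hard clamping pins activations to the external values;
    soft clamping blends by the clamp gain.
    """

    layer: str
    mode: str  # "hard" | "soft"
    values: np.ndarray
    unit_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.unit_mask is not None:
            self.unit_mask = np.asarray(self.unit_mask, dtype=bool)


@dataclass
class Phase:
    """One settling phase of a trial: fixed clamps and an optional target."""

    cycles: int
    clamps: list[ClampSpec] = field(default_factory=list)
    target_layer: str | None = None
    target: np.ndarray | None = None
    early_stop: bool = True

    def __post_init__(self):
        if (self.target_layer is None) != (self.target is None):
            raise ValueError("target_layer and target must be given together")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=np.float64)


@dataclass
class TrialSpec:
    task: str
    phases: list[Phase]
    train: bool = False
    item_index: int | None = None


@dataclass
class Trajectory:
    """Per-cycle record of one trial.

    Arrays are indexed 0..T where index 0 is the initial (clamped) state;
    ``a_p``/``a_h`` are post-clamp activations over packed peripheral and
    hidden units, ``a_int_p`` the pre-clamp sigmoid outputs, and ``dadz_p``
    the per-unit clamp factor (1 free, 1-gain soft, 0 hard) used by BPTT.
    """

    s_p: np.ndarray
    s_h: np.ndarray
    a_p: np.ndarray
    a_h: np.ndarray
    a_int_p: np.ndarray
    dadz_p: np.ndarray
    phase_of_cycle: np.ndarray  # (T+1,), -1 for the initial state
    phase_stop: list[int]  # stop cycle of each phase, in trial cycles
    phase_start: list[int]
    spec: TrialSpec

    @property
    def stop_cycle(self) -> int:
        return self.phase_stop[-1]

    def layer_activations(self, weights: WeightSet, layer: str, cycle: int) -> np.ndarray:
        """Full-width activations of one layer at a given trial cycle."""
        return weights.unpack(layer, self.a_p[cycle][weights.slices[layer]])

    def hidden_activations(self) -> np.ndarray:
        """(T+1, n_hidden) hidden activations, initial state included."""
        return self.a_h


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def _packed_clamps(weights: WeightSet, clamps: list[ClampSpec]):
    """Pre-pack clamp values/indices into peripheral-vector coordinates."""
    packed = []
    for c in clamps:
        sl = weights.slices[c.layer]
        lmask = weights.mask.mask_for(c.layer)
        vals = np.asarray(c.values, dtype=np.float64)[lmask]
        if c.unit_mask is None:
            idx = np.arange(sl.start, sl.stop)
        else:
            sub = c.unit_mask[lmask]
            idx = np.arange(sl.start, sl.stop)[sub]
            vals = vals[sub]
        packed.append((c.mode, idx, vals))
    return packed


def step_activations(state, weights: WeightSet, clamps, params: NetworkParams, rng=None):
    """One synchronous update of the whole network.

    ``state`` is ``(s_p, s_h, a_p, a_h)``; ``clamps`` a list of ClampSpec.
    Returns the new state.  Mainly a single-step convenience wrapper around
    the dynamics used by :func:`run_trial`.
    """
    s_p, s_h, a_p, a_h = state
    packed = _packed_clamps(weights, clamps)
    r = params.integration_rate
    net_h = a_p @ weights.W_ph + weights.b_h
    if rng is not None and params.hidden_input_noise_sd > 0:
        net_h = net_h + rng.normal(0.0, params.hidden_input_noise_sd, size=net_h.shape)
    net_p = a_h @ weights.W_hp + weights.b_p
    s_h = s_h + r * (net_h - s_h)
    s_p = s_p + r * (net_p - s_p)
    a_h = _sigmoid(s_h)
    a_p = _sigmoid(s_p)
    for mode, idx, vals in packed:
        if mode == "hard":
            a_p[idx] = vals
        else:
            a_p[idx] = a_p[idx] + params.clamp_gain * (vals - a_p[idx])
    if not (np.isfinite(s_p).all() and np.isfinite(s_h).all()):
        raise NonFiniteStateError("state", 1)
    return s_p, s_h, a_p, a_h


def run_trial(
    spec: TrialSpec,
    weights: WeightSet,
    params: NetworkParams | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run a (possibly multi-phase) trial and record the full trajectory.

    Net inputs start at zero (activations 0.5) and persist across phase
    boundaries; each phase runs for its cycle budget unless early stopping is
    enabled and every target unit's |output - target| falls below the
    early-stop threshold.  ``rng`` enables the hidden-layer training noise;
    pass None for deterministic evaluation.
    """
    if params is None:
        params = weights.params
    n_p, n_h = weights.n_p, weights.n_h
    total = sum(ph.cycles for ph in spec.phases)
    s_p = np.zeros((total + 1, n_p))
    s_h = np.zeros((total + 1, n_h))
    a_p = np.zeros((total + 1, n_p))
    a_h = np.full((total + 1, n_h), 0.5)
    a_int_p = np.full((total + 1, n_p), 0.5)
    dadz_p = np.ones((total + 1, n_p))
    phase_of_cycle = np.full(total + 1, -1, dtype=int)
    a_p[0] = 0.5

    r = params.integration_rate
    g = params.clamp_gain
    noise_sd = params.hidden_input_noise_sd
    W_ph, W_hp, b_h, b_p = weights.W_ph, weights.W_hp, weights.b_h, weights.b_p

    t = 0
    phase_stop: list[int] = []
    phase_start: list[int] = []
    cs_p, cs_h = s_p[0].copy(), s_h[0].copy()
    ca_p, ca_h = a_p[0].copy(), a_h[0].copy()

    for p_i, phase in enumerate(spec.phases):
        packed = _packed_clamps(weights, phase.clamps)
        # clamps take effect on the state feeding the phase's first cycle
        for mode, idx, vals in packed:
            if mode == "hard":
                ca_p[idx] = vals
                dadz_p[t][idx] = 0.0
            else:
                ca_p[idx] = ca_p[idx] + g * (vals - ca_p[idx])
                dadz_p[t][idx] *= 1.0 - g
        a_p[t] = ca_p
        phase_start.append(t)
        if phase.target is not None:
            tgt_idx = weights.slices[phase.target_layer]
            tgt_mask = weights.mask.mask_for(phase.target_layer)
            tgt = np.asarray(phase.target, dtype=np.float64)[tgt_mask]
        for _ in range(phase.cycles):
            t += 1
            net_h = ca_p @ W_ph + b_h
            if rng is not None and noise_sd > 0:
                net_h += rng.normal(0.0, noise_sd, size=n_h)
            net_p = ca_h @ W_hp + b_p
            cs_h = cs_h + r * (net_h - cs_h)
            cs_p = cs_p + r * (net_p - cs_p)
            ca_h = _sigmoid(cs_h)
            a_int = _sigmoid(cs_p)
            ca_p = a_int.copy()
            dz = dadz_p[t]
            for mode, idx, vals in packed:
                if mode == "hard":
                    ca_p[idx] = vals
                    dz[idx] = 0.0
                else:
                    ca_p[idx] += g * (vals - ca_p[idx])
                    dz[idx] = 1.0 - g
            if not (np.isfinite(cs_p).all() and np.isfinite(cs_h).all()):
                raise NonFiniteStateError("state", t)
            s_p[t], s_h[t] = cs_p, cs_h
            a_p[t], a_h[t], a_int_p[t] = ca_p, ca_h, a_int
            phase_of_cycle[t] = p_i
            if (
                phase.target is not None
                and phase.early_stop
                and params.early_stop_threshold > 0
                and (t - phase_start[-1]) >= params.early_stop_min_cycle
                and np.all(np.abs(ca_p[tgt_idx] - tgt) < params.early_stop_threshold)
            ):
                break
        phase_stop.append(t)

    T = t
    return Trajectory(
        s_p=s_p[: T + 1],
        s_h=s_h[: T + 1],
        a_p=a_p[: T + 1],
        a_h=a_h[: T + 1],
        a_int_p=a_int_p[: T + 1],
        dadz_p=dadz_p[: T + 1],
        phase_of_cycle=phase_of_cycle[: T + 1],
        phase_stop=phase_stop,
        phase_start=phase_start,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# error and learning
# ---------------------------------------------------------------------------

def compute_error(
    output: np.ndarray,
    target: np.ndarray,
    zero_error_radius: float = 0.1,
    eps: float = 1e-7,
):
    """Cross-entropy error and its gradient w.r.t. the unit net inputs.

    Error is summed over target units; any unit within ``zero_error_radius``
    of its target contributes zero gradient (but still counts toward the
    reported error).  The returned gradient is d(error)/d(net input) for
    sigmoid units, i.e. (output - target) with the radius mask applied.
    """
    a = np.clip(np.asarray(output, dtype=np.float64), eps, 1.0 - eps)
    t = np.asarray(target, dtype=np.float64)
    err = float(-np.sum(t * np.log(a) + (1.0 - t) * np.log(1.0 - a)))
    grad = a - t
    grad[np.abs(grad) <= zero_error_radius] = 0.0
    return err, grad


def bptt_gradients(traj: Trajectory, weights: WeightSet, params: NetworkParams | None = None):
    """Cross-entropy gradients through the unrolled dynamics.

    Error is injected per ``params.error_schedule`` (at each target phase's
    stop cycle, or at every cycle of the phase) and propagated backward
    through the time-averaged net-input recurrence, the sigmoid, and the
    clamp factors.  Returns ``(gW_ph, gW_hp, gb_h, gb_p, error)``.
    """
    if params is None:
        params = weights.params
    spec = traj.spec
    T = traj.a_p.shape[0] - 1
    n_p, n_h = weights.n_p, weights.n_h
    r = params.integration_rate
    radius = params.zero_error_radius
    eps = params.eps

    # per-cycle error gradients dL/dA on the packed peripheral vector
    G_err = np.zeros((T + 1, n_p))
    total_err = 0.0
    for p_i, phase in enumerate(spec.phases):
        if phase.target is None:
            continue
        sl = weights.slices[phase.target_layer]
        tgt = np.asarray(phase.target, dtype=np.float64)[weights.mask.mask_for(phase.target_layer)]
        if params.error_schedule == "final_cycle":
            cyc = [traj.phase_stop[p_i]]
        elif params.error_schedule == "every_cycle":
            cyc = np.flatnonzero(traj.phase_of_cycle == p_i)
        elif params.error_schedule == "on_failure":
            # an early-stopped phase met its criterion; no error flows from it
            stop = traj.phase_stop[p_i]
            cyc = [] if stop - traj.phase_start[p_i] < phase.cycles else [stop]
        else:
            raise ValueError(f"unknown error_schedule {params.error_schedule!r}")
        for t in cyc:
            a = np.clip(traj.a_p[t, sl], eps, 1.0 - eps)
            total_err += float(-np.sum(tgt * np.log(a) + (1.0 - tgt) * np.log(1.0 - a)))
            diff = a - tgt
            live = np.abs(diff) > radius
            # dL/dA = (a - t) / (a (1 - a)) on live units
            G_err[t, sl][live] = diff[live] / (a[live] * (1.0 - a[live]))

    Gs_p = np.zeros((T + 1, n_p))
    Gs_h = np.zeros((T + 1, n_h))
    next_Gs_p = np.zeros(n_p)
    next_Gs_h = np.zeros(n_h)
    for t in range(T, 0, -1):
        G_a_p = G_err[t] + r * (weights.W_ph @ next_Gs_h)
        G_a_h = r * (weights.W_hp @ next_Gs_p)
        sig_p = traj.a_int_p[t] * (1.0 - traj.a_int_p[t])
        sig_h = traj.a_h[t] * (1.0 - traj.a_h[t])
        cur_Gs_p = (1.0 - r) * next_Gs_p + G_a_p * traj.dadz_p[t] * sig_p
        cur_Gs_h = (1.0 - r) * next_Gs_h + G_a_h * sig_h
        Gs_p[t] = cur_Gs_p
        Gs_h[t] = cur_Gs_h
        next_Gs_p, next_Gs_h = cur_Gs_p, cur_Gs_h

    # s[t] receives r * (A[t-1] @ W + b); accumulate over cycles in one matmul
    gW_ph = r * (traj.a_p[:-1].T @ Gs_h[1:])
    gW_hp = r * (traj.a_h[:-1].T @ Gs_p[1:])
    gb_h = r * Gs_h[1:].sum(axis=0)
    gb_p = r * Gs_p[1:].sum(axis=0)
    if not np.isfinite(gW_ph).all() or not np.isfinite(gW_hp).all():
        raise NonFiniteStateError("gradient", T)
    return gW_ph, gW_hp, gb_h, gb_p, total_err


def apply_bptt_update(
    traj: Trajectory,
    weights: WeightSet,
    params: NetworkParams | None = None,
) -> float:
    """In-place weight update from one training trial; returns the trial error.

    update = -learning_rate * gradient - weight_decay * w (+ momentum * previous
    update; momentum defaults to zero and then contributes nothing).
    """
    if params is None:
        params = weights.params
    gW_ph, gW_hp, gb_h, gb_p, err = bptt_gradients(traj, weights, params)
    lr, wd, mom = params.learning_rate, params.weight_decay, params.momentum
    steps = (
        -lr * gW_ph - wd * weights.W_ph,
        -lr * gW_hp - wd * weights.W_hp,
        -lr * gb_h - wd * weights.b_h,
        -lr * gb_p - wd * weights.b_p,
    )
    if mom != 0.0:
        if weights._velocity is None:
            weights._velocity = [np.zeros_like(s) for s in steps]
        steps = tuple(s + mom * v for s, v in zip(steps, weights._velocity))
        weights._velocity = [s.copy() for s in steps]
    weights.W_ph += steps[0]
    weights.W_hp += steps[1]
    weights.b_h += steps[2]
    weights.b_p += steps[3]
    return err
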
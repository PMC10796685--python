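"""Simulated two-cursor closed-loop task and online performance metrics.

A simulated user stands in for the participant: at each 20-ms step it forms a
point-at-target intention per active cursor (unit vector from cursor to
target), encodes it through a simulated population with context-appropriate
coefficients, and adds calibrated noise.  A decoder converts the resulting bin
vector into cursor velocities; assistance (attenuation of off-axis velocity,
target-directed push scaled by decoded speed, or locking the inactive cursor)
and the dwell/timeout rules follow the online task: both cursors must dwell in
their targets simultaneously for 500 ms within a 10-s trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import (
    BIN_S,
    BIMANUAL,
    NO_MOVEMENT,
    UNI_LEFT,
    UNI_RIGHT,
    Frames,
    NoiseModel,
    SimPopulation,
    context_code,
    encode_rates,
)


@dataclass
class TaskConfig:
    target_radius: float = 0.15
    target_distance: float = 0.7
    dwell_s: float = 0.5
    timeout_s: float = 10.0
    dt: float = BIN_S
    gain: float = 1.0  # decoded velocity -> workspace units/s
    workspace: float = 1.0  # positions clipped to [-workspace, workspace]^2

    @property
    def dwell_bins(self) -> int:
        return int(round(self.dwell_s / self.dt))

    @property
    def timeout_bins(self) -> int:
        return int(round(self.timeout_s / self.dt))


@dataclass
class AssistConfig:
    error_assist: float = 0.0
    push_assist: float = 0.0
    lock_mode: bool = False

    def __post_init__(self) -> None:
        for v in (self.error_assist, self.push_assist):
            if not 0.0 <= v <= 1.0:
                raise ValueError("assist factors must be in [0, 1]")


@dataclass
class TaskState:
    pos: np.ndarray  # (2 cursors, 2) right = row 0, left = row 1
    target: np.ndarray  # (2, 2)
    trial_type: int
    dwell_bins: int = 0
    t_bins: int = 0
    done: bool = False
    success: bool = False

    @property
    def active(self) -> tuple:
        if self.trial_type == UNI_RIGHT:
            return (0,)
        if self.trial_type == UNI_LEFT:
            return (1,)
        return (0, 1)

    def to_target(self, cursor: int) -> np.ndarray:
        return self.target[cursor] - self.pos[cursor]


def cursors_in_target(state: TaskState, cfg: TaskConfig) -> np.ndarray:
    d = np.linalg.norm(state.target - state.pos, axis=1)
    return d <= cfg.target_radius


# ---------------------------------------------------------------------------
# Simulated user
# ---------------------------------------------------------------------------


@dataclass
class SimUser:
    """Synthetic participant emitting one bin of neural activity per step."""

    population: SimPopulation
    noise: NoiseModel
    strategy: str = "simultaneous"  # or "sequential"
    reaction_bins: int = 10  # 200 ms
    intention_noise: float = 0.0  # angular jitter (radians sd) on intention
    switch_hysteresis: int = 3  # bins before the sequential strategy switches
    _attend: int = field(default=0, repr=False)
    _switch_count: int = field(default=0, repr=False)

    def reset(self) -> None:
        self._attend = 0
        self._switch_count = 0

    def intention(self, state: TaskState, cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
        """(2, 2) unit point-at-target intention per cursor (zero if on target)."""
        intent = np.zeros((2, 2))
        if state.t_bins < self.reaction_bins:
            return intent
        active = list(state.active)
        if self.strategy == "sequential" and len(active) > 1:
            dists = [np.linalg.norm(state.to_target(c)) for c in active]
            far = active[int(np.argmax(dists))]
            if far != self._attend:
                self._switch_count += 1
                if self._switch_count >= self.switch_hysteresis:
                    self._attend = far
                    self._switch_count = 0
            else:
                self._switch_count = 0
            active = [self._attend] if self._attend in active else [active[0]]
        for c in active:
            v = state.to_target(c)
            dist = np.linalg.norm(v)
            if dist > cfg.target_radius:
                u = v / dist
                if self.intention_noise > 0:
                    a = rng.normal(0, self.intention_noise)
                    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
                    u = R @ u
                intent[c] = u
        return intent


def user_step(
    user: SimUser, state: TaskState, rng: np.random.Generator, cfg: TaskConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One bin of synthetic neural activity; returns (bin_vector, intention)."""
    cfg = cfg or TaskConfig()
    intent = user.intention(state, cfg, rng)
    moving = intent.any()
    if not moving:
        ctx = NO_MOVEMENT
    elif user.strategy == "sequential" or state.trial_type != BIMANUAL:
        # context reflects which hand is actually driving
        r_on, l_on = intent[0].any(), intent[1].any()
        ctx = BIMANUAL if (r_on and l_on) else (UNI_RIGHT if r_on else UNI_LEFT)
    else:
        ctx = BIMANUAL
    frames = Frames(intent.reshape(1, 4), np.array([ctx]))
    rates = encode_rates(user.population, frames)[0]
    noisy = np.maximum(rates + user.noise.sigma * rng.standard_normal(rates.shape), 0.0)
    return noisy, intent


# ---------------------------------------------------------------------------
# Task dynamics
# ---------------------------------------------------------------------------


def task_step(
    state: TaskState,
    velocities: np.ndarray,
    assist: AssistConfig | None = None,
    cfg: TaskConfig | None = None,
) -> TaskState:
    """Advance the task one 20-ms bin given decoded (2, 2) cursor velocities.

    Per cursor the decoded velocity is decomposed along/orthogonal to the
    cursor-to-target line; the orthogonal component is attenuated by
    ``1 - error_assist`` and a target-directed push of magnitude
    ``push_assist * |decoded velocity|`` is added.  Locked (inactive) cursors
    do not move.  The shared dwell timer advances only while every required
    cursor is inside its target and resets otherwise; the trial ends on
    acquisition or at the timeout.
    """
    assist = assist or AssistConfig()
    cfg = cfg or TaskConfig()
    if state.done:
        return state
    velocities = np.asarray(velocities, dtype=float).reshape(2, 2)
    if not np.all(np.isfinite(velocities)):
        raise ValueError("decoded velocities must be finite")

    for c in range(2):
        if assist.lock_mode and c not in state.active:
            continue
        v = velocities[c]
        to_t = state.to_target(c)
        dist = np.linalg.norm(to_t)
        if dist > 0:
            u = to_t / dist
            par = (v @ u) * u
            orth = v - par
            v = par + (1.0 - assist.error_assist) * orth
            v = v + assist.push_assist * np.linalg.norm(velocities[c]) * u
        state.pos[c] = np.clip(state.pos[c] + cfg.gain * v * cfg.dt, -cfg.workspace, cfg.workspace)

    state.t_bins += 1
    if cursors_in_target(state, cfg).all():
        state.dwell_bins += 1
    else:
        state.dwell_bins = 0
    if state.dwell_bins >= cfg.dwell_bins:
        state.done = True
        state.success = True
    elif state.t_bins >= cfg.timeout_bins:
        state.done = True
        state.success = False
    return state


def new_trial(
    trial_type: int | str, rng: np.random.Generator, cfg: TaskConfig | None = None
) -> TaskState:
    """Initialize a trial: cursors at the center, targets on wedge directions.

    The inactive cursor of a unimanual trial keeps a target at its start
    position (it must stay put for the trial to succeed).
    """
    cfg = cfg or TaskConfig()
    trial_type = context_code(trial_type)
    pos = np.zeros((2, 2))
    target = np.zeros((2, 2))
    for c in (0, 1):
        ang = rng.uniform(0, 2 * np.pi)
        target[c] = cfg.target_distance * np.array([np.cos(ang), np.sin(ang)])
    if trial_type == UNI_RIGHT:
        target[1] = pos[1]
    elif trial_type == UNI_LEFT:
        target[0] = pos[0]
    return TaskState(pos=pos, target=target, trial_type=trial_type)


# ---------------------------------------------------------------------------
# Trial rollouts and metrics
# ---------------------------------------------------------------------------

ANGULAR_WINDOW = (0.3, 0.5)  # seconds after go: ballistic portion


def trial_metrics(
    decoded: np.ndarray,
    to_target: np.ndarray,
    success: bool,
    n_bins: int,
    window: tuple = ANGULAR_WINDOW,
    dt: float = BIN_S,
) -> dict:
    """TTA (s) and per-hand angular error (deg) over the ballistic window.

    The angular error is the mean absolute angle between the decoded velocity
    (pre-assist) and the cursor-to-target direction within ``window`` after
    the go cue, per cursor.
    """
    lo, hi = (int(round(w / dt)) for w in window)
    if lo >= decoded.shape[0]:
        raise ValueError("angular-error window lies outside the trial")
    hi = min(hi, decoded.shape[0])
    out = {"tta_s": n_bins * dt if success else float("nan"), "success": success}
    for c, hand in ((0, "right"), (1, "left")):
        errs = []
        for t in range(lo, hi):
            v = decoded[t, c]
            u = to_target[t, c]
            nv, nu = np.linalg.norm(v), np.linalg.norm(u)
            if nv > 0 and nu > 0:
                cosang = np.clip(v @ u / (nv * nu), -1, 1)
                errs.append(np.degrees(np.arccos(cosang)))
        out[f"angular_error_{hand}_deg"] = float(np.mean(errs)) if errs else float("nan")
    return out


def run_trials(
    decoder,
    user: SimUser,
    n_trials: int = 20,
    trial_types=(UNI_RIGHT, UNI_LEFT),
    cfg: TaskConfig | None = None,
    assist: AssistConfig | None = None,
    seed: int = 0,
    return_trajectories: bool = False,
    reset_each_trial: bool = False,
):
    """Run closed-loop trials; returns a per-trial results DataFrame.

    ``decoder`` must expose ``reset()`` and ``step(bin_vector, state) ->
    (2, 2) velocities``; wrappers for the package's decoder families are in
    :mod:`bimanual.experiments`.  By default the decoder runs continuously
    across back-to-back trials, as deployed online; ``reset_each_trial``
    restores the offline convention of a fresh decoder state per trial.
    """
    cfg = cfg or TaskConfig()
    assist = assist or AssistConfig()
    rng = np.random.default_rng(seed)
    rows = []
    trajs = []
    decoder.reset()
    for i in range(n_trials):
        ttype = trial_types[i % len(trial_types)]
        state = new_trial(ttype, rng, cfg)
        user.reset()
        if reset_each_trial:
            decoder.reset()
        decoded_hist, to_target_hist, pos_hist = [], [], []
        while not state.done:
            x, _ = user_step(user, state, rng, cfg)
            v = np.asarray(decoder.step(x, state), dtype=float).reshape(2, 2)
            decoded_hist.append(v.copy())
            to_target_hist.append(np.stack([state.to_target(0), state.to_target(1)]))
            task_step(state, v, assist, cfg)
            pos_hist.append(state.pos.copy())
        decoded_hist = np.array(decoded_hist)
        mets = trial_metrics(
            decoded_hist, np.array(to_target_hist), state.success, state.t_bins, dt=cfg.dt
        )
        rows.append(dict(trial=i, type=int(context_code(ttype)), **mets))
        if return_trajectories:
            trajs.append(np.array(pos_hist))
    results = pd.DataFrame(rows)
    if return_trajectories:
        return results, trajs
    return results


def cursor_jitter(velocities: np.ndarray, active_context: np.ndarray) -> dict:
    """Rest-to-move mean speed ratio per cursor.

    ``active_context`` labels which cursor should be active per bin (context
    codes); a cursor's rest bins are those in which the *other* cursor is
    active.
    """
    velocities = np.asarray(velocities, dtype=float)
    active_context = np.asarray(active_context)
    out = {}
    for hand, own, other, sl in (
        ("right", UNI_RIGHT, UNI_LEFT, slice(0, 2)),
        ("left", UNI_LEFT, UNI_RIGHT, slice(2, 4)),
    ):
        speed = np.linalg.norm(velocities[:, sl], axis=1)
        move = active_context == own
        rest = active_context == other
        if not move.any():
            raise ValueError(f"no movement bins for {hand} cursor")
        move_speed = float(speed[move].mean())
        rest_speed = float(speed[rest].mean()) if rest.any() else 0.0
        out[hand] = rest_speed / move_speed if move_speed > 0 else float("nan")
    return out
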
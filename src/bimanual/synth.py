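"""Synthetic motor-cortical populations and delayed-movement sessions.

The generator emulates multiunit threshold-crossing activity recorded while a
participant attempts unimanual or bimanual cursor movements.  Each channel's
firing rate is a linear function of the intended velocity of each hand,

    f = b0 + b_rx d_rx + b_ry d_ry + b_lx d_lx + b_ly d_ly + b_lat c_lat,

where ``d`` is the intended (unit) velocity of the right/left hand and
``c_lat`` is a direction-independent laterality code (+1 for unimanual right,
-1 for unimanual left).  Tuning coefficients may differ between the unimanual
and bimanual movement contexts (suppression and decorrelation of the left
hand), and i.i.d. Gaussian noise with a single shared standard deviation is
added per channel per 20-ms bin, with negative rates clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Global constants / configuration defaults
# ---------------------------------------------------------------------------

BIN_S = 0.02  # 20-ms bins everywhere

UNI_RIGHT = 0
UNI_LEFT = 1
BIMANUAL = 2
NO_MOVEMENT = 3

CONTEXT_NAMES = ("unimanual_right", "unimanual_left", "bimanual", "no_movement")
CONTEXT_CODES = {name: i for i, name in enumerate(CONTEXT_NAMES)}

#: predictor column order used throughout the package
VEL_COLUMNS = ("rx", "ry", "lx", "ly")

N_WEDGES = 8  # movement-direction wedges tiling the unit circle


def context_code(context: int | str) -> int:
    """Normalize a context given as name or integer code."""
    if isinstance(context, str):
        try:
            return CONTEXT_CODES[context]
        except KeyError:
            raise ValueError(f"unknown context {context!r}") from None
    if context not in (UNI_RIGHT, UNI_LEFT, BIMANUAL, NO_MOVEMENT):
        raise ValueError(f"unknown context code {context}")
    return int(context)


def laterality_code(context: int | str, bimanual_c_lat: float = 1.0) -> float:
    """c_lat convention: +1 unimanual right, -1 unimanual left.

    The code is only defined by the task for unimanual movement; for bimanual
    bins we default to +1 (bimanual population activity most closely resembles
    unimanual-right activity) and 0 for no-movement.  The bimanual value is
    configurable.
    """
    c = context_code(context)
    if c == UNI_RIGHT:
        return 1.0
    if c == UNI_LEFT:
        return -1.0
    if c == BIMANUAL:
        return float(bimanual_c_lat)
    return 0.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SimPopulation:
    """Encoding coefficients for a simulated population of channels.

    ``tuning_uni``/``tuning_bi`` are (n_channels, 4) arrays with columns in
    :data:`VEL_COLUMNS` order, in Hz per unit velocity.  ``laterality`` is the
    per-channel coefficient of the laterality code.
    """

    n_channels: int
    baseline: np.ndarray
    tuning_uni: np.ndarray
    tuning_bi: np.ndarray
    laterality: np.ndarray
    rho_x: float
    rho_y: float
    lat_scale: float
    seed: int
    bimanual_c_lat: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline", "tuning_uni", "tuning_bi", "laterality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[0] != self.n_channels:
                raise ValueError(f"{name} must have length n_channels")

    def coefficients(self, context: int | str) -> np.ndarray:
        """(n_channels, 4) directional coefficients active in ``context``."""
        c = context_code(context)
        if c == BIMANUAL:
            return self.tuning_bi
        return self.tuning_uni

    def column(self, name: str, context: int | str = UNI_RIGHT) -> np.ndarray:
        return self.coefficients(context)[:, VEL_COLUMNS.index(name)]


@dataclass
class KinematicFrame:
    """Intended kinematics for a single 20-ms bin."""

    d_rx: float = 0.0
    d_ry: float = 0.0
    d_lx: float = 0.0
    d_ly: float = 0.0
    context: int | str = NO_MOVEMENT
    p_target: np.ndarray | None = None
    p_cursor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.context = context_code(self.context)
        if self.context == UNI_RIGHT and (self.d_lx or self.d_ly):
            raise ValueError("unimanual_right frame must have zero left-hand velocity")
        if self.context == UNI_LEFT and (self.d_rx or self.d_ry):
            raise ValueError("unimanual_left frame must have zero right-hand velocity")
        if self.context == NO_MOVEMENT and any(
            (self.d_rx, self.d_ry, self.d_lx, self.d_ly)
        ):
            raise ValueError("no_movement frame must have zero velocity")

    @property
    def d(self) -> np.ndarray:
        return np.array([self.d_rx, self.d_ry, self.d_lx, self.d_ly])


class Frames:
    """Vectorized sequence of kinematic frames (bins x 4 velocities, context)."""

    def __init__(self, d: np.ndarray, context: np.ndarray):
        self.d = np.asarray(d, dtype=float)
        self.context = np.asarray(context, dtype=np.int8)
        if self.d.ndim != 2 or self.d.shape[1] != 4:
            raise ValueError("d must be (bins, 4)")
        if self.context.shape != (self.d.shape[0],):
            raise ValueError("context must be (bins,)")

    def __len__(self) -> int:
        return self.d.shape[0]

    @classmethod
    def from_list(cls, frames) -> "Frames":
        frames = list(frames)
        d = np.array([f.d for f in frames]) if frames else np.zeros((0, 4))
        ctx = np.array([f.context for f in frames], dtype=np.int8)
        return cls(d, ctx)

    def frame(self, i: int) -> KinematicFrame:
        return KinematicFrame(*self.d[i], context=int(self.context[i]))


@dataclass
class NoiseModel:
    """Shared-scalar diagonal Gaussian noise on binned firing rates."""

    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError("sigma must be finite and >= 0")

    def covariance(self, n: int) -> np.ndarray:
        return np.eye(n) * self.sigma**2


@dataclass
class SessionData:
    """A binned session: rates tensor, per-bin labels, per-trial table.

    ``trial_table`` columns: trial, type (context code), wedge_r, wedge_l,
    start, go, move_end, end (bin indices; delay = [start, go), move =
    [go, move_end), idle = [move_end, end)).
    """

    rates: np.ndarray  # (bins, channels)
    labels: Frames
    trial_table: pd.DataFrame
    target_vel: np.ndarray | None = None  # (bins, 4) training velocity targets
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape[0] != len(self.labels):
            raise ValueError("rates and labels must align")

    @property
    def n_bins(self) -> int:
        return self.rates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.rates.shape[1]

    def copy_with(self, **kw) -> "SessionData":
        defaults = dict(
            rates=self.rates,
            labels=self.labels,
            trial_table=self.trial_table,
            target_vel=self.target_vel,
            preprocessing=dict(self.preprocessing),
        )
        defaults.update(kw)
        return SessionData(**defaults)

    def trials(self, context: int | str | None = None) -> pd.DataFrame:
        if context is None:
            return self.trial_table
        return self.trial_table[self.trial_table["type"] == context_code(context)]

    def move_window_bins(self, row, window=(0.3, 0.7)) -> np.ndarray:
        """Bin indices of the analysis window relative to the go cue."""
        lo = int(row.go + round(window[0] / BIN_S))
        hi = int(row.go + round(window[1] / BIN_S))
        hi = min(hi, int(row.end))
        return np.arange(lo, hi)

    # -- persistence -------------------------------------------------------

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("rates", data=self.rates.astype(np.float32))
            g = f.create_group("labels")
            g.create_dataset("d", data=self.labels.d)
            g.create_dataset("context", data=self.labels.context)
            if self.target_vel is not None:
                f.create_dataset("target_vel", data=self.target_vel)
            rec = self.trial_table.to_records(index=False)
            f.create_dataset("trials", data=rec)
            for k, v in self.preprocessing.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path: str) -> "SessionData":
        with h5py.File(path, "r") as f:
            rates = f["rates"][:]
            labels = Frames(f["labels/d"][:], f["labels/context"][:])
            tv = f["target_vel"][:] if "target_vel" in f else None
            trials = pd.DataFrame.from_records(f["trials"][:])
            pre = dict(f.attrs)
        return cls(rates, labels, trials, target_vel=tv, preprocessing=pre)

    def trial_table_csv(self, path: str) -> None:
        self.trial_table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        return v
    return v / n


def _mixed_vector(
    ref: np.ndarray, rho: float, rng: np.random.Generator, norm: float, exact: bool
) -> np.ndarray:
    """Vector with (approximate) correlation ``rho`` to ``ref`` and given norm."""
    w = rng.standard_normal(ref.shape[0])
    if exact:
        # enforce the cosine on mean-centered components exactly
        ref_c = ref - ref.mean()
        w_c = w - w.mean()
        w_c -= _unit(ref_c) * (w_c @ _unit(ref_c))
        v = rho * _unit(ref_c) + np.sqrt(max(0.0, 1 - rho**2)) * _unit(w_c)
    else:
        v = rho * _unit(ref) + np.sqrt(max(0.0, 1 - rho**2)) * _unit(w)
    return _unit(v) * norm


def sample_population(
    n_channels: int = 192,
    rho_x: float = 0.5,
    rho_y: float = 0.5,
    lat_scale: float = 1.0,
    magnitudes: float | dict | None = None,
    suppression: tuple[float, float] = (1.0, 0.66),
    seed: int = 0,
    context_correlation: tuple[float, float] | None = (0.85, 0.45),
    baseline_range: tuple[float, float] = (5.0, 50.0),
    bimanual_c_lat: float = 1.0,
    exact_correlation: bool = False,
) -> SimPopulation:
    """Sample a population of linearly tuned channels.

    Directional coefficients are drawn from a standard normal per channel and
    rescaled so each coefficient column has the requested norm.  Left-hand
    columns are built as ``rho * right + sqrt(1 - rho^2) * independent`` (then
    rescaled), enforcing an inter-hand tuning correlation of about ``rho``.
    Bimanual coefficients are the unimanual columns scaled by the per-hand
    ``suppression`` factors (right, left); when ``context_correlation`` is
    given the bimanual columns are additionally re-mixed with an independent
    draw to hit the requested unimanual-to-bimanual tuning correlation per hand
    (tuning-axis change, i.e. decorrelation).  The laterality column norm is
    ``lat_scale`` times the mean directional column norm.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    for rho in (rho_x, rho_y):
        if not np.isfinite(rho) or abs(rho) > 1:
            raise ValueError("|rho| must be <= 1 and finite")
    if not np.isfinite(lat_scale) or lat_scale < 0:
        raise ValueError("lat_scale must be finite and >= 0")
    if len(suppression) != 2 or any(s < 0 or not np.isfinite(s) for s in suppression):
        raise ValueError("suppression must be two finite non-negative factors")

    if magnitudes is None:
        # unit per-channel RMS tuning (1 Hz per unit velocity)
        magnitudes = float(np.sqrt(n_channels))
    if np.isscalar(magnitudes):
        magnitudes = {c: float(magnitudes) for c in VEL_COLUMNS}
    if any(m <= 0 or not np.isfinite(m) for m in magnitudes.values()):
        raise ValueError("magnitudes must be positive and finite")

    rng = np.random.default_rng(seed)
    uni = np.zeros((n_channels, 4))
    uni[:, 0] = _unit(rng.standard_normal(n_channels)) * magnitudes["rx"]
    uni[:, 1] = _unit(rng.standard_normal(n_channels)) * magnitudes["ry"]
    uni[:, 2] = _mixed_vector(uni[:, 0], rho_x, rng, magnitudes["lx"], exact_correlation)
    uni[:, 3] = _mixed_vector(uni[:, 1], rho_y, rng, magnitudes["ly"], exact_correlation)

    ref_norm = float(np.mean([np.linalg.norm(uni[:, j]) for j in range(4)]))
    if lat_scale == 0:
        lat = np.zeros(n_channels)
    else:
        lat = _unit(rng.standard_normal(n_channels)) * (lat_scale * ref_norm)

    sup_r, sup_l = suppression
    bi = np.zeros_like(uni)
    for j, col in enumerate(VEL_COLUMNS):
        hand_right = col.startswith("r")
        s = sup_r if hand_right else sup_l
        target_norm = s * np.linalg.norm(uni[:, j])
        if context_correlation is None:
            bi[:, j] = uni[:, j] * s
        else:
            rho_ctx = context_correlation[0] if hand_right else context_correlation[1]
            bi[:, j] = _mixed_vector(
                uni[:, j], rho_ctx, rng, target_norm, exact_correlation
            )

    baseline = rng.uniform(*baseline_range, size=n_channels)
    return SimPopulation(
        n_channels=n_channels,
        baseline=baseline,
        tuning_uni=uni,
        tuning_bi=bi,
        laterality=lat,
        rho_x=rho_x,
        rho_y=rho_y,
        lat_scale=lat_scale,
        seed=seed,
        bimanual_c_lat=bimanual_c_lat,
    )


# ---------------------------------------------------------------------------
# Rate encoding and noise
# ---------------------------------------------------------------------------


def encode_rates(pop: SimPopulation, frames) -> np.ndarray:
    """Noiseless firing rates (bins x channels) for a sequence of frames."""
    if not isinstance(frames, Frames):
        frames = Frames.from_list(frames)
    rates = np.tile(pop.baseline, (len(frames), 1))
    c_lat = np.array(
        [laterality_code(int(c), pop.bimanual_c_lat) for c in frames.context]
    )
    bi_mask = frames.context == BIMANUAL
    # directional term, context-appropriate coefficients
    rates += frames.d @ pop.tuning_uni.T
    if bi_mask.any():
        rates[bi_mask] = (
            pop.baseline + frames.d[bi_mask] @ pop.tuning_bi.T
        )
    rates += np.outer(c_lat, pop.laterality)
    return rates


def add_noise_and_clip(
    rates: np.ndarray, noise: NoiseModel, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Add i.i.d. Gaussian noise per bin per channel; clip rates at zero."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = rates + noise.sigma * rng.standard_normal(rates.shape)
    return np.maximum(noisy, 0.0)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _wedge_directions(n_trials: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Balanced wedge assignments and uniform unit vectors within each wedge."""
    base = n_trials // N_WEDGES
    counts = np.full(N_WEDGES, base)
    counts[: n_trials - base * N_WEDGES] += 1
    wedges = np.repeat(np.arange(N_WEDGES), counts)
    rng.shuffle(wedges)
    width = 2 * np.pi / N_WEDGES
    angles = wedges * width + rng.uniform(0, width, size=n_trials)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    return wedges, dirs


def generate_unimanual_dataset(
    pop: SimPopulation,
    n_per_hand: int = 2000,
    trial_len: float = 0.4,
    seed: int = 0,
) -> SessionData:
    """Movement-window-only unimanual trials (default 400 ms / 20 bins each).

    Each trial's intended velocity is a uniformly random unit vector inside its
    assigned direction wedge, balanced across the 8 wedges per hand, constant
    over the trial.  Rates are noiseless encoder outputs.
    """
    if n_per_hand < N_WEDGES:
        raise ValueError("n_per_hand must be >= 8 to balance direction wedges")
    rng = np.random.default_rng(seed)
    bins_per_trial = int(round(trial_len / BIN_S))

    wr, dr = _wedge_directions(n_per_hand, rng)
    wl, dl = _wedge_directions(n_per_hand, rng)

    types = np.array([UNI_RIGHT] * n_per_hand + [UNI_LEFT] * n_per_hand, dtype=np.int8)
    wedge_r = np.concatenate([wr, np.full(n_per_hand, -1)])
    wedge_l = np.concatenate([np.full(n_per_hand, -1), wl])
    d4 = np.zeros((2 * n_per_hand, 4))
    d4[:n_per_hand, :2] = dr
    d4[n_per_hand:, 2:] = dl

    order = rng.permutation(2 * n_per_hand)
    types, wedge_r, wedge_l, d4 = types[order], wedge_r[order], wedge_l[order], d4[order]

    n_trials = 2 * n_per_hand
    d = np.repeat(d4, bins_per_trial, axis=0)
    ctx = np.repeat(types, bins_per_trial)
    frames = Frames(d, ctx)
    rates = encode_rates(pop, frames)

    starts = np.arange(n_trials) * bins_per_trial
    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "type": types,
            "wedge_r": wedge_r,
            "wedge_l": wedge_l,
            "start": starts,
            # movement-only trials: the whole trial is the move epoch
            "go": starts - int(round(0.3 / BIN_S)),
            "move_end": starts + bins_per_trial,
            "end": starts + bins_per_trial,
        }
    )
    return SessionData(
        rates, frames, table, target_vel=d.copy(), preprocessing={"block_means_removed": False, "zscored": False}
    )


def generate_session(
    pop: SimPopulation,
    n_per_type: int = 40,
    types: tuple = (UNI_RIGHT, UNI_LEFT),
    delay_range: tuple[float, float] = (1.0, 2.0),
    move_range: tuple[float, float] = (1.0, 2.0),
    idle_s: float = 1.0,
    reaction_s: float = 0.2,
    seed: int = 0,
    noise: NoiseModel | None = None,
) -> SessionData:
    """Delayed-movement session: delay (1-2 s) / move (1-2 s) / idle per trial.

    During the move epoch (after a reaction lag) the intended velocity is the
    unit vector pointing from the cursor to the target, constant per trial.
    ``target_vel`` holds the saturated velocity-profile training targets; the
    encoded drive is the unit direction itself.  Delay and idle bins carry
    no-movement context (baseline rates).
    """
    rng = np.random.default_rng(seed)
    types = [context_code(t) for t in types]
    trial_types = np.repeat(np.array(types, dtype=np.int8), n_per_type)
    rng.shuffle(trial_types)
    n_trials = trial_types.size

    wedges_r, dirs_r = _wedge_directions(n_trials, rng)
    wedges_l, dirs_l = _wedge_directions(n_trials, rng)

    d_list, ctx_list, tv_list = [], [], []
    rows = []
    cursor = 0
    react_bins = int(round(reaction_s / BIN_S))
    for i in range(n_trials):
        t = int(trial_types[i])
        delay_b = int(round(rng.uniform(*delay_range) / BIN_S))
        move_b = int(round(rng.uniform(*move_range) / BIN_S))
        idle_b = int(round(idle_s / BIN_S))
        total = delay_b + move_b + idle_b

        d = np.zeros((total, 4))
        tv = np.zeros((total, 4))
        ctx = np.full(total, NO_MOVEMENT, dtype=np.int8)
        ctx[delay_b : delay_b + move_b] = t

        _, sat = kinematic_profiles(
            distance=1.0, move_duration=move_b * BIN_S, reaction_time=reaction_s
        )
        active = np.zeros(move_b)
        active[react_bins:] = 1.0
        use_r = t in (UNI_RIGHT, BIMANUAL)
        use_l = t in (UNI_LEFT, BIMANUAL)
        if use_r:
            d[delay_b : delay_b + move_b, :2] = np.outer(active, dirs_r[i])
            tv[delay_b : delay_b + move_b, :2] = np.outer(sat, dirs_r[i])
        if use_l:
            d[delay_b : delay_b + move_b, 2:] = np.outer(active, dirs_l[i])
            tv[delay_b : delay_b + move_b, 2:] = np.outer(sat, dirs_l[i])

        rows.append(
            dict(
                trial=i,
                type=t,
                wedge_r=wedges_r[i] if use_r else -1,
                wedge_l=wedges_l[i] if use_l else -1,
                start=cursor,
                go=cursor + delay_b,
                move_end=cursor + delay_b + move_b,
                end=cursor + total,
            )
        )
        d_list.append(d)
        ctx_list.append(ctx)
        tv_list.append(tv)
        cursor += total

    frames = Frames(np.concatenate(d_list), np.concatenate(ctx_list))
    rates = encode_rates(pop, frames)
    if noise is not None and noise.sigma > 0:
        rates = add_noise_and_clip(rates, noise, rng)
    return SessionData(
        rates,
        frames,
        pd.DataFrame(rows),
        target_vel=np.concatenate(tv_list),
        preprocessing={"block_means_removed": False, "zscored": False},
    )


# ---------------------------------------------------------------------------
# Functional SNR
# ---------------------------------------------------------------------------


def estimate_fsnr(decoded: np.ndarray, pointing: np.ndarray) -> float:
    """Functional SNR of decoder output against point-at-target intention.

    Fits ``decoded = D @ pointing + eps`` by least squares (D is 2x2) and
    returns ``(D11 + D22) / 2`` divided by the residual standard deviation
    averaged over both dimensions.  Zero residual returns ``inf``.
    """
    decoded = np.asarray(decoded, dtype=float)
    pointing = np.asarray(pointing, dtype=float)
    if decoded.shape != pointing.shape or decoded.ndim != 2 or decoded.shape[1] != 2:
        raise ValueError("decoded and pointing must both be (n, 2)")
    if decoded.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if np.linalg.matrix_rank(pointing) < 2:
        raise ValueError("pointing sequence is degenerate (rank < 2)")
    D, *_ = np.linalg.lstsq(pointing, decoded, rcond=None)
    D = D.T  # decoded ~ D @ pointing
    resid = decoded - pointing @ D.T
    sigma = float(np.mean(resid.std(axis=0, ddof=0)))
    gain = float((D[0, 0] + D[1, 1]) / 2)
    scale = float(decoded.std()) or 1.0
    if sigma <= 1e-12 * scale:  # exact fit up to float error
        return float("inf") if gain != 0 else 0.0
    return gain / sigma


def _cv_linear_decode(rates: np.ndarray, targets: np.ndarray, k: int = 5) -> np.ndarray:
    """Held-out OLS predictions of targets from rates (contiguous k folds)."""
    n = rates.shape[0]
    X = np.column_stack([np.ones(n), rates])
    preds = np.zeros_like(targets, dtype=float)
    bounds = np.linspace(0, n, k + 1).astype(int)
    for i in range(k):
        test = np.zeros(n, dtype=bool)
        test[bounds[i] : bounds[i + 1]] = True
        W, *_ = np.linalg.lstsq(X[~test], targets[~test], rcond=None)
        preds[test] = X[test] @ W
    return preds


def measure_fsnr(session: SessionData, k: int = 5) -> dict:
    """Per-hand fSNR of a cross-validated linear decode of a unimanual session."""
    rates = session.rates - session.rates.mean(axis=0)
    d = session.labels.d
    move = d.any(axis=1)
    preds = _cv_linear_decode(rates[move], d[move], k=k)
    ctx = session.labels.context[move]
    out = {}
    for hand, code, sl in (("right", UNI_RIGHT, slice(0, 2)), ("left", UNI_LEFT, slice(2, 4))):
        mask = ctx == code
        if mask.sum() >= 4:
            out[hand] = estimate_fsnr(preds[mask, sl], d[move][mask, sl])
    return out


def calibrate_sigma(
    pop: SimPopulation,
    dataset: SessionData,
    target_fsnr: float | tuple[float, float] = 1.5,
    tol: float = 0.05,
    sigma_bounds: tuple[float, float] = (1e-4, 200.0),
    seed: int = 0,
    max_iter: int = 60,
) -> NoiseModel:
    """Bisect the shared noise standard deviation to match a target fSNR.

    The same standard-normal draw is reused at every candidate sigma so the
    measured fSNR is a smooth, monotone-decreasing function of sigma; the
    objective is the mean fSNR across hands against the mean target.
    """
    if np.isscalar(target_fsnr):
        target = float(target_fsnr)
    else:
        target = float(np.mean(target_fsnr))
    if target <= 0:
        raise ValueError("target_fsnr must be > 0")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(dataset.rates.shape)

    def fsnr_at(sigma: float) -> float:
        noisy = np.maximum(dataset.rates + sigma * eps, 0.0)
        vals = measure_fsnr(dataset.copy_with(rates=noisy))
        return float(np.mean(list(vals.values())))

    lo, hi = sigma_bounds
    f_lo, f_hi = fsnr_at(lo), fsnr_at(hi)
    if f_lo < target or f_hi > target:
        raise ValueError(
            f"target fSNR {target:g} unreachable: achieved bracket "
            f"[{f_hi:.3g} at sigma={hi:g}, {f_lo:.3g} at sigma={lo:g}]"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection: fSNR ~ 1/sigma
        f_mid = fsnr_at(mid)
        if abs(f_mid - target) <= tol:
            return NoiseModel(sigma=float(mid))
        if f_mid > target:
            lo = mid
        else:
            hi = mid
    return NoiseModel(sigma=float(np.sqrt(lo * hi)))


# ---------------------------------------------------------------------------
# Kinematic velocity profiles
# ---------------------------------------------------------------------------


def kinematic_profiles(
    distance: float,
    move_duration: float,
    reaction_time: float = 0.2,
    bin_s: float = BIN_S,
    taper_fraction: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk and saturated speed profiles over the move epoch.

    The minimum-jerk profile follows the fifth-order polynomial position
    ``10 tau^3 - 15 tau^4 + 6 tau^5`` (peak speed 1.875 * distance /
    move_duration at tau = 0.5).  The saturated profile is zero during the
    reaction time, then constant at maximum speed until the remaining distance
    falls below ``taper_fraction`` of the total, then tapers linearly to zero.
    Both discrete profiles displace the cursor by exactly ``distance``
    (speeds are average speeds over each bin).
    """
    if move_duration <= 0 or bin_s <= 0:
        raise ValueError("durations must be positive")
    if not 0 <= reaction_time < move_duration:
        raise ValueError("reaction_time must be in [0, move_duration)")
    n = int(round(move_duration / bin_s))
    edges = np.linspace(0.0, 1.0, n + 1)

    def mj_pos(tau):
        return distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)

    minjerk = np.diff(mj_pos(edges)) / bin_s

    # saturated: plateau speed v such that v*(A - t_tap/2) = distance with the
    # taper covering the last taper_fraction of the distance
    t = edges[:-1] * move_duration
    active = move_duration - reaction_time
    v_max = (1 + taper_fraction) * distance / active
    t_tap = 2 * taper_fraction * distance / v_max
    t_tap_start = move_duration - t_tap

    def sat_pos(tt):
        tt = np.asarray(tt, dtype=float)
        out = np.zeros_like(tt)
        ramp = (tt > reaction_time) & (tt <= t_tap_start)
        out[ramp] = v_max * (tt[ramp] - reaction_time)
        tap = tt > t_tap_start
        dt_ = np.minimum(tt[tap] - t_tap_start, t_tap)
        out[tap] = v_max * (t_tap_start - reaction_time) + v_max * dt_ - v_max * dt_**2 / (2 * t_tap)
        return out

    saturated = np.diff(sat_pos(edges * move_duration)) / bin_s
    return minjerk, saturated
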
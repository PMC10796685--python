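"""End-to-end experiment runners.

Ties the pipeline together: the simulation sweep over inter-hand tuning
correlation and laterality-dimension size (ridge vs feed-forward decoding and
cursor jitter), the augmentation comparison (recurrent decoders trained on
stereotyped vs time-dilated/shuffled snippets, evaluated offline and in the
simulated closed loop), and a best-effort reanalysis hook for a locally
downloaded copy of the deposited dataset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import augment, closedloop, decoders, synth, tuning
from .synth import BIMANUAL, NO_MOVEMENT, UNI_LEFT, UNI_RIGHT


@dataclass
class SweepGrid:
    """Grid of inter-hand correlations and laterality sizes (our choice of
    values; the default mirrors the qualitative span of the published sweep)."""

    rho: tuple = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)
    lat_scale: tuple = (0.0, 0.25, 0.5, 1.0)
    seeds: tuple = (0,)


@dataclass
class SweepCellConfig:
    n_channels: int = 192
    n_per_hand: int = 2000
    calib_n_per_hand: int = 400  # smaller matched dataset for noise calibration
    fsnr_target: float = 1.5
    test_fraction: float = 0.2
    k: int = 5
    ffn: decoders.FfnConfig = field(default_factory=decoders.FfnConfig)
    alpha_grid: tuple = tuple(np.logspace(-1, 5, 9))
    remove_laterality: bool = False
    train_ffn: bool = True
    train_ridge: bool = True


def _train_test_split_trials(session, test_fraction, rng):
    table = session.trial_table
    test_trials = []
    for t, group in table.groupby("type"):
        ids = group["trial"].to_numpy()
        ids = rng.permutation(ids)
        test_trials.extend(ids[: int(round(test_fraction * len(ids)))].tolist())
    test_set = set(test_trials)
    bin_trial = np.repeat(
        table["trial"].to_numpy(), (table["end"] - table["start"]).to_numpy()
    )
    test_mask = np.isin(bin_trial, list(test_set))
    return ~test_mask, test_mask, bin_trial


def run_sweep_cell(
    rho: float, lat_scale: float, seed: int = 0, config: SweepCellConfig | None = None
) -> dict:
    """One simulation cell: generate, calibrate noise, decode with both models.

    Returns held-out Pearson r (mean over the active hand's dimensions per
    hand) and left/right cursor jitter for the ridge and feed-forward
    decoders trained on matched data and folds.
    """
    config = config or SweepCellConfig()
    pop = synth.sample_population(
        n_channels=config.n_channels,
        rho_x=rho,
        rho_y=rho,
        lat_scale=lat_scale,
        suppression=(1.0, 1.0),
        context_correlation=None,
        seed=seed,
    )
    session = synth.generate_unimanual_dataset(pop, n_per_hand=config.n_per_hand, seed=seed + 1)
    # the fSNR depends on the population and noise, not the dataset length,
    # so calibrate on a smaller matched dataset for speed
    calib = (
        session
        if config.calib_n_per_hand >= config.n_per_hand
        else synth.generate_unimanual_dataset(pop, n_per_hand=config.calib_n_per_hand, seed=seed + 1)
    )
    noise = synth.calibrate_sigma(pop, calib, target_fsnr=config.fsnr_target, seed=seed + 2)
    rates = synth.add_noise_and_clip(session.rates, noise, seed=seed + 3)
    session = session.copy_with(rates=rates)
    session = tuning.preprocess(session, remove_block_means=True)
    if config.remove_laterality:
        session = tuning.remove_laterality(session, k=config.k)

    rng = np.random.default_rng(seed + 4)
    train_mask, test_mask, bin_trial = _train_test_split_trials(
        session, config.test_fraction, rng
    )
    sd = session.rates[train_mask].std(axis=0)
    sd[sd == 0] = 1.0
    X, Y = session.rates / sd, session.labels.d
    ctx = session.labels.context
    fold_ids = decoders.stratified_bin_folds(ctx[train_mask], bin_trial[train_mask], config.k)

    models = []
    if config.train_ridge:
        models.append(
            (
                "ridge",
                decoders.train_ridge(
                    X[train_mask],
                    Y[train_mask],
                    alpha_grid=config.alpha_grid,
                    k=config.k,
                    fold_ids=fold_ids,
                ),
            )
        )
    if config.train_ffn:
        models.append(
            ("ffn", decoders.train_ffn(X[train_mask], Y[train_mask], replace(config.ffn, seed=seed)))
        )

    out = dict(rho=rho, lat_scale=lat_scale, seed=seed, sigma=noise.sigma)
    for name, model in models:
        preds, r = decoders.decode_offline(model, X[test_mask], Y[test_mask])
        jitter = closedloop.cursor_jitter(preds, ctx[test_mask])
        out[f"{name}_r"] = float(np.nanmean(r))
        out[f"{name}_r_right"] = float(np.nanmean(r[:2]))
        out[f"{name}_r_left"] = float(np.nanmean(r[2:]))
        out[f"{name}_jitter_right"] = jitter["right"]
        out[f"{name}_jitter_left"] = jitter["left"]
        out[f"{name}_jitter"] = float(np.mean([jitter["right"], jitter["left"]]))
    return out


def run_fig3_sweep(
    grid: SweepGrid | None = None, config: SweepCellConfig | None = None
) -> pd.DataFrame:
    """Full decoding sweep over (rho, lat_scale, seed); one row per cell."""
    grid = grid or SweepGrid()
    rows = []
    for rho in grid.rho:
        for lat in grid.lat_scale:
            for seed in grid.seeds:
                try:
                    rows.append(run_sweep_cell(rho, lat, seed, config))
                except Exception as e:  # propagate with cell coordinates
                    raise RuntimeError(
                        f"sweep cell failed at rho={rho}, lat_scale={lat}, seed={seed}"
                    ) from e
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Augmentation comparison (raw vs altered training data)
# ---------------------------------------------------------------------------


@dataclass
class AugmentationComparisonConfig:
    """Desk-scale raw-vs-altered training comparison.

    The source session and the closed-loop task both include unimanual and
    bimanual trials (as run online); the stereotyped decoder's failure mode
    online is concentrated in bimanual trials, where mid-trial context
    transitions (one cursor acquired while the other still moves) never occur
    in delay/move/idle training blocks.
    """

    n_channels: int = 64
    n_per_type: int = 40
    trial_types: tuple = (UNI_RIGHT, UNI_LEFT, BIMANUAL)
    fsnr_target: float = 1.5
    lat_scale: float = 1.0
    rho: float = 0.5
    snippet_len: int = 250  # desk scale: 5-s snippets
    n_snippets: int = 200
    validation_fraction: float = 0.15
    rnn: decoders.RnnConfig = field(
        default_factory=lambda: decoders.RnnConfig(hidden=128, n_batches=1000)
    )
    n_closedloop_trials: int = 24
    gain: float = 1.0


def _zscore_stream(stream: augment.LabeledStream, mean=None, sd=None):
    if mean is None:
        mean = stream.inputs.mean(axis=0)
        sd = stream.inputs.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    z = augment.LabeledStream(
        (stream.inputs - mean) / sd, stream.outputs, stream.condition, stream.trial_ids
    )
    return z, mean, sd


class _RnnClosedLoopDecoder:
    """Adapter running an RnnModel one bin at a time with stored z-scoring."""

    def __init__(self, model, mean, sd, day="day0"):
        self.model = model
        self.mean, self.sd = mean, sd
        self.day = day
        self.state = None

    def reset(self):
        self.state = self.model.initial_state(1)

    def step(self, x, task_state):
        xz = (x - self.mean) / self.sd
        v, _, self.state = decoders.rnn_step(self.model, xz, self.state, self.day)
        return v.reshape(2, 2)


def run_augmentation_comparison(
    config: AugmentationComparisonConfig | None = None, seed: int = 0
) -> dict:
    """Train rawRNN (stereotyped snippets) and altRNN (augmented snippets) on
    the same source session; report offline held-out r and simulated
    closed-loop performance for both.  Bit-reproducible at fixed seed."""
    config = config or AugmentationComparisonConfig()
    pop = synth.sample_population(
        n_channels=config.n_channels,
        rho_x=config.rho,
        rho_y=config.rho,
        lat_scale=config.lat_scale,
        suppression=(1.0, 1.0),
        context_correlation=None,
        seed=seed,
    )
    # calibrate noise on a movement-only dataset, then generate the session
    calib = synth.generate_unimanual_dataset(pop, n_per_hand=200, seed=seed + 1)
    noise = synth.calibrate_sigma(pop, calib, target_fsnr=config.fsnr_target, seed=seed + 2)
    session = synth.generate_session(
        pop, n_per_type=config.n_per_type, types=config.trial_types, seed=seed + 3, noise=noise
    )
    stream = augment.label_stream(session)
    train_stream, val_stream = augment.split_pools(stream, config.validation_fraction, seed=seed + 4)
    train_z, mean, sd = _zscore_stream(train_stream)
    val_z, _, _ = _zscore_stream(val_stream, mean, sd)

    raw_set = augment.stereotyped_snippets(train_z, config.snippet_len)
    alt_set = augment.assemble_snippets(
        train_z, n_snippets=config.n_snippets, snippet_len=config.snippet_len, seed=seed + 5
    )
    raw_rnn = decoders.train_rnn(raw_set, replace(config.rnn, seed=seed + 6))
    alt_rnn = decoders.train_rnn(alt_set, replace(config.rnn, seed=seed + 6))

    report = {"seed": seed}
    for name, model in (("raw", raw_rnn), ("alt", alt_rnn)):
        preds, r = decoders.decode_offline(model, val_z.inputs, val_z.outputs[:, :4])
        report[f"{name}_offline_r"] = float(np.nanmean(r))
        user = closedloop.SimUser(population=pop, noise=noise)
        dec = _RnnClosedLoopDecoder(model, mean, sd)
        results = closedloop.run_trials(
            dec,
            user,
            n_trials=config.n_closedloop_trials,
            trial_types=config.trial_types,
            cfg=closedloop.TaskConfig(gain=config.gain),
            seed=seed + 7,
        )
        report[f"{name}_success_rate"] = float(results["success"].mean())
        report[f"{name}_mean_tta_s"] = float(
            results["tta_s"].fillna(closedloop.TaskConfig().timeout_s).mean()
        )
        report[f"{name}_trials"] = results
    return report


# ---------------------------------------------------------------------------
# Reanalysis hook for the deposited dataset
# ---------------------------------------------------------------------------

EXPECTED_LAYOUT = (
    "expected a directory of per-session HDF5 files (*.h5), each containing "
    "/rates (bins x channels, 20-ms bins), /labels/d, /labels/context and a "
    "/trials table as written by SessionData.to_hdf5"
)


def tuning_report(session: synth.SessionData, k: int = 5) -> dict:
    """Suppression, context correlation and dPCA statistics for one session."""
    session = tuning.preprocess(session, remove_block_means=True)
    out = {}
    has_bi = (session.trial_table["type"] == BIMANUAL).any()
    uni_r = tuning.fit_encoding_cv(session, UNI_RIGHT, k=k)
    uni_l = tuning.fit_encoding_cv(session, UNI_LEFT, k=k)
    if has_bi:
        bi = tuning.fit_encoding_cv(session, BIMANUAL, k=k)
        out["suppression_right"] = tuning.suppression_ratio(bi, uni_r, "right")
        out["suppression_left"] = tuning.suppression_ratio(bi, uni_l, "left")
        for col, fit in (("rx", uni_r), ("ry", uni_r), ("lx", uni_l), ("ly", uni_l)):
            _, corr = tuning.cv_vector_stats(fit, bi, col)
            out[f"context_corr_{col}"] = corr
    mv = tuning.dpca_marginal_variance(session)
    for f, v in mv.fraction.items():
        out[f"dpca_fraction_{f}"] = v
    return out


def reanalyze_deposited(path: str, k: int = 5) -> pd.DataFrame:
    """Run the tuning analyses on locally downloaded sessions.

    The archive is never fetched automatically; ``path`` must point at a
    directory of per-session HDF5 files in the package's session layout (a
    best-effort loader for the public deposit — convert sessions first).
    """
    if not os.path.isdir(path):
        raise FileNotFoundError(
            f"no session directory at {path!r}; download and convert the "
            f"deposited data first ({EXPECTED_LAYOUT})"
        )
    files = sorted(f for f in os.listdir(path) if f.endswith((".h5", ".hdf5")))
    if not files:
        raise FileNotFoundError(f"no HDF5 session files under {path!r}; {EXPECTED_LAYOUT}")
    rows = []
    for fname in files:
        try:
            session = synth.SessionData.from_hdf5(os.path.join(path, fname))
        except Exception as e:
            raise ValueError(f"could not read {fname}: {e}; {EXPECTED_LAYOUT}") from e
        rows.append({"session": fname, **tuning_report(session, k=k)})
    return pd.DataFrame(rows)
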
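"""Cross-validated population tuning statistics.

Implements the offline population-level analyses: fold-wise ordinary least
squares fits of the linear encoding model (optionally with the laterality
predictor), cross-validated coefficient-vector magnitudes and correlations
(unbiased under additive noise), bimanual-vs-unimanual suppression ratios,
split-half cross-validated demixed-PCA marginalized variance, PCA laterality
visualization, per-electrode ANOVA/FVAF tuning tests, and removal of the
laterality dimension from a session.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .synth import (
    BIN_S,
    BIMANUAL,
    NO_MOVEMENT,
    UNI_LEFT,
    UNI_RIGHT,
    Frames,
    SessionData,
    context_code,
    laterality_code,
)

DEFAULT_WINDOW = (0.3, 0.7)  # seconds after the go cue

#: predictor names in encoding-matrix column order
FULL_PREDICTORS = ("intercept", "rx", "ry", "lx", "ly")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess(
    session: SessionData,
    remove_block_means: bool = True,
    zscore: bool = False,
    block_size_trials: int | None = None,
) -> SessionData:
    """Remove block-wise means (and optionally z-score) the rates.

    A block is a contiguous group of trials (``block_size_trials``; the whole
    session forms one block by default, appropriate for synthetic sessions
    without drift).
    """
    rates = session.rates.copy()
    table = session.trial_table
    if remove_block_means:
        if block_size_trials is None:
            rates -= rates.mean(axis=0)
        else:
            for s in range(0, len(table), block_size_trials):
                chunk = table.iloc[s : s + block_size_trials]
                lo, hi = int(chunk["start"].iloc[0]), int(chunk["end"].iloc[-1])
                rates[lo:hi] -= rates[lo:hi].mean(axis=0)
    if zscore:
        sd = rates.std(axis=0)
        sd[sd == 0] = 1.0
        rates = (rates - rates.mean(axis=0)) / sd
    pre = dict(session.preprocessing)
    pre["block_means_removed"] = pre.get("block_means_removed", False) or remove_block_means
    pre["zscored"] = pre.get("zscored", False) or zscore
    return session.copy_with(rates=rates, preprocessing=pre)


# ---------------------------------------------------------------------------
# Cross-validated OLS encoding fits
# ---------------------------------------------------------------------------


@dataclass
class CvFit:
    """Per-fold encoding matrices from fold-wise OLS.

    ``fold_coeffs[i]`` is (channels x predictors); ``predictors`` names the
    columns (subset of intercept, rx, ry, lx, ly, lat).  Folds are fitted on
    disjoint sets of trials, so their estimation noise is independent.
    """

    fold_coeffs: list
    predictors: tuple
    window: tuple = DEFAULT_WINDOW
    k: int = 5

    @property
    def n_channels(self) -> int:
        return self.fold_coeffs[0].shape[0]

    def column(self, name: str) -> np.ndarray:
        """(k, channels) stack of a predictor's per-fold coefficient vectors."""
        j = self.predictors.index(name)
        return np.stack([c[:, j] for c in self.fold_coeffs])

    def pooled(self, name: str) -> np.ndarray:
        return self.column(name).mean(axis=0)

    def negate(self) -> "CvFit":
        return CvFit([-c for c in self.fold_coeffs], self.predictors, self.window, self.k)


def _stratified_fold_ids(table: pd.DataFrame, k: int) -> np.ndarray:
    """Trial-level fold assignment, round-robin within (type, wedge) strata."""
    fold = np.zeros(len(table), dtype=int)
    strata = table.groupby(["type", "wedge_r", "wedge_l"], sort=True).indices
    offset = 0
    for key in sorted(strata):
        idx = strata[key]
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return fold


def design_matrix(
    frames: Frames, contexts: np.ndarray, with_laterality: bool, active_columns: tuple
) -> np.ndarray:
    cols = [np.ones(len(frames))]
    for name in ("rx", "ry", "lx", "ly"):
        if name in active_columns:
            cols.append(frames.d[:, ("rx", "ry", "lx", "ly").index(name)])
    if with_laterality:
        cols.append(np.array([laterality_code(int(c)) for c in contexts]))
    return np.column_stack(cols)


def fit_encoding_cv(
    session: SessionData,
    context_filter=None,
    k: int = 5,
    with_laterality: bool = False,
    window: tuple = DEFAULT_WINDOW,
) -> CvFit:
    """Fold-wise OLS fit of the linear encoding model on move-window bins.

    ``context_filter`` selects trials by context (name/code or list); unimanual
    filters drop the inactive hand's velocity columns from the model.  Each
    fold is fitted on its own disjoint trials (stacked 20-ms bins in the
    analysis window after the go cue).
    """
    table = session.trial_table
    if context_filter is not None:
        if isinstance(context_filter, (str, int)):
            context_filter = [context_filter]
        codes = {context_code(c) for c in context_filter}
        table = table[table["type"].isin(codes)]
    else:
        codes = set(table["type"].unique())
    if len(table) < k:
        raise ValueError(f"need at least k={k} trials in the context filter")

    active = ["rx", "ry", "lx", "ly"]
    if codes == {UNI_RIGHT}:
        active = ["rx", "ry"]
    elif codes == {UNI_LEFT}:
        active = ["lx", "ly"]
    active = tuple(active)

    predictors = ("intercept",) + active + (("lat",) if with_laterality else ())
    fold_ids = _stratified_fold_ids(table, k)

    fold_coeffs = []
    for f in range(k):
        rows = table.iloc[np.flatnonzero(fold_ids == f)]
        bins = np.concatenate([session.move_window_bins(r, window) for r in rows.itertuples()])
        frames = Frames(session.labels.d[bins], session.labels.context[bins])
        X = design_matrix(frames, frames.context, with_laterality, active)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient predictors in fold {f}")
        cond = np.linalg.cond(X)
        if cond > 1e6:
            warnings.warn(f"ill-conditioned design matrix (cond={cond:.2g})")
        B, *_ = np.linalg.lstsq(X, session.rates[bins], rcond=None)
        fold_coeffs.append(B.T)  # (channels, predictors)
    return CvFit(fold_coeffs, predictors, window, k)


# ---------------------------------------------------------------------------
# Cross-validated vector statistics
# ---------------------------------------------------------------------------


def _cv_sq_norm(cols: np.ndarray) -> float:
    """Unbiased squared norm: mean inner product over distinct fold pairs."""
    k = cols.shape[0]
    if k < 2:
        raise ValueError("need at least 2 folds")
    G = cols @ cols.T
    return float((G.sum() - np.trace(G)) / (k * (k - 1)))


def cv_vector_stats(fit_a: CvFit, fit_b: CvFit | None, column: str) -> tuple[float, float]:
    """Cross-validated magnitude of a coefficient column and its correlation.

    The squared magnitude is the average inner product between the column
    estimated on disjoint folds (unbiased under additive zero-mean estimation
    noise); the magnitude is its signed square root.  The correlation between
    ``fit_a`` and ``fit_b`` columns uses mean-centered vectors with
    cross-validated norms in the denominator.  Values outside [-1, 1] or
    negative squared norms can occur at high noise and are passed through.
    If ``fit_b`` is None the correlation is ``nan``.
    """
    a = fit_a.column(column)
    sq_a = _cv_sq_norm(a)
    mag = float(np.sign(sq_a) * np.sqrt(abs(sq_a)))
    if fit_b is None:
        return mag, float("nan")
    b = fit_b.column(column)
    if b.shape[1] != a.shape[1]:
        raise ValueError("mismatched channel counts between fits")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    # cross-fold pairs only: unbiased for independent fits and exact for
    # fits sharing (or negating) the same fold noise
    G = ac @ bc.T
    k = ac.shape[0]
    cov = (G.sum() - np.trace(G)) / (k * (k - 1))
    denom_sq = _cv_sq_norm(ac) * _cv_sq_norm(bc)
    denom = np.sign(denom_sq) * np.sqrt(abs(denom_sq))
    corr = float(cov / denom) if denom != 0 else float("nan")
    return mag, corr


def cv_sq_norm(fit: CvFit, column: str) -> float:
    """Raw (signed) cross-validated squared norm of a coefficient column."""
    return _cv_sq_norm(fit.column(column))


def naive_sq_norm(fit: CvFit, column: str) -> float:
    """Plain squared norm of the pooled column (upward-biased under noise)."""
    return float(np.sum(fit.pooled(column) ** 2))


def _hand_strength(fit: CvFit, hand: str) -> float:
    x, y = ("rx", "ry") if hand == "right" else ("lx", "ly")
    mx, _ = cv_vector_stats(fit, None, x)
    my, _ = cv_vector_stats(fit, None, y)
    return float((mx + my) / 2)


def suppression_ratio(bimanual: CvFit, unimanual: CvFit, hand: str) -> float:
    """Ratio of mean(x-, y-column magnitude) bimanual over unimanual."""
    if bimanual.n_channels != unimanual.n_channels:
        raise ValueError("fits must share channels")
    uni = _hand_strength(unimanual, hand)
    if uni == 0:
        raise ValueError("zero unimanual tuning strength")
    return _hand_strength(bimanual, hand) / uni


# ---------------------------------------------------------------------------
# Direction quadrants
# ---------------------------------------------------------------------------


def direction_quadrant(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Quadrant index 0-3 with half-open angular intervals [0, 90) degrees etc."""
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    return np.minimum((ang // (np.pi / 2)).astype(int), 3)


def _trial_means(session: SessionData, table: pd.DataFrame, window) -> np.ndarray:
    """(n_trials, channels) mean rate in the analysis window per trial."""
    return np.stack(
        [session.rates[session.move_window_bins(r, window)].mean(axis=0) for r in table.itertuples()]
    )


def _trial_direction(session: SessionData, table: pd.DataFrame, hand: str) -> np.ndarray:
    sl = slice(0, 2) if hand == "right" else slice(2, 4)
    dirs = []
    for r in table.itertuples():
        d = session.labels.d[int(r.go) : int(r.move_end), sl]
        active = d[np.abs(d).sum(axis=1) > 0]
        dirs.append(active[0] if len(active) else np.zeros(2))
    return np.asarray(dirs)


# ---------------------------------------------------------------------------
# dPCA marginalized variance
# ---------------------------------------------------------------------------

DPCA_FACTORS = ("time", "laterality", "direction", "laterality_x_direction")


@dataclass
class MarginalVariance:
    """Split-half cross-validated variance per marginalization factor."""

    cv_variance: dict
    fraction: dict
    raw_variance: dict = field(default_factory=dict)


def _marginalize(X: np.ndarray) -> dict:
    """Additive factor decomposition of a (channels, 2, 4, T) tensor.

    The tensor is centered by its per-channel grand mean; the time factor is
    the mean over laterality and direction, and the laterality / direction
    factors (which absorb their interactions with time) are deviations of the
    partial averages from the time course.  Components sum to the centered
    tensor and are mutually orthogonal for balanced data.
    """
    Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
    m_time = Xc.mean(axis=(1, 2), keepdims=True)
    m_lat = Xc.mean(axis=2, keepdims=True) - m_time
    m_dir = Xc.mean(axis=1, keepdims=True) - m_time
    m_int = Xc - m_time - m_lat - m_dir
    shape = Xc.shape
    return {
        "time": np.broadcast_to(m_time, shape),
        "laterality": np.broadcast_to(m_lat, shape),
        "direction": np.broadcast_to(m_dir, shape),
        "laterality_x_direction": m_int,
    }


def _cell_tensor(session, table, window, trial_idx) -> np.ndarray:
    """Trial-averaged (channels, 2 laterality, 4 direction, T) tensor."""
    n_bins = len(session.move_window_bins(next(table.itertuples()), window))
    first = None
    out = None
    for (lat, quad), idx in trial_idx.items():
        rows = table.iloc[idx]
        acc = []
        for r in rows.itertuples():
            bins = session.move_window_bins(r, window)[:n_bins]
            acc.append(session.rates[bins])
        cell = np.mean(acc, axis=0).T  # (channels, T)
        if out is None:
            out = np.zeros((cell.shape[0], 2, 4, cell.shape[1]))
            first = cell.shape[1]
        out[:, lat, quad, :first] = cell
    return out


def dpca_marginal_variance(
    session: SessionData, split_seed: int = 0, window: tuple = DEFAULT_WINDOW
) -> MarginalVariance:
    """Cross-validated marginalized variance over unimanual trials.

    Factors: time, laterality (which hand), movement direction (4 quadrants of
    the active hand), and the laterality x direction interaction.  Trials in
    each (laterality x direction) cell are split into two halves; each half is
    trial-averaged and marginalized, and the cross-validated variance of a
    factor is the sum over entries of the element-wise product of the two
    halves' marginalized tensors.  Negative cross-validated components are
    floored at zero before computing fractions (raw signed values are kept).
    """
    table = session.trial_table
    table = table[table["type"].isin([UNI_RIGHT, UNI_LEFT])].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no unimanual trials")

    lat_idx = (table["type"] == UNI_LEFT).astype(int).to_numpy()  # 0=right, 1=left
    quads = np.zeros(len(table), dtype=int)
    for hand, code in (("right", UNI_RIGHT), ("left", UNI_LEFT)):
        mask = (table["type"] == code).to_numpy()
        if mask.any():
            d = _trial_direction(session, table[mask], hand)
            quads[mask] = direction_quadrant(d[:, 0], d[:, 1])

    cells = {}
    missing = []
    for lat, quad in itertools.product(range(2), range(4)):
        idx = np.flatnonzero((lat_idx == lat) & (quads == quad))
        if len(idx) < 2:
            missing.append((("right", "left")[lat], f"Q{quad + 1}"))
        cells[(lat, quad)] = idx
    if missing:
        raise ValueError(f"cells with fewer than 2 trials: {missing}")

    rng = np.random.default_rng(split_seed)
    half_a, half_b = {}, {}
    for key, idx in cells.items():
        idx = rng.permutation(idx)
        half_a[key] = idx[: len(idx) // 2]
        half_b[key] = idx[len(idx) // 2 :]

    Xa = _cell_tensor(session, table, window, half_a)
    Xb = _cell_tensor(session, table, window, half_b)
    Ma, Mb = _marginalize(Xa), _marginalize(Xb)
    Xf = _cell_tensor(session, table, window, cells)
    Mf = _marginalize(Xf)

    cv = {f: float(np.sum(Ma[f] * Mb[f])) for f in DPCA_FACTORS}
    raw = {f: float(np.sum(Mf[f] ** 2)) for f in DPCA_FACTORS}
    floored = {f: max(v, 0.0) for f, v in cv.items()}
    total = sum(floored.values())
    frac = {f: (v / total if total > 0 else 0.0) for f, v in floored.items()}
    return MarginalVariance(cv_variance=cv, fraction=frac, raw_variance=raw)


# ---------------------------------------------------------------------------
# PCA laterality visualization
# ---------------------------------------------------------------------------


@dataclass
class LateralityView:
    trial_scores: np.ndarray  # (n_trials, 2)
    trial_types: np.ndarray
    pc1_timecourse: np.ndarray  # (n_trials, span_bins) projection on PC1
    time_s: np.ndarray


def pca_laterality_view(
    session: SessionData, window: tuple = DEFAULT_WINDOW, span: tuple = (-0.5, 1.5)
) -> LateralityView:
    """Top-2 PC scores of per-trial mean rates, plus per-bin PC1 time courses.

    Expects a z-scored session; trial vectors are each trial's average firing
    rate in the analysis window, and the time course spans ``span`` seconds
    around the go cue.
    """
    table = session.trial_table
    M = _trial_means(session, table, window)
    pca = PCA(n_components=2)
    scores = pca.fit_transform(M)

    lo, hi = (int(round(s / BIN_S)) for s in span)
    tc = []
    for r in table.itertuples():
        bins = np.clip(np.arange(int(r.go) + lo, int(r.go) + hi), 0, session.n_bins - 1)
        tc.append(session.rates[bins] @ pca.components_[0])
    return LateralityView(
        trial_scores=scores,
        trial_types=table["type"].to_numpy(),
        pc1_timecourse=np.stack(tc),
        time_s=np.arange(lo, hi) * BIN_S,
    )


# ---------------------------------------------------------------------------
# Per-electrode tuning (ANOVA + FVAF)
# ---------------------------------------------------------------------------

ANOVA_P_THRESHOLD = 1e-5  # electrode counted as strongly tuned below this


def electrode_tuning(
    session: SessionData, context: str, window: tuple = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Per-electrode 1-way ANOVA over 4 direction quadrants and FVAF score.

    ``context`` is one of unimanual_right, unimanual_left, bimanual_right,
    bimanual_left (bimanual grouping for one hand ignores the other hand's
    direction).  FVAF = SS_dir / SS_total of per-trial mean rates; undefined
    (NaN) when the total variance is zero.
    """
    ctx, _, hand = context.partition("_")
    if hand not in ("right", "left"):
        raise ValueError("context must name a hand, e.g. 'bimanual_right'")
    code = BIMANUAL if ctx == "bimanual" else (UNI_RIGHT if hand == "right" else UNI_LEFT)
    table = session.trial_table[session.trial_table["type"] == code]
    if len(table) == 0:
        raise ValueError(f"no trials for context {context}")

    M = _trial_means(session, table, window)
    d = _trial_direction(session, table, hand)
    quad = direction_quadrant(d[:, 0], d[:, 1])
    counts = np.bincount(quad, minlength=4)
    if (counts < 2).any():
        raise ValueError(f"need >= 2 trials per quadrant, got {counts.tolist()}")

    grand = M.mean(axis=0)
    ss_total = ((M - grand) ** 2).sum(axis=0)
    group_means = np.stack([M[quad == q].mean(axis=0) for q in range(4)])
    ss_dir = ((group_means[quad] - grand) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fvaf = np.where(ss_total > 0, ss_dir / ss_total, np.nan)

    pvals = np.array(
        [
            stats.f_oneway(*(M[quad == q, e] for q in range(4))).pvalue
            for e in range(M.shape[1])
        ]
    )
    return pd.DataFrame(
        {
            "electrode": np.arange(M.shape[1]),
            "p_value": pvals,
            "fvaf": fvaf,
            "strongly_tuned": pvals < ANOVA_P_THRESHOLD,
            "ss_total": ss_total,
            "ss_dir": ss_dir,
        }
    )


# ---------------------------------------------------------------------------
# Laterality dimension removal
# ---------------------------------------------------------------------------


def remove_laterality(
    session: SessionData, k: int = 5, window: tuple = DEFAULT_WINDOW
) -> SessionData:
    """Project out the fitted laterality dimension from a unimanual session.

    Fits the encoding model with the laterality predictor by fold-wise OLS,
    takes the pooled laterality coefficient vector, and subtracts each bin's
    projection onto that (unit) direction from the mean-centered rates.
    Refitting the model on the output yields laterality coefficients of
    essentially zero norm.
    """
    fit = fit_encoding_cv(
        session, context_filter=[UNI_RIGHT, UNI_LEFT], k=k, with_laterality=True, window=window
    )
    b_lat = fit.pooled("lat")
    norm = np.linalg.norm(b_lat)
    if norm == 0:
        return session.copy_with(rates=session.rates.copy())
    u = b_lat / norm
    mean = session.rates.mean(axis=0)
    centered = session.rates - mean
    removed = centered - np.outer(centered @ u, u) + mean
    pre = dict(session.preprocessing)
    pre["laterality_removed"] = True
    return session.copy_with(rates=removed, preprocessing=pre)
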
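"""Velocity decoders: ridge regression, feed-forward net, gated recurrent net.

Three decoder families map binned firing rates to the x/y velocities of the
right and left cursors:

* ridge regression with the penalty selected by cross-validated Pearson r,
* a single-hidden-layer feed-forward network (512 rectifier units by default)
  decoding one 20-ms bin at a time, and
* a single-layer gated-recurrent-unit network with day-specific affine input
  transforms, a continuous velocity head and a discrete movement-context head
  (unimanual right / unimanual left / bimanual / no movement) whose argmax
  gates the output velocities per cursor.

No deep-learning framework is assumed: the recurrent model is implemented in
numpy with truncated-free BPTT and Adam, and its analytic gradients are
verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPRegressor

from .synth import BIMANUAL, NO_MOVEMENT, UNI_LEFT, UNI_RIGHT

N_OUTPUTS = 4  # (v_rx, v_ry, v_lx, v_ly)
N_CONTEXTS = 4  # softmax classes: uni right, uni left, bimanual, no movement


def pearson_r(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-column Pearson correlation; NaN for degenerate (constant) columns."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    p = pred - pred.mean(axis=0)
    t = target - target.mean(axis=0)
    sp = np.sqrt((p**2).sum(axis=0))
    st = np.sqrt((t**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (p * t).sum(axis=0) / (sp * st)
    r[(sp == 0) | (st == 0)] = np.nan
    return r


def stratified_bin_folds(
    contexts: np.ndarray, trial_ids: np.ndarray, k: int = 5
) -> np.ndarray:
    """Trial-level fold ids per bin, round-robin within each context stratum.

    Keeps held-out folds balanced for unimanual right vs left time steps while
    never splitting a trial across folds.
    """
    trial_ids = np.asarray(trial_ids)
    contexts = np.asarray(contexts)
    uniq, first = np.unique(trial_ids, return_index=True)
    trial_ctx = contexts[first]
    fold_of_trial = {}
    for c in np.unique(trial_ctx):
        members = uniq[trial_ctx == c]
        for i, t in enumerate(members):
            fold_of_trial[t] = i % k
    return np.array([fold_of_trial[t] for t in trial_ids])


# ---------------------------------------------------------------------------
# Ridge regression
# ---------------------------------------------------------------------------


@dataclass
class RidgeModel:
    coef: np.ndarray  # (channels, 4)
    intercept: np.ndarray
    alpha: float
    cv_r: np.ndarray  # per-output held-out Pearson r at the chosen alpha

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.coef + self.intercept


def train_ridge(
    features: np.ndarray,
    targets: np.ndarray,
    alpha_grid=None,
    k: int = 5,
    fold_ids: np.ndarray | None = None,
) -> RidgeModel:
    """Ridge regression with the penalty maximizing mean held-out Pearson r.

    ``fold_ids`` should come from :func:`stratified_bin_folds` so folds are
    balanced across unimanual right/left time steps; contiguous blocks are
    used as a fallback.
    """
    if alpha_grid is None:
        alpha_grid = np.logspace(-2, 5, 15)
    alpha_grid = np.asarray(list(alpha_grid), dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("empty alpha grid")
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = features.shape[0]
    if fold_ids is None:
        fold_ids = (np.arange(n) * k // n).astype(int)

    best = (-np.inf, None, None)
    for alpha in alpha_grid:
        preds = np.zeros_like(targets)
        for f in range(k):
            test = fold_ids == f
            model = Ridge(alpha=alpha).fit(features[~test], targets[~test])
            preds[test] = model.predict(features[test])
        r = pearson_r(preds, targets)
        score = np.nanmean(r)
        if score > best[0]:
            best = (score, alpha, r)
    _, alpha, cv_r = best
    final = Ridge(alpha=alpha).fit(features, targets)
    return RidgeModel(coef=final.coef_.T, intercept=final.intercept_, alpha=float(alpha), cv_r=cv_r)


# ---------------------------------------------------------------------------
# Feed-forward network (single-bin decoder)
# ---------------------------------------------------------------------------


@dataclass
class FfnConfig:
    """Training configuration for the single-hidden-layer decoder.

    Optimizer settings were tuned once for convergence at desk scale (a large
    initial learning rate is needed for the net to leave the linear regime and
    learn the laterality gating).
    """

    hidden: int = 512
    activation: str = "relu"
    alpha: float = 1e-4  # L2 penalty
    learning_rate: float = 0.05
    batch_size: int = 512
    max_iter: int = 300
    n_iter_no_change: int = 100
    solver: str = "adam"
    tol: float = 1e-7
    seed: int = 0


@dataclass
class FfnModel:
    net: MLPRegressor
    config: FfnConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(np.asarray(X, dtype=float))


def train_ffn(features: np.ndarray, targets: np.ndarray, config: FfnConfig | None = None) -> FfnModel:
    """Train the single-hidden-layer network mapping one bin to 4 velocities."""
    config = config or FfnConfig()
    net = MLPRegressor(
        hidden_layer_sizes=(config.hidden,),
        activation=config.activation,
        alpha=config.alpha,
        learning_rate_init=config.learning_rate,
        batch_size=min(config.batch_size, len(features)),
        max_iter=config.max_iter,
        n_iter_no_change=config.n_iter_no_change,
        solver=config.solver,
        tol=config.tol,
        random_state=config.seed,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at desk scale
        net.fit(np.asarray(features, dtype=float), np.asarray(targets, dtype=float))
    if not np.isfinite(net.loss_):
        raise RuntimeError(f"FFN training diverged (loss={net.loss_})")
    return FfnModel(net=net, config=config)


# ---------------------------------------------------------------------------
# Gated recurrent decoder
# ---------------------------------------------------------------------------


@dataclass
class RnnConfig:
    hidden: int = 512
    learning_rate: float = 2e-3
    batch_size: int = 8
    n_batches: int = 300
    l2: float = 1e-5
    mse_weight: float = 1.0
    ce_weight: float = 1.0
    input_noise_sd: float = 0.0
    mean_drift_sd: float = 0.0
    grad_clip: float = 10.0
    seed: int = 0
    context_smoothing: float = 0.0  # exponential smoothing of context probs


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class RnnModel:
    """Single-layer GRU with day-specific affine inputs and two heads.

    Parameters are plain numpy arrays; one inference step corresponds to one
    20-ms bin.  The continuous head emits the 4 cursor velocities; the
    discrete head emits softmax logits over the 4 movement contexts, whose
    per-bin argmax gates the velocities (a cursor only moves when its context
    class says it is engaged).
    """

    def __init__(self, n_inputs: int, config: RnnConfig, days=("day0",)):
        self.config = config
        self.n_inputs = n_inputs
        H = config.hidden
        rng = np.random.default_rng(config.seed)

        def init(shape, scale):
            return rng.standard_normal(shape) * scale

        self.params = {}
        for day in days:
            self.params[f"Wday_{day}"] = np.eye(n_inputs)
            self.params[f"bday_{day}"] = np.zeros(n_inputs)
        sx = 1.0 / np.sqrt(n_inputs)
        sh = 1.0 / np.sqrt(H)
        self.params.update(
            Wx=init((n_inputs, 3 * H), sx),  # columns: [z | r | c]
            Wh=init((H, 3 * H), sh),
            b=np.zeros(3 * H),
            Wv=init((H, N_OUTPUTS), sh),
            bv=np.zeros(N_OUTPUTS),
            Wc=init((H, N_CONTEXTS), sh),
            bc=np.zeros(N_CONTEXTS),
        )
        self.days = tuple(days)
        self.train_log: pd.DataFrame | None = None

    # -- forward -----------------------------------------------------------

    def _apply_day(self, X: np.ndarray, day: str) -> np.ndarray:
        if day not in self.days:
            raise KeyError(f"unknown day id {day!r}; known: {self.days}")
        return X @ self.params[f"Wday_{day}"] + self.params[f"bday_{day}"]

    def forward(self, X: np.ndarray, day: str = "day0", h0: np.ndarray | None = None, cache: bool = False):
        """Run the network over (B, T, N) inputs; returns (v, logits, h_T).

        With ``cache=True`` also returns the intermediates needed for BPTT.
        """
        B, T, _ = X.shape
        H = self.config.hidden
        p = self.params
        Xd = self._apply_day(X, day)
        h = np.zeros((B, H)) if h0 is None else h0.copy()
        hs = np.zeros((B, T, H))
        caches = [] if cache else None
        for t in range(T):
            x = Xd[:, t]
            a = x @ p["Wx"] + h @ p["Wh"] + p["b"]
            z = _sigmoid(a[:, :H])
            r = _sigmoid(a[:, H : 2 * H])
            c = np.tanh(x @ p["Wx"][:, 2 * H :] + (r * h) @ p["Wh"][:, 2 * H :] + p["b"][2 * H :])
            h_new = (1 - z) * h + z * c
            if cache:
                caches.append((x, h, z, r, c))
            h = h_new
            hs[:, t] = h
        v = hs @ p["Wv"] + p["bv"]
        logits = hs @ p["Wc"] + p["bc"]
        if cache:
            return v, logits, h, (Xd, hs, caches)
        return v, logits, h

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(self, X, v_target, ctx_target, day="day0"):
        """Sum of weighted squared error, cross-entropy and L2; full BPTT."""
        cfg = self.config
        p = self.params
        H = cfg.hidden
        B, T, _ = X.shape
        v, logits, _, (Xd, hs, caches) = self.forward(X, day, cache=True)

        probs = _softmax(logits)
        mse = np.mean((v - v_target) ** 2)
        onehot = np.eye(N_CONTEXTS)[ctx_target]
        ce = -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=-1))
        l2 = sum(np.sum(w**2) for k, w in p.items() if k.startswith("W"))
        loss = cfg.mse_weight * mse + cfg.ce_weight * ce + cfg.l2 * l2

        grads = {k: np.zeros_like(w) for k, w in p.items()}
        dv = cfg.mse_weight * 2 * (v - v_target) / v.size
        dlogits = cfg.ce_weight * (probs - onehot) / (B * T)

        grads["Wv"] = np.einsum("bth,bto->ho", hs, dv)
        grads["bv"] = dv.sum(axis=(0, 1))
        grads["Wc"] = np.einsum("bth,bto->ho", hs, dlogits)
        grads["bc"] = dlogits.sum(axis=(0, 1))
        dhs = dv @ p["Wv"].T + dlogits @ p["Wc"].T

        Whz, Whr, Whc = p["Wh"][:, :H], p["Wh"][:, H : 2 * H], p["Wh"][:, 2 * H :]
        Wxz, Wxr, Wxc = p["Wx"][:, :H], p["Wx"][:, H : 2 * H], p["Wx"][:, 2 * H :]
        dWx = np.zeros_like(p["Wx"])
        dWh = np.zeros_like(p["Wh"])
        db = np.zeros_like(p["b"])
        dXd = np.zeros_like(Xd)

        dh = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x, h_prev, z, r, c = caches[t]
            dh = dh + dhs[:, t]
            da_c = dh * z * (1 - c**2)
            da_z = dh * (c - h_prev) * z * (1 - z)
            drh = da_c @ Whc.T
            dr = drh * h_prev
            da_r = dr * r * (1 - r)
            dh_prev = dh * (1 - z) + drh * r + da_z @ Whz.T + da_r @ Whr.T

            dWx[:, :H] += x.T @ da_z
            dWx[:, H : 2 * H] += x.T @ da_r
            dWx[:, 2 * H :] += x.T @ da_c
            dWh[:, :H] += h_prev.T @ da_z
            dWh[:, H : 2 * H] += h_prev.T @ da_r
            dWh[:, 2 * H :] += (r * h_prev).T @ da_c
            db[:H] += da_z.sum(axis=0)
            db[H : 2 * H] += da_r.sum(axis=0)
            db[2 * H :] += da_c.sum(axis=0)
            dXd[:, t] = da_z @ Wxz.T + da_r @ Wxr.T + da_c @ Wxc.T
            dh = dh_prev

        grads["Wx"] = dWx
        grads["Wh"] = dWh
        grads["b"] = db
        grads[f"Wday_{day}"] = np.einsum("btn,btm->nm", X, dXd)
        grads[f"bday_{day}"] = dXd.sum(axis=(0, 1))
        for k in grads:
            if k.startswith("W"):
                grads[k] += cfg.l2 * 2 * p[k]
        return loss, grads, dict(mse=mse, ce=ce, l2=l2)

    # -- inference ---------------------------------------------------------

    def initial_state(self, batch: int = 1) -> np.ndarray:
        return np.zeros((batch, self.config.hidden))

    def decode_sequence(self, X: np.ndarray, day: str = "day0", gated: bool = True):
        """Decode a (T, N) stream; returns (velocities (T,4), context probs)."""
        v, logits, _ = self.forward(X[None], day)
        v, probs = v[0], _softmax(logits[0])
        if gated:
            v = apply_gate(v, probs.argmax(axis=1))
        return v, probs


def apply_gate(v: np.ndarray, context: np.ndarray) -> np.ndarray:
    """Zero each cursor's velocity unless its context class is active."""
    v = np.array(v, copy=True)
    right_ok = (context == UNI_RIGHT) | (context == BIMANUAL)
    left_ok = (context == UNI_LEFT) | (context == BIMANUAL)
    v[..., :2] *= right_ok[..., None]
    v[..., 2:] *= left_ok[..., None]
    return v


def rnn_step(model: RnnModel, bin_vector: np.ndarray, state: np.ndarray, day: str = "day0"):
    """One 20-ms inference step: (gated velocities, context probs, new state)."""
    v, logits, h = model.forward(bin_vector[None, None, :], day, h0=state)
    probs = _softmax(logits[0, 0])
    gated = apply_gate(v[0, 0], np.array(int(probs.argmax())))
    return gated, probs, h


def train_rnn(snippets, config: RnnConfig | None = None, val_snippets=None, day: str = "day0") -> RnnModel:
    """Train the recurrent decoder on a :class:`~bimanual.augment.SnippetSet`.

    The loss is the sum of an L2 weight penalty, a cross-entropy loss over the
    discrete context classes, and squared error over the continuous velocities.
    Optional input-noise and slowly varying mean-drift augmentations perturb
    the inputs each draw.  Deterministic given the config seed.
    """
    config = config or RnnConfig()
    X = np.asarray(snippets.inputs, dtype=float)
    Y = np.asarray(snippets.outputs, dtype=float)
    v_target, ctx_target = Y[..., :N_OUTPUTS], Y[..., N_OUTPUTS].astype(int)
    if X.shape[:2] != Y.shape[:2]:
        raise ValueError("snippet input/output dimensions mismatch")
    S, T, N = X.shape

    model = RnnModel(N, config, days=(day,))
    rng = np.random.default_rng(config.seed)
    m = {k: np.zeros_like(w) for k, w in model.params.items()}
    v_adam = {k: np.zeros_like(w) for k, w in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    log = []
    for step in range(1, config.n_batches + 1):
        idx = rng.choice(S, size=min(config.batch_size, S), replace=False)
        xb = X[idx]
        if config.input_noise_sd > 0:
            xb = xb + rng.normal(0, config.input_noise_sd, xb.shape)
        if config.mean_drift_sd > 0:
            drift = np.cumsum(
                rng.normal(0, config.mean_drift_sd / np.sqrt(T), (len(idx), T, N)), axis=1
            )
            xb = xb + drift + rng.normal(0, config.mean_drift_sd, (len(idx), 1, N))
        loss, grads, parts = model.loss_and_grads(xb, v_target[idx], ctx_target[idx], day)
        if not np.isfinite(loss):
            raise RuntimeError(f"RNN training diverged at step {step} (loss={loss})")
        gnorm = np.sqrt(sum(np.sum(g**2) for g in grads.values()))
        scale = min(1.0, config.grad_clip / (gnorm + 1e-12))
        for k, g in grads.items():
            g = g * scale
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g**2
            mhat = m[k] / (1 - beta1**step)
            vhat = v_adam[k] / (1 - beta2**step)
            model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        entry = dict(step=step, loss=loss, **parts)
        if val_snippets is not None and (step % 50 == 0 or step == config.n_batches):
            entry["val_loss"] = _eval_loss(model, val_snippets, day)
        log.append(entry)
    model.train_log = pd.DataFrame(log)
    return model


def _eval_loss(model: RnnModel, snippets, day: str) -> float:
    X = np.asarray(snippets.inputs, dtype=float)
    Y = np.asarray(snippets.outputs, dtype=float)
    v, logits, _ = model.forward(X, day)
    probs = _softmax(logits)
    mse = np.mean((v - Y[..., :N_OUTPUTS]) ** 2)
    onehot = np.eye(N_CONTEXTS)[Y[..., N_OUTPUTS].astype(int)]
    ce = -np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=-1))
    cfg = model.config
    return float(cfg.mse_weight * mse + cfg.ce_weight * ce)


# ---------------------------------------------------------------------------
# Offline evaluation
# ---------------------------------------------------------------------------


def decode_offline(model, features: np.ndarray, targets: np.ndarray, day: str = "day0"):
    """Decode a held-out stream and report per-dimension Pearson r.

    ``model`` may be a :class:`RidgeModel`, :class:`FfnModel` (single-bin
    decoders) or :class:`RnnModel` (sequential rollout with context gating).
    Returns ``(predictions, r)`` where r has one entry per output dimension
    (NaN where the prediction is constant).
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if isinstance(model, RnnModel):
        preds, _ = model.decode_sequence(features, day)
    else:
        preds = model.predict(features)
    return preds, pearson_r(preds, targets)
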
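"""Training-data alteration: labeled clips, time dilation, shuffling, balancing.

Recurrent decoders trained on stereotyped delay/move/idle calibration blocks
overlearn the task's temporal structure.  This module fractures that structure:
the labeled data stream is cut into clips of random position and duration
(0.2-0.8 of the 10-s snippet length), each clip is stretched or compressed in
time by a factor drawn uniformly from [0.5, 2] using linear interpolation, and
the modified clips are appended in random order into fixed-length training
snippets, subject to a per-condition balancing record (movement quadrant per
hand x movement type, with delay-period and rest subtypes of no-movement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .synth import (
    BIMANUAL,
    NO_MOVEMENT,
    UNI_LEFT,
    UNI_RIGHT,
    SessionData,
)
from .tuning import direction_quadrant

SNIPPET_BINS = 500  # 10 s at 20-ms bins
CLIP_FRACTION = (0.2, 0.8)  # raw clip duration as fraction of snippet length
DILATION_RANGE = (0.5, 2.0)

#: no-movement subtypes
DELAY_SUBTYPES = {
    UNI_RIGHT: "delay_unimanual_right",
    UNI_LEFT: "delay_unimanual_left",
    BIMANUAL: "delay_bimanual",
}
REST = "rest"


# ---------------------------------------------------------------------------
# Labeled stream
# ---------------------------------------------------------------------------


@dataclass
class LabeledStream:
    """Aligned input/output tensors with a per-bin condition label.

    ``outputs`` stacks the 4 velocity targets and the context class index;
    ``condition`` is a string label per bin (e.g. ``"unimanual_right:Q2"`` or
    ``"delay_bimanual"``) used by the balancing record.
    """

    inputs: np.ndarray  # (bins, channels)
    outputs: np.ndarray  # (bins, 5)
    condition: np.ndarray  # (bins,) str
    trial_ids: np.ndarray  # (bins,)

    def __post_init__(self) -> None:
        n = self.inputs.shape[0]
        if not (self.outputs.shape[0] == self.condition.shape[0] == self.trial_ids.shape[0] == n):
            raise ValueError("stream tensors must be aligned")

    def __len__(self) -> int:
        return self.inputs.shape[0]


def _move_condition(ttype: int, d4: np.ndarray) -> str:
    parts = []
    if ttype in (UNI_RIGHT, BIMANUAL):
        q = direction_quadrant(np.array([d4[0]]), np.array([d4[1]]))[0]
        parts.append(f"R-Q{q + 1}")
    if ttype in (UNI_LEFT, BIMANUAL):
        q = direction_quadrant(np.array([d4[2]]), np.array([d4[3]]))[0]
        parts.append(f"L-Q{q + 1}")
    name = ("unimanual_right", "unimanual_left", "bimanual")[ttype]
    return f"{name}:{'x'.join(parts)}"


def label_stream(session: SessionData) -> LabeledStream:
    """Label every bin of a session with its balancing condition.

    Move bins are labeled by trial type and per-hand direction quadrant; delay
    bins take the delay subtype of the upcoming trial's type; idle bins are
    labeled rest.  Raises if any bin falls outside the trial annotations.
    """
    if session.target_vel is None:
        raise ValueError("session has no velocity targets; use a delayed-movement session")
    n = session.n_bins
    condition = np.full(n, "", dtype=object)
    trial_ids = np.full(n, -1)
    ctx_class = np.full(n, NO_MOVEMENT)

    for r in session.trial_table.itertuples():
        start, go, move_end, end = int(r.start), int(r.go), int(r.move_end), int(r.end)
        t = int(r.type)
        condition[start:go] = DELAY_SUBTYPES[t]
        condition[move_end:end] = REST
        trial_ids[start:end] = r.trial
        ctx_class[go:move_end] = t
        for b in range(go, move_end):
            d4 = session.labels.d[b]
            if np.any(d4):
                condition[b] = _move_condition(t, d4)
            else:
                # reaction-time bins before movement onset count as preparation
                condition[b] = DELAY_SUBTYPES[t]
                ctx_class[b] = NO_MOVEMENT
    if (condition == "").any():
        raise ValueError("unannotated bins present in session")
    outputs = np.column_stack([session.target_vel, ctx_class])
    return LabeledStream(session.rates.copy(), outputs, condition.astype(str), trial_ids)


# ---------------------------------------------------------------------------
# Clip resampling
# ---------------------------------------------------------------------------


def resample_clip(
    inputs: np.ndarray, outputs: np.ndarray, d_f: float, labels: np.ndarray | None = None
):
    """Stretch or compress a clip in time by factor ``d_f``.

    Continuous channels are linearly interpolated onto ``round(L * d_f)``
    points with endpoints preserved; categorical labels (and the context class
    column of ``outputs``) are resampled by nearest neighbor.
    """
    if not DILATION_RANGE[0] <= d_f <= DILATION_RANGE[1]:
        raise ValueError(f"d_f must be within {DILATION_RANGE}")
    L = inputs.shape[0]
    new_len = int(round(L * d_f))
    if new_len < 2:
        raise ValueError("resampled clip would be shorter than 2 bins")
    src = np.arange(L)
    dst = np.linspace(0, L - 1, new_len)
    nearest = np.rint(dst).astype(int)

    new_in = np.empty((new_len, inputs.shape[1]))
    for j in range(inputs.shape[1]):
        new_in[:, j] = np.interp(dst, src, inputs[:, j])
    new_out = np.empty((new_len, outputs.shape[1]))
    for j in range(outputs.shape[1] - 1):
        new_out[:, j] = np.interp(dst, src, outputs[:, j])
    new_out[:, -1] = outputs[nearest, -1]  # context class: nearest neighbor
    if labels is None:
        return new_in, new_out
    return new_in, new_out, labels[nearest]


# ---------------------------------------------------------------------------
# Snippet assembly with balancing
# ---------------------------------------------------------------------------


@dataclass
class Clip:
    start: int
    raw_len: int
    d_f: float
    used_len: int  # bins contributed after resampling (last clip may truncate)


@dataclass
class AugmentConfig:
    snippet_len: int = SNIPPET_BINS
    clip_fraction: tuple = CLIP_FRACTION
    dilation: tuple = DILATION_RANGE
    tolerance: float = 0.1  # max absolute excess of a condition's bin share
    allow_cross_trial: bool = True
    max_rejects: int = 200


@dataclass
class SnippetSet:
    """Augmented training tensors plus balance record and provenance."""

    inputs: np.ndarray  # (S, T, N)
    outputs: np.ndarray  # (S, T, R)
    balance: dict  # condition -> realized bin count
    target_share: dict  # condition -> target share
    provenance: list  # per snippet: list of Clip
    seed: int

    @property
    def shares(self) -> dict:
        total = sum(self.balance.values())
        return {c: v / total for c, v in self.balance.items()}

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("inputs", data=self.inputs.astype(np.float32))
            f.create_dataset("outputs", data=self.outputs.astype(np.float32))
            prov = [
                [(c.start, c.raw_len, c.d_f, c.used_len) for c in clips]
                for clips in self.provenance
            ]
            g = f.create_group("provenance")
            for i, clips in enumerate(prov):
                g.create_dataset(str(i), data=np.array(clips))
            f.attrs["seed"] = self.seed


def _target_shares(conditions: np.ndarray) -> dict:
    """Uniform share over movement types, subdivided uniformly by direction."""
    uniq = np.unique(conditions)
    groups: dict[str, list] = {}
    for c in uniq:
        key = c.split(":")[0]
        groups.setdefault(key, []).append(c)
    share = {}
    for key, members in groups.items():
        for c in members:
            share[c] = 1.0 / (len(groups) * len(members))
    return share


def _required_conditions(stream: LabeledStream) -> set:
    req = set()
    types = {c.split(":")[0] for c in np.unique(stream.condition)}
    # a delay subtype implies its trial type occurs in the stream
    for t, sub in DELAY_SUBTYPES.items():
        if sub in types:
            types.add(("unimanual_right", "unimanual_left", "bimanual")[t])
    for t in ("unimanual_right", "unimanual_left"):
        if t in types:
            hand = "R" if t.endswith("right") else "L"
            req |= {f"{t}:{hand}-Q{q}" for q in range(1, 5)}
            req.add(f"delay_{t}")
    if "bimanual" in types:
        req.add("delay_bimanual")
    if types - {"rest"}:
        req.add(REST)
    return req


def assemble_snippets(
    stream: LabeledStream,
    n_snippets: int = 2000,
    snippet_len: int = SNIPPET_BINS,
    config: AugmentConfig | None = None,
    seed: int = 0,
) -> SnippetSet:
    """Build fixed-length training snippets from dilated, shuffled clips.

    Each snippet is assembled by appending accepted clips until it reaches
    ``snippet_len`` bins (the final clip is truncated).  A candidate clip is
    rejected (and redrawn) whenever accepting it would push any condition's
    share of total assembled bins above its target share by more than the
    configured tolerance.
    """
    config = config or AugmentConfig()
    config = AugmentConfig(
        snippet_len=snippet_len,
        clip_fraction=config.clip_fraction,
        dilation=config.dilation,
        tolerance=config.tolerance,
        allow_cross_trial=config.allow_cross_trial,
        max_rejects=config.max_rejects,
    )
    n_bins = len(stream)
    lo = max(2, int(np.ceil(config.clip_fraction[0] * snippet_len)))
    hi = int(np.floor(config.clip_fraction[1] * snippet_len))
    if n_bins <= hi:
        raise ValueError("stream too short to draw clips")

    missing = _required_conditions(stream) - set(np.unique(stream.condition))
    if missing:
        raise ValueError(f"balancing infeasible; conditions absent from stream: {sorted(missing)}")

    target = _target_shares(stream.condition)
    counts: dict[str, int] = {c: 0 for c in target}
    total = 0
    rng = np.random.default_rng(seed)

    S = n_snippets
    N = stream.inputs.shape[1]
    R = stream.outputs.shape[1]
    X = np.zeros((S, snippet_len, N))
    Y = np.zeros((S, snippet_len, R))
    provenance = []

    for s in range(S):
        filled = 0
        clips = []
        while filled < snippet_len:
            accepted = False
            for _ in range(config.max_rejects):
                raw_len = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, n_bins - raw_len))
                if not config.allow_cross_trial:
                    tid = stream.trial_ids[start : start + raw_len]
                    if len(np.unique(tid)) > 1:
                        continue
                d_f = float(rng.uniform(*config.dilation))
                new_in, new_out, new_lab = resample_clip(
                    stream.inputs[start : start + raw_len],
                    stream.outputs[start : start + raw_len],
                    d_f,
                    labels=stream.condition[start : start + raw_len],
                )
                used = min(len(new_in), snippet_len - filled)
                cand = {}
                for c in new_lab[:used]:
                    cand[c] = cand.get(c, 0) + 1
                new_total = total + used
                # soften the denominator during the first snippet's worth of
                # bins so early draws are not rejected on tiny totals
                denom = max(new_total, config.snippet_len)
                ok = all(
                    (counts.get(c, 0) + cand.get(c, 0)) / denom
                    <= target.get(c, 0.0) + config.tolerance
                    for c in set(counts) | set(cand)
                )
                if ok:
                    X[s, filled : filled + used] = new_in[:used]
                    Y[s, filled : filled + used] = new_out[:used]
                    for c, k in cand.items():
                        counts[c] = counts.get(c, 0) + k
                    total = new_total
                    clips.append(Clip(start, raw_len, d_f, used))
                    filled += used
                    accepted = True
                    break
            if not accepted:
                raise RuntimeError(
                    "could not draw a balanced clip; loosen the tolerance or "
                    "provide a longer/better-balanced stream"
                )
        provenance.append(clips)
    return SnippetSet(X, Y, counts, target, provenance, seed)


def replay_provenance(stream: LabeledStream, clips, snippet_len: int = SNIPPET_BINS):
    """Rebuild one snippet bit-exactly from its provenance record."""
    N, R = stream.inputs.shape[1], stream.outputs.shape[1]
    X = np.zeros((snippet_len, N))
    Y = np.zeros((snippet_len, R))
    filled = 0
    for c in clips:
        new_in, new_out = resample_clip(
            stream.inputs[c.start : c.start + c.raw_len],
            stream.outputs[c.start : c.start + c.raw_len],
            c.d_f,
        )
        X[filled : filled + c.used_len] = new_in[: c.used_len]
        Y[filled : filled + c.used_len] = new_out[: c.used_len]
        filled += c.used_len
    return X, Y


def stereotyped_snippets(stream: LabeledStream, snippet_len: int = SNIPPET_BINS) -> SnippetSet:
    """Cut the raw stream into consecutive unaltered snippets (no augmentation)."""
    n = (len(stream) // snippet_len) * snippet_len
    if n == 0:
        raise ValueError("stream shorter than one snippet")
    S = n // snippet_len
    X = stream.inputs[:n].reshape(S, snippet_len, -1)
    Y = stream.outputs[:n].reshape(S, snippet_len, -1)
    counts: dict[str, int] = {}
    for c in stream.condition[:n]:
        counts[c] = counts.get(c, 0) + 1
    prov = [
        [Clip(s * snippet_len, snippet_len, 1.0, snippet_len)] for s in range(S)
    ]
    return SnippetSet(X, Y, counts, _target_shares(stream.condition), prov, seed=-1)


def split_pools(stream: LabeledStream, validation_fraction: float, seed: int = 0):
    """Trial-level split into disjoint training and validation streams."""
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    trials = np.unique(stream.trial_ids)
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(validation_fraction * len(trials))))
    val_trials = set(rng.choice(trials, size=n_val, replace=False).tolist())
    val_mask = np.isin(stream.trial_ids, list(val_trials))

    def subset(mask):
        return LabeledStream(
            stream.inputs[mask],
            stream.outputs[mask],
            stream.condition[mask],
            stream.trial_ids[mask],
        )

    return subset(~val_mask), subset(val_mask)
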
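"""EEG signal chain and FLDA target classification.

Preprocessing follows the standard single-trial P300 recipe: zero-phase
band-pass at 0.1-30 Hz on the 1 kHz / 30-channel recording; per stimulus
flash an 800 ms epoch is cut, the 50-800 ms window retained, the window
mean removed, and a 50-fold rate reduction applied (non-overlapping
50-sample block means by default), giving 15 values per channel which are
concatenated head-to-tail over the 30 channels into a 450-length feature
vector.  A shrinkage-regularized Fisher linear discriminant trained on
target (+1) vs nontarget (-1) epochs scores each flash; a repetition is
classified as the cell at (argmax row score, argmax column score); online
selections vote over 3 repetitions, falling back to the largest summed
discriminant score when all three disagree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .p300_speller import SpellerLayout

__all__ = [
    "SFREQ",
    "N_CHANNELS",
    "N_FEATURES",
    "RawEEG",
    "FLDAModel",
    "bandpass_filter",
    "extract_features",
    "train_flda",
    "classify_repetition",
    "vote_online",
    "session_accuracy",
    "training_set",
    "predict_session",
    "save_model",
    "load_model",
    "save_raw",
    "load_raw",
]

SFREQ = 1000.0  # Hz, fixed by the acquisition protocol
N_CHANNELS = 30
BAND = (0.1, 30.0)  # Hz
FILTER_ORDER = 4
EPOCH_MS = 800
WINDOW_START_MS = 50
DECIMATION = 50
SAMPLES_PER_CHANNEL = (EPOCH_MS - WINDOW_START_MS) // DECIMATION  # 15
N_FEATURES = N_CHANNELS * SAMPLES_PER_CHANNEL  # 450


@dataclass
class RawEEG:
    """A 30-channel, 1 kHz recording plus its stimulus event log.

    ``events`` is a DataFrame with one row per flash: ``sample`` (absolute
    onset sample index), ``kind`` ('row'|'col'), ``index`` (0..2),
    ``trial`` and ``repetition`` counters; ``true_targets`` holds one
    target id per trial (None for unlabeled recordings).
    """

    data: np.ndarray
    events: pd.DataFrame
    sfreq: float = SFREQ
    true_targets: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(f"data must be ({N_CHANNELS}, n_samples), got {self.data.shape}")
        if self.sfreq != SFREQ:
            raise ValueError(f"sampling rate is fixed at {SFREQ} Hz")
        required = {"sample", "kind", "index", "trial", "repetition"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"event log must have columns {sorted(required)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def bandpass_filter(raw: RawEEG) -> RawEEG:
    """Zero-phase 0.1-30 Hz band-pass (4th-order Butterworth, forward-backward).

    Realized in second-order sections: the 0.1 Hz edge at a 1 kHz rate makes
    the polynomial transfer-function form numerically unstable.
    """
    sos = butter(FILTER_ORDER, BAND, btype="bandpass", fs=raw.sfreq, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if raw.n_samples <= padlen:
        raise ValueError(f"recording too short for the filter warm-up ({padlen} samples)")
    filtered = sosfiltfilt(sos, raw.data, axis=1)
    return RawEEG(
        data=filtered, events=raw.events.copy(), sfreq=raw.sfreq, true_targets=raw.true_targets
    )


def extract_features(raw: RawEEG, onset: int, block_mean: bool = True) -> np.ndarray:
    """450-length feature vector for the flash at sample index ``onset``.

    Window (onset+50 ms, onset+800 ms] = 750 samples per channel; window
    mean removed; 50-fold rate reduction (block means, or every 50th sample
    when ``block_mean`` is False); channels concatenated head to tail.
    """
    start = onset + WINDOW_START_MS + 1
    stop = onset + EPOCH_MS + 1
    if onset < 0 or stop > raw.n_samples:
        raise ValueError(f"epoch [{onset}, {onset + EPOCH_MS}] outside the recording")
    seg = raw.data[:, start:stop]
    seg = seg - seg.mean(axis=1, keepdims=True)
    if block_mean:
        reduced = seg.reshape(N_CHANNELS, SAMPLES_PER_CHANNEL, DECIMATION).mean(axis=2)
    else:
        reduced = seg[:, ::DECIMATION]
    return reduced.reshape(-1)


@dataclass
class FLDAModel:
    """Fisher linear discriminant: score(x) = w.x + b, target class positive."""

    weights: np.ndarray
    bias: float
    shrinkage: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ValueError("model coefficients must be finite")

    def score(self, X: np.ndarray) -> np.ndarray | float:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.weights.shape[0]:
            raise ValueError(f"expected {self.weights.shape[0]} features, got {X.shape[-1]}")
        return X @ self.weights + self.bias


def train_flda(X: np.ndarray, y: np.ndarray, shrinkage: float = 0.05) -> FLDAModel:
    """Fit the discriminant on labelled epochs (+1 target / -1 nontarget).

    w solves (S_w + shrinkage * mean-diagonal * I) w = mu_+ - mu_-, with
    S_w the pooled within-class scatter; the bias centers the projected
    class-mean midpoint at zero.  Shrinkage keeps the 450-D scatter
    invertible for small sessions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
    if not (0.0 <= shrinkage < 1.0):
        raise ValueError("shrinkage must lie in [0, 1)")
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes (+1 and -1) must be present")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    cp, cn = pos - mu_p, neg - mu_n
    scatter = cp.T @ cp + cn.T @ cn
    d = X.shape[1]
    ridge = shrinkage * np.trace(scatter) / d
    if ridge <= 0.0:
        ridge = shrinkage if shrinkage > 0.0 else 1e-12
    scatter = scatter + ridge * np.eye(d)
    w = np.linalg.solve(scatter, mu_p - mu_n)
    b = -float(w @ (mu_p + mu_n) / 2.0)
    return FLDAModel(weights=w, bias=b, shrinkage=shrinkage)


_STIMULI = tuple(("row", i) for i in range(3)) + tuple(("col", i) for i in range(3))


def classify_repetition(scores: dict[tuple[str, int], float], layout: SpellerLayout) -> str:
    """Cell at (argmax row score, argmax col score); ties -> lowest index.

    ``scores`` must hold exactly one score per row/column stimulus.
    """
    if set(scores) != set(_STIMULI) or len(scores) != 6:
        raise ValueError("need exactly 6 scores, one per row and column")
    row = int(np.argmax([scores[("row", i)] for i in range(3)]))
    col = int(np.argmax([scores[("col", i)] for i in range(3)]))
    return layout.target_at(row, col)


def vote_online(
    predictions: list[str], fallback_scores: dict[str, float] | None = None
) -> str:
    """Majority vote over the 3 online repetitions.

    A target with >= 2 of the 3 votes wins; when all three disagree the
    target with the greatest summed row+column discriminant score across
    the repetitions is selected (``fallback_scores``).
    """
    if len(predictions) != 3:
        raise ValueError(f"need exactly 3 repetition predictions, got {len(predictions)}")
    (winner, count), = Counter(predictions).most_common(1)
    if count >= 2:
        return winner
    if fallback_scores is None:
        raise ValueError("all three predictions differ and no fallback scores were given")
    return max(sorted(fallback_scores), key=lambda t: fallback_scores[t])


def session_accuracy(results: list[tuple[str, str]]) -> float:
    """Percent of correct (predicted, true) selections, half-up, 2 decimals."""
    if not results:
        raise ValueError("no selection results to score")
    correct = sum(1 for pred, true in results if pred == true)
    pct = 100.0 * correct / len(results)
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# session-level plumbing

def _event_scores(model: FLDAModel, raw: RawEEG, block_mean: bool = True) -> np.ndarray:
    feats = np.stack(
        [extract_features(raw, int(s), block_mean=block_mean) for s in raw.events["sample"]]
    )
    return np.asarray(model.score(feats), dtype=float)


def training_set(
    raw: RawEEG, layout: SpellerLayout | None = None, block_mean: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and +-1 labels for every flash of a labelled session."""
    layout = layout or SpellerLayout()
    if raw.true_targets is None:
        raise ValueError("training requires true_targets on the recording")
    X, y = [], []
    for rec in raw.events.to_dict("records"):
        X.append(extract_features(raw, int(rec["sample"]), block_mean=block_mean))
        pos = layout.position(raw.true_targets[int(rec["trial"])])
        covers = (rec["kind"] == "row" and rec["index"] == pos[0]) or (
            rec["kind"] == "col" and rec["index"] == pos[1]
        )
        y.append(1 if covers else -1)
    return np.stack(X), np.asarray(y)


def predict_session(
    model: FLDAModel,
    raw: RawEEG,
    layout: SpellerLayout | None = None,
    mode: str = "offline",
    block_mean: bool = True,
) -> list[str]:
    """Predicted target per trial of a (filtered) session.

    ``mode='offline'`` sums each stimulus's scores over all of a trial's
    repetitions before the row/column argmax; ``mode='online'`` classifies
    each repetition separately and votes over the 3 repetitions.
    """
    if mode not in ("offline", "online"):
        raise ValueError(f"mode must be 'offline' or 'online', got {mode!r}")
    layout = layout or SpellerLayout()
    events = raw.events.copy()
    events["score"] = _event_scores(model, raw, block_mean=block_mean)

    predictions = []
    for _, trial_ev in events.groupby("trial", sort=True):
        if mode == "offline":
            summed = {
                (kind, idx): float(grp["score"].sum())
                for (kind, idx), grp in trial_ev.groupby(["kind", "index"])
            }
            predictions.append(classify_repetition(summed, layout))
        else:
            rep_preds = []
            totals: dict[str, float] = {t: 0.0 for t in layout.targets}
            for _, rep_ev in trial_ev.groupby("repetition", sort=True):
                scores = {
                    (str(rec["kind"]), int(rec["index"])): float(rec["score"])
                    for rec in rep_ev.to_dict("records")
                }
                rep_preds.append(classify_repetition(scores, layout))
                for t in layout.targets:
                    r, c = layout.position(t)
                    totals[t] += scores[("row", r)] + scores[("col", c)]
            predictions.append(vote_online(rep_preds, totals))
    return predictions


# ---------------------------------------------------------------------------
# flat-text I/O for models and recordings

def save_model(path, model: FLDAModel) -> None:
    header = f"flda shrinkage={model.shrinkage} bias={model.bias!r}"
    np.savetxt(path, model.weights, header=header)


def load_model(path) -> FLDAModel:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    fields = dict(part.split("=", 1) for part in header[1:])
    weights = np.loadtxt(path)
    return FLDAModel(
        weights=weights, bias=float(fields["bias"]), shrinkage=float(fields["shrinkage"])
    )


def save_raw(path_data, path_events, raw: RawEEG) -> None:
    """Recording as delimited text: one row per sample; events as TSV."""
    cols = [f"ch{c:02d}" for c in range(N_CHANNELS)]
    df = pd.DataFrame(raw.data.T, columns=cols)
    df.to_csv(path_data, sep="\t", index=False, float_format="%.6f")
    ev = raw.events.copy()
    if raw.true_targets is not None:
        ev["true_target"] = [raw.true_targets[int(t)] for t in ev["trial"]]
    ev.to_csv(path_events, sep="\t", index=False)


def load_raw(path_data, path_events) -> RawEEG:
    data = pd.read_csv(path_data, sep="\t").to_numpy().T
    ev = pd.read_csv(path_events, sep="\t")
    true_targets = None
    if "true_target" in ev.columns:
        per_trial = ev.groupby("trial", sort=True)["true_target"].first()
        true_targets = tuple(per_trial.tolist())
        ev = ev.drop(columns=["true_target"])
    return RawEEG(data=data, events=ev, true_targets=true_targets)
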
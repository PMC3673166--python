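"""Behaviour prediction from immersion/light windows.

A feed-forward neural network (one hidden layer, logistic activation,
softmax output) is trained to predict the GPS-derived behaviour label of a
moment from a fixed-length window of logger samples centred on it.  The
training protocol mirrors supervised bio-logging practice:

* a class-balanced pool (default 2000 examples, as equal per class as
  3 divides it) is drawn at random from the labelled windows to avoid the
  classifier learning the class prior;
* the pool splits 50/25/25 into training / test / validation subsets;
* network weights are checkpointed at the epoch that maximises accuracy on
  the *test* subset (early stopping), and performance is reported on the
  untouched *validation* subset together with a permutation p-value
  against chance.

Applied to a year-round logger record, the model emits one behaviour per
10-min sample, which is then aggregated into daily activity budgets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier

from shearwater.labelling import LABELS
from shearwater.synthetic import SALT_MAX, LIGHT_MAX

_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class ModelConfig:
    """Classifier and sampling configuration.

    ``window_samples`` must be odd: a window covers (W-1)/2 logger samples
    either side of its centre (default 35 samples ~ 5.8 h at 10-min
    cadence).  ``use_light`` appends the light channel to the salt
    features.
    """

    total_examples: int = 2000
    split: tuple = (0.50, 0.25, 0.25)
    window_samples: int = 35
    hidden_units: int = 10
    max_epochs: int = 150
    learning_rate: float = 1e-3
    use_light: bool = False
    label_match_tolerance_s: float = 600.0
    max_gap_interpolate: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_samples % 2 != 1:
            raise ValueError("window_samples must be odd (centred windows)")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class FeatureWindows:
    """Stacked feature windows: X (n, d), centre times and labels."""

    X: np.ndarray
    center_time: pd.DatetimeIndex
    labels: np.ndarray  # behaviour string or "unknown"


@dataclass
class ConfusionResult:
    matrix: np.ndarray  # rows true, cols predicted, order rest/flight/forage
    accuracy: float
    per_class_accuracy: dict
    balanced_accuracy: float
    permutation_p: float | None = None


def make_windows(
    logger: pd.DataFrame,
    labelled: pd.DataFrame | None,
    config: ModelConfig | None = None,
) -> FeatureWindows:
    """Slide a centred window over the logger series.

    One window per sample whose full window fits in the series.  Missing
    samples (NaN salt) are linearly interpolated up to
    ``max_gap_interpolate`` consecutive samples; windows still containing
    NaN are dropped.  When ``labelled`` fixes are given, each window takes
    the label of the fix nearest its centre time if within
    ``label_match_tolerance_s``, else ``unknown``.
    """
    cfg = config or ModelConfig()
    W = cfg.window_samples
    if W > len(logger):
        raise ValueError(f"window of {W} samples exceeds series length {len(logger)}")
    log = logger.sort_values("time").reset_index(drop=True)
    salt = log["salt"].to_numpy(float) / SALT_MAX
    salt = _interpolate_gaps(salt, cfg.max_gap_interpolate)
    channels = [salt]
    if cfg.use_light:
        channels.append(log["light"].to_numpy(float) / LIGHT_MAX)
    half = W // 2
    centers = np.arange(half, len(log) - half)
    X = np.hstack(
        [np.lib.stride_tricks.sliding_window_view(c, W) for c in channels]
    )
    times = pd.DatetimeIndex(log["time"])[centers]

    good = ~np.isnan(X).any(axis=1)
    X, times = X[good], times[good]

    if labelled is not None and len(labelled):
        lab_ok = labelled[labelled["label"].isin(LABELS)]
        lab_t = pd.DatetimeIndex(lab_ok["time"]).astype("int64").to_numpy() / 1e9
        lab_v = lab_ok["label"].to_numpy()
        ct = times.astype("int64").to_numpy() / 1e9
        labels = np.full(len(ct), "unknown", dtype=object)
        if len(lab_t):
            pos = np.searchsorted(lab_t, ct)
            for k, (c, p) in enumerate(zip(ct, pos)):
                best, bdt = None, np.inf
                for q in (p - 1, p):
                    if 0 <= q < len(lab_t):
                        dt = abs(lab_t[q] - c)
                        if dt < bdt:
                            best, bdt = q, dt
                if best is not None and bdt <= cfg.label_match_tolerance_s:
                    labels[k] = lab_v[best]
    else:
        labels = np.full(len(times), "unknown", dtype=object)
    return FeatureWindows(X=X, center_time=times, labels=labels)


def _interpolate_gaps(x: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill NaN runs of length <= max_gap by linear interpolation."""
    x = x.copy()
    isnan = np.isnan(x)
    if not isnan.any():
        return x
    idx = np.arange(len(x))
    i = 0
    while i < len(x):
        if isnan[i]:
            j = i
            while j < len(x) and isnan[j]:
                j += 1
            if j - i <= max_gap and i > 0 and j < len(x):
                x[i:j] = np.interp(idx[i:j], [i - 1, j], [x[i - 1], x[j]])
            i = j
        else:
            i += 1
    return x


def balance_and_split(
    windows: FeatureWindows, config: ModelConfig | None = None, seed: int | None = None
) -> tuple:
    """Draw a class-balanced pool and split it 50/25/25.

    Per-class counts follow a largest-remainder allocation of
    ``total_examples`` over the three classes (they differ by at most one
    when 3 does not divide the total).  Each subset is itself built
    class-by-class so it stays balanced.  Returns
    ``(train, test, validation)`` as (X, y) pairs with integer labels.
    """
    cfg = config or ModelConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    per_class_base = cfg.total_examples // 3
    remainder = cfg.total_examples - 3 * per_class_base
    counts = {
        lab: per_class_base + (1 if i < remainder else 0) for i, lab in enumerate(LABELS)
    }
    picked: dict[str, np.ndarray] = {}
    for lab in LABELS:
        pool = np.flatnonzero(windows.labels == lab)
        if len(pool) < counts[lab]:
            raise ValueError(
                f"class '{lab}' has only {len(pool)} labelled windows, "
                f"needs {counts[lab]}"
            )
        picked[lab] = rng.choice(pool, size=counts[lab], replace=False)

    # exact subset sizes by largest remainder over the split fractions
    raw = [f * cfg.total_examples for f in cfg.split]
    sizes = [int(np.floor(r)) for r in raw]
    for k in sorted(range(3), key=lambda k: raw[k] - sizes[k], reverse=True)[
        : cfg.total_examples - sum(sizes)
    ]:
        sizes[k] += 1
    # greedy class-balanced assignment: always draw from the class with the
    # most examples left, keeping every subset within one example of balance
    queues = {lab: list(rng.permutation(picked[lab])) for lab in LABELS}
    out = []
    for size in sizes:
        sel = []
        for _ in range(size):
            lab = max(LABELS, key=lambda l: len(queues[l]))
            sel.append(queues[lab].pop())
        sel = np.asarray(sel)
        rng.shuffle(sel)
        y = np.array([_LABEL_INDEX[l] for l in windows.labels[sel]])
        out.append((windows.X[sel], y))
    return tuple(out)


@dataclass
class ClassifierModel:
    """Trained network plus the normalisation fitted on the training subset."""

    net: MLPClassifier
    feature_mean: np.ndarray
    feature_std: np.ndarray
    config: ModelConfig
    history: list = field(default_factory=list)  # per-epoch test accuracy
    best_epoch: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_mean) / self.feature_std
        return self.net.predict_proba(Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(LABELS, dtype=object)[np.argmax(self.predict_proba(X), axis=1)]

    def to_json(self) -> str:
        payload = {
            "labels": list(LABELS),
            "config": asdict(self.config),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "coefs": [w.tolist() for w in self.net.coefs_],
            "intercepts": [b.tolist() for b in self.net.intercepts_],
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        p = json.loads(text)
        cfgd = dict(p["config"])
        cfgd["split"] = tuple(cfgd["split"])
        cfg = ModelConfig(**cfgd)
        net = _fresh_net(cfg)
        coefs = [np.asarray(w) for w in p["coefs"]]
        X0 = np.zeros((3, coefs[0].shape[0]))
        net.partial_fit(X0, np.array([0, 1, 2]), classes=[0, 1, 2])
        net.coefs_ = coefs
        net.intercepts_ = [np.asarray(b) for b in p["intercepts"]]
        return cls(
            net=net,
            feature_mean=np.asarray(p["feature_mean"]),
            feature_std=np.asarray(p["feature_std"]),
            config=cfg,
            history=p["history"],
            best_epoch=p["best_epoch"],
        )


def _fresh_net(cfg: ModelConfig) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation="logistic",
        solver="adam",
        learning_rate_init=cfg.learning_rate,
        random_state=cfg.seed,
        max_iter=1,
        warm_start=False,
    )


def train_classifier(
    train: tuple, test: tuple, config: ModelConfig | None = None, seed: int | None = None
) -> ClassifierModel:
    """Train with per-epoch checkpointing on test-subset accuracy.

    Runs ``max_epochs`` passes of minibatch gradient descent; after each
    epoch the test accuracy is recorded and the weights of the best epoch
    are restored at the end.  Deterministic for a given seed.
    """
    cfg = config or ModelConfig()
    if seed is not None:
        cfg = ModelConfig(**{**asdict(cfg), "seed": seed})
    Xtr, ytr = train
    Xte, yte = test
    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0)
    std[std == 0] = 1.0
    Ztr, Zte = (Xtr - mean) / std, (Xte - mean) / std

    net = _fresh_net(cfg)
    classes = np.array([0, 1, 2])
    best_acc, best_epoch, best_weights = -1.0, 0, None
    history = []
    for epoch in range(cfg.max_epochs):
        net.partial_fit(Ztr, ytr, classes=classes)
        if np.any(~np.isfinite(net.coefs_[0])):
            raise RuntimeError(f"training diverged (non-finite weights) at epoch {epoch}")
        acc = float(np.mean(net.predict(Zte) == yte))
        history.append(acc)
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_weights = (
                [w.copy() for w in net.coefs_],
                [b.copy() for b in net.intercepts_],
            )
    net.coefs_, net.intercepts_ = best_weights
    return ClassifierModel(
        net=net,
        feature_mean=mean,
        feature_std=std,
        config=cfg,
        history=history,
        best_epoch=best_epoch,
    )


def evaluate_classifier(
    model: ClassifierModel,
    validation: tuple,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ConfusionResult:
    """Confusion matrix, accuracies and a permutation p-value vs chance.

    The p-value is the fraction of label permutations of the validation
    set whose accuracy reaches the observed one (add-one corrected).
    """
    Xv, yv = validation
    if len(yv) == 0:
        raise ValueError("validation set is empty")
    pred = np.argmax(model.predict_proba(Xv), axis=1)
    cm = _sk_confusion(yv, pred, labels=[0, 1, 2])
    acc = float(np.trace(cm) / cm.sum())
    per_class = {
        lab: (float(cm[i, i] / cm[i].sum()) if cm[i].sum() else float("nan"))
        for i, lab in enumerate(LABELS)
    }
    bal = float(np.nanmean(list(per_class.values())))
    rng = np.random.default_rng(seed)
    hits = sum(
        float(np.mean(pred == rng.permutation(yv))) >= acc for _ in range(n_permutations)
    )
    p = (hits + 1.0) / (n_permutations + 1.0)
    return ConfusionResult(
        matrix=cm,
        accuracy=acc,
        per_class_accuracy=per_class,
        balanced_accuracy=bal,
        permutation_p=p,
    )


def predict_series(
    model: ClassifierModel, logger: pd.DataFrame, config: ModelConfig | None = None
) -> pd.DataFrame:
    """One behaviour per logger sample with a complete window.

    Samples in the half-window margins at the ends of the series get label
    ``unknown`` with NaN probabilities.  The logger must run at the 10-min
    cadence the model was trained on.
    """
    cfg = config or model.config
    if len(logger) == 0:
        return pd.DataFrame(
            columns=["time", "label", "p_rest", "p_flight", "p_forage"]
        )
    log = logger.sort_values("time").reset_index(drop=True)
    dt = pd.DatetimeIndex(log["time"]).to_series().diff().dropna()
    expected = pd.Timedelta(seconds=600)
    if len(dt) and (dt.median() != expected):
        raise ValueError(
            f"logger cadence {dt.median()} differs from the 10-min training cadence"
        )
    windows = make_windows(log, None, cfg)
    proba = model.predict_proba(windows.X)
    out = pd.DataFrame(
        {
            "time": pd.DatetimeIndex(log["time"]),
            "label": "unknown",
            "p_rest": np.nan,
            "p_flight": np.nan,
            "p_forage": np.nan,
        }
    )
    pos = out["time"].isin(windows.center_time)
    out.loc[pos, ["p_rest", "p_flight", "p_forage"]] = proba
    out.loc[pos, "label"] = np.asarray(LABELS, dtype=object)[np.argmax(proba, axis=1)]
    return out


def daily_proportions(predictions: pd.DataFrame, min_known_fraction: float = 0.5) -> pd.DataFrame:
    """Per-UTC-day behaviour budget: proportions of rest/flight/forage.

    Proportions are over known labels and sum to 1; days where fewer than
    ``min_known_fraction`` of samples have a known label are flagged.
    """
    df = predictions.copy()
    df["date"] = pd.DatetimeIndex(df["time"]).date
    rows = []
    for date, g in df.groupby("date"):
        known = g[g["label"].isin(LABELS)]
        n = len(known)
        row = {"date": date, "n_known": n, "flagged": n < min_known_fraction * len(g)}
        for lab in LABELS:
            row[f"p_{lab}"] = float((known["label"] == lab).mean()) if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
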
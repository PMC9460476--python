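"""Streaming multi-day evaluation protocol, error metrics and drift PCA.

Predictors are trained on the first 50% of day-1 trials.  The remaining
trials stream in chronological order: every event in a trial is predicted
with the current predictor, then the trial is handed to the adaptation
strategy, and after every two trials the predictors are retrained on the
grown pools.  No event ever enters a training pool before it has been
predicted; the audit trail proves this per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .activities import Activity
from .adapt import (
    AdaptationState,
    EntropyGate,
    PoolSample,
    backward_entropy_update,
    backward_relabel,
    entropy_select,
    maybe_retrain,
    perfect_update,
)
from .dataset import EventSample, SessionDataset
from .errors import ConfigurationError, ValidationError
from .models import (
    AnyClassifier,
    Classifier,
    ModeSpecificPredictor,
    NetConfig,
    train_backward,
    train_mode_specific,
)

BACKWARD_STRATEGIES = ("backward", "backward_entropy")


def error_rate(predictions: Sequence, truth: Sequence) -> float:
    """Wrongly classified samples divided by total samples."""
    if len(predictions) != len(truth):
        raise ValidationError("predictions and truth differ in length")
    if len(predictions) == 0:
        raise ValidationError("cannot compute an error rate on zero samples")
    wrong = sum(1 for p, t in zip(predictions, truth) if p != t)
    return wrong / len(predictions)


@dataclass(frozen=True)
class ProtocolConfig:
    """Streaming protocol parameters."""

    strategy: str = "baseline"
    train_fraction: float = 0.5
    retrain_interval: int = 2
    net: NetConfig = NetConfig()
    seed: int = 0
    random_split: bool = False
    pool_cap: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train fraction must lie in (0, 1)")
        if self.retrain_interval < 1:
            raise ConfigurationError("retrain interval must be >= 1")


@dataclass
class EvaluationResult:
    """Per-day and running error rates plus the full audit trail."""

    strategy: str
    seed: int
    days: list[int]
    predictions: pd.DataFrame
    retrain_log: pd.DataFrame
    selection_log: pd.DataFrame
    pool_audit: pd.DataFrame = field(default_factory=pd.DataFrame)
    initial_uids: set = field(default_factory=set)

    @property
    def day_errors(self) -> dict[int, float]:
        g = self.predictions.groupby("day", sort=False)["fwd_wrong"].mean()
        return {int(d): float(v) for d, v in g.items()}

    @property
    def day_backward_errors(self) -> dict[int, float] | None:
        if "bwd_wrong" not in self.predictions.columns:
            return None
        sub = self.predictions.dropna(subset=["bwd_wrong"])
        g = sub.groupby("day", sort=False)["bwd_wrong"].mean()
        return {int(d): float(v) for d, v in g.items()}

    @property
    def running_errors(self) -> pd.DataFrame:
        g = (
            self.predictions.groupby("stream_pos", sort=True)
            .agg(day=("day", "first"), error=("fwd_wrong", "mean"), n=("fwd_wrong", "size"))
            .reset_index()
        )
        return g

    def summary(self) -> str:
        lines = [
            "Streaming evaluation" ,
            "=" * 60,
            f"strategy: {self.strategy}    seed: {self.seed}",
            f"{'day':>5} {'n':>7} {'forward error':>14}"
            + ("  backward error" if self.day_backward_errors else ""),
        ]
        back = self.day_backward_errors or {}
        counts = self.predictions.groupby("day", sort=False).size()
        for d, err in self.day_errors.items():
            row = f"{d:>5} {int(counts[d]):>7} {100 * err:>13.1f}%"
            if d in back:
                row += f" {100 * back[d]:>14.1f}%"
            lines.append(row)
        lines.append(f"retrains: {int(self.retrain_log['executed'].sum()) if len(self.retrain_log) else 0}")
        return "\n".join(lines)


def _initial_pools(
    trials: list[list[EventSample]], state: AdaptationState
) -> tuple[list[EventSample], list[EventSample]]:
    fwd, bwd = [], []
    for trial in trials:
        for ev in trial:
            fwd.append(ev)
            state.add_forward(PoolSample(ev.uid, ev.mode, ev.label, ev.forward, "initial", -1))
            if ev.backward is not None:
                bwd.append(ev)
                state.add_backward(
                    PoolSample(ev.uid, ev.mode, ev.label, ev.backward, "initial", -1)
                )
    return fwd, bwd


def _pool_audit_frame(state: AdaptationState) -> pd.DataFrame:
    rows = [
        {"pool": pool_name, "uid": p.uid, "origin": p.origin, "added_at": p.added_at,
         "label": p.label.value, "mode": p.mode.value}
        for pool_name, pool in (("forward", state.forward_pool), ("backward", state.backward_pool))
        for p in pool
    ]
    return pd.DataFrame(rows, columns=["pool", "uid", "origin", "added_at", "label", "mode"])


def _retrain_forward(
    state: AdaptationState,
    class_lists: dict[Activity, list[Activity]],
    net: NetConfig,
    seed: int,
) -> ModeSpecificPredictor:
    samples = [
        EventSample(day=0, trial=0, event=0, mode=p.mode, label=p.label, forward=p.features)
        for p in state.forward_pool
    ]
    return train_mode_specific(samples, replace(net, seed=seed), class_lists=class_lists)


def run_protocol(dataset: SessionDataset, config: ProtocolConfig) -> EvaluationResult:
    """Run one strategy through the streaming multi-day protocol."""
    if not dataset.days:
        raise ValidationError("dataset has no days")
    day1 = dataset.days[0]
    trials1 = dataset.trials[day1]
    if len(trials1) < 2:
        raise ValidationError("day 1 needs at least 2 trials")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xADA]))
    n_train = max(1, int(round(config.train_fraction * len(trials1))))
    order = list(range(len(trials1)))
    if config.random_split:
        order = list(rng.permutation(len(trials1)))
    train_ids = sorted(order[:n_train])
    test_ids1 = sorted(set(range(len(trials1))) - set(train_ids))

    state = AdaptationState(
        strategy=config.strategy,
        retrain_interval=config.retrain_interval,
        pool_cap=config.pool_cap,
    )
    init_fwd, init_bwd = _initial_pools([trials1[i] for i in train_ids], state)
    initial_uids = {ev.uid for ev in init_fwd}

    class_lists = {
        m: sorted({s.label for s in init_fwd if s.mode is m}, key=lambda a: a.value)
        for m in {s.mode for s in init_fwd}
    }
    base_seed = int(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31))
    forward = train_mode_specific(
        init_fwd, replace(config.net, seed=base_seed), class_lists=class_lists
    )
    needs_backward = config.strategy in BACKWARD_STRATEGIES
    backward_clf: Classifier | None = None
    if needs_backward:
        bx = np.array([ev.backward for ev in init_bwd])
        by = [ev.label for ev in init_bwd]
        backward_clf = train_backward(
            bx, by, replace(config.net, seed=base_seed + 1), classes=list(dataset.classes)
        )
        backward_gate = EntropyGate(n_classes=backward_clf.n_classes)

    stream: list[tuple[int, int, list[EventSample]]] = [
        (day1, i, trials1[i]) for i in test_ids1
    ]
    for day in dataset.days[1:]:
        stream.extend((day, i, t) for i, t in enumerate(dataset.trials[day]))

    pred_rows: list[dict] = []
    retrain_rows: list[dict] = []
    retrain_count = 0
    last_pool_sizes = (len(state.forward_pool), len(state.backward_pool))

    for pos, (day, t_idx, trial) in enumerate(stream):
        # prediction pass: every event is predicted before any updating
        trial_posteriors: list[tuple[np.ndarray, list[Activity]]] = []
        for ev in trial:
            post, classes = forward.posterior(ev.mode, ev.forward)
            pred = classes[int(np.argmax(post))]
            row = {
                "uid": ev.uid,
                "day": day,
                "trial": t_idx,
                "event": ev.event,
                "stream_pos": pos,
                "mode": ev.mode.value,
                "true_label": ev.label.value,
                "fwd_pred": pred.value,
                "fwd_wrong": int(pred is not ev.label),
            }
            if needs_backward and backward_clf is not None:
                if ev.backward is not None:
                    bpost = backward_clf.predict_posterior(ev.backward)
                    bpred = backward_clf.classes[int(np.argmax(bpost))]
                    row["bwd_pred"] = bpred.value
                    row["bwd_wrong"] = int(bpred is not ev.label)
                else:
                    row["bwd_pred"] = None
                    row["bwd_wrong"] = np.nan
            pred_rows.append(row)
            trial_posteriors.append((post, classes))

        # update pass
        for ev, (post, classes) in zip(trial, trial_posteriors):
            if config.strategy == "baseline":
                continue
            if config.strategy == "perfect":
                perfect_update(ev, state, pos)
            elif config.strategy == "entropy":
                gate = EntropyGate(n_classes=len(classes))
                entropy_select(ev, post, classes, gate, state, pos)
            elif config.strategy == "backward":
                backward_relabel(ev, backward_clf, state, pos)
            elif config.strategy == "backward_entropy":
                backward_entropy_update(ev, backward_clf, backward_gate, state, pos)

        decision = maybe_retrain(state)
        if decision.due:
            pool_sizes = (len(state.forward_pool), len(state.backward_pool))
            executed = False
            if decision.retrain_forward and pool_sizes[0] != last_pool_sizes[0]:
                retrain_count += 1
                forward = _retrain_forward(
                    state, class_lists, config.net, base_seed + 100 + retrain_count
                )
                executed = True
            if decision.retrain_backward and pool_sizes[1] != last_pool_sizes[1]:
                bx = np.array([p.features for p in state.backward_pool])
                by = [p.label for p in state.backward_pool]
                backward_clf = train_backward(
                    bx, by,
                    replace(config.net, seed=base_seed + 5000 + retrain_count),
                    classes=list(dataset.classes),
                )
                executed = True
            retrain_rows.append(
                {
                    "stream_pos": pos,
                    "day": day,
                    "trial": t_idx,
                    "forward_pool": pool_sizes[0],
                    "backward_pool": pool_sizes[1],
                    "executed": executed,
                }
            )
            last_pool_sizes = pool_sizes

    predictions = pd.DataFrame(pred_rows)
    retrain_log = pd.DataFrame(
        retrain_rows,
        columns=["stream_pos", "day", "trial", "forward_pool", "backward_pool", "executed"],
    )
    selection_log = pd.DataFrame(state.selection_log)
    return EvaluationResult(
        strategy=config.strategy,
        seed=config.seed,
        days=list(dataset.days),
        predictions=predictions,
        retrain_log=retrain_log,
        selection_log=selection_log,
        pool_audit=_pool_audit_frame(state),
        initial_uids=initial_uids,
    )


def verify_causality(result: EvaluationResult) -> int:
    """Number of audit violations: pool entries whose event had not yet been
    predicted when it entered a pool.

    Initial (day-1 first-half) training samples are exempt — they are never
    streamed, hence never tested.  Every other pool entry must belong to an
    event predicted at a stream position <= its insertion position.
    """
    if result.pool_audit.empty:
        return 0
    predicted_at = {
        uid: pos
        for uid, pos in zip(result.predictions["uid"], result.predictions["stream_pos"])
    }
    violations = 0
    for row in result.pool_audit.itertuples():
        if row.origin == "initial":
            if row.uid not in result.initial_uids or row.uid in predicted_at:
                violations += 1
        elif row.uid not in predicted_at or predicted_at[row.uid] > row.added_at:
            violations += 1
    return violations


def per_activity_errors(result: EvaluationResult) -> pd.DataFrame:
    """day x activity table of forward error rates, conditioned on the TRUE
    label; cells with zero samples are NaN."""
    table = result.predictions.pivot_table(
        index="day", columns="true_label", values="fwd_wrong", aggfunc="mean"
    )
    order = [a.value for a in Activity if a.value in table.columns]
    return table[order]


def aggregate_runs(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Mean +/- SD of per-day error rates across runs, per strategy."""
    if len(results) < 2:
        raise ValidationError("aggregation needs at least 2 runs")
    rows = []
    for r in results:
        for d, e in r.day_errors.items():
            rows.append({"strategy": r.strategy, "day": d, "seed": r.seed, "error": e})
    frame = pd.DataFrame(rows)
    out = (
        frame.groupby(["strategy", "day"], sort=False)["error"]
        .agg(["mean", "std", "size"])
        .reset_index()
        .rename(columns={"std": "sd", "size": "n"})
    )
    return out


@dataclass
class PCADrift:
    """Two-component PCA of day-1 features with all days projected on it."""

    components: np.ndarray
    day1_mean: np.ndarray
    projections: dict[int, np.ndarray]
    means: dict[int, np.ndarray]
    ellipses: dict[int, tuple[float, float, float]]  # (sd_major, sd_minor, angle_rad)


def pca_drift(
    dataset: SessionDataset,
    n_components: int = 2,
    activity: Activity | None = None,
) -> PCADrift:
    """PCA fitted on day-1 forward features only; other days projected on the
    same components.  Per-day mean and one-SD ellipse parameters follow."""

    def matrix(day: int) -> np.ndarray:
        rows = [
            ev.forward
            for ev in dataset.iter_events(day)
            if activity is None or ev.label is activity
        ]
        return np.array(rows)

    x1 = matrix(dataset.days[0])
    if x1.shape[0] < n_components or np.linalg.matrix_rank(x1 - x1.mean(axis=0)) < n_components:
        raise ValidationError("day-1 features are rank-deficient for the requested components")
    pca = PCA(n_components=n_components)
    pca.fit(x1)
    projections, means, ellipses = {}, {}, {}
    for day in dataset.days:
        proj = pca.transform(matrix(day))
        projections[day] = proj
        means[day] = proj.mean(axis=0)
        cov = np.cov(proj, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
        ellipses[day] = (float(np.sqrt(max(eigval[0], 0.0))),
                         float(np.sqrt(max(eigval[1], 0.0))), angle)
    return PCADrift(
        components=pca.components_,
        day1_mean=pca.mean_,
        projections=projections,
        means=means,
        ellipses=ellipses,
    )


def compare_per_day(results_a: Sequence[EvaluationResult], results_b: Sequence[EvaluationResult]):
    """Paired per-seed comparison helper: returns per-day mean difference and
    paired t-test p-value (a minus b)."""
    days = results_a[0].days
    rows = []
    for d in days:
        a = np.array([r.day_errors[d] for r in results_a])
        b = np.array([r.day_errors[d] for r in results_b])
        t = stats.ttest_rel(a, b)
        rows.append({"day": d, "mean_diff": float((a - b).mean()), "p": float(t.pvalue)})
    return pd.DataFrame(rows)
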
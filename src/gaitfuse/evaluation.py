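"""Two-stage model-selection and robustness protocol.

Stage 1: every candidate classifier ensemble is evaluated under all
eight fusion rules with repeated stratified 10-fold cross-validation,
alongside the best single member on identical folds. For each rule we
count (a) how many ensembles fuse at least as accurately as their best
single member and (b) how many achieve their row maximum; the rule
maximizing (a) (ties by (b), then fixed rule order) is carried forward.

Stage 2: with the selected rule, each surviving ensemble is re-evaluated
under missing-feature scenarios -- all features of one kinematic channel
removed and the classifiers retrained -- emulating single-sensor failure.
Per ensemble, the scenario accuracies are summarized by their mean (in
percent) and population standard deviation (as a fraction); the ensemble
with maximal mean wins, ties broken by minimal SD, then smallest size.

Accuracies are percentages throughout. All comparisons use unrounded
values; rounding (2 decimals for percent, 4 for SD) is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from . import fusion
from .classifiers import ScoreMatrix
from .selection import FeatureGroup


@dataclass(frozen=True)
class EnsembleSpec:
    """A candidate combination of base classifiers (ids from 1..5)."""

    classifier_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        ids = tuple(sorted(set(int(i) for i in self.classifier_ids)))
        if len(ids) < 2:
            raise ValueError("an ensemble needs at least 2 distinct classifiers")
        if not set(ids) <= set(clf.DEFAULT_SPECS):
            raise ValueError(f"unknown classifier ids in {ids}")
        object.__setattr__(self, "classifier_ids", ids)

    def __str__(self) -> str:
        return ", ".join(str(i) for i in self.classifier_ids)


@dataclass(frozen=True)
class ScenarioResult:
    ensemble: EnsembleSpec
    rule: str
    scenario: str
    accuracy_mean: float  # percent, mean over repeats
    single_max: float     # percent, best member on identical folds
    member_accuracy: Mapping[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class RobustnessSummary:
    per_scenario_accuracy: tuple[float, ...]  # percent
    mean: float                               # percent
    sd: float                                 # population SD of fractions

    @property
    def display(self) -> tuple[float, float]:
        return round(self.mean, 2), round(self.sd, 4)


def stratified_kfold(y, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Shuffled stratified k-fold test-index sets; deterministic per seed."""
    y = np.asarray(y).ravel()
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def _fold_rule_hits(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    member_ids: Sequence[int],
    rules: Sequence[str],
    seed: int,
    alpha: float,
) -> tuple[dict[str, int], dict[int, int]]:
    """Correct-decision counts for every rule and member on one fold."""
    models = [clf.train(m, X[train_idx], y[train_idx], seed=seed) for m in member_ids]
    class_ids = models[0].class_ids
    test_scores = np.stack([m.score_batch(X[test_idx]) for m in models], axis=1)

    templates = None
    if "dt" in rules:
        train_scores = np.stack([m.score_batch(X[train_idx]) for m in models], axis=1)
        train_mats = [
            ScoreMatrix(z=s, classifier_ids=tuple(member_ids), class_ids=class_ids)
            for s in train_scores
        ]
        templates = fusion.dt_fit(train_mats, y[train_idx])

    rule_hits = {r: 0 for r in rules}
    for s, label in zip(test_scores, y[test_idx]):
        Z = ScoreMatrix(z=s, classifier_ids=tuple(member_ids), class_ids=class_ids)
        for r in rules:
            if fusion.fuse(Z, r, alpha=alpha, templates=templates) == label:
                rule_hits[r] += 1

    member_hits = {}
    for mid, scores in zip(member_ids, np.swapaxes(test_scores, 0, 1)):
        pred = np.asarray(class_ids)[np.argmax(scores, axis=1)]
        member_hits[mid] = int((pred == y[test_idx]).sum())
    return rule_hits, member_hits


def cv_accuracies(
    X,
    y,
    member_ids: Sequence[int],
    rules: Sequence[str],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.95,
) -> tuple[dict[str, float], dict[int, float]]:
    """Repeated stratified k-fold accuracies (percent) for fusion rules
    and individual ensemble members, on identical folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    ss = np.random.SeedSequence([int(seed), 0xE7A1])
    fold_seeds = ss.generate_state(repeats) % (2**31 - 1)
    rule_acc = {r: 0.0 for r in rules}
    member_acc = {m: 0.0 for m in member_ids}
    for r_i in range(repeats):
        rs = int(fold_seeds[r_i])
        folds = stratified_kfold(y, k=k, seed=rs)
        all_idx = np.arange(y.size)
        rh_total = {r: 0 for r in rules}
        mh_total = {m: 0 for m in member_ids}
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            rh, mh = _fold_rule_hits(
                X, y, train_idx, test_idx, member_ids, rules, seed=rs, alpha=alpha
            )
            for r in rules:
                rh_total[r] += rh[r]
            for m in member_ids:
                mh_total[m] += mh[m]
        for r in rules:
            rule_acc[r] += 100.0 * rh_total[r] / y.size
        for m in member_ids:
            member_acc[m] += 100.0 * mh_total[m] / y.size
    rule_acc = {r: v / repeats for r, v in rule_acc.items()}
    member_acc = {m: v / repeats for m, v in member_acc.items()}
    return rule_acc, member_acc


def run_cv(
    X,
    y,
    ensemble: EnsembleSpec,
    rule: str,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.95,
    scenario: str = "full",
) -> ScenarioResult:
    """Evaluate one (ensemble, rule) by repeated stratified k-fold CV."""
    rule_acc, member_acc = cv_accuracies(
        X, y, ensemble.classifier_ids, [rule], k=k, repeats=repeats, seed=seed, alpha=alpha
    )
    return ScenarioResult(
        ensemble=ensemble,
        rule=rule,
        scenario=scenario,
        accuracy_mean=rule_acc[rule],
        single_max=max(member_acc.values()),
        member_accuracy=member_acc,
    )


# ---------------------------------------------------------------------------
# stage 1: fusion-rule selection


def stage1_table(
    X,
    y,
    ensembles: Sequence[EnsembleSpec],
    rules: Sequence[str] = fusion.RULES,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.95,
) -> pd.DataFrame:
    """Accuracy matrix: one row per ensemble, columns single_max + rules."""
    if len(ensembles) == 0:
        raise ValueError("need at least one candidate ensemble")
    rows = []
    for ens in ensembles:
        rule_acc, member_acc = cv_accuracies(
            X, y, ens.classifier_ids, rules, k=k, repeats=repeats, seed=seed, alpha=alpha
        )
        rows.append({"ensemble": str(ens), "single_max": max(member_acc.values()), **rule_acc})
    return pd.DataFrame(rows).set_index("ensemble")


def stage1_counts(table: pd.DataFrame, rules: Sequence[str] = fusion.RULES) -> pd.DataFrame:
    """Per-rule counts over a stage-1 accuracy table.

    ``beats_single``: ensembles whose fused accuracy >= their best single
    member. ``row_max``: ensembles for which the rule attains the row
    maximum over all rules.
    """
    eps = 1e-9
    out = []
    rule_block = table[list(rules)]
    row_max = rule_block.max(axis=1)
    for r in rules:
        beats = int((table[r] >= table["single_max"] - eps).sum())
        at_max = int((table[r] >= row_max - eps).sum())
        out.append({"rule": r, "beats_single": beats, "row_max": at_max})
    return pd.DataFrame(out).set_index("rule")


def select_rule(counts: pd.DataFrame, rules: Sequence[str] = fusion.RULES) -> str:
    """Best rule: max beats_single, ties by row_max, then fixed rule order."""
    best = None
    for r in rules:  # iteration order is the documented tie-break
        row = counts.loc[r]
        key = (row["beats_single"], row["row_max"])
        if best is None or key > best[0]:
            best = (key, r)
    return best[1]


def stage1_compare(
    X,
    y,
    ensembles: Sequence[EnsembleSpec],
    rules: Sequence[str] = fusion.RULES,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Full stage 1: accuracy table, per-rule counts, selected rule."""
    table = stage1_table(X, y, ensembles, rules, k=k, repeats=repeats, seed=seed, alpha=alpha)
    counts = stage1_counts(table, rules)
    return table, counts, select_rule(counts, rules)


def improvement_pct(fused: float, single_max: float) -> float:
    """Fused-minus-best-single improvement, displayed to 2 decimals."""
    return round(fused - single_max, 2)


# ---------------------------------------------------------------------------
# stage 2: missing-feature robustness


def ablate_group(
    X, groups: Sequence[FeatureGroup], g: int | str, names: Sequence[str] | None = None
):
    """Remove all columns of one feature group (a failed sensor).

    ``g`` is a group position or a channel abbreviation. Returns the
    reduced matrix, or ``(matrix, remaining_names)`` when ``names`` is
    given.
    """
    X = np.asarray(X, dtype=float)
    if isinstance(g, str):
        matches = [grp for grp in groups if grp.channel_abbr == g]
        if not matches:
            raise ValueError(f"no feature group for channel {g!r}")
        group = matches[0]
    else:
        if not 0 <= g < len(groups):
            raise ValueError(f"group index {g} out of range")
        group = groups[g]
    drop = set(group.member_indices)
    keep = [j for j in range(X.shape[1]) if j not in drop]
    if names is None:
        return X[:, keep]
    return X[:, keep], [names[j] for j in keep]


def robustness_summary(acc) -> RobustnessSummary:
    """Mean (percent) and population SD (fraction) of 5 scenario accuracies."""
    acc = np.asarray(acc, dtype=float).ravel()
    if acc.size != 5:
        raise ValueError(f"expected exactly 5 scenario accuracies, got {acc.size}")
    frac = acc / 100.0
    return RobustnessSummary(
        per_scenario_accuracy=tuple(float(a) for a in acc),
        mean=float(acc.mean()),
        sd=float(frac.std()),  # population convention (divisor N)
    )


def stage2_robustness(
    X,
    y,
    groups: Sequence[FeatureGroup],
    ensembles: Sequence[EnsembleSpec],
    rule: str = "ds",
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.95,
) -> dict[EnsembleSpec, RobustnessSummary]:
    """Ablate each feature group in turn, retrain, and summarize.

    ``groups`` must hold exactly 5 groups (five sensor-failure
    scenarios); classifiers are retrained from scratch on each reduced
    feature set.
    """
    if len(groups) != 5:
        raise ValueError(f"the robustness protocol uses 5 scenarios, got {len(groups)}")
    summaries: dict[EnsembleSpec, RobustnessSummary] = {}
    for ens in ensembles:
        accs = []
        for gi in range(len(groups)):
            X_red = ablate_group(X, groups, gi)
            res = run_cv(
                X_red, y, ens, rule, k=k, repeats=repeats, seed=seed, alpha=alpha,
                scenario=f"no {groups[gi].channel_abbr} features",
            )
            accs.append(res.accuracy_mean)
        summaries[ens] = robustness_summary(accs)
    return summaries


def stage2_select(summaries: Mapping[EnsembleSpec, RobustnessSummary]) -> EnsembleSpec:
    """Pick the ensemble with maximal mean accuracy; ties by minimal SD,
    then smallest ensemble.
    """
    if not summaries:
        raise ValueError("no robustness summaries to select from")
    return min(
        summaries,
        key=lambda e: (
            -summaries[e].mean,
            summaries[e].sd,
            len(e.classifier_ids),
            e.classifier_ids,
        ),
    )
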
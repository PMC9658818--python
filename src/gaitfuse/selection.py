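"""Two-stage feature selection: mRMR ranking then a binary-matrix
shuffling filter (BMSF), plus the per-channel grouping used for the
missing-sensor ablation.

Stage 1 (mRMR) greedily ranks features by the MID criterion

    score(f) = I(f; y) - (1/|S|) * sum_{s in S} I(f; s)

with plug-in mutual information (in nats) on equal-frequency-binned
features. Stage 2 (BMSF) is a wrapper: random binary feature-inclusion
subsets are scored by cross-validated SVM accuracy and a feature is
retained when subsets that include it are reliably more accurate than
subsets that exclude it. BMSF is described only loosely in the
literature that introduced it; the update and stopping rules here are
this package's own reconstruction (documented in the methods note) --
the contract is "keeps informative features, sheds noise", not
bit-compatibility with any other implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import parse_feature_name


# ---------------------------------------------------------------------------
# mutual information and mRMR


def _equal_frequency_bins(f: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into (at most) ``bins`` equal-frequency codes."""
    edges = np.quantile(f, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, f, side="right")


def mutual_information(f, y, bins: int | None = None, *, y_discrete: bool = True) -> float:
    """Plug-in mutual information (nats) between a feature and labels.

    The feature is discretized into equal-frequency bins
    (default ``ceil(sqrt(N))``); ``y`` is treated as categorical unless
    ``y_discrete=False``, in which case it is binned the same way (used
    for feature-feature redundancy, where both variables are
    continuous). A constant feature carries no information and returns 0.
    """
    f = np.asarray(f, dtype=float).ravel()
    y = np.asarray(y).ravel()
    n = f.size
    if n < 10:
        raise ValueError("need at least 10 samples for a stable MI estimate")
    if y.size != n:
        raise ValueError("feature and labels must have equal length")
    if bins is None:
        bins = math.ceil(math.sqrt(n))
    if bins < 2:
        raise ValueError("bins must be >= 2")
    fb = _equal_frequency_bins(f, bins)
    yb = y if y_discrete else _equal_frequency_bins(y.astype(float), bins)
    _, fi = np.unique(fb, return_inverse=True)
    _, yi = np.unique(yb, return_inverse=True)
    joint = np.zeros((fi.max() + 1, yi.max() + 1))
    np.add.at(joint, (fi, yi), 1.0)
    joint /= n
    pf = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pf @ py)[nz])).sum())


def mrmr_rank(X, y, k: int, bins: int | None = None) -> list[int]:
    """Greedy mRMR (MID form): rank ``k`` features by relevance minus
    mean redundancy. The first pick is the feature with maximal I(f; y);
    each later pick maximizes I(f; y) - mean_{s selected} I(f; s).
    Returns column indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    n, p = X.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}, got {k}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")

    relevance = np.array([mutual_information(X[:, j], y, bins) for j in range(p)])
    selected: list[int] = [int(np.argmax(relevance))]
    remaining = [j for j in range(p) if j != selected[0]]
    # pairwise feature MI cached lazily: row = candidate, col = selected
    redundancy_sum = np.zeros(p)
    while len(selected) < k:
        last = selected[-1]
        for j in remaining:
            redundancy_sum[j] += mutual_information(
                X[:, j], X[:, last], bins, y_discrete=False
            )
        scores = relevance[remaining] - redundancy_sum[remaining] / len(selected)
        best = remaining[int(np.argmax(scores))]
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# BMSF


@dataclass(frozen=True)
class BmsfConfig:
    """Settings for the binary-matrix shuffling filter.

    ``n_rows`` random inclusion subsets are scored per iteration by
    ``cv``-fold cross-validated linear-SVM accuracy. A feature is locked
    in (or dropped) when its with/without mean-accuracy gap exceeds
    ``evidence_z`` standard errors of that gap and the floor
    ``retain_margin``; undecided features are reshuffled. Filtering is
    evidence-based: if no feature ever clears the threshold (e.g. every
    subset is equally accurate) nothing can be discarded and all
    non-dropped candidates are kept. ``force_size`` optionally
    truncates/extends the result to an exact subset size by
    accuracy-ranked search.
    """

    n_rows: int = 30
    max_iter: int = 8
    cv: int = 5
    retain_margin: float = 0.01
    evidence_z: float = 2.0
    include_prob: float = 0.5
    seed: int = 0
    force_size: int | None = None


@dataclass(frozen=True)
class SelectionResult:
    mrmr_ranking: tuple[int, ...]
    final_subset: tuple[int, ...]
    objective_trace: tuple[float, ...]
    converged: bool = True

    def __post_init__(self) -> None:
        if len(set(self.final_subset)) != len(self.final_subset):
            raise ValueError("final_subset contains duplicates")
        if not set(self.final_subset) <= set(self.mrmr_ranking):
            raise ValueError("final_subset must be a subset of mrmr_ranking")


def _subset_accuracy(X: np.ndarray, y: np.ndarray, cols: np.ndarray, cv: int, seed: int) -> float:
    model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    return float(cross_val_score(model, X[:, cols], y, cv=folds).mean())


def bmsf_select(
    X_candidates,
    y,
    cfg: BmsfConfig = BmsfConfig(),
    candidate_indices: Sequence[int] | None = None,
) -> SelectionResult:
    """Binary-matrix shuffling filter over a candidate feature matrix.

    ``candidate_indices`` (default ``range(p)``) are the labels reported
    in the result, so the mRMR ranking's original column indices survive
    the round trip. Deterministic given ``cfg.seed``.
    """
    X = np.asarray(X_candidates, dtype=float)
    y = np.asarray(y).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 candidate features")
    idx = np.arange(p) if candidate_indices is None else np.asarray(candidate_indices)
    if idx.size != p:
        raise ValueError("candidate_indices length must match matrix width")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB35F]))
    retained: set[int] = set()
    dropped: set[int] = set()
    undecided: set[int] = set(range(p))
    trace: list[float] = []
    converged = False

    for _ in range(cfg.max_iter):
        und = sorted(undecided)
        mask = np.zeros((cfg.n_rows, p), dtype=bool)
        mask[:, sorted(retained)] = True
        mask[:, und] = rng.random((cfg.n_rows, len(und))) < cfg.include_prob
        # every row needs at least one feature
        empty = ~mask.any(axis=1)
        if empty.any():
            mask[empty, rng.integers(0, p, size=int(empty.sum()))] = True

        acc = np.array(
            [
                _subset_accuracy(X, y, np.flatnonzero(row), cfg.cv, cfg.seed)
                for row in mask
            ]
        )
        trace.append(float(acc.mean()))

        newly_decided = False
        for j in und:
            inc = mask[:, j]
            n1, n0 = int(inc.sum()), int((~inc).sum())
            if n1 < 2 or n0 < 2:
                continue  # no contrast this round; stays undecided
            gap = acc[inc].mean() - acc[~inc].mean()
            se = np.sqrt(acc[inc].var(ddof=1) / n1 + acc[~inc].var(ddof=1) / n0)
            threshold = max(cfg.retain_margin, cfg.evidence_z * se)
            if gap > threshold:
                retained.add(j)
                undecided.discard(j)
                newly_decided = True
            elif gap < -threshold:
                dropped.add(j)
                undecided.discard(j)
                newly_decided = True
        if not undecided or not newly_decided:
            converged = True
            break

    # evidence-based filtering: with no clear winners, nothing can be
    # discarded, so every non-dropped candidate survives
    survivors = sorted(set(range(p)) - dropped)
    subset = sorted(retained) if retained else survivors
    if retained and len(subset) < len(survivors):
        # verification: a filter must not cost accuracy -- if the retained
        # set underperforms the full surviving pool (undecided features may
        # still carry signal), keep the pool
        acc_retained = _subset_accuracy(X, y, np.array(subset), cfg.cv, cfg.seed)
        acc_pool = _subset_accuracy(X, y, np.array(survivors), cfg.cv, cfg.seed)
        if acc_retained + cfg.retain_margin < acc_pool:
            subset = survivors

    if cfg.force_size is not None and len(subset) != cfg.force_size:
        subset = _force_size(X, y, subset, cfg)

    return SelectionResult(
        mrmr_ranking=tuple(int(i) for i in idx),
        final_subset=tuple(int(idx[j]) for j in subset),
        objective_trace=tuple(trace),
        converged=converged,
    )


def _force_size(X: np.ndarray, y: np.ndarray, subset: list[int], cfg: BmsfConfig) -> list[int]:
    """Accuracy-ranked truncation/extension to exactly ``cfg.force_size``."""
    target = cfg.force_size
    p = X.shape[1]
    order = list(subset) + [j for j in range(p) if j not in subset]
    if len(subset) <= target:
        return sorted(order[:target])
    if target <= len(subset) // 2:
        # big reduction: greedy forward selection from the retained pool
        chosen: list[int] = []
        pool = list(subset)
        while len(chosen) < target:
            accs = [
                _subset_accuracy(X, y, np.array(chosen + [j]), cfg.cv, cfg.seed)
                for j in pool
            ]
            best = pool[int(np.argmax(accs))]
            chosen.append(best)
            pool.remove(best)
        return sorted(chosen)
    # mild reduction: drop the member whose removal hurts least, repeatedly
    cur = list(subset)
    while len(cur) > target:
        accs = [
            _subset_accuracy(X, y, np.array([c for c in cur if c != j]), cfg.cv, cfg.seed)
            for j in cur
        ]
        cur.remove(cur[int(np.argmax(accs))])
    return sorted(cur)


# ---------------------------------------------------------------------------
# channel grouping for ablation


@dataclass(frozen=True)
class FeatureGroup:
    """All selected features derived from one kinematic channel."""

    channel_abbr: str
    member_indices: tuple[int, ...] = field(default_factory=tuple)


def group_features_by_channel(names: Sequence[str]) -> list[FeatureGroup]:
    """Partition feature names into per-channel groups.

    ``names`` are feature names like ``"lt av.mean"``; indices in the
    returned groups refer to positions within ``names``. Groups are
    ordered by first appearance.
    """
    if len(names) == 0:
        raise ValueError("names must be non-empty")
    members: dict[str, list[int]] = {}
    for i, name in enumerate(names):
        channel, _ = parse_feature_name(name)
        members.setdefault(channel, []).append(i)
    return [
        FeatureGroup(channel_abbr=ch, member_indices=tuple(ix))
        for ch, ix in members.items()
    ]
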
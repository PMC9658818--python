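"""Decision-level fusion of base-classifier scores.

Eight rules are implemented, all consuming the same
:class:`~gaitfuse.classifiers.ScoreMatrix` (n classifiers x m classes,
rows on the simplex) and returning one class id:

``ds``
    Dempster-Shafer evidence combination. Each classifier's score row
    is turned into a basic probability assignment by reliability
    discounting: singleton masses ``alpha * z_ij`` plus ``1 - alpha``
    on the whole recognition frame Theta. Dempster's rule then pools
    the n mass functions; the decision is the singleton with maximal
    combined mass. With alpha < 1 every source keeps mass on Theta, so
    total conflict (K = 1) cannot arise; at alpha = 1 it can, and the
    fold falls back to the sum rule (logged).
``vote``
    Majority voting on the classifiers' crisp argmax labels; when no
    class holds a strict majority the plurality wins (logged), ties
    toward the lowest class id.
``dt``
    Decision templates: the per-class mean training score matrix is the
    template; prediction maximizes the squared-Euclidean similarity
    ``1 - mean((Z - T_c)^2)``.
``sum / average / max / min / product``
    Columnwise algebraic combiners of the score matrix. Sum and average
    share every argmax. The product rule floors scores at 1e-12 first,
    because one-hot rows (KNN with k = 1) would otherwise annihilate
    every class.

All argmax decisions break ties toward the lowest class id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifiers import ScoreMatrix
from .errors import TotalConflictError

logger = logging.getLogger(__name__)

#: Canonical rule names, in the fixed order used for tie-breaking.
RULES: tuple[str, ...] = ("ds", "vote", "dt", "sum", "average", "max", "min", "product")

ALGEBRAIC_RULES: tuple[str, ...] = ("sum", "average", "max", "min", "product")

_PRODUCT_EPS = 1e-12


@dataclass(frozen=True)
class MassFunction:
    """Basic probability assignment over singleton classes plus Theta."""

    singleton_masses: np.ndarray
    theta_mass: float
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.singleton_masses, dtype=float)
        if m.ndim != 1 or m.size != len(self.class_ids):
            raise ValueError("singleton_masses must align with class_ids")
        if np.any(m < -1e-12) or self.theta_mass < -1e-12:
            raise ValueError("masses must be nonnegative")
        if abs(m.sum() + self.theta_mass - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")
        object.__setattr__(self, "singleton_masses", m)
        object.__setattr__(self, "class_ids", tuple(self.class_ids))

    def mass(self, class_id: int) -> float:
        return float(self.singleton_masses[self.class_ids.index(class_id)])


def scores_to_mass(row, alpha: float = 0.95, class_ids=None) -> MassFunction:
    """Reliability-discount a score row into a mass function.

    Singleton masses are ``alpha * row``; the held-back ``1 - alpha``
    goes to the full frame Theta, encoding source unreliability.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    row = np.asarray(row, dtype=float)
    if class_ids is None:
        class_ids = tuple(range(1, row.size + 1))
    return MassFunction(
        singleton_masses=alpha * row,
        theta_mass=1.0 - alpha * float(row.sum()),
        class_ids=tuple(class_ids),
    )


def ds_combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule for two mass functions on singletons + Theta.

    The focal-set intersections reduce to the closed form
    ``m({c}) propto m1_c m2_c + m1_c m2_T + m1_T m2_c`` and
    ``m(Theta) propto m1_T m2_T``, renormalized by 1 - K where K is the
    mass on conflicting (disjoint singleton) pairs.
    """
    if m1.class_ids != m2.class_ids:
        raise ValueError("mass functions live on different frames")
    a, b = m1.singleton_masses, m2.singleton_masses
    at, bt = m1.theta_mass, m2.theta_mass
    singles = a * b + a * bt + at * b
    theta = at * bt
    total = singles.sum() + theta  # = 1 - K
    if total <= 1e-15:
        raise TotalConflictError("total conflict: K = 1, combination undefined")
    return MassFunction(
        singleton_masses=singles / total,
        theta_mass=theta / total,
        class_ids=m1.class_ids,
    )


def bel_pl(m: MassFunction, class_id: int) -> tuple[float, float]:
    """Belief and plausibility of one singleton class.

    For a singleton A, Bel(A) = m(A) and Pl(A) = m(A) + m(Theta):
    [Bel, Pl] is the uncertainty interval of A.
    """
    if class_id not in m.class_ids:
        raise ValueError(f"class {class_id!r} not in the recognition frame")
    bel = m.mass(class_id)
    return bel, bel + m.theta_mass


def ds_fuse(Z: ScoreMatrix, alpha: float = 0.95) -> int:
    """Pool all classifier rows with Dempster's rule; argmax singleton mass.

    On total conflict (possible only at alpha = 1) the sample falls back
    to the sum rule so batch evaluation stays total.
    """
    if Z.z.shape[0] < 2:
        raise ValueError("Dempster fusion needs at least 2 classifiers")
    combined = scores_to_mass(Z.z[0], alpha, Z.class_ids)
    try:
        for row in Z.z[1:]:
            combined = ds_combine(combined, scores_to_mass(row, alpha, Z.class_ids))
    except TotalConflictError:
        logger.warning("total conflict in Dempster fusion; falling back to sum rule")
        return algebraic_fuse(Z, "sum")
    return int(Z.class_ids[int(np.argmax(combined.singleton_masses))])


def majority_vote(labels) -> int:
    """Majority vote over crisp labels; plurality fallback, lowest-id ties."""
    labels = np.asarray(labels).ravel()
    if labels.size == 0:
        raise ValueError("no votes cast")
    values, counts = np.unique(labels, return_counts=True)  # values sorted asc
    winner = int(values[int(np.argmax(counts))])
    if counts.max() * 2 <= labels.size:
        logger.debug("no strict majority; plurality fallback chose %s", winner)
    return winner


@dataclass(frozen=True)
class DecisionTemplateSet:
    """Per-class mean score matrices from a training set."""

    templates: np.ndarray  # (m_classes, n_classifiers, m_classes)
    class_ids: tuple[int, ...]


def dt_fit(score_matrices, y) -> DecisionTemplateSet:
    """Fit decision templates: elementwise class means of score matrices."""
    y = np.asarray(y).ravel()
    if len(score_matrices) != y.size:
        raise ValueError("score matrices and labels must align")
    class_ids = score_matrices[0].class_ids
    stack = np.stack([Z.z for Z in score_matrices])
    templates = np.empty((len(class_ids),) + stack.shape[1:])
    for k, c in enumerate(class_ids):
        sel = y == c
        if not sel.any():
            raise ValueError(f"class {c} absent from the training labels")
        templates[k] = stack[sel].mean(axis=0)
    return DecisionTemplateSet(templates=templates, class_ids=class_ids)


def dt_predict(templates: DecisionTemplateSet, Z: ScoreMatrix) -> int:
    """Nearest decision template by squared-Euclidean similarity."""
    if Z.z.shape != templates.templates.shape[1:]:
        raise ValueError(
            f"score matrix shape {Z.z.shape} does not match "
            f"template shape {templates.templates.shape[1:]}"
        )
    diff = templates.templates - Z.z[None]
    sim = 1.0 - np.mean(diff**2, axis=(1, 2))
    return int(templates.class_ids[int(np.argmax(sim))])


def algebraic_fuse(Z: ScoreMatrix, rule: str) -> int:
    """Columnwise sum/average/max/min/product combiner; argmax class."""
    z = Z.z
    if rule == "sum":
        e = z.sum(axis=0)
    elif rule == "average":
        e = z.mean(axis=0)
    elif rule == "max":
        e = z.max(axis=0)
    elif rule == "min":
        e = z.min(axis=0)
    elif rule == "product":
        e = np.clip(z, _PRODUCT_EPS, None).prod(axis=0)
    else:
        raise ValueError(f"unknown algebraic rule: {rule!r}")
    return int(Z.class_ids[int(np.argmax(e))])


def fuse(
    Z: ScoreMatrix,
    rule: str,
    alpha: float = 0.95,
    templates: DecisionTemplateSet | None = None,
) -> int:
    """Dispatch one fusion rule by name (see :data:`RULES`)."""
    if rule == "ds":
        return ds_fuse(Z, alpha)
    if rule == "vote":
        crisp = [Z.class_ids[int(np.argmax(row))] for row in Z.z]
        return majority_vote(crisp)
    if rule == "dt":
        if templates is None:
            raise ValueError("decision-template rule needs fitted templates")
        return dt_predict(templates, Z)
    if rule in ALGEBRAIC_RULES:
        return algebraic_fuse(Z, rule)
    raise ValueError(f"unknown fusion rule: {rule!r}")
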
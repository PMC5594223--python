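"""Nested cross-validated SVM classification with greedy feature selection.

For one pairwise group contrast under one feature scenario the procedure
is a three-layer nested design:

outer layer   a single stratified split holding out 10% of subjects for
              the final test; the remaining 90% is the outer training set
middle layer  stratified 10-fold over the outer training set; each fold's
              training portion gets its own t-test feature ranking and a
              greedy stepwise forward selection
inner layer   stratified 10-fold cross-validated linear SVM accuracy used
              to score each candidate feature vector during the greedy
              search

The ten per-fold selections are consolidated by vote counting (features
chosen in >= 3 of 10 folds; falling back to 2 and then 1 if empty; capped
at the 41 most-voted).  A linear 2-norm soft-margin SVM is trained on the
full outer training set with the final features and evaluated once on the
held-out outer test set.

Greedy search inclusion criteria for a candidate feature, scored by inner
CV (accuracies compared as exact fractions of fold counts):

(i)   overall accuracy at least the maximum of all previously evaluated
      candidate accuracies;
(ii)  if the best first-group accuracy (sensitivity) so far is below
      0.75, the candidate's sensitivity must be at least that best;
(iii) if the best second-group accuracy (specificity) so far is below
      0.5, the candidate's specificity must exceed that best.

The search stops when features are exhausted, the vector reaches 40
entries, or more than 10% of all available features were rejected
consecutively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numpy.typing import NDArray
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .features import FeatureDescriptor

__all__ = [
    "SelectionConfig",
    "ComparisonResult",
    "PairwiseComparison",
    "train_svm",
    "rank_by_ttest",
    "greedy_forward_select",
    "consolidate_votes",
    "accuracy_per_group",
    "max_chance",
    "run_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Knobs of the nested selection procedure (defaults as in the design)."""

    middle_folds: int = 10
    inner_folds: int = 10
    outer_test_fraction: float = 0.10
    sens_threshold: float = 0.75
    spec_threshold: float = 0.5
    growth_cap: int = 40
    final_cap: int = 41
    vote_thresholds: tuple[int, ...] = (3, 2, 1)
    stall_fraction: float = 0.10
    svm_C: float = 1.0
    standardize: bool = True
    equal_var: bool = True  # pooled-variance t-test; False -> Welch
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.outer_test_fraction < 1:
            raise ValueError("outer_test_fraction must lie in (0, 1)")
        if self.growth_cap <= 0 or self.final_cap <= 0:
            raise ValueError("caps must be positive")
        if list(self.vote_thresholds) != sorted(
            self.vote_thresholds, reverse=True
        ) or len(set(self.vote_thresholds)) != len(self.vote_thresholds):
            raise ValueError("vote thresholds must be strictly decreasing")


def train_svm(X: NDArray, y, C: float = 1.0, standardize: bool = True):
    """Fit a linear 2-norm soft-margin SVM (squared-hinge slack penalty).

    Features are standardized to train-set mean 0 / variance 1 first
    (constant features pass through unscaled).  Solver tolerance is the
    scikit-learn default 1e-4.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("training data must contain exactly two classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        ("svm", LinearSVC(loss="squared_hinge", C=C, dual="auto", max_iter=20000))
    )
    clf = Pipeline(steps)
    clf.fit(X, y)
    return clf


def rank_by_ttest(X: NDArray, y, pair, equal_var: bool = True):
    """Rank features by ascending two-sample t-test p-value.

    Returns ``(order, pvalues)`` where ``order`` is a permutation of all
    column indices (ties and undefined tests broken by original index).
    Features with zero variance in both groups get p = 1.
    """
    y = np.asarray(y)
    g1 = X[y == pair[0]]
    g2 = X[y == pair[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need >= 2 members for the t-test")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features (e.g. structural zeros of directed
        # measures) trigger precision warnings; they get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(g1, g2, axis=0, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    n_bad = int(np.sum(~np.isfinite(p)))
    if n_bad:
        logger.info("t-test undefined for %d zero-variance features; p set to 1",
                    n_bad)
    p = np.where(np.isfinite(p), p, 1.0)
    order = np.argsort(p, kind="stable")
    return order, p


def _inner_cv_scores(X, y, pair, feature_idx, folds, C, standardize):
    """Exact-fraction (overall, group-1, group-2) inner-CV accuracies."""
    Xs = X[:, feature_idx]
    correct = {pair[0]: 0, pair[1]: 0}
    total = {pair[0]: 0, pair[1]: 0}
    for train_idx, test_idx in folds:
        clf = train_svm(Xs[train_idx], y[train_idx], C=C, standardize=standardize)
        pred = clf.predict(Xs[test_idx])
        for lab in pair:
            mask = y[test_idx] == lab
            total[lab] += int(mask.sum())
            correct[lab] += int((pred[mask] == lab).sum())
    n = total[pair[0]] + total[pair[1]]
    acc = Fraction(correct[pair[0]] + correct[pair[1]], n)
    sens = Fraction(correct[pair[0]], total[pair[0]]) if total[pair[0]] else Fraction(0)
    spec = Fraction(correct[pair[1]], total[pair[1]]) if total[pair[1]] else Fraction(0)
    return acc, sens, spec


def greedy_forward_select(
    X: NDArray,
    y,
    pair,
    ranked: NDArray,
    config: SelectionConfig,
    rng: np.random.Generator,
) -> list[int]:
    """Greedy stepwise forward search over t-test-ranked features.

    ``ranked`` must come from :func:`rank_by_ttest` on this training set
    only.  Inner folds are drawn once per call and reused for every
    candidate so that accuracy comparisons are exact.
    Returns selected column indices in order of addition.
    """
    y = np.asarray(y)
    n_features = len(ranked)
    stall_limit = max(1, int(round(config.stall_fraction * n_features)))
    skf = StratifiedKFold(
        n_splits=config.inner_folds,
        shuffle=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    folds = list(skf.split(X, y))

    selected = [int(ranked[0])]
    acc, sens, spec = _inner_cv_scores(
        X, y, pair, selected, folds, config.svm_C, config.standardize
    )
    best_acc, best_sens, best_spec = acc, sens, spec
    sens_thr = Fraction(config.sens_threshold).limit_denominator(10**6)
    spec_thr = Fraction(config.spec_threshold).limit_denominator(10**6)

    consecutive_rejects = 0
    for cand in ranked[1:]:
        if len(selected) >= config.growth_cap:
            break
        candidate = selected + [int(cand)]
        acc, sens, spec = _inner_cv_scores(
            X, y, pair, candidate, folds, config.svm_C, config.standardize
        )
        ok = acc >= best_acc
        if ok and best_sens < sens_thr:
            ok = sens >= best_sens
        if ok and best_spec < spec_thr:
            ok = spec > best_spec
        best_acc = max(best_acc, acc)
        best_sens = max(best_sens, sens)
        best_spec = max(best_spec, spec)
        if ok:
            selected = candidate
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
            if consecutive_rejects >= stall_limit:
                break
    return selected


def consolidate_votes(
    per_fold_selections: list[list[int]], config: SelectionConfig
) -> list[int]:
    """Vote-count consolidation of the middle-layer selections.

    Keeps features selected in at least 3 folds, falling back to 2 and
    then 1 until non-empty; if more than ``final_cap`` survive, the most
    voted are kept (ties broken by better mean position in the per-fold
    selection lists, then by feature index).
    """
    if len(per_fold_selections) != config.middle_folds:
        raise ValueError(
            f"expected {config.middle_folds} fold selections, "
            f"got {len(per_fold_selections)}"
        )
    votes: dict[int, int] = {}
    positions: dict[int, list[int]] = {}
    for sel in per_fold_selections:
        for pos, f in enumerate(sel):
            votes[f] = votes.get(f, 0) + 1
            positions.setdefault(f, []).append(pos)
    if not votes:
        raise ValueError("all fold selections are empty (degenerate selection)")
    survivors: list[int] = []
    for thr in config.vote_thresholds:
        survivors = [f for f, v in votes.items() if v >= thr]
        if survivors:
            break
    if not survivors:
        raise ValueError("no feature reaches any vote threshold")
    survivors.sort(
        key=lambda f: (-votes[f], float(np.mean(positions[f])), f)
    )
    return survivors[: config.final_cap]


def accuracy_per_group(predictions, labels, pair):
    """Per-group fraction of correctly classified subjects (NaN if empty)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    out = []
    for lab in pair:
        mask = labels == lab
        if mask.sum() == 0:
            out.append(float("nan"))
        else:
            out.append(float((predictions[mask] == lab).sum() / mask.sum()))
    return tuple(out)


def max_chance(n1: int, n2: int) -> float:
    """Maximum-chance criterion: share of the larger group."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    return max(n1, n2) / (n1 + n2)


@dataclass
class ComparisonResult:
    """Outcome of one pairwise contrast under one scenario."""

    group_pair: tuple[str, str]
    scenario: str
    overall_accuracy: float
    per_group_accuracy: tuple[float, float]
    chance_level: float
    final_features: list[int]
    final_descriptors: list[FeatureDescriptor] | None
    per_fold_selections: list[list[int]]
    outer_train_indices: NDArray[np.int64]
    outer_test_indices: NDArray[np.int64]
    middle_fold_train_indices: list[NDArray[np.int64]] = field(default_factory=list)
    n_train: int = 0
    n_test: int = 0

    def summary(self) -> str:
        a, b = self.group_pair
        acc1, acc2 = self.per_group_accuracy
        lines = [
            f"Pairwise comparison {a} vs {b} [{self.scenario}]",
            f"  outer train/test:  {self.n_train}/{self.n_test} subjects",
            f"  overall accuracy:  {self.overall_accuracy:.2f}",
            f"  per-group accuracy: {a} {acc1:.2f} / {b} {acc2:.2f}",
            f"  chance level:      {self.chance_level:.2f}",
            f"  final features ({len(self.final_features)}):",
        ]
        if self.final_descriptors is not None:
            for d in self.final_descriptors:
                lines.append(f"    {d.name()}")
        else:
            lines.append(f"    indices {self.final_features}")
        return "\n".join(lines)

    def table_cell(self) -> str:
        """'overall (acc1/acc2)' formatting used in the report table."""
        a1, a2 = self.per_group_accuracy
        return f"{self.overall_accuracy:.2f} ({a1:.2f}/{a2:.2f})"


class PairwiseComparison:
    """Model object: one pairwise contrast on a feature matrix.

    Parameters
    ----------
    X : (n_subjects, n_features) array
    y : array of group labels
    pair : (label_1, label_2)
        Order fixes the sensitivity/specificity convention: sensitivity is
        the accuracy on ``pair[0]``, specificity on ``pair[1]``.
    descriptors : list of FeatureDescriptor, optional
    config : SelectionConfig, optional
    scenario : str
    """

    def __init__(self, X, y, pair, descriptors=None,
                 config: SelectionConfig | None = None, scenario: str = ""):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_subjects, n_features) matching y")
        present = set(np.unique(y))
        if not set(pair) <= present:
            raise ValueError(f"groups {pair} not both present in labels")
        mask = np.isin(y, list(pair))
        self.X = X[mask]
        self.y = y[mask]
        self._orig_index = np.flatnonzero(mask)
        self.pair = tuple(pair)
        self.descriptors = descriptors
        self.config = config or SelectionConfig()
        self.scenario = scenario
        n1 = int((self.y == pair[0]).sum())
        n2 = int((self.y == pair[1]).sum())
        min_needed = self.config.inner_folds
        # smallest class after outer split and middle fold must still fill
        # the inner stratified folds
        est = int(min(n1, n2) * (1 - self.config.outer_test_fraction)
                  * (self.config.middle_folds - 1) / self.config.middle_folds)
        if est < min_needed:
            raise ValueError(
                f"group sizes {n1}/{n2} too small for "
                f"{self.config.middle_folds}x{self.config.inner_folds} nested "
                f"stratified folds; smallest class must keep >= {min_needed} "
                "members in the middle-layer training sets"
            )

    def fit(self, seed: int | None = None) -> ComparisonResult:
        """Run the full three-layer nested procedure."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        outer_seed, middle_seed, *fold_seeds = [
            int(s.generate_state(1)[0] % (2**31 - 1))
            for s in ss.spawn(2 + cfg.middle_folds)
        ]

        idx = np.arange(len(self.y))
        train_idx, test_idx = train_test_split(
            idx,
            test_size=cfg.outer_test_fraction,
            stratify=self.y,
            random_state=outer_seed,
        )
        X_tr, y_tr = self.X[train_idx], self.y[train_idx]

        skf = StratifiedKFold(
            n_splits=cfg.middle_folds, shuffle=True, random_state=middle_seed
        )
        per_fold_selections: list[list[int]] = []
        middle_train_abs: list[NDArray[np.int64]] = []
        for fold_i, (mtr, _mte) in enumerate(skf.split(X_tr, y_tr)):
            X_m, y_m = X_tr[mtr], y_tr[mtr]
            middle_train_abs.append(train_idx[mtr])
            order, _ = rank_by_ttest(X_m, y_m, self.pair,
                                     equal_var=cfg.equal_var)
            rng = np.random.default_rng(fold_seeds[fold_i])
            sel = greedy_forward_select(X_m, y_m, self.pair, order, cfg, rng)
            per_fold_selections.append(sel)
            logger.debug("middle fold %d: selected %d features",
                         fold_i, len(sel))

        final = consolidate_votes(per_fold_selections, cfg)

        clf = train_svm(
            X_tr[:, final], y_tr, C=cfg.svm_C, standardize=cfg.standardize
        )
        pred = clf.predict(self.X[test_idx][:, final])
        y_te = self.y[test_idx]
        acc1, acc2 = accuracy_per_group(pred, y_te, self.pair)
        overall = float((pred == y_te).mean())
        n1 = int((self.y == self.pair[0]).sum())
        n2 = int((self.y == self.pair[1]).sum())

        return ComparisonResult(
            group_pair=self.pair,
            scenario=self.scenario,
            overall_accuracy=overall,
            per_group_accuracy=(acc1, acc2),
            chance_level=max_chance(n1, n2),
            final_features=list(final),
            final_descriptors=(
                [self.descriptors[i] for i in final]
                if self.descriptors is not None else None
            ),
            per_fold_selections=per_fold_selections,
            outer_train_indices=self._orig_index[train_idx],
            outer_test_indices=self._orig_index[test_idx],
            middle_fold_train_indices=[self._orig_index[m]
                                       for m in middle_train_abs],
            n_train=len(train_idx),
            n_test=len(test_idx),
        )


def run_comparison(X, y, pair, scenario: str = "", descriptors=None,
                   config: SelectionConfig | None = None,
                   seed: int | None = None) -> ComparisonResult:
    """Functional wrapper around :class:`PairwiseComparison`."""
    return PairwiseComparison(
        X, y, pair, descriptors=descriptors, config=config, scenario=scenario
    ).fit(seed=seed)
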
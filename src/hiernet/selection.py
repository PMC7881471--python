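"""Three-stage feature-selection cascade: t-test filter, mRMR, SVM-RFE.

High-dimensional edge and ROI features are reduced in three stages, each
fit on training data only:

1. a per-feature two-sample Student t-test keeps features whose
   between-group difference is significant at ``alpha``;
2. minimum-redundancy maximum-relevance (mRMR) greedily ranks the
   survivors by mutual information with the label minus (MID) or divided
   by (MIQ) their average mutual information with already-chosen
   features, on features discretized into three bins at mean +/- 1 SD;
3. recursive feature elimination (SVM-RFE) repeatedly fits a linear
   maximum-margin classifier and drops the features with the smallest
   squared weights until the requested count remains.

Stage outputs are nested subsets of stage inputs, and every tie (equal
p, mRMR score, or squared weight) is broken by feature name so the
cascade is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "SelectionError",
    "SelectionTrace",
    "ttest_filter",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "svm_rfe",
    "run_cascade",
]


class SelectionError(ValueError):
    """Raised when a cascade stage cannot produce a valid feature subset."""


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable parameters of the selection cascade.

    Parameters
    ----------
    alpha
        Significance level of the t-test screen.
    mrmr_keep
        Features retained after mRMR (capped at the number of t-test
        survivors).
    rfe_keep
        Features retained after SVM-RFE: an integer, or ``"auto"`` to
        choose among ``rfe_grid`` by inner cross-validated accuracy.
    rfe_grid
        Candidate final sizes evaluated when ``rfe_keep="auto"``.
    rfe_step
        Features eliminated per RFE iteration; ``None`` applies the
        default rule (10% of the remaining features above 50, one at a
        time below).
    n_bins
        Discretization levels for mutual information (bins split at
        mean +/- 1 SD when 3).
    mrmr_criterion
        ``"MID"`` (relevance minus mean redundancy, default) or
        ``"MIQ"`` (relevance divided by mean redundancy).
    svm_C
        Cost parameter of the linear classifier used by RFE.
    """

    alpha: float = 0.05
    mrmr_keep: int = 200
    rfe_keep: Union[int, str] = "auto"
    rfe_grid: tuple[int, ...] = (10, 20, 30)
    rfe_step: int | None = None
    n_bins: int = 3
    mrmr_criterion: str = "MID"
    svm_C: float = 1.0
    #: when > 0 and no feature passes the screen, keep this many
    #: lowest-p features instead of raising (used by the CV protocol so a
    #: null fold stays classifiable; 0 preserves the hard error)
    screen_floor: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise SelectionError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.mrmr_keep < 1:
            raise SelectionError("mrmr_keep must be >= 1")
        if isinstance(self.rfe_keep, str):
            if self.rfe_keep != "auto":
                raise SelectionError(f"rfe_keep must be an int or 'auto', got {self.rfe_keep!r}")
            if not self.rfe_grid:
                raise SelectionError("rfe_grid must be non-empty when rfe_keep='auto'")
        else:
            if not 1 <= self.rfe_keep <= self.mrmr_keep:
                raise SelectionError("need mrmr_keep >= rfe_keep >= 1")
        if self.mrmr_criterion not in ("MID", "MIQ"):
            raise SelectionError(f"unknown mRMR criterion {self.mrmr_criterion!r}")
        if self.n_bins < 2:
            raise SelectionError("n_bins must be >= 2")


@dataclass
class SelectionTrace:
    """Audit record of one cascade run on one training set."""

    ttest_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    ttest_survivors: list[str] = field(default_factory=list)
    mrmr_ranking: list[str] = field(default_factory=list)
    rfe_elimination: list[str] = field(default_factory=list)
    rfe_keep: int = 0
    selected: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ttest_survivors": self.ttest_survivors,
            "mrmr_ranking": self.mrmr_ranking,
            "rfe_elimination": self.rfe_elimination,
            "rfe_keep": self.rfe_keep,
            "selected": self.selected,
            "ttest_stats": {
                row.Index: {"t": row.t, "p": row.p}
                for row in self.ttest_stats.itertuples()
            },
        }


def _as_binary(y: Sequence) -> np.ndarray:
    arr = np.asarray(y)
    classes = np.unique(arr)
    if len(classes) != 2:
        raise SelectionError(f"need exactly two groups, got classes {classes.tolist()}")
    # first class in sort order is the positive group ("high" < "low"),
    # so the reported t statistic is high-group minus low-group
    return (arr == classes[0]).astype(int)


# ---------------------------------------------------------------------------
# stage 1: t-test filter
# ---------------------------------------------------------------------------


def ttest_filter(
    X: pd.DataFrame, y: Sequence, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Keep features with a two-sample Student t-test p-value below alpha.

    A pooled-variance two-sided test is applied to every feature
    independently (no multiple-testing correction — this is a coarse
    screen).  Features with zero variance in both groups cannot separate
    them and are assigned p = 1.

    Returns the surviving feature names (input order) and a per-feature
    statistics table with columns ``t`` and ``p``.
    """
    yb = _as_binary(y)
    a = X.to_numpy(float)[yb == 1]
    b = X.to_numpy(float)[yb == 0]
    if len(a) < 2 or len(b) < 2:
        raise SelectionError("each group needs at least two subjects for the t-test")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    flat = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if flat.any():
        logger.info("t-test screen: %d zero-variance features assigned p=1", int(flat.sum()))
        t = np.where(flat, 0.0, t)
        p = np.where(flat, 1.0, p)
    table = pd.DataFrame({"t": t, "p": p}, index=X.columns)
    survivors = [c for c, pv in zip(X.columns, p) if pv < alpha]
    return survivors, table


# ---------------------------------------------------------------------------
# stage 2: mRMR
# ---------------------------------------------------------------------------


def discretize(X: pd.DataFrame, n_bins: int = 3) -> np.ndarray:
    """Discretize each feature for mutual-information estimation.

    With the default three bins, the cut points are the per-feature mean
    +/- one standard deviation.  Other bin counts use equally spaced
    quantile edges.  Constant features collapse to a single level.
    """
    vals = X.to_numpy(float)
    if n_bins == 3:
        m = vals.mean(axis=0)
        s = vals.std(axis=0)
        out = np.ones_like(vals, dtype=np.int64)
        out[vals < m - s] = 0
        out[vals > m + s] = 2
        return out
    out = np.empty_like(vals, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(vals.shape[1]):
        edges = np.quantile(vals[:, j], qs)
        out[:, j] = np.searchsorted(edges, vals[:, j], side="right")
    return out


def mutual_information(ref: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Mutual information (nats) between one discrete vector and each column of D."""
    n = len(ref)
    ref_levels = int(ref.max()) + 1 if n else 1
    d_levels = int(D.max()) + 1 if D.size else 1
    mi = np.zeros(D.shape[1])
    for a in range(ref_levels):
        mask = ref == a
        pa = mask.mean()
        if pa == 0.0:
            continue
        for b in range(d_levels):
            pab = (mask[:, None] & (D == b)).sum(axis=0) / n
            pb = (D == b).sum(axis=0) / n
            with np.errstate(invalid="ignore", divide="ignore"):
                term = pab * np.log(pab / (pa * pb))
            mi += np.where(pab > 0, term, 0.0)
    return np.maximum(mi, 0.0)


def mrmr_rank(
    X: pd.DataFrame,
    y: Sequence,
    keep: int,
    n_bins: int = 3,
    criterion: str = "MID",
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    The first pick maximizes relevance (mutual information with the
    label); each subsequent pick maximizes relevance minus (MID) or
    divided by (MIQ) the mean mutual information with the features
    already chosen.  Ties favor the lexically smaller feature name.
    """
    names = list(X.columns)
    if keep > len(names):
        warnings.warn(
            f"mRMR keep={keep} exceeds the {len(names)} candidate features; keeping all",
            stacklevel=2,
        )
        keep = len(names)
    if keep < 1 or not names:
        raise SelectionError("mRMR requires at least one candidate feature")
    yb = _as_binary(y)
    D = discretize(X, n_bins=n_bins)
    relevance = mutual_information(yb, D)

    remaining = list(range(len(names)))
    redundancy_sum = np.zeros(len(names))
    ranked: list[int] = []
    for step in range(keep):
        if step == 0:
            scores = relevance
        elif criterion == "MID":
            scores = relevance - redundancy_sum / len(ranked)
        else:  # MIQ
            scores = relevance / np.maximum(redundancy_sum / len(ranked), 1e-12)
        best = min(remaining, key=lambda j: (-scores[j], names[j]))
        ranked.append(best)
        remaining.remove(best)
        if remaining:
            redundancy_sum[remaining] += mutual_information(D[:, best], D[:, remaining])
    return [names[j] for j in ranked]


# ---------------------------------------------------------------------------
# stage 3: SVM-RFE
# ---------------------------------------------------------------------------


def _zscore(vals: np.ndarray) -> np.ndarray:
    m = vals.mean(axis=0)
    s = vals.std(axis=0)
    s = np.where(s == 0.0, 1.0, s)
    return (vals - m) / s


def _rfe_step_size(current: int, step: int | None) -> int:
    if step is not None:
        return max(1, step)
    return max(1, current // 10) if current > 50 else 1


def svm_rfe(
    X: pd.DataFrame,
    y: Sequence,
    keep: int,
    step: int | None = None,
    C: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Recursive feature elimination by linear maximum-margin weights.

    Features are z-scored, a linear SVM is fit, and the features with the
    smallest squared weights are dropped (10% of the remaining set above
    50 features, one at a time below, unless ``step`` overrides); the
    process repeats until ``keep`` features remain.  Among tied weights
    the lexically greater name is eliminated first.

    Returns
    -------
    (selected, elimination_order)
        Surviving names in input-column order, and the eliminated names
        in elimination order.
    """
    names = list(X.columns)
    if not 1 <= keep <= len(names):
        raise SelectionError(f"rfe keep={keep} out of range for {len(names)} features")
    yb = _as_binary(y)
    if len(np.unique(yb)) < 2:
        raise SelectionError("SVM-RFE requires both classes in the training data")
    vals = X.to_numpy(float)
    current = list(range(len(names)))
    eliminated: list[str] = []
    while len(current) > keep:
        Z = _zscore(vals[:, current])
        clf = SVC(kernel="linear", C=C)
        try:
            clf.fit(Z, yb)
        except Exception as exc:  # pragma: no cover - degenerate training data
            raise SelectionError(f"SVM-RFE training failed with {len(current)} features: {exc}")
        w2 = (clf.coef_.ravel() ** 2)
        n_remove = min(_rfe_step_size(len(current), step), len(current) - keep)
        # smallest weight first; ties remove the lexically greater name first
        order = sorted(range(len(current)), key=lambda k: names[current[k]], reverse=True)
        order.sort(key=lambda k: w2[k])
        drop = sorted(order[:n_remove], reverse=True)
        for k in drop:
            eliminated.append(names[current[k]])
        for k in drop:
            del current[k]
    selected = [names[j] for j in sorted(current)]
    return selected, eliminated


def _choose_rfe_keep(
    X: pd.DataFrame,
    y: Sequence,
    elimination: list[str],
    grid: Sequence[int],
    C: float,
) -> int:
    """Pick the final RFE size from a grid by inner cross-validated accuracy.

    The elimination order defines nested candidate subsets; each is
    scored with a 3-fold stratified RBF-SVM.  Ties go to the *largest*
    candidate: on small training sets the scores saturate, and falsely
    excluding an informative feature degrades the downstream kernel far
    more than retaining a few noise features dilutes it.
    """
    names = list(X.columns)
    yb = _as_binary(y)
    vals = X.to_numpy(float)
    candidates = sorted({k for k in grid if 1 <= k <= len(names)})
    if not candidates:
        return min(len(names), max(grid))
    n_splits = min(3, int(np.bincount(yb).min()))
    if n_splits < 2:
        return candidates[0]
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=0)
    best_k, best_acc = candidates[0], -1.0
    for k in candidates:
        removed = set(elimination[: len(names) - k]) if len(names) > k else set()
        cols = [j for j, nm in enumerate(names) if nm not in removed]
        acc = 0.0
        for tr, te in cv.split(vals, yb):
            Ztr = _zscore(vals[np.ix_(tr, cols)])
            mu = vals[np.ix_(tr, cols)].mean(axis=0)
            sd = vals[np.ix_(tr, cols)].std(axis=0)
            sd = np.where(sd == 0.0, 1.0, sd)
            Zte = (vals[np.ix_(te, cols)] - mu) / sd
            clf = SVC(kernel="rbf", C=C, gamma="scale")
            clf.fit(Ztr, yb[tr])
            acc += (clf.predict(Zte) == yb[te]).mean()
        acc /= n_splits
        if acc >= best_acc:
            best_k, best_acc = k, acc
    return best_k


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


def run_cascade(
    X: pd.DataFrame, y: Sequence, config: SelectionConfig | None = None
) -> tuple[list[str], SelectionTrace]:
    """Apply t-test -> mRMR -> SVM-RFE on one training set.

    Returns the final feature subset (in input-column order) and the full
    :class:`SelectionTrace`.  Raises :class:`SelectionError` if any stage
    empties the candidate set.
    """
    config = config or SelectionConfig()
    trace = SelectionTrace()
    survivors, trace.ttest_stats = ttest_filter(X, y, alpha=config.alpha)
    trace.ttest_survivors = survivors
    if not survivors:
        if config.screen_floor > 0:
            order = trace.ttest_stats.sort_values(["p", "t"]).index
            survivors = sorted(order[: config.screen_floor])
            trace.ttest_survivors = survivors
            logger.info(
                "t-test screen empty at alpha=%g; keeping %d lowest-p feature(s)",
                config.alpha,
                len(survivors),
            )
        else:
            raise SelectionError(
                f"no features survive the t-test screen at alpha={config.alpha}; "
                "consider a larger alpha"
            )

    keep = min(config.mrmr_keep, len(survivors))
    trace.mrmr_ranking = mrmr_rank(
        X[survivors], y, keep, n_bins=config.n_bins, criterion=config.mrmr_criterion
    )

    pool = X[[c for c in X.columns if c in set(trace.mrmr_ranking)]]
    if config.rfe_keep == "auto":
        floor = max(1, min(k for k in config.rfe_grid))
        floor = min(floor, pool.shape[1])
        _, elimination = svm_rfe(
            pool, y, keep=floor, step=config.rfe_step, C=config.svm_C
        )
        chosen = _choose_rfe_keep(pool, y, elimination, config.rfe_grid, config.svm_C)
    else:
        chosen = min(int(config.rfe_keep), pool.shape[1])
        _, elimination = svm_rfe(pool, y, keep=chosen, step=config.rfe_step, C=config.svm_C)
    trace.rfe_keep = chosen
    removed = set(elimination[: pool.shape[1] - chosen])
    trace.rfe_elimination = elimination[: pool.shape[1] - chosen]
    trace.selected = [c for c in pool.columns if c not in removed]
    if not trace.selected:
        raise SelectionError("selection cascade produced an empty feature set")
    return trace.selected, trace
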
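"""Multi-kernel SVM classification under repeated nested cross-validation.

Two feature blocks — the bottom-layer ROI morphometry block and one
network (edge) block — each yield a Gaussian RBF kernel over subjects.
The kernels are fused as a convex combination

    K = beta * K_roi + (1 - beta) * K_net,      beta in [0, 1],

which preserves positive semi-definiteness, and a support-vector
machine is trained on the fused (precomputed) kernel.

Generalization is estimated by repeated stratified twofold
cross-validation: per repetition the cohort is split in half, the
selection cascade and all hyperparameter choices (C, beta) run on the
training half only (inner stratified CV), and the held-out half is
predicted.  Feature stability is summarized as the number of fold-fits
in which each feature survives the cascade, mirroring the
selection-frequency tables used to rank discriminative regions and
edges.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .atlas import AtlasHierarchy
from .features import parse_feature_name
from .selection import SelectionConfig, SelectionError, run_cascade

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_LABEL",
    "KernelSpec",
    "MetricSet",
    "FoldResult",
    "CVConfig",
    "CVReport",
    "rbf_kernel",
    "fuse_kernels",
    "default_gamma",
    "compute_metrics",
    "nested_cv",
    "weight_sweep",
    "baseline_classifiers",
    "frequency_table",
]

#: Label treated as the positive class for sensitivity/specificity.
POSITIVE_LABEL = "high"


@dataclass(frozen=True)
class KernelSpec:
    """Fused-kernel hyperparameters chosen for one fold."""

    beta: float  # weight of the ROI kernel; 1 - beta weighs the network kernel
    C: float
    gamma_roi: float | None = None
    gamma_net: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")


@dataclass(frozen=True)
class MetricSet:
    """Binary classification metrics, all proportions in [0, 1]."""

    acc: float
    sen: float
    spe: float
    auc: float
    youden: float
    f_score: float
    bac: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc,
            "SEN": self.sen,
            "SPE": self.spe,
            "AUC": self.auc,
            "Y": self.youden,
            "F": self.f_score,
            "BAC": self.bac,
        }


@dataclass
class FoldResult:
    repetition: int
    fold: int
    test_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    kernel: KernelSpec
    selected: dict[str, list[str]]  # role ("roi"/"net") -> selected feature names


@dataclass(frozen=True)
class CVConfig:
    """Protocol for repeated nested cross-validation.

    ``roi_block``/``net_block`` name the feature blocks entering the two
    kernels; either may be ``None`` for single-kernel classification, in
    which case beta is pinned to the corresponding endpoint.
    ``fixed_beta`` removes beta from the inner grid (used by the weight
    sweep).  ``gamma_scale`` multiplies the per-block default gamma
    ``1 / (n_features * variance)`` and may carry several candidates for
    inner tuning.
    """

    repetitions: int = 100
    outer_folds: int = 2
    inner_folds: int = 5
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    #: inner tuning grid for the kernel weight; deliberately coarse — the
    #: inner validation sets are small, and a fine grid only overfits their
    #: noise (the weight-coefficient sweep runs its own fine grid)
    beta_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    fixed_beta: float | None = None
    gamma_scale: tuple[float, ...] = (1.0,)
    roi_block: str | None = "roi_L4"
    net_block: str | None = "net_all"
    #: re-run the selection cascade inside every inner fold so the
    #: hyperparameter search scores leakage-free estimates; without it the
    #: inner accuracies are optimistically flat (features were chosen on
    #: the full training half) and the grid search cannot rank beta
    inner_selection: bool = True

    def __post_init__(self) -> None:
        if self.repetitions < 1 or self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("repetitions >= 1, outer_folds >= 2 and inner_folds >= 2 required")
        if self.roi_block is None and self.net_block is None:
            raise ValueError("at least one feature block is required")
        if self.fixed_beta is not None and not 0.0 <= self.fixed_beta <= 1.0:
            raise ValueError("fixed_beta must lie in [0, 1]")


@dataclass
class CVReport:
    """Aggregated outcome of one repeated nested-CV run."""

    folds: list[FoldResult]
    per_rep_metrics: list[MetricSet]
    metrics_mean: MetricSet
    metrics_sd: MetricSet
    frequencies: dict[str, Counter]
    n_subjects: int
    repetitions: int
    outer_folds: int
    config: dict = field(default_factory=dict)

    @property
    def n_fold_fits(self) -> int:
        return len(self.folds)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "repetitions": self.repetitions,
            "outer_folds": self.outer_folds,
            "config": self.config,
            "metrics_mean": self.metrics_mean.as_dict(),
            "metrics_sd": self.metrics_sd.as_dict(),
            "per_rep_metrics": [m.as_dict() for m in self.per_rep_metrics],
            "frequencies": {role: dict(c) for role, c in self.frequencies.items()},
            "folds": [
                {
                    "repetition": f.repetition,
                    "fold": f.fold,
                    "test_ids": f.test_ids,
                    "beta": f.kernel.beta,
                    "C": f.kernel.C,
                    "selected": f.selected,
                }
                for f in self.folds
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def default_gamma(X: np.ndarray) -> float:
    """Heuristic RBF width: 1 / (n_features * total variance)."""
    var = float(np.asarray(X, float).var())
    n_feat = X.shape[1] if X.ndim == 2 else 1
    if var <= 0 or n_feat == 0:
        return 1.0 / max(n_feat, 1)
    return 1.0 / (n_feat * var)


def rbf_kernel(
    X: np.ndarray, Y: np.ndarray | None = None, gamma: float | None = None
) -> np.ndarray:
    """Gaussian RBF kernel matrix exp(-gamma * ||x - y||^2)."""
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        i, j = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(f"non-finite feature value at subject {i}, feature {j}")
    if Y is not None:
        Y = np.asarray(Y, float)
        if not np.isfinite(Y).all():
            i, j = np.argwhere(~np.isfinite(Y))[0]
            raise ValueError(f"non-finite feature value at subject {i}, feature {j}")
    if gamma is None:
        gamma = default_gamma(X if Y is None else Y)
    return pairwise.rbf_kernel(X, Y, gamma=gamma)


def fuse_kernels(k_roi: np.ndarray, k_net: np.ndarray, beta: float) -> np.ndarray:
    """Convex combination beta * K_roi + (1 - beta) * K_net."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    k_roi = np.asarray(k_roi, float)
    k_net = np.asarray(k_net, float)
    if k_roi.shape != k_net.shape:
        raise ValueError(f"kernel shape mismatch: {k_roi.shape} vs {k_net.shape}")
    return beta * k_roi + (1.0 - beta) * k_net


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _to_binary(y: Sequence, positive: str = POSITIVE_LABEL) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "USO":
        return (arr == positive).astype(int)
    return arr.astype(int)


def compute_metrics(
    y_true: Sequence,
    y_pred: Sequence,
    decision_scores: Sequence | None = None,
) -> MetricSet:
    """ACC, SEN, SPE, AUC, Youden's index, F-score and balanced accuracy.

    The high-self-esteem group is the positive class.  With a
    single-class truth vector the class-conditional metrics are NaN (and
    a warning is emitted); AUC requires decision scores and is otherwise
    NaN.  F is 0 when no positives are predicted.
    """
    yt = _to_binary(y_true)
    yp = _to_binary(y_pred)
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else float("nan")
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("single-class truth vector: SEN/SPE undefined", stacklevel=2)
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    f_score = (
        2 * precision * sen / (precision + sen)
        if not math.isnan(sen) and precision + sen > 0
        else 0.0
    )
    auc = float("nan")
    if decision_scores is not None and len(np.unique(yt)) == 2:
        auc = float(roc_auc_score(yt, np.asarray(decision_scores, float)))
    return MetricSet(
        acc=acc,
        sen=sen,
        spe=spe,
        auc=auc,
        youden=sen + spe - 1.0,
        f_score=f_score,
        bac=(sen + spe) / 2.0,
    )


def _nanmean_metrics(metrics: list[MetricSet]) -> tuple[MetricSet, MetricSet]:
    arr = np.array([[getattr(m, f) for f in MetricSet.__dataclass_fields__] for m in metrics])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0)
    names = list(MetricSet.__dataclass_fields__)
    return (
        MetricSet(**dict(zip(names, mean))),
        MetricSet(**dict(zip(names, sd))),
    )


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


def _standardize_pair(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _roles(config: CVConfig) -> list[tuple[str, str]]:
    roles = []
    if config.roi_block is not None:
        roles.append(("roi", config.roi_block))
    if config.net_block is not None:
        roles.append(("net", config.net_block))
    return roles


def _beta_candidates(config: CVConfig) -> tuple[float, ...]:
    if config.roi_block is None:
        return (0.0,)
    if config.net_block is None:
        return (1.0,)
    if config.fixed_beta is not None:
        return (float(config.fixed_beta),)
    return tuple(float(b) for b in config.beta_grid)


def _stratified_split(y, n_splits, seed, max_redraws=10):
    """Outer split; redraws (logged) in the unlikely event a fold lacks a class."""
    for attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=(seed + attempt) % 2**31)
        splits = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2 for tr, te in splits):
            return splits
        logger.warning("fold lacked a class; redrawing split (attempt %d)", attempt + 1)
    raise ValueError("could not draw a stratified split containing both classes")


def _fit_fold(
    blocks: Mapping[str, pd.DataFrame],
    y: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    config: CVConfig,
    selection_config: SelectionConfig,
) -> tuple[dict[str, list[str]], KernelSpec, np.ndarray, np.ndarray]:
    """Select features, tune (beta, gamma scale, C) on the training half, fit, predict."""
    scales = tuple(config.gamma_scale) or (1.0,)
    z_pair: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
    selected: dict[str, list[str]] = {}
    for role, block_name in _roles(config):
        X = blocks[block_name]
        sel, _ = run_cascade(X.iloc[tr], y[tr], selection_config)
        selected[role] = sel
        vals = X[sel].to_numpy(float)
        z_tr, z_te = _standardize_pair(vals[tr], vals[te])
        z_pair[role] = (z_tr, z_te, default_gamma(z_tr))

    def kernels_at(scale: float) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        k_tr, k_te = {}, {}
        for role, (z_tr, z_te, g0) in z_pair.items():
            k_tr[role] = rbf_kernel(z_tr, gamma=scale * g0)
            k_te[role] = rbf_kernel(z_te, z_tr, gamma=scale * g0)
        return k_tr, k_te

    def fused(kd: Mapping[str, np.ndarray], beta: float) -> np.ndarray:
        if "roi" in kd and "net" in kd:
            return fuse_kernels(kd["roi"], kd["net"], beta)
        return kd["roi"] if "roi" in kd else kd["net"]

    betas = _beta_candidates(config)
    y_tr = y[tr]
    n_inner = min(config.inner_folds, int(np.bincount(y_tr).min()))
    scale, beta, C = 1.0, betas[0], config.c_grid[min(1, len(config.c_grid) - 1)]
    if n_inner >= 2 and (len(betas) > 1 or len(config.c_grid) > 1 or len(scales) > 1):
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=0)
        inner_splits = list(inner.split(np.zeros(len(y_tr)), y_tr))
        # per inner split: standardized features and base gamma per role;
        # with inner_selection the cascade is redone on the inner training
        # set so validation subjects never influence feature choice
        inner_z = []
        for itr, ite in inner_splits:
            zd: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}
            for role, block_name in _roles(config):
                X = blocks[block_name]
                sub_tr, sub_te = tr[itr], tr[ite]
                sel_i = selected[role]
                if config.inner_selection:
                    try:
                        sel_i, _ = run_cascade(X.iloc[sub_tr], y[sub_tr], selection_config)
                    except SelectionError:
                        pass  # rare on small inner sets; reuse outer-fold selection
                vals_i = X[sel_i].to_numpy(float)
                z_tr, z_te = _standardize_pair(vals_i[sub_tr], vals_i[sub_te])
                zd[role] = (z_tr, z_te, default_gamma(z_tr))
            inner_z.append((zd, itr, ite))
        # ties (the inner accuracy can still saturate on small training
        # halves) prefer the balanced fusion beta=0.5, the default kernel
        # width, and the smaller beta/C
        best_key = None
        for sc in scales:
            per_split = []
            for zd, itr, ite in inner_z:
                kd_tr = {r: rbf_kernel(z[0], gamma=sc * z[2]) for r, z in zd.items()}
                kd_te = {r: rbf_kernel(z[1], z[0], gamma=sc * z[2]) for r, z in zd.items()}
                per_split.append((kd_tr, kd_te, itr, ite))
            for b in betas:
                folded = [
                    (fused(kd_tr, b), fused(kd_te, b), itr, ite)
                    for kd_tr, kd_te, itr, ite in per_split
                ]
                for c in config.c_grid:
                    acc = 0.0
                    for k_ii, k_vi, itr, ite in folded:
                        clf = SVC(kernel="precomputed", C=c)
                        clf.fit(k_ii, y_tr[itr])
                        acc += (clf.predict(k_vi) == y_tr[ite]).mean()
                    acc /= len(inner_splits)
                    key = (round(acc, 12), -abs(b - 0.5), -b, -abs(math.log(sc)), -c)
                    if best_key is None or key > best_key:
                        best_key, scale, beta, C = key, sc, b, c

    k_train, k_test = kernels_at(scale)
    spec = KernelSpec(
        beta=beta,
        C=C,
        gamma_roi=scale * z_pair["roi"][2] if "roi" in z_pair else None,
        gamma_net=scale * z_pair["net"][2] if "net" in z_pair else None,
    )
    clf = SVC(kernel="precomputed", C=C)
    clf.fit(fused(k_train, beta), y_tr)
    k_te = fused(k_test, beta)
    return selected, spec, clf.predict(k_te), clf.decision_function(k_te)


def nested_cv(
    blocks: Mapping[str, pd.DataFrame],
    labels: Sequence,
    config: CVConfig | None = None,
    selection_config: SelectionConfig | None = None,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified twofold nested cross-validation.

    Parameters
    ----------
    blocks
        Feature blocks (subjects x features), all indexed identically.
    labels
        Group label per subject (``"high"``/``"low"`` or 0/1), aligned
        with the block rows.
    config, selection_config
        CV protocol and cascade parameters; defaults apply when omitted.
    seed
        Master seed; every repetition's split derives from it.

    Returns
    -------
    CVReport
        Per-fold results, per-repetition metrics (each subject is tested
        exactly once per repetition), their mean/SD, and per-feature
        selection frequencies over all fold-fits.
    """
    config = config or CVConfig()
    selection_config = selection_config or SelectionConfig(screen_floor=1)
    roles = _roles(config)
    first = blocks[roles[0][1]]
    ids = [str(i) for i in first.index]
    for _, bname in roles:
        if bname not in blocks:
            raise KeyError(f"feature block {bname!r} not provided")
        if list(blocks[bname].index) != list(first.index):
            raise ValueError(f"block {bname!r} subjects differ from {roles[0][1]!r}")
    y = _to_binary(labels)
    if len(y) != len(ids):
        raise ValueError("labels length does not match block rows")
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.outer_folds * 2:
        raise ValueError(
            f"need at least {config.outer_folds * 2} subjects per group, got {counts.tolist()}"
        )

    rep_seeds = np.random.SeedSequence(seed).generate_state(config.repetitions)
    folds: list[FoldResult] = []
    per_rep: list[MetricSet] = []
    freq: dict[str, Counter] = {role: Counter() for role, _ in roles}
    for rep in range(config.repetitions):
        splits = _stratified_split(y, config.outer_folds, int(rep_seeds[rep]))
        rep_true = np.empty(len(y), int)
        rep_pred = np.empty(len(y), int)
        rep_scores = np.empty(len(y), float)
        for fold, (tr, te) in enumerate(splits):
            selected, spec, pred, scores = _fit_fold(
                blocks, y, tr, te, config, selection_config
            )
            rep_true[te] = y[te]
            rep_pred[te] = pred
            rep_scores[te] = scores
            for role, names in selected.items():
                freq[role].update(names)
            folds.append(
                FoldResult(
                    repetition=rep,
                    fold=fold,
                    test_ids=[ids[i] for i in te],
                    y_true=y[te],
                    y_pred=pred,
                    scores=scores,
                    kernel=spec,
                    selected=selected,
                )
            )
        per_rep.append(compute_metrics(rep_true, rep_pred, rep_scores))
    mean, sd = _nanmean_metrics(per_rep)
    return CVReport(
        folds=folds,
        per_rep_metrics=per_rep,
        metrics_mean=mean,
        metrics_sd=sd,
        frequencies=freq,
        n_subjects=len(ids),
        repetitions=config.repetitions,
        outer_folds=config.outer_folds,
        config={
            "roi_block": config.roi_block,
            "net_block": config.net_block,
            "repetitions": config.repetitions,
            "outer_folds": config.outer_folds,
            "inner_folds": config.inner_folds,
            "c_grid": list(config.c_grid),
            "fixed_beta": config.fixed_beta,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# weight sweep and baselines
# ---------------------------------------------------------------------------


def weight_sweep(
    blocks: Mapping[str, pd.DataFrame],
    labels: Sequence,
    beta_grid: Sequence[float],
    config: CVConfig | None = None,
    selection_config: SelectionConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested-CV metrics at each fixed kernel weight beta.

    Returns a DataFrame indexed by beta with the mean metrics (columns
    ACC, SEN, SPE, AUC, Y, F, BAC) plus the accuracy SD across
    repetitions.
    """
    config = config or CVConfig()
    rows = {}
    for beta in beta_grid:
        cfg = replace(config, fixed_beta=float(beta))
        report = nested_cv(blocks, labels, cfg, selection_config, seed=seed)
        row = report.metrics_mean.as_dict()
        row["ACC_sd"] = report.metrics_sd.acc
        rows[float(beta)] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "beta"
    return out


def _default_baselines() -> dict[str, object]:
    return {
        "svm_rbf": SVC(kernel="rbf", gamma="scale"),
        "svm_linear": SVC(kernel="linear"),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "naive_bayes": GaussianNB(),
        "decision_tree": DecisionTreeClassifier(random_state=0),
    }


def baseline_classifiers(
    blocks: Mapping[str, pd.DataFrame],
    labels: Sequence,
    config: CVConfig | None = None,
    selection_config: SelectionConfig | None = None,
    seed: int = 0,
    classifiers: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Comparison classifiers under the same CV protocol.

    Each fold runs the selection cascade per block, concatenates the
    selected (standardized) features, and fits every baseline on the
    training half.  Returns mean and SD accuracy per classifier.
    """
    from sklearn.base import clone

    config = config or CVConfig()
    selection_config = selection_config or SelectionConfig(screen_floor=1)
    classifiers = dict(classifiers) if classifiers is not None else _default_baselines()
    roles = _roles(config)
    first = blocks[roles[0][1]]
    y = _to_binary(labels)
    rep_seeds = np.random.SeedSequence(seed).generate_state(config.repetitions)
    accs: dict[str, list[float]] = {name: [] for name in classifiers}
    for rep in range(config.repetitions):
        splits = _stratified_split(y, config.outer_folds, int(rep_seeds[rep]))
        for tr, te in splits:
            parts_tr, parts_te = [], []
            for _, bname in roles:
                X = blocks[bname]
                sel, _ = run_cascade(X.iloc[tr], y[tr], selection_config)
                vals = X[sel].to_numpy(float)
                z_tr, z_te = _standardize_pair(vals[tr], vals[te])
                parts_tr.append(z_tr)
                parts_te.append(z_te)
            Ztr = np.hstack(parts_tr)
            Zte = np.hstack(parts_te)
            for name, proto in classifiers.items():
                clf = clone(proto)
                clf.fit(Ztr, y[tr])
                accs[name].append(float((clf.predict(Zte) == y[te]).mean()))
    return pd.DataFrame(
        {
            "accuracy_mean": {n: float(np.mean(a)) for n, a in accs.items()},
            "accuracy_sd": {n: float(np.std(a)) for n, a in accs.items()},
        }
    )


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------


def frequency_table(
    report: CVReport,
    atlas: AtlasHierarchy | None = None,
    top_k: int = 15,
    role: str = "roi",
) -> pd.DataFrame:
    """Features ranked by selection frequency over all fold-fits.

    ``role`` is ``"roi"`` or ``"net"``.  With an atlas, features are
    annotated with ROI name(s), hemisphere(s) and measure or layer.
    Ties are broken lexically by feature name; ``top_k`` larger than the
    table returns everything.
    """
    if role not in report.frequencies:
        raise KeyError(f"report has no {role!r} frequencies")
    counter = report.frequencies[role]
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[: max(top_k, 0) or None]
    rows = []
    for name, count in items:
        row: dict[str, object] = {"feature": name, "frequency": count}
        try:
            info = parse_feature_name(name)
        except ValueError:
            info = {}
        if info.get("kind") == "roi":
            row["measure"] = info["measure"]
            if atlas is not None:
                roi = atlas.roi(4, int(info["roi"]))
                row["roi"] = roi.name
                row["hemisphere"] = roi.hemisphere
        elif info.get("kind") == "edge":
            row["layer"] = info["layer"]
            if atlas is not None:
                ri = atlas.roi(int(info["layer"]), int(info["roi_i"]))
                rj = atlas.roi(int(info["layer"]), int(info["roi_j"]))
                row["roi_i"] = ri.name
                row["hemisphere_i"] = ri.hemisphere
                row["roi_j"] = rj.name
                row["hemisphere_j"] = rj.hemisphere
        rows.append(row)
    return pd.DataFrame(rows)
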
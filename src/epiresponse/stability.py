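"""Stability-selected gradient boosting for therapy-response prediction.

The prognostic classifier works on M-values of the training samples only:

1. a stratified 70/30 train/test split;
2. repeated stratified cross-validation; each of ``n_resamples`` resamples
   is one training fold into which a freshly drawn random noise column is
   injected before fitting gradient-boosted trees;
3. features whose gain importance strictly exceeds the noise column's are
   marked selected in that resample; the full importance ranking feeds a
   pairwise win matrix;
4. resamples are aggregated into a consensus panel: ordering by Copeland
   score of the win matrix, membership by a paired one-sided sign-flip
   permutation test of each feature's importance margin over the noise
   probe, with Benjamini-Hochberg control across features;
5. a final model is retrained on the panel features and evaluated by AUROC
   on the held-out test set (per-repetition cross-validated AUROCs are
   reported alongside).

Every resample is reproducible from (seed, resample index); the test set
never influences selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError

NOISE_FEATURE = "__noise__"


@dataclass
class BoostConfig:
    """Hyperparameters of the stability-selection run.

    The boosting settings (200 trees, depth 3, learning rate 0.1, subsample
    0.8) are fixed defaults so runs are reproducible; ``cv_repeats`` is
    derived from ``n_resamples`` when left unset (each resample is one fold
    of one repeat).
    """

    train_fraction: float = 0.7
    n_resamples: int = 100
    cv_folds: int = 5
    cv_repeats: int | None = None
    n_estimators: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    subsample: float = 0.8
    #: random feature subspace per tree; diversifies the trees so that
    #: chance-correlated features cannot monopolize every split
    colsample_bytree: float = 0.3
    noise_probe: str = "normal"  # or "permuted": a permuted copy of a real feature
    #: screening rule for panel candidacy: the feature's importance must beat
    #: the noise probe in more than this fraction of successful resamples
    #: before the permutation test is applied.  0.9 is the conservative end
    #: of the conventional stability-selection range; on a single fixed
    #: dataset, features with chance dataset-level label correlation can beat
    #: a median-quality noise draw in well over half the resamples, so
    #: majority thresholds are too lax.
    stability_threshold: float = 0.9
    aggregation_alpha: float = 0.05
    #: sign-flip draws for the membership test; the smallest achievable
    #: p-value is 1/(n_permutations+1), which must undercut the BH threshold
    #: alpha * k / n_features — 10000 resolves panels against arrays of a few
    #: thousand features.
    n_permutations: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_resamples < 2:
            raise ValidationError("n_resamples must be >= 2")
        for name in ("cv_folds", "n_estimators", "max_depth", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.noise_probe not in ("normal", "permuted"):
            raise ValidationError("noise_probe must be 'normal' or 'permuted'")

    @property
    def repeats(self) -> int:
        if self.cv_repeats is not None:
            return self.cv_repeats
        return math.ceil(self.n_resamples / self.cv_folds)


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2^31 derived from (seed, key...)."""
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % (2**31))


def _as_binary_labels(y) -> np.ndarray:
    y = pd.Series(y)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, found {classes}")
    if set(classes) == {0, 1}:
        return y.to_numpy(dtype=int)
    # 'responder' sorts after 'non_responder'; positives are the later class
    return (y == classes[1]).astype(int).to_numpy()


def split_train_test(X: pd.DataFrame, y, fraction: float = 0.7, seed: int = 0):
    """Deterministic stratified split of samples x features into train/test.

    Per class, round-half-up(fraction * n_class) samples go to training, so
    class balance is preserved within one sample.  Raises if either side of
    the split would lose a class entirely.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError("fraction must lie strictly in (0, 1)")
    yb = _as_binary_labels(y)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in (0, 1):
        members = np.flatnonzero(yb == cls)
        if members.size < 2:
            raise ValidationError("each class needs at least 2 samples")
        k = int(np.floor(fraction * members.size + 0.5))
        if k == 0 or k == members.size:
            raise ValidationError("split leaves a class empty on one side")
        perm = rng.permutation(members)
        train_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.sort(np.asarray(test_idx))
    return (
        X.iloc[train_idx],
        pd.Series(yb[train_idx], index=X.index[train_idx], name="label"),
        X.iloc[test_idx],
        pd.Series(yb[test_idx], index=X.index[test_idx], name="label"),
    )


@dataclass
class StabilityResult:
    """Raw output of the resampling loop."""

    feature_names: list
    selection_counts: np.ndarray  # times importance strictly beat the noise probe
    importances: np.ndarray  # n_resamples x n_features gain importances (NaN on failure)
    noise_trace: np.ndarray  # noise-probe importance per resample
    win_matrix: np.ndarray  # W[i, j]: resamples where feature i outranked j
    cv_auc: np.ndarray  # validation-fold AUROC per resample
    resample_meta: list  # (repeat, fold, model seed) per resample
    failed: list = field(default_factory=list)
    seed: int = 0

    @property
    def n_resamples(self) -> int:
        return self.importances.shape[0]

    @property
    def successful(self) -> np.ndarray:
        mask = np.ones(self.n_resamples, dtype=bool)
        mask[self.failed] = False
        return mask

    def per_repetition_auc(self, cv_folds: int) -> np.ndarray:
        """Mean validation AUROC per cross-validation repeat."""
        ok = self.successful
        out = []
        for start in range(0, self.n_resamples, cv_folds):
            sl = slice(start, min(start + cv_folds, self.n_resamples))
            vals = self.cv_auc[sl][ok[sl]]
            if vals.size:
                out.append(float(np.mean(vals)))
        return np.asarray(out)


def _fit_booster(Xa: np.ndarray, ya: np.ndarray, config: BoostConfig, seed: int):
    from xgboost import XGBClassifier

    model = XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        colsample_bytree=config.colsample_bytree,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )
    model.fit(Xa, ya)
    return model


def _gain_importances(model, n_features: int) -> np.ndarray:
    score = model.get_booster().get_score(importance_type="total_gain")
    imp = np.zeros(n_features)
    for name, value in score.items():
        imp[int(name[1:])] = value
    return imp


def run_stability_selection(X: pd.DataFrame, y, config: BoostConfig) -> StabilityResult:
    """Run the resampled noise-probe selection loop on the training set."""
    config.validate()
    yb = _as_binary_labels(y)
    counts = np.bincount(yb, minlength=2)
    if counts.min() < config.cv_folds:
        raise ValidationError(
            f"need at least cv_folds={config.cv_folds} samples per class, have {counts.tolist()}"
        )
    Xa = X.to_numpy(dtype=float)
    n, n_feat = Xa.shape

    fold_plan = []
    for rep in range(config.repeats):
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=_child_seed(config.seed, 1, rep)
        )
        fold_plan.extend((rep, f, tr, va) for f, (tr, va) in enumerate(skf.split(Xa, yb)))
    fold_plan = fold_plan[: config.n_resamples]
    if len(fold_plan) < config.n_resamples:
        raise ValidationError("cv_repeats * cv_folds < n_resamples")

    selection = np.zeros(n_feat, dtype=int)
    importances = np.full((config.n_resamples, n_feat), np.nan)
    noise_trace = np.full(config.n_resamples, np.nan)
    win = np.zeros((n_feat, n_feat), dtype=np.int32)
    cv_auc = np.full(config.n_resamples, np.nan)
    meta, failed = [], []

    for r, (rep, fold, tr, va) in enumerate(fold_plan):
        noise_rng = np.random.default_rng(_child_seed(config.seed, 2, r))
        if config.noise_probe == "normal":
            noise_col = noise_rng.normal(size=n)
        else:
            noise_col = noise_rng.permutation(Xa[:, noise_rng.integers(n_feat)])
        Xr = np.column_stack([Xa, noise_col])
        model_seed = _child_seed(config.seed, 3, r)
        meta.append((rep, fold, model_seed))
        try:
            model = _fit_booster(Xr[tr], yb[tr], config, model_seed)
            imp = _gain_importances(model, n_feat + 1)
            scores = model.predict_proba(Xr[va])[:, 1]
            cv_auc[r] = auroc(scores, yb[va])
        except Exception:  # noqa: BLE001 - a failed resample is recorded, not fatal
            failed.append(r)
            continue
        importances[r] = imp[:n_feat]
        noise_trace[r] = imp[n_feat]
        selection += imp[:n_feat] > imp[n_feat]
        win += (imp[:n_feat, None] > imp[None, :n_feat]).astype(np.int32)

    if len(failed) > 0.1 * config.n_resamples:
        raise RuntimeError(
            f"{len(failed)} of {config.n_resamples} resamples failed (> 10%); aborting"
        )
    return StabilityResult(
        feature_names=list(X.columns),
        selection_counts=selection,
        importances=importances,
        noise_trace=noise_trace,
        win_matrix=win,
        cv_auc=cv_auc,
        resample_meta=meta,
        failed=failed,
        seed=config.seed,
    )


@dataclass
class Panel:
    """Consensus feature panel: members ordered most to least important."""

    features: list
    table: pd.DataFrame  # all features: copeland, mean_importance, selection_freq, p, q, member
    alpha: float

    def __len__(self) -> int:
        return len(self.features)


def aggregate_pairwise(result: StabilityResult, config: BoostConfig) -> Panel:
    """Aggregate resamples into the final panel.

    Consensus order is the Copeland score of the pairwise win matrix
    (feature i beats j iff it outranked j in more resamples than the
    converse); ties break by mean importance, then feature id.  Membership
    is a two-step rule: a candidate must beat the noise probe in more than
    ``stability_threshold`` of the resamples (the stability-selection
    screen), and its per-resample importance margin over the noise probe
    must be significantly positive under a paired one-sided sign-flip
    permutation test, Benjamini-Hochberg corrected across the screened
    candidates at ``aggregation_alpha``.  Resamples of one dataset are not
    independent replicates, so the permutation test alone is anti-
    conservative for features with chance dataset-level correlation; the
    majority screen is what keeps null panels empty.  An empty panel is a
    valid outcome.
    """
    from statsmodels.stats.multitest import multipletests

    ok = result.successful
    if ok.sum() < 2:
        raise ValidationError("need at least 2 successful resamples to aggregate")
    D = result.importances[ok] - result.noise_trace[ok][:, None]  # resamples x features
    n_ok, n_feat = D.shape
    obs = D.mean(axis=0)

    rng = np.random.default_rng(_child_seed(result.seed, 4))
    exceed = np.zeros(n_feat, dtype=np.int64)
    done = 0
    while done < config.n_permutations:  # chunked to bound memory
        block = min(2000, config.n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(block, n_ok))
        perm_means = signs @ D / n_ok
        exceed += (perm_means >= obs[None, :]).sum(axis=0)
        done += block
    p = (1.0 + exceed) / (config.n_permutations + 1.0)

    selection_freq = result.selection_counts / n_ok
    candidate = selection_freq > config.stability_threshold
    q = np.full(n_feat, np.nan)
    member = np.zeros(n_feat, dtype=bool)
    if candidate.any():
        reject, q_cand, *_ = multipletests(
            p[candidate], alpha=config.aggregation_alpha, method="fdr_bh"
        )
        q[candidate] = q_cand
        member[candidate] = reject & (obs[candidate] > 0)

    W = result.win_matrix
    copeland = ((W > W.T).sum(axis=1)).astype(int)
    mean_imp = np.nanmean(result.importances, axis=0)
    table = pd.DataFrame(
        {
            "feature": result.feature_names,
            "copeland": copeland,
            "mean_importance": mean_imp,
            "selection_freq": selection_freq,
            "candidate": candidate,
            "p_permutation": p,
            "q_value": q,
            "member": member,
        }
    )
    order = table.sort_values(
        ["copeland", "mean_importance", "feature"], ascending=[False, False, True]
    )
    features = order.loc[order["member"], "feature"].tolist()
    return Panel(features=features, table=table.set_index("feature"), alpha=config.aggregation_alpha)


@dataclass
class ClassifierPerformance:
    test_auroc: float
    roc: pd.DataFrame | None  # fpr, tpr, threshold
    cv_auc_per_repetition: np.ndarray | None = None
    note: str = ""

    @property
    def mean_cv_auroc(self) -> float:
        if self.cv_auc_per_repetition is None or len(self.cv_auc_per_repetition) == 0:
            return float("nan")
        return float(np.mean(self.cv_auc_per_repetition))


def train_final(X_train: pd.DataFrame, y_train, panel, config: BoostConfig):
    """Retrain a boosted-tree model on the full training set, panel features only.

    ``panel`` may be a :class:`Panel`, a feature list, or None (all
    features).  An empty panel yields None — the explicit no-model result.
    """
    features = panel.features if isinstance(panel, Panel) else panel
    if features is not None and len(features) == 0:
        return None
    cols = list(features) if features is not None else list(X_train.columns)
    yb = _as_binary_labels(y_train)
    model = _fit_booster(
        X_train[cols].to_numpy(dtype=float), yb, config, _child_seed(config.seed, 5)
    )
    model._panel_features = cols
    return model


def evaluate(
    model,
    X_test: pd.DataFrame,
    y_test,
    result: StabilityResult | None = None,
    cv_folds: int = 5,
) -> ClassifierPerformance:
    """Held-out AUROC (and ROC curve) of the final model."""
    from sklearn.metrics import roc_curve

    cv_rep = result.per_repetition_auc(cv_folds) if result is not None else None
    if model is None:
        return ClassifierPerformance(
            test_auroc=float("nan"),
            roc=None,
            cv_auc_per_repetition=cv_rep,
            note="empty panel: no model; AUROC undefined",
        )
    yb = _as_binary_labels(y_test)
    scores = model.predict_proba(X_test[model._panel_features].to_numpy(dtype=float))[:, 1]
    fpr, tpr, thr = roc_curve(yb, scores)
    return ClassifierPerformance(
        test_auroc=auroc(scores, yb),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        cv_auc_per_repetition=cv_rep,
    )


def auroc(scores, labels) -> float:
    """AUROC by the Mann-Whitney pair count; ties earn half credit.

    Equals ``(#{pos > neg} + 0.5 #{pos == neg}) / (n_pos * n_neg)``.
    """
    scores = np.asarray(scores, dtype=float)
    yb = _as_binary_labels(labels)
    n_pos = int(yb.sum())
    n_neg = int(yb.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[yb == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
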
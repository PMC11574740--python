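"""PTE vs non-PTE classification with nested leave-one-pair-out CV.

The feature table concatenates 15 ROI lesion volumes, 105 Fisher-z
connectivity values and 15 ROI ALFF means (135 columns).  Each CV repeat
draws a random PTE/non-PTE pairing; every pair in turn is held out while
standardization, PCA and hyperparameter selection (inner stratified k-fold,
AUC criterion) happen strictly on the remaining training subjects, so no
information leaks from the held-out pair.  Out-of-fold decision scores are
pooled into one AUC per repeat.  Significance comes from a permutation null
(labels shuffled before a CV pass) compared with a rank-sum test, and sample
-size behaviour from a learning curve with quadratic extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "CVConfig",
    "CVResult",
    "NullAUC",
    "LearningCurve",
    "ExtrapolatedAUC",
    "feature_columns",
    "assemble_features",
    "nested_cv_auc",
    "permutation_auc_null",
    "svm_feature_importance",
    "learning_curve",
    "extrapolate_auc",
]

FEATURE_BLOCKS = ("lesion", "connectivity", "alff")


def _col(name: str) -> str:
    return name.replace(" ", "_")


def feature_columns(roi_names) -> tuple[list[str], list[str], list[str]]:
    """Column names per block: lesvol_<roi>, conn_<a>_<b>, alff_<roi>."""
    roi_names = list(roi_names)
    lesion = [f"lesvol_{_col(n)}" for n in roi_names]
    iu = np.triu_indices(len(roi_names), k=1)
    conn = [f"conn_{_col(roi_names[i])}_{_col(roi_names[j])}" for i, j in zip(*iu)]
    alff = [f"alff_{_col(n)}" for n in roi_names]
    return lesion, conn, alff


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and per-column block tags."""

    data: pd.DataFrame  # indexed by subject_id, fixed block order
    labels: pd.Series  # "PTE" / "nonPTE", aligned with data.index
    feature_group: pd.Series  # block tag per column

    @property
    def x(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return (self.labels.to_numpy() == "PTE").astype(int)

    def subset_block(self, block: str) -> "FeatureTable":
        cols = self.feature_group.index[self.feature_group == block]
        return FeatureTable(self.data[cols], self.labels, self.feature_group[cols])

    def subset_subjects(self, index) -> "FeatureTable":
        return FeatureTable(self.data.loc[index], self.labels.loc[index], self.feature_group)


def assemble_features(
    lesion_volumes: pd.DataFrame,
    connectivity_z: pd.DataFrame,
    alff_means: pd.DataFrame,
    labels: pd.Series,
    roi_names=None,
) -> FeatureTable:
    """Concatenate the three feature blocks, aligned by subject id.

    Inputs are DataFrames indexed by subject_id.  Column order is fixed as
    lesion | connectivity | ALFF; a subject present in one block but not all
    raises with the offending ids listed.
    """
    blocks = {
        "lesion": lesion_volumes,
        "connectivity": connectivity_z,
        "alff": alff_means,
    }
    all_ids = set(labels.index)
    for name, df in blocks.items():
        all_ids |= set(df.index)
    missing_msgs = []
    for name, df in list(blocks.items()) + [("labels", labels.to_frame())]:
        missing = sorted(all_ids - set(df.index))
        if missing:
            missing_msgs.append(f"{name}: missing {missing}")
    if missing_msgs:
        raise ValueError("subjects absent from some blocks — " + "; ".join(missing_msgs))

    order = list(labels.index)
    if roi_names is not None:
        les_cols, conn_cols, alff_cols = feature_columns(roi_names)
        lesion_volumes = lesion_volumes[les_cols]
        connectivity_z = connectivity_z[conn_cols]
        alff_means = alff_means[alff_cols]
    data = pd.concat(
        [lesion_volumes.loc[order], connectivity_z.loc[order], alff_means.loc[order]],
        axis=1,
    )
    group = pd.Series(
        ["lesion"] * lesion_volumes.shape[1]
        + ["connectivity"] * connectivity_z.shape[1]
        + ["alff"] * alff_means.shape[1],
        index=data.columns,
    )
    return FeatureTable(data=data, labels=labels.loc[order], feature_group=group)


@dataclass(frozen=True)
class CVConfig:
    """Nested-CV settings.  One "repeat" is a complete leave-one-pair-out
    pass with a freshly randomized PTE/non-PTE pairing."""

    method: str = "ksvm"  # ksvm | svm | rf | nn
    n_repeats: int = 1000
    inner_folds: int = 5
    pca_components_grid: tuple[int, ...] = (5, 10, 20, 40)
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    gamma_factors: tuple[float, ...] = (0.1, 1.0, 10.0)  # x the scale heuristic
    rf_trees: int = 500
    rf_depth_grid: tuple = (None, 5)
    mlp_hidden: tuple[int, ...] = (32, 16, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ksvm", "svm", "rf", "nn"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_repeats < 1 or self.inner_folds < 2:
            raise ValueError("n_repeats >= 1 and inner_folds >= 2 required")
        if not self.pca_components_grid:
            raise ValueError("pca_components_grid must be nonempty")


def fast_config(**overrides) -> CVConfig:
    """Reduced profile for tests and calibration runs."""
    base = dict(
        n_repeats=5,
        inner_folds=3,
        pca_components_grid=(4, 8),
        c_grid=(1.0,),
        gamma_factors=(1.0,),
        rf_trees=100,
        rf_depth_grid=(None,),
    )
    base.update(overrides)
    return CVConfig(**base)


__all__.append("fast_config")


@dataclass
class CVResult:
    auc_samples: np.ndarray  # one AUC per repeat
    oof_scores: np.ndarray  # (n_repeats, n_subjects) out-of-fold scores
    chosen: list  # per repeat: list of per-fold (pca_n, params)
    subject_ids: list[str]
    method: str

    @property
    def mean(self) -> float:
        return float(self.auc_samples.mean())

    @property
    def sd(self) -> float:
        return float(self.auc_samples.std(ddof=1)) if self.auc_samples.size > 1 else 0.0


@dataclass
class NullAUC:
    null_auc_samples: np.ndarray
    ranksum_p: float | None  # vs the observed AUC samples, if provided
    kde_grid: np.ndarray
    kde_density: np.ndarray


@dataclass
class LearningCurve:
    n_values: np.ndarray
    mean_auc: np.ndarray
    sd_auc: np.ndarray


@dataclass
class ExtrapolatedAUC:
    coefficients: np.ndarray  # quadratic in n, highest degree first
    fit_last_k: int
    target_n: int
    predicted_auc: float


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _make_estimator(config: CVConfig, params: dict, x: np.ndarray, seed: int):
    if config.method == "ksvm":
        d = x.shape[1]
        var = x.var()
        scale = 1.0 / (d * var) if var > 0 else 1.0
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma_factor"] * scale)
    if config.method == "svm":
        return SVC(kernel="linear", C=params["C"])
    if config.method == "rf":
        return RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_depth=params["max_depth"],
            random_state=seed,
            n_jobs=1,
        )
    return MLPClassifier(
        hidden_layer_sizes=config.mlp_hidden,
        activation="relu",
        # early stopping needs a stratifiable validation split
        early_stopping=x.shape[0] >= 24,
        max_iter=300,
        random_state=seed,
    )


def _param_candidates(config: CVConfig) -> list[dict]:
    if config.method == "ksvm":
        return [
            {"C": c, "gamma_factor": g}
            for c in config.c_grid
            for g in config.gamma_factors
        ]
    if config.method == "svm":
        return [{"C": c} for c in config.c_grid]
    if config.method == "rf":
        return [{"max_depth": d} for d in config.rf_depth_grid]
    return [{}]


def _scores(est, x: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return est.decision_function(x)
    return est.predict_proba(x)[:, 1]


def _pca_grid(config: CVConfig, n_train: int, n_features: int) -> list[int]:
    cap = min(n_train - 1, n_features)
    grid = sorted({min(c, cap) for c in config.pca_components_grid if c >= 1})
    return [g for g in grid if g >= 1] or [1]


def _fit_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    config: CVConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple]:
    """Select (pca_n, params) by inner-CV AUC on the training set only,
    refit, and return decision scores for the test rows."""
    pca_grid = _pca_grid(config, x_train.shape[0], x_train.shape[1])
    params_grid = _param_candidates(config)
    max_pca = max(pca_grid)
    inner_seed = int(rng.integers(2**31 - 1))

    # inner stratified folds; scaler/PCA fit on each inner training split.
    # PCA components are nested, so one fit at max_pca serves every pca_n.
    skf = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=inner_seed
    )
    inner_scores = {
        (p, i): [] for p in pca_grid for i in range(len(params_grid))
    }
    inner_truth = {k: [] for k in inner_scores}
    for tr, te in skf.split(x_train, y_train):
        mu, sd = _standardize_fit(x_train[tr])
        xt = (x_train[tr] - mu) / sd
        xv = (x_train[te] - mu) / sd
        pca = PCA(n_components=min(max_pca, xt.shape[0], xt.shape[1]),
                  svd_solver="full").fit(xt)
        zt_full = pca.transform(xt)
        zv_full = pca.transform(xv)
        for p in pca_grid:
            pp = min(p, zt_full.shape[1])
            for i, params in enumerate(params_grid):
                est = _make_estimator(config, params, zt_full[:, :pp], inner_seed)
                est.fit(zt_full[:, :pp], y_train[tr])
                inner_scores[(p, i)].append(_scores(est, zv_full[:, :pp]))
                inner_truth[(p, i)].append(y_train[te])
    best, best_auc = None, -np.inf
    for p in pca_grid:
        for i in range(len(params_grid)):
            yv = np.concatenate(inner_truth[(p, i)])
            sv = np.concatenate(inner_scores[(p, i)])
            auc = roc_auc_score(yv, sv) if len(np.unique(yv)) == 2 else 0.5
            if auc > best_auc:
                best, best_auc = (p, i), auc

    p, i = best
    mu, sd = _standardize_fit(x_train)
    xt = (x_train - mu) / sd
    pca = PCA(n_components=min(p, xt.shape[0], xt.shape[1]), svd_solver="full").fit(xt)
    zt = pca.transform(xt)
    est = _make_estimator(config, params_grid[i], zt, inner_seed)
    est.fit(zt, y_train)
    zq = pca.transform((x_test - mu) / sd)
    return _scores(est, zq), (p, params_grid[i])


def _one_repeat(
    x: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, list]:
    """One complete leave-one-pair-out pass with a random pairing."""
    pte_idx = np.flatnonzero(y == 1)
    non_idx = np.flatnonzero(y == 0)
    pairs = list(zip(rng.permutation(pte_idx), rng.permutation(non_idx)))
    oof = np.full(y.size, np.nan)
    chosen = []
    for ip, inn in pairs:
        test = np.array([ip, inn])
        train = np.setdiff1d(np.arange(y.size), test)
        scores, sel = _fit_fold(x[train], y[train], x[test], config, rng)
        oof[test] = scores
        chosen.append(sel)
    auc = roc_auc_score(y, oof)
    return float(auc), oof, chosen


def _check_balanced(y: np.ndarray) -> None:
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 != n0:
        raise ValueError(
            f"leave-one-pair-out needs balanced groups (got {n1} PTE / {n0} nonPTE)"
        )
    if n1 < 3:
        raise ValueError("need at least 3 subjects per group")


def nested_cv_auc(table: FeatureTable, config: CVConfig) -> CVResult:
    """Nested leave-one-pair-out stratified CV; one pooled AUC per repeat.

    Standardization and PCA are fit inside each outer training set;
    hyperparameters (PCA dimension and model parameters) are chosen by inner
    stratified k-fold AUC.  Each outer test fold holds exactly one PTE and
    one non-PTE subject.
    """
    x, y = table.x, table.y
    _check_balanced(y)
    aucs, oofs, chosen_all = [], [], []
    for rep in range(config.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep]))
        auc, oof, chosen = _one_repeat(x, y, config, rng)
        aucs.append(auc)
        oofs.append(oof)
        chosen_all.append(chosen)
    return CVResult(
        auc_samples=np.array(aucs),
        oof_scores=np.stack(oofs),
        chosen=chosen_all,
        subject_ids=list(table.data.index),
        method=config.method,
    )


def permutation_auc_null(
    table: FeatureTable,
    config: CVConfig,
    n_null: int = 200,
    observed: CVResult | None = None,
) -> NullAUC:
    """Null AUC distribution from label permutations.

    Each draw permutes the subject labels and runs one complete CV pass; the
    resulting AUCs estimate chance-level performance.  If ``observed`` is
    given, a two-sided rank-sum test compares observed vs null AUC samples.
    """
    if n_null < 10:
        warnings.warn("n_null < 10 gives an unstable permutation p-value",
                      stacklevel=2)
    x, y = table.x, table.y
    _check_balanced(y)
    null_aucs = []
    for draw in range(n_null):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919, draw]))
        yp = rng.permutation(y)
        auc, _, _ = _one_repeat(x, yp, config, rng)
        null_aucs.append(auc)
    null_aucs = np.array(null_aucs)
    p = None
    if observed is not None:
        p = float(
            stats.mannwhitneyu(
                observed.auc_samples, null_aucs, alternative="two-sided"
            ).pvalue
        )
    grid = np.linspace(0.0, 1.0, 201)
    if np.ptp(null_aucs) > 0:
        density = stats.gaussian_kde(null_aucs)(grid)
    else:
        density = np.zeros_like(grid)
    return NullAUC(
        null_auc_samples=null_aucs, ranksum_p=p, kde_grid=grid, kde_density=density
    )


def svm_feature_importance(
    table: FeatureTable, config: CVConfig, roi_names=None
) -> tuple[pd.Series, pd.Series]:
    """Positive linear-SVM coefficients back-projected through PCA.

    A linear SVM is fit on the standardized full table in PCA space; its
    coefficient vector is mapped back to the 135 features, negative parts are
    dropped, and feature importances are aggregated per ROI (connectivity
    features contribute half to each of their two ROIs).
    """
    if config.method in ("rf", "nn"):
        raise ValueError("feature importance is defined for linear SVM coefficients only")
    x, y = table.x, table.y
    mu, sd = _standardize_fit(x)
    xs = (x - mu) / sd
    n_comp = min(max(config.pca_components_grid), xs.shape[0], xs.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full").fit(xs)
    z = pca.transform(xs)
    est = SVC(kernel="linear", C=1.0).fit(z, y)
    w = pca.components_.T @ est.coef_.ravel()
    importance = pd.Series(np.clip(w, 0.0, None), index=table.data.columns)

    if roi_names is None:
        # recover ROI names from the alff columns
        roi_names = [
            c[len("alff_"):].replace("_", " ")
            for c in table.data.columns
            if c.startswith("alff_")
        ]
    roi_imp = pd.Series(0.0, index=list(roi_names))
    cols = {_col(n): n for n in roi_names}
    for feat, val in importance.items():
        if feat.startswith("lesvol_"):
            roi_imp[cols[feat[len("lesvol_"):]]] += val
        elif feat.startswith("alff_"):
            roi_imp[cols[feat[len("alff_"):]]] += val
        elif feat.startswith("conn_"):
            rest = feat[len("conn_"):]
            # split at the boundary between the two ROI column tokens
            for key in cols:
                if rest.startswith(key + "_"):
                    a, b = key, rest[len(key) + 1 :]
                    roi_imp[cols[a]] += val / 2.0
                    roi_imp[cols[b]] += val / 2.0
                    break
    return importance, roi_imp


def learning_curve(
    table: FeatureTable,
    config: CVConfig,
    n_grid,
    subset_draws: int = 3,
) -> LearningCurve:
    """Mean/sd CV AUC on random balanced subsets of each size in ``n_grid``.

    Sizes below 6 subjects are skipped with a warning (inner stratification
    degenerates).  ``subset_draws`` fresh subsets are drawn per size; each is
    scored with ``config.n_repeats`` CV repeats.
    """
    x, y = table.x, table.y
    _check_balanced(y)
    total = y.size
    ns, means, sds = [], [], []
    for n in n_grid:
        if n % 2 != 0 or n > total:
            raise ValueError(f"subset size {n} must be even and <= {total}")
        if n < 6:
            warnings.warn(f"subset size {n} < 6 skipped", stacklevel=2)
            continue
        aucs = []
        for draw in range(subset_draws):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, n, draw]))
            pte = rng.choice(np.flatnonzero(y == 1), n // 2, replace=False)
            non = rng.choice(np.flatnonzero(y == 0), n // 2, replace=False)
            idx = table.data.index[np.concatenate([pte, non])]
            sub = table.subset_subjects(idx)
            res = nested_cv_auc(sub, replace(config, seed=config.seed + draw + 1))
            aucs.extend(res.auc_samples)
        ns.append(n)
        means.append(float(np.mean(aucs)))
        sds.append(float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0)
    return LearningCurve(
        n_values=np.array(ns), mean_auc=np.array(means), sd_auc=np.array(sds)
    )


def extrapolate_auc(
    curve: LearningCurve, fit_last_k: int, target_n: int
) -> ExtrapolatedAUC:
    """Least-squares quadratic in n through the last k curve points,
    evaluated at ``target_n`` and clipped to [0, 1]."""
    if fit_last_k < 3:
        raise ValueError("need at least 3 points for a quadratic fit")
    if fit_last_k > curve.n_values.size:
        raise ValueError(
            f"fit_last_k={fit_last_k} exceeds available points ({curve.n_values.size})"
        )
    ns = curve.n_values[-fit_last_k:].astype(np.float64)
    aucs = curve.mean_auc[-fit_last_k:]
    coeffs = np.polyfit(ns, aucs, 2)
    pred = float(np.polyval(coeffs, target_n))
    if not (0.0 <= pred <= 1.0):
        warnings.warn(
            f"extrapolated AUC {pred:.3f} outside [0, 1]; clipped", stacklevel=2
        )
        pred = float(np.clip(pred, 0.0, 1.0))
    return ExtrapolatedAUC(
        coefficients=coeffs,
        fit_last_k=fit_last_k,
        target_n=target_n,
        predicted_auc=pred,
    )
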
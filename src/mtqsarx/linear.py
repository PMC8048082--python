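"""Linear discriminant modelling on deviation features.

Covers descriptor pre-treatment (variance and pairwise-correlation
cut-offs), two deterministic feature selectors — p-value driven forward
stepwise (FS) and cross-validated sequential forward selection with
optional floating (SFS) — goodness-of-fit statistics (Wilks' lambda, F, p),
the cross-correlation matrix of selected descriptors, and response+condition
randomisation for robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import boxjenkins as bj
from .dataset import MTQSARDataset

__all__ = [
    "PretreatReport",
    "LDAModel",
    "YcReport",
    "pretreat",
    "fs_lda",
    "sfs_lda",
    "wilks_lambda",
    "cross_correlation",
    "yc_randomize",
]


@dataclass
class PretreatReport:
    removed_constant: list
    removed_correlated: list          # (kept, dropped, |r|)
    variance_cutoff: float
    correlation_cutoff: float


def pretreat(features: pd.DataFrame, variance_cutoff: float = 0.001,
             correlation_cutoff: float = 1.0) -> tuple[pd.DataFrame, PretreatReport]:
    """Drop low-variance columns, then the later column of any pair whose
    |Pearson r| reaches the correlation cut-off. Deterministic: columns are
    scanned in stored order."""
    if len(features) < 2:
        raise ValueError("pre-treatment needs at least two rows")
    if variance_cutoff < 0:
        raise ValueError("variance_cutoff must be >= 0")
    if not 0.0 < correlation_cutoff <= 1.0:
        raise ValueError("correlation_cutoff must lie in (0, 1]")

    variances = features.var(axis=0, ddof=1)
    removed_constant = [c for c in features.columns if variances[c] < variance_cutoff]
    kept = [c for c in features.columns if c not in set(removed_constant)]
    if not kept:
        raise ValueError("pre-treatment removed every feature (variance filter)")

    corr = features[kept].corr().abs().to_numpy()
    alive = np.ones(len(kept), dtype=bool)
    removed_correlated = []
    for i in range(len(kept)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(kept)):
            if alive[j] and corr[i, j] >= correlation_cutoff - 1e-12:
                alive[j] = False
                removed_correlated.append((kept[i], kept[j], float(corr[i, j])))
    surviving = [c for c, a in zip(kept, alive) if a]
    if not surviving:
        raise ValueError("pre-treatment removed every feature")
    report = PretreatReport(removed_constant, removed_correlated,
                            variance_cutoff, correlation_cutoff)
    return features[surviving], report


@dataclass
class LDAModel:
    selected: list
    coefficients: np.ndarray
    intercept: float
    wilks_lambda: float
    f_stat: float
    p_value: float
    selection_log: list = field(default_factory=list)
    estimator: Optional[LinearDiscriminantAnalysis] = None
    selector: str = ""

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.decision_function(X[self.selected])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(X[self.selected])


def wilks_lambda(scores, labels) -> tuple[float, float, float]:
    """One-way decomposition of discriminant scores.

    lambda = within-group SS / total SS (0 = perfect discrimination,
    1 = none); F and p from the standard one-way ANOVA identity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("both classes must be present")
    grand = scores.mean()
    ss_total = float(((scores - grand) ** 2).sum())
    ss_within = 0.0
    for g in groups:
        s = scores[labels == g]
        ss_within += float(((s - s.mean()) ** 2).sum())
    if ss_total == 0.0:
        return 1.0, 0.0, 1.0
    lam = ss_within / ss_total
    k, n = len(groups), len(scores)
    df_between, df_within = k - 1, n - k
    if ss_within == 0.0:
        return 0.0, float("inf"), 0.0
    f = ((ss_total - ss_within) / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(lam), float(f), p


def _fit_final(X: pd.DataFrame, y, selected: list, log: list,
               selector: str) -> LDAModel:
    lda = LinearDiscriminantAnalysis(solver="svd")
    lda.fit(X[selected], y)
    scores = lda.decision_function(X[selected])
    lam, f, p = wilks_lambda(scores, y)
    return LDAModel(selected=list(selected),
                    coefficients=lda.coef_.ravel().copy(),
                    intercept=float(lda.intercept_[0]),
                    wilks_lambda=lam, f_stat=f, p_value=p,
                    selection_log=log, estimator=lda, selector=selector)


def fs_lda(X: pd.DataFrame, y, p_enter: float = 0.05, p_remove: float = 0.05,
           max_descriptors: int = 10) -> LDAModel:
    """Forward stepwise selection on coefficient p-values of the OLS
    regression of the class indicator, with backward elimination at
    ``p_remove``; the final discriminant is refit on the selected set."""
    if max_descriptors < 1:
        raise ValueError("max_descriptors must be >= 1")
    if p_enter > p_remove:
        warnings.warn("p_enter > p_remove may cause cycling")
    y = np.asarray(y, dtype=float)
    selected: list = []
    log: list = []
    candidates = list(X.columns)

    def _pvalues(cols):
        design = sm.add_constant(X[cols].to_numpy(dtype=float))
        fit = sm.OLS(y, design).fit()
        return fit.pvalues[1:]          # skip intercept

    for _ in range(10 * len(candidates) + 10):
        if len(selected) >= max_descriptors:
            break
        best_col, best_p = None, np.inf
        for col in candidates:
            if col in selected:
                continue
            try:
                p = float(_pvalues(selected + [col])[-1])
            except Exception:
                continue
            if np.isnan(p):
                continue
            if p < best_p - 1e-15:      # strict improvement; ties keep first
                best_col, best_p = col, p
        if best_col is None or best_p >= p_enter:
            break
        selected.append(best_col)
        log.append({"step": len(log) + 1, "action": "enter",
                    "descriptor": best_col, "p_value": best_p})
        # backward elimination
        while len(selected) > 1:
            pv = _pvalues(selected)
            worst = int(np.argmax(pv))
            if pv[worst] <= p_remove:
                break
            dropped = selected.pop(worst)
            log.append({"step": len(log) + 1, "action": "remove",
                        "descriptor": dropped, "p_value": float(pv[worst])})
            if dropped == best_col:
                break                   # guard against enter/remove cycling
    if not selected:
        raise ValueError("no descriptor meets the p-value-to-enter criterion")
    return _fit_final(X, y, selected, log, selector="fs")


def _cv_score(X: pd.DataFrame, y, cols: list, scoring: str, cv_folds: int,
              seed: Optional[int]) -> float:
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={cv_folds} exceeds the minority-class count {counts.min()}")
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=seed is not None,
                          random_state=seed)
    Xs = X[cols].to_numpy(dtype=float)
    scores = []
    for tr, te in skf.split(Xs, y):
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(Xs[tr], y[tr])
        if scoring == "accuracy":
            scores.append(float((lda.predict(Xs[te]) == y[te]).mean()))
        elif scoring == "auroc":
            scores.append(float(roc_auc_score(y[te], lda.decision_function(Xs[te]))))
        else:
            raise ValueError("scoring must be 'accuracy' or 'auroc'")
    return float(np.mean(scores))


def sfs_lda(X: pd.DataFrame, y, scoring: str = "accuracy",
            floating: bool = True, max_descriptors: int = 10,
            cv_folds: int = 5, seed: int = 0) -> LDAModel:
    """Sequential forward selection (optionally floating) maximising the
    cross-validated score of a discriminant on the candidate set."""
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if max_descriptors < 1:
        raise ValueError("max_descriptors must be >= 1")
    selected: list = []
    log: list = []
    best_score = -np.inf
    while len(selected) < max_descriptors:
        best_col, best_new = None, best_score
        for col in X.columns:
            if col in selected:
                continue
            s = _cv_score(X, y, selected + [col], scoring, cv_folds, seed)
            if s > best_new + 1e-12:
                best_col, best_new = col, s
        if best_col is None:
            break
        selected.append(best_col)
        best_score = best_new
        log.append({"step": len(log) + 1, "action": "add",
                    "descriptor": best_col, "score": best_new})
        if floating and len(selected) > 2:
            improved = True
            while improved and len(selected) > 1:
                improved = False
                for col in list(selected[:-1]):       # never the one just added
                    trial = [c for c in selected if c != col]
                    s = _cv_score(X, y, trial, scoring, cv_folds, seed)
                    if s > best_score + 1e-12:
                        selected = trial
                        best_score = s
                        log.append({"step": len(log) + 1, "action": "float-remove",
                                    "descriptor": col, "score": s})
                        improved = True
                        break
    if not selected:
        raise ValueError("sequential selection found no improving descriptor")
    return _fit_final(X, y, selected, log, selector="sfs")


def cross_correlation(features: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pearson cross-correlation matrix of the selected descriptors and the
    maximum off-diagonal |r|. Constant features yield NaN correlations."""
    if features.shape[1] < 2:
        raise ValueError("cross-correlation needs at least two features")
    corr = features.corr()
    np.fill_diagonal(corr.to_numpy(), 1.0)
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, np.nan)
    max_off = float(np.nanmax(np.abs(off))) if not np.all(np.isnan(off)) else float("nan")
    return corr, max_off


@dataclass
class YcReport:
    n_runs: int
    lambda_r: float               # mean randomised Wilks' lambda
    accuracy_r: float             # mean randomised sub-training accuracy, %
    runs: pd.DataFrame            # per-run lambda and accuracy


def _scramble(train: MTQSARDataset, rng: np.random.Generator) -> MTQSARDataset:
    """Permute the response column and each condition column independently."""
    resp = pd.Series(rng.permutation(train.response.to_numpy()), index=train.ids)
    cond = {}
    for col in train.conditions.columns:
        cond[col] = rng.permutation(train.conditions[col].to_numpy())
    return MTQSARDataset(
        ids=list(train.ids),
        response=resp,
        conditions=pd.DataFrame(cond, index=train.ids),
        descriptors=train.descriptors,
        set_tag=train.set_tag,
        p_user=train.p_user,
    )


def yc_randomize(train: MTQSARDataset, model: LDAModel, bj_method: int,
                 n_runs: int = 100, seed: int = 0, *,
                 subtrain_ids=None, avg_over: str = "actives",
                 links: dict | None = None) -> YcReport:
    """Response-and-condition randomisation of a fitted linear model.

    Each run scrambles the response and every condition column across rows,
    refits the deviation-descriptor statistics on the scrambled training
    data, rebuilds the SAME named descriptors, refits the discriminant, and
    records Wilks' lambda and sub-training accuracy. A robust model's
    original lambda/accuracy clearly beat the randomised means.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    for name in model.selected:
        desc, col = bj.parse_feature_name(name)
        if desc not in train.descriptors.columns or col not in train.conditions.columns:
            raise ValueError(f"model descriptor {name!r} not reconstructible "
                             f"from the training data")
    ids = list(subtrain_ids) if subtrain_ids is not None else list(train.ids)
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        scrambled = _scramble(train, rng)
        bj_model = bj.fit_boxjenkins(scrambled, bj_method, avg_over=avg_over,
                                     links=links, allow_empty_elements=True)
        feats = bj.transform(scrambled.subset(ids), bj_model)
        X = feats.X
        missing = [c for c in model.selected if c not in X.columns]
        if missing:
            raise ValueError(f"descriptors {missing} lost after scrambling "
                             f"(invariant on the scrambled training set)")
        y = scrambled.response.loc[ids].to_numpy()
        lda = LinearDiscriminantAnalysis(solver="svd")
        lda.fit(X[model.selected], y)
        lam, _, _ = wilks_lambda(lda.decision_function(X[model.selected]), y)
        acc = 100.0 * float((lda.predict(X[model.selected]) == y).mean())
        rows.append({"run": run + 1, "wilks_lambda": lam, "accuracy_pct": acc})
    runs = pd.DataFrame(rows)
    return YcReport(n_runs=n_runs,
                    lambda_r=float(runs["wilks_lambda"].mean()),
                    accuracy_r=float(runs["accuracy_pct"].mean()),
                    runs=runs)
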
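"""Genotype classification with repeated cross-validated AUC.

Per training partition: features are ranked by orientation-folded
univariate AUC, admitted greedily subject to a |Pearson r| < 0.7 bound
against already-admitted features (top-10 kept), z-standardized on
training statistics, and fed to an unpenalized logistic regression.
Held-out AUC is collected over stratified 5-fold CV repeated 10 times;
the summary interval is the 95% normal-theory interval of the mean over
all fold AUCs.

Feature selection and standardization use the training partition only —
no information from the held-out fold leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features.names import FEATURE_NAMES


class ClassifierError(ValueError):
    pass


@dataclass
class CVResult:
    """Repeated-CV summary for one (roi_kind, setting) cell."""

    mean_auc: float
    interval: tuple[float, float]
    fold_aucs: list[float]
    selection_counts: dict[str, int]
    setting: tuple = ()

    @property
    def n_partitions(self) -> int:
        return len(self.fold_aucs)


def univariate_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of one feature, ties counted half.

    Returns the raw orientation: P(value_pos > value_neg) + 0.5 * ties.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("both classes must be present")
    ranks = rankdata(values)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def folded_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Orientation-folded AUC, max(auc, 1 - auc); used for ranking only."""
    a = univariate_auc(values, labels)
    return max(a, 1.0 - a)


def select_features(train_table: pd.DataFrame, labels: np.ndarray,
                    k_top: int = 10, r_threshold: float = 0.7) -> list[str]:
    """Greedy top-k univariate-AUC selection with Pearson pruning.

    Candidates are ranked by folded AUC (descending, ties broken by name
    ascending); a candidate is admitted only if |Pearson r| < r_threshold
    against every already-admitted feature.  Constant features (undefined
    correlation) are skipped.
    """
    feats = [c for c in train_table.columns if c in set(FEATURE_NAMES)]
    if not feats:
        raise ClassifierError("no canonical feature columns in table")
    labels = np.asarray(labels).astype(int)
    scored = []
    for name in feats:
        v = train_table[name].to_numpy(float)
        if np.std(v) == 0:
            continue
        scored.append((-folded_auc(v, labels), name))
    scored.sort()

    kept: list[str] = []
    for _, name in scored:
        if len(kept) >= k_top:
            break
        v = train_table[name].to_numpy(float)
        admissible = True
        for other in kept:
            r = np.corrcoef(v, train_table[other].to_numpy(float))[0, 1]
            if not np.isfinite(r) or abs(r) >= r_threshold:
                admissible = False
                break
        if admissible:
            kept.append(name)
    return kept


def _fit_score(train_x, train_y, test_x, test_y) -> float:
    mu = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd[sd == 0] = 1.0
    # C=inf -> maximum-likelihood fit with no penalty
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    model.fit((train_x - mu) / sd, train_y)
    scores = model.decision_function((test_x - mu) / sd)
    return float(roc_auc_score(test_y, scores))


def repeated_cv_auc(table: pd.DataFrame, labels: np.ndarray,
                    folds: int = 5, repeats: int = 10, seed: int = 0,
                    k_top: int = 10, r_threshold: float = 0.7) -> CVResult:
    """Stratified k-fold CV repeated ``repeats`` times; fully seeded."""
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ClassifierError(
            f"need >= {folds} subjects per class, have {counts.tolist()}"
        )
    feats = [c for c in table.columns if c in set(FEATURE_NAMES)]
    X = table[feats]
    rng_seeds = np.random.SeedSequence([int(seed)]).generate_state(repeats)
    fold_aucs: list[float] = []
    selection_counts: dict[str, int] = {f: 0 for f in feats}
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng_seeds[r] % (2**31)))
        for train_idx, test_idx in skf.split(X, labels):
            train = X.iloc[train_idx]
            chosen = select_features(train, labels[train_idx],
                                     k_top=k_top, r_threshold=r_threshold)
            if not chosen:
                raise ClassifierError("no admissible features selected")
            for f in chosen:
                selection_counts[f] += 1
            auc = _fit_score(
                train[chosen].to_numpy(float), labels[train_idx],
                X.iloc[test_idx][chosen].to_numpy(float), labels[test_idx],
            )
            fold_aucs.append(auc)
    arr = np.asarray(fold_aucs)
    mean = float(arr.mean())
    half = 1.96 * float(arr.std(ddof=1)) / np.sqrt(arr.size) if arr.size > 1 else 0.0
    return CVResult(
        mean_auc=mean,
        interval=(mean - half, mean + half),
        fold_aucs=[float(a) for a in fold_aucs],
        selection_counts={f: c for f, c in selection_counts.items() if c > 0},
    )


def auc_grid(cohort_tables: dict[tuple, tuple[pd.DataFrame, np.ndarray]],
             folds: int = 5, repeats: int = 10, seed: int = 0
             ) -> dict[tuple, CVResult]:
    """Repeated-CV AUC for every (roi_kind, normalization, resampling,
    n_gray_levels) cell.  ``cohort_tables`` maps each cell key to a
    (feature table, labels) pair; a missing cell raises with its name."""
    results: dict[tuple, CVResult] = {}
    for key in sorted(cohort_tables):
        table, labels = cohort_tables[key]
        if table is None or len(table) == 0:
            raise ClassifierError(f"missing or empty cell {key}")
        res = repeated_cv_auc(table, labels, folds=folds, repeats=repeats,
                              seed=seed)
        res.setting = key
        results[key] = res
    return results


def grid_to_frame(results: dict[tuple, CVResult]) -> pd.DataFrame:
    """Tables-shaped long CSV: one row per grid cell."""
    rows = []
    for key, res in results.items():
        roi_kind, norm, resamp, nb = key
        rows.append({
            "roi_kind": roi_kind,
            "normalization": norm,
            "resampling": resamp,
            "n_gray_levels": nb,
            "mean_auc": res.mean_auc,
            "ci_low": res.interval[0],
            "ci_high": res.interval[1],
            "n_partitions": res.n_partitions,
        })
    return pd.DataFrame(rows).sort_values(
        ["roi_kind", "normalization", "resampling", "n_gray_levels"]
    ).reset_index(drop=True)
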
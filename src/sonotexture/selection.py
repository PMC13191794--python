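"""Feature selection: min–max scaling, correlation pruning, forest ranking.

The selector reduces the radiomic feature table in a fixed order —
normalize, prune correlated pairs (|r| > 0.9), rank by randomized-tree
permutation importance under repeated cross-validation, keep the top 15.
The composition is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .types import OUTCOME_COL

logger = logging.getLogger("sonotexture")

__all__ = [
    "minmax_normalize",
    "prune_correlated",
    "rank_importance",
    "select_top",
    "select_features",
]


def minmax_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale every feature column to [0, 1]; constant columns go to 0.

    Returns the scaled table and the list of constant (flagged) columns.
    The outcome column, if present, is passed through untouched.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 subjects")
    out = table.copy()
    flagged: list[str] = []
    for col in table.columns:
        if col == OUTCOME_COL:
            continue
        x = table[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            out[col] = 0.0
            flagged.append(col)
        else:
            out[col] = (x - lo) / (hi - lo)
    return out, flagged


def prune_correlated(
    table: pd.DataFrame, threshold: float = 0.9, method: str = "pearson"
) -> tuple[list[str], list[str]]:
    """Greedy elimination of highly correlated feature pairs.

    While any pair exceeds |r| > threshold, the member with the larger
    mean absolute correlation to all remaining features is dropped
    (lexicographic tie-break).  Returns (kept, dropped), both sorted.
    """
    feats = [c for c in table.columns if c != OUTCOME_COL]
    sub = table[feats].astype(float)
    if sub.isna().any().any():
        raise ValueError("correlation pruning requires complete data")
    corr = sub.corr(method=method).abs()
    np.fill_diagonal(corr.values, 0.0)
    kept = sorted(feats)
    corr = corr.loc[kept, kept]
    dropped: list[str] = []
    while True:
        m = corr.loc[kept, kept]
        peak = m.to_numpy().max() if kept else 0.0
        if peak <= threshold or np.isnan(peak):
            break
        # candidates: members of any offending pair
        offenders = sorted({c for c in kept if (m[c] > threshold).any()})
        mean_abs = m.loc[offenders, kept].mean(axis=1)
        worst = mean_abs.max()
        victim = sorted(mean_abs.index[mean_abs >= worst - 1e-15])[0]
        kept.remove(victim)
        dropped.append(victim)
    return kept, sorted(dropped)


def rank_importance(
    table: pd.DataFrame,
    outcome: str = OUTCOME_COL,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    n_estimators: int = 500,
) -> pd.DataFrame:
    """Permutation-importance ranking under repeated K-fold resampling.

    Within each of ``folds × repeats`` resamples a random forest
    regressor (bootstrap trees, feature subsetting ⌈p/3⌉ at splits) is
    trained on the training part; the importance of a feature is the
    mean increase in held-out squared error when that feature's column
    is permuted.  Scores are averaged over resamples and sorted
    descending (ties broken by name).  Deterministic given ``seed``.
    """
    feats = [c for c in table.columns if c != outcome]
    y = table[outcome].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("outcome must be strictly positive")
    X = table[feats].to_numpy(dtype=float)
    n = len(table)
    if folds > n:
        raise ValueError("more folds than subjects")

    rng = np.random.default_rng(seed)
    cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=int(rng.integers(2**31)))
    scores = np.zeros(len(feats))
    p = len(feats)
    max_features = max(int(np.ceil(p / 3)), 1)
    for split_idx, (tr, te) in enumerate(cv.split(X)):
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max_features,
            bootstrap=True,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(X[tr], y[tr])
        perm = rng.permutation(len(te))
        # one batched predict: original held-out block + p permuted copies
        stacked = np.tile(X[te], (p + 1, 1))
        m = len(te)
        for j in range(p):
            stacked[(j + 1) * m : (j + 2) * m, j] = X[te][perm, j]
        preds = forest.predict(stacked).reshape(p + 1, m)
        errs = np.mean((preds - y[te]) ** 2, axis=1)
        scores += errs[1:] - errs[0]
    scores /= cv.get_n_splits()
    out = pd.DataFrame({"feature": feats, "score": scores})
    out = out.sort_values(["score", "feature"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def select_top(ranked: pd.DataFrame, k: int = 15) -> list[str]:
    """First ``k`` features of a ranking (ties already broken by name)."""
    if k > len(ranked):
        raise ValueError("k exceeds the number of ranked features")
    return ranked["feature"].head(k).tolist()


def select_features(
    table: pd.DataFrame,
    k: int = 15,
    threshold: float = 0.9,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    n_estimators: int = 500,
) -> tuple[pd.DataFrame, dict]:
    """Full selector: normalize → prune → rank → top-k.

    Returns the reduced table (selected features + outcome) and a report
    dict (flagged constants, dropped correlated features, ranking).
    """
    n_missing = int(table.isna().any(axis=1).sum())
    if n_missing:
        logger.info("dropping %d subjects with missing features", n_missing)
        table = table.dropna()
    normed, flagged = minmax_normalize(table)
    normed = normed.drop(columns=flagged)
    kept, dropped = prune_correlated(normed, threshold=threshold)
    ranked = rank_importance(
        normed[kept + [OUTCOME_COL]],
        folds=folds,
        repeats=repeats,
        seed=seed,
        n_estimators=n_estimators,
    )
    top = select_top(ranked, k=min(k, len(ranked)))
    report = {
        "constant_features": flagged,
        "dropped_correlated": dropped,
        "ranking": ranked,
        "selected": top,
        "seed": seed,
        "n_dropped_subjects": n_missing,
    }
    return normed[top + [OUTCOME_COL]], report
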
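"""Random-forest estimation of transcription speed without half-life data.

Half-life measurements need a dedicated time-course experiment; a forest
trained on cheaper observables (codon-usage indices, positional GC, gene
length, mRNA level, RNAP density and their ratio) can stand in for the
model when half-lives are unavailable, at matched growth conditions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ArgumentError, DataError

log = logging.getLogger(__name__)

SEQUENCE_FEATURES = ["cai", "tai", "gc1", "gc3", "length"]
MEASUREMENT_FEATURES = ["z_mrna", "d_p", "mrna_rnap_ratio"]
FEATURES = SEQUENCE_FEATURES + MEASUREMENT_FEATURES


def build_features(
    speed_table: pd.DataFrame,
    measurements: pd.DataFrame | None = None,
    codon_feats: pd.DataFrame | None = None,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inner-join the model inputs into the forest's feature matrix.

    Expected sources: ``speed_table`` supplies the target ``v``, gene
    length, mRNA level ``n_r`` and RNAP density ``d_p``; ``codon_feats``
    supplies gc1/gc3; ``external`` supplies cai/tai. The mRNA level is
    z-scored over the included genes (the other features are left on
    their natural scales); the ratio feature is n_r/d_p. Rows with any
    missing feature are dropped and counted in the log.
    """
    df = speed_table[["gene", "length", "n_r", "d_p", "v"]].copy()
    if measurements is not None:
        extra = measurements[["gene"] + [c for c in ("n_r", "d_p") if c not in df.columns]]
        df = df.merge(extra, on="gene", how="inner")
    for other, cols in ((codon_feats, ["gc1", "gc3"]), (external, ["cai", "tai"])):
        if other is None:
            continue
        o = other.reset_index() if "gene" not in other.columns else other
        df = df.merge(o[["gene"] + cols], on="gene", how="inner")
    for col in ("cai", "tai", "gc1", "gc3"):
        if col not in df.columns:
            raise DataError(f"feature column {col!r} missing; supply codon/external tables")
    before = len(df)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["mrna_rnap_ratio"] = np.where(df["d_p"] > 0, df["n_r"] / df["d_p"], np.nan)
    df = df.replace([np.inf, -np.inf], np.nan).dropna()
    if df.empty:
        raise DataError("empty join: no gene has all features")
    dropped = before - len(df)
    if dropped:
        log.info("dropped %d genes with missing features", dropped)
    mu, sd = df["n_r"].mean(), df["n_r"].std(ddof=0)
    df["z_mrna"] = (df["n_r"] - mu) / (sd if sd > 0 else 1.0)
    out = df.rename(columns={"v": "target"})
    return out[["gene"] + FEATURES + ["target"]].reset_index(drop=True)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels from a seeded shuffle stratified on target quartiles."""
    quart = pd.qcut(y, 4, labels=False, duplicates="drop")
    folds = np.empty(len(y), dtype=int)
    for q in np.unique(quart):
        idx = np.flatnonzero(quart == q)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cv_train(features: pd.DataFrame, k: int = 5, seed: int = 0) -> dict:
    """k-fold cross-validated forest with pooled-error reporting.

    The forest uses the library's default hyperparameters (logged for the
    record). Reports the mean over folds of out-of-fold R^2 (``r2_mean``),
    the pooled relative root squared error
    RRSE = sqrt(sum((y-yhat)^2) / sum((y-ybar)^2)) over all out-of-fold
    predictions (1 = predicting the mean), and impurity-based variable
    importances averaged over folds.
    """
    n = len(features)
    if n < k * 5:
        raise ArgumentError(f"need >= {k * 5} rows for {k}-fold CV, got {n}")
    X = features[FEATURES].to_numpy(dtype=float)
    y = features["target"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    yhat = np.empty(n)
    r2s, imps = [], []
    params_logged = None
    for fold in range(k):
        test = folds == fold
        model = RandomForestRegressor(random_state=int(rng.integers(2**31)))
        if params_logged is None:
            params_logged = model.get_params()
            log.info("random forest parameters: %s", params_logged)
        model.fit(X[~test], y[~test])
        pred = model.predict(X[test])
        yhat[test] = pred
        sst = np.sum((y[test] - y[test].mean()) ** 2)
        r2s.append(1.0 - np.sum((y[test] - pred) ** 2) / sst)
        imps.append(model.feature_importances_)
    rrse = float(np.sqrt(np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)))
    importance = pd.Series(np.mean(imps, axis=0), index=FEATURES).sort_values(ascending=False)
    return {
        "r2_mean": float(np.mean(r2s)),
        "r2_folds": [float(r) for r in r2s],
        "rrse": rrse,
        "importance": importance,
        "predictions": pd.DataFrame({"gene": features["gene"], "y": y, "yhat": yhat}),
        "params": params_logged,
    }
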
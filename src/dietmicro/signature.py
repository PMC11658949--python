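"""Microbiome profile signatures for dietary patterns via elastic net.

The dietary index is regressed on CLR-transformed genus abundances in a
random 70/30 train/test split with 10-fold cross-validated elastic net.
The profile score of a participant is the weighted sum of the selected
genera's standardized CLR values, weights equal to the elastic-net
coefficients.  Test-set participants are scored by the model fit on the full
training set; training-set participants are scored leave-one-out at the tuned
hyperparameters so their scores are also out-of-sample.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV

logger = logging.getLogger(__name__)

L1_RATIO_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


def split_train_test(ids, train_fraction: float, seed: int) -> tuple[list, list]:
    """Uniformly random participant-level partition, |train| = round(f * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train fraction must be in (0, 1), got {train_fraction}")
    ids = sorted(ids)
    n = len(ids)
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty train or test set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


@dataclass
class ElasticNetProfile:
    """A fitted dietary-pattern microbiome signature.

    ``coef`` holds the coefficients on the standardized-CLR scale for every
    training genus; ``selected`` is the nonzero subset.  Feature means/SDs are
    the training-set standardization constants and travel with the profile so
    scoring new samples is reproducible.
    """

    index_name: str
    coef: pd.Series
    intercept: float
    alpha: float
    l1_ratio: float
    feature_means: pd.Series
    feature_sds: pd.Series
    train_ids: list = field(default_factory=list)
    seed: int = 0

    @property
    def selected(self) -> pd.Series:
        return self.coef[self.coef != 0.0]

    def train_ids_hash(self) -> str:
        joined = ",".join(str(i) for i in self.train_ids)
        return hashlib.sha256(joined.encode()).hexdigest()[:16]

    def save(self, stem: str | Path) -> None:
        """Write <stem>.tsv (genus, coefficient; nonzero only) and <stem>.json."""
        stem = Path(stem)
        self.selected.rename("coefficient").rename_axis("genus").reset_index().to_csv(
            stem.with_suffix(".tsv"), sep="\t", index=False
        )
        sidecar = {
            "index_name": self.index_name,
            "intercept": self.intercept,
            "alpha": self.alpha,
            "l1_ratio": self.l1_ratio,
            "seed": self.seed,
            "train_ids": [str(i) for i in self.train_ids],
            "train_ids_sha256_16": self.train_ids_hash(),
            "features": list(self.coef.index),
            "coef": [float(v) for v in self.coef],
            "feature_means": [float(v) for v in self.feature_means],
            "feature_sds": [float(v) for v in self.feature_sds],
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, stem: str | Path) -> "ElasticNetProfile":
        meta = json.loads(Path(stem).with_suffix(".json").read_text())
        features = meta["features"]
        return cls(
            index_name=meta["index_name"],
            coef=pd.Series(meta["coef"], index=features),
            intercept=float(meta["intercept"]),
            alpha=float(meta["alpha"]),
            l1_ratio=float(meta["l1_ratio"]),
            feature_means=pd.Series(meta["feature_means"], index=features),
            feature_sds=pd.Series(meta["feature_sds"], index=features),
            train_ids=meta["train_ids"],
            seed=int(meta["seed"]),
        )


def _standardize(X: pd.DataFrame, means: pd.Series | None = None, sds: pd.Series | None = None):
    if means is None:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        sds = sds.where(sds > 0, 1.0)  # constant columns contribute nothing
    Z = (X - means) / sds
    return Z, means, sds


def _cv_folds(index, n_folds: int, seed: int, pair_ids: pd.Series | None = None):
    """Random fold assignment; with pair ids, co-twins share a fold."""
    rng = np.random.default_rng(seed)
    n = len(index)
    if pair_ids is not None:
        pairs = pd.Series(pair_ids).reindex(index)
        groups = pairs.fillna(pd.Series([f"solo_{i}" for i in range(n)], index=index))
        unique = sorted(set(groups))
        order = rng.permutation(len(unique))
        fold_of_group = {g: order[i] % n_folds for i, g in enumerate(sorted(unique))}
        fold = np.array([fold_of_group[g] for g in groups])
    else:
        fold = rng.permutation(n) % n_folds
    splits = []
    idx = np.arange(n)
    for f in range(n_folds):
        test = idx[fold == f]
        train = idx[fold != f]
        if len(test) == 0:
            continue
        splits.append((train, test))
    return splits


def fit_profile(
    X: pd.DataFrame,
    y: pd.Series,
    index_name: str = "index",
    n_folds: int = 10,
    seed: int = 0,
    l1_ratios=L1_RATIO_GRID,
    pair_ids: pd.Series | None = None,
    selection_rule: str = "1se",
) -> ElasticNetProfile:
    """Tune an elastic net by K-fold cross-validation and refit on the full
    training set.

    ``X`` is the training CLR table indexed by participant id, ``y`` the
    dietary score aligned to it.  The penalty strength and the L1/L2 mixing
    parameter are tuned jointly over ``l1_ratios``; predictors are
    standardized internally with training-set statistics and coefficients are
    reported on that standardized scale.  When ``pair_ids`` is given, co-twins
    are kept in the same CV fold to avoid within-pair leakage.

    ``selection_rule`` picks the penalty on the CV curve: ``"min"`` takes the
    minimum mean squared error; ``"1se"`` (default) takes the strongest
    penalty within one standard error of that minimum, the usual glmnet rule,
    which keeps the selected genus set near-empty when the dietary score
    carries no microbiome signal.
    """
    if selection_rule not in {"min", "1se"}:
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    if len(X) < n_folds:
        raise ValueError(f"{len(X)} training participants < {n_folds} folds")
    X = X.sort_index()
    y = y.reindex(X.index)
    if y.isna().any():
        raise ValueError("dietary score missing for some training participants")
    Z, means, sds = _standardize(X)
    splits = _cv_folds(X.index, n_folds, seed, pair_ids)
    model = ElasticNetCV(
        l1_ratio=list(l1_ratios),
        cv=splits,
        alphas=100,  # size of the automatic penalty path
        max_iter=20_000,
        tol=1e-6,
    )
    model.fit(Z.to_numpy(), y.to_numpy())

    mse = model.mse_path_  # (n_l1_ratios, n_alphas, n_folds)
    mean_mse = mse.mean(axis=2)
    i, j = np.unravel_index(np.argmin(mean_mse), mean_mse.shape)
    l1_ratio = list(l1_ratios)[i]
    alphas_i = np.atleast_2d(model.alphas_)[i]
    if selection_rule == "1se":
        se = mse[i].std(axis=1, ddof=1) / np.sqrt(mse.shape[2])
        threshold = mean_mse[i, j] + se[j]
        j = int(np.flatnonzero(mean_mse[i] <= threshold).min())  # alphas descend: first = strongest
    alpha = float(alphas_i[j])
    net = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=20_000, tol=1e-6)
    net.fit(Z.to_numpy(), y.to_numpy())
    coef = pd.Series(net.coef_, index=X.columns)
    profile = ElasticNetProfile(
        index_name=index_name,
        coef=coef,
        intercept=float(net.intercept_),
        alpha=alpha,
        l1_ratio=float(l1_ratio),
        feature_means=means,
        feature_sds=sds,
        train_ids=list(X.index),
        seed=seed,
    )
    logger.info(
        "fit_profile[%s]: %d/%d genera selected (alpha=%.5g, l1_ratio=%.1f)",
        index_name, int((coef != 0).sum()), len(coef), profile.alpha, profile.l1_ratio,
    )
    return profile


def score_samples(profile: ElasticNetProfile, X: pd.DataFrame) -> pd.Series:
    """Intercept-free weighted sum over selected genera.

    New samples are standardized with the profile's training means/SDs; a
    missing genus column is an error.
    """
    missing = [c for c in profile.coef.index if c not in X.columns]
    if missing:
        raise ValueError(f"test table missing genus columns: {missing[:10]}")
    Xa = X[list(profile.coef.index)]
    Z = (Xa - profile.feature_means) / profile.feature_sds
    return pd.Series(Z.to_numpy() @ profile.coef.to_numpy(), index=X.index, name=f"{profile.index_name}_mb_score")


def loo_training_scores(X: pd.DataFrame, y: pd.Series, profile: ElasticNetProfile) -> pd.Series:
    """Leave-one-out profile scores for the training set.

    For each training participant the elastic net is refit at the tuned
    (alpha, l1_ratio) on the remaining n-1 participants — with standardization
    constants recomputed from those n-1 — and the held-out participant is
    scored by the intercept-free weighted sum.
    """
    X = X.sort_index()
    y = y.reindex(X.index)
    scores = np.empty(len(X))
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    mask = np.ones(len(X), dtype=bool)
    for i in range(len(X)):
        mask[i] = False
        Xi, yi = Xv[mask], yv[mask]
        mu = Xi.mean(axis=0)
        sd = Xi.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        net = ElasticNet(alpha=profile.alpha, l1_ratio=profile.l1_ratio, max_iter=20_000, tol=1e-6)
        net.fit((Xi - mu) / sd, yi)
        scores[i] = ((Xv[i] - mu) / sd) @ net.coef_
        mask[i] = True
    return pd.Series(scores, index=X.index, name=f"{profile.index_name}_mb_score")


def correlate_components(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix for aligned columns.

    Meant for the plot-ready matrix relating profile scores, dietary scores,
    single genera and dietary food components.  Constant columns produce
    missing correlations and are logged.
    """
    constant = [c for c in columns.columns if columns[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("correlate_components: constant columns give missing correlations: %s", constant)
    rho = columns.corr(method="spearman")
    for c in constant:
        rho.loc[c, :] = np.nan
        rho.loc[:, c] = np.nan
    return rho
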
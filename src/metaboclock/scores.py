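"""Sparse metabolomic scores by cross-validated elastic net.

A score is a sparse linear predictor of a continuous outcome (chronologic
age in years, or the FEV1/FVC ratio) from log2 metabolite levels, with no
clinical covariates.  Model selection follows the classic glmnet-style
protocol: for each mixing parameter alpha on a 0..1 grid (step 0.05),
10-fold cross-validation traces mean squared error along a geometric
lambda path; within each alpha the penalty is chosen by the
one-standard-error rule (the largest lambda whose CV MSE is within one
standard error of that alpha's minimum); across alphas the grid point with
the smallest CV MSE at its 1-SE lambda wins, and the model is refit on all
training data there.

The coordinate-descent solver is scikit-learn's; the penalty
parametrization matches glmnet's ``lambda * (alpha*|b|_1 +
(1-alpha)/2*|b|_2^2)`` with the loss scaled by 1/(2n), so lambdas are
comparable across sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path

from .io import MetaboliteMatrix

# coordinate descent is unreliable at l1_ratio exactly 0; glmnet itself
# recommends a small positive mixing value to emulate ridge
_MIN_L1_RATIO = 1e-3


@dataclass(frozen=True)
class ElasticNetConfig:
    """Settings for :func:`fit_score_cv`.

    alpha_grid
        L1/L2 mixing values; default 0.00-1.00 in steps of 0.05.
    n_folds
        Cross-validation folds (default 10).
    n_lambda, lambda_min_ratio
        Geometric lambda path length and its floor relative to the
        smallest lambda that zeroes every coefficient.
    seed
        Governs the fold assignment (shared across the whole alpha grid).
    """

    alpha_grid: tuple = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    n_folds: int = 10
    seed: int = 0
    standardize: bool = True
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    max_iter: int = 5000
    tol: float = 1e-4

    def __post_init__(self):
        g = np.asarray(self.alpha_grid, dtype=float)
        if g.size == 0 or g.min() < 0 or g.max() > 1:
            raise ValueError("alpha grid must lie within [0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class ScoreModel:
    """A fitted sparse linear score.

    ``coefficients`` are on the standardized-predictor scale;
    ``raw_coefficients`` fold the training sds back in (units: outcome per
    log2 unit).  Prediction is ``intercept + sum(coef * (x - mean)/sd)``
    over the selected metabolites.
    """

    outcome: str
    metabolite_ids: list[str]
    coefficients: np.ndarray          # standardized scale, one per selected id
    intercept: float
    alpha: float
    lam: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    cv_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.metabolite_ids)

    @property
    def raw_coefficients(self) -> np.ndarray:
        return self.coefficients / self.feature_sds

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "metabolite_ids": list(self.metabolite_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
            "lam": float(self.lam),
            "feature_means": [float(m) for m in self.feature_means],
            "feature_sds": [float(s) for s in self.feature_sds],
            "provenance": dict(self.provenance),
        }
        if self.cv_table is not None:
            d["cv_table"] = self.cv_table.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        cv = pd.DataFrame(d["cv_table"]) if "cv_table" in d else None
        return cls(
            outcome=d["outcome"],
            metabolite_ids=list(d["metabolite_ids"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
            lam=float(d["lam"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            cv_table=cv,
            provenance=dict(d.get("provenance", {})),
        )


@dataclass(frozen=True)
class ScoreEvaluation:
    pearson_r: float
    rmse: float
    n: int


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, MetaboliteMatrix):
        return X.data
    return pd.DataFrame(X)


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded random permutation cut into near-equal folds."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(perm, n_folds)):
        folds[idx] = f
    return folds


def _lambda_path(Xs: np.ndarray, yc: np.ndarray, l1_ratio: float,
                 n_lambda: int, min_ratio: float) -> np.ndarray:
    n = Xs.shape[0]
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * max(l1_ratio, _MIN_L1_RATIO))
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def fit_score_cv(X, y, cfg: ElasticNetConfig | None = None,
                 outcome: str = "age") -> ScoreModel:
    """Train a sparse score with the grid-of-alphas / lambda-1SE protocol.

    ``X`` is a complete (imputed, log2) :class:`MetaboliteMatrix` or
    DataFrame; ``y`` the outcome aligned to its samples.  The same seeded
    fold assignment is reused for every alpha so CV errors are comparable
    across the grid.
    """
    cfg = cfg or ElasticNetConfig()
    frame = _as_frame(X)
    Xv = frame.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if Xv.shape[0] != yv.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    if np.isnan(Xv).any():
        raise ValueError("X must be complete (impute first)")
    if not np.all(np.isfinite(yv)):
        raise ValueError("y must be finite")
    if np.ptp(yv) == 0:
        raise ValueError("outcome is constant; nothing to fit")
    n, p = Xv.shape
    if n < cfg.n_folds:
        raise ValueError("fewer samples than folds")

    folds = _fold_assignment(n, cfg.n_folds, cfg.seed)
    if np.bincount(folds, minlength=cfg.n_folds).min() < 2:
        raise ValueError("degenerate folds (a fold has < 2 samples)")

    # path anchored on the full training data, standardized
    mu_full = Xv.mean(axis=0)
    sd_full = Xv.std(axis=0, ddof=0)
    if cfg.standardize:
        sd_safe = np.where(sd_full > 0, sd_full, 1.0)
    else:
        mu_full = np.zeros(p)
        sd_safe = np.ones(p)
    Xs_full = (Xv - mu_full) / sd_safe
    y_mean = yv.mean()
    yc_full = yv - y_mean

    rows = []
    best = None  # (cv_mse_at_1se, alpha, lambda, se)
    for alpha in cfg.alpha_grid:
        l1 = max(float(alpha), _MIN_L1_RATIO)
        path = _lambda_path(Xs_full, yc_full, float(alpha),
                            cfg.n_lambda, cfg.lambda_min_ratio)
        fold_mse = np.empty((cfg.n_folds, cfg.n_lambda))
        for f in range(cfg.n_folds):
            tr, te = folds != f, folds == f
            mu = Xv[tr].mean(axis=0)
            sd = Xv[tr].std(axis=0, ddof=0) if cfg.standardize else np.ones(p)
            sd = np.where(sd > 0, sd, 1.0)
            mu = mu if cfg.standardize else np.zeros(p)
            ym = yv[tr].mean()
            _, coefs, _ = enet_path(
                (Xv[tr] - mu) / sd, yv[tr] - ym, l1_ratio=l1, alphas=path,
                max_iter=cfg.max_iter, tol=cfg.tol,
            )
            pred = ((Xv[te] - mu) / sd) @ coefs + ym
            fold_mse[f] = ((pred - yv[te, None]) ** 2).mean(axis=0)
        mean_mse = fold_mse.mean(axis=0)
        se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(cfg.n_folds)
        i_min = int(np.argmin(mean_mse))
        # path is in decreasing lambda order: first index within one SE of
        # the minimum is the largest admissible lambda
        within = np.nonzero(mean_mse <= mean_mse[i_min] + se_mse[i_min])[0]
        i_1se = int(within[0])
        rows.append(pd.DataFrame({
            "alpha": float(alpha), "lam": path, "mean_mse": mean_mse,
            "se_mse": se_mse,
            "is_1se": [i == i_1se for i in range(cfg.n_lambda)],
            "is_min": [i == i_min for i in range(cfg.n_lambda)],
        }))
        cand = (float(mean_mse[i_1se]), float(alpha), float(path[i_1se]))
        if best is None or cand[0] < best[0]:
            best = cand
    cv_table = pd.concat(rows, ignore_index=True)
    _, best_alpha, best_lam = best

    # refit on all training data at the winning grid point
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = ElasticNet(
            alpha=best_lam, l1_ratio=max(best_alpha, _MIN_L1_RATIO),
            fit_intercept=False, max_iter=cfg.max_iter * 4, tol=cfg.tol,
        ).fit(Xs_full, yc_full)
    coef = final.coef_
    sel = np.nonzero(coef != 0.0)[0]
    return ScoreModel(
        outcome=outcome,
        metabolite_ids=[str(frame.columns[j]) for j in sel],
        coefficients=coef[sel].copy(),
        intercept=float(y_mean),
        alpha=best_alpha,
        lam=best_lam,
        feature_means=mu_full[sel].copy(),
        feature_sds=sd_safe[sel].copy(),
        cv_table=cv_table,
        provenance={
            "seed": int(cfg.seed), "n_folds": int(cfg.n_folds),
            "n_train": int(n), "n_features": int(p),
            "standardize": bool(cfg.standardize),
        },
    )


def predict_score(model: ScoreModel, X) -> pd.Series:
    """Apply a fitted score: intercept + sum of standardized contributions.

    Every selected metabolite must be present in ``X`` — absence is an
    error, never a silent zero-fill.
    """
    frame = _as_frame(X)
    missing = [m for m in model.metabolite_ids if m not in frame.columns]
    if missing:
        raise KeyError(f"matrix lacks selected metabolites: {missing}")
    if model.n_selected == 0:
        return pd.Series(np.full(len(frame), model.intercept), index=frame.index,
                         name=model.outcome)
    Z = frame.loc[:, model.metabolite_ids].to_numpy(dtype=float)
    Zs = (Z - model.feature_means) / model.feature_sds
    pred = model.intercept + Zs @ model.coefficients
    return pd.Series(pred, index=frame.index, name=model.outcome)


def evaluate_score(pred, actual) -> ScoreEvaluation:
    """Pearson correlation and RMSE between predicted and actual outcomes."""
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("prediction/actual length mismatch")
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(p) == 0 or np.ptp(a) == 0:
        raise ValueError("zero variance in predictions or outcomes")
    r = stats.pearsonr(p, a).statistic
    rmse = float(np.sqrt(np.mean((p - a) ** 2)))
    return ScoreEvaluation(pearson_r=float(r), rmse=rmse, n=int(p.size))
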
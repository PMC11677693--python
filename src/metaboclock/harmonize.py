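"""Cross-cohort preprocessing: batch-median normalization, missingness
classification and filtering, metabolite-neighbor kNN imputation, log2.

The stage order is fixed — normalize, filter, impute, log2 — because the
median scaling must see raw intensities, imputation operates on the
normalized (pre-log) scale, and the log transform requires a complete,
strictly positive matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MetaboliteMatrix

log = logging.getLogger(__name__)

#: missingness classes
RETAINED = "retained"
DISCREPANT = "discrepant"
SEVERE = "severe"
BOTH_MODERATE = "both_moderate"


@dataclass(frozen=True)
class HarmonizationConfig:
    """Thresholds for the preprocessing stages.

    max_missing
        A metabolite is retained only if its missing fraction is <= this in
        every cohort (default 0.20).
    severe_missing
        Missing fraction at or above this in either cohort marks the
        metabolite "severe" (default 0.80).
    knn_k
        Number of metabolite neighbors averaged per imputed cell.
    min_coobserved
        Minimum co-observed samples for a neighbor distance to be valid.
    """

    max_missing: float = 0.20
    severe_missing: float = 0.80
    knn_k: int = 10
    log_base: int = 2
    min_coobserved: int = 3

    def __post_init__(self):
        if not (0.0 < self.max_missing < self.severe_missing <= 1.0):
            raise ValueError("require 0 < max_missing < severe_missing <= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.log_base != 2:
            raise ValueError("only log base 2 is supported")


def batch_median_normalize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each metabolite by its within-batch observed median.

    Post-condition: within every batch each metabolite's observed median is
    exactly 1; missing cells stay missing.  Scale-invariant per batch, and
    idempotent.
    """
    if matrix.scale != "intensity":
        raise ValueError("normalization expects raw intensity scale")
    out = matrix.data.copy()
    for _, idx in out.groupby(matrix.batch, sort=False).groups.items():
        block = out.loc[idx]
        med = block.median(axis=0, skipna=True)
        # positivity of intensities guarantees observed medians > 0
        assert not (med <= 0).any(), "observed batch median must be positive"
        out.loc[idx] = block / med
    return MetaboliteMatrix(out, matrix.batch.copy(), matrix.cohort.copy())


def classify_missingness(
    m_a: MetaboliteMatrix, m_b: MetaboliteMatrix,
    cfg: HarmonizationConfig | None = None,
) -> pd.DataFrame:
    """Classify each shared metabolite by its per-cohort missing fractions.

    Classes partition the shared namespace:

    - ``retained``: fraction <= max_missing in both cohorts (only these
      proceed to imputation);
    - ``severe``: fraction >= severe_missing in either cohort;
    - ``discrepant``: <= max_missing in one cohort but in
      (max_missing, severe_missing) in the other;
    - ``both_moderate``: the remainder (moderate in both).

    Returns a frame indexed by metabolite with columns ``frac_a``,
    ``frac_b``, ``missing_class``.
    """
    cfg = cfg or HarmonizationConfig()
    shared = [m for m in m_a.metabolite_ids if m in set(m_b.metabolite_ids)]
    if not shared:
        raise ValueError("cohorts share no metabolites")
    fa = m_a.missing_fraction().loc[shared]
    fb = m_b.missing_fraction().loc[shared]
    lo_a, lo_b = fa <= cfg.max_missing, fb <= cfg.max_missing
    hi = (fa >= cfg.severe_missing) | (fb >= cfg.severe_missing)
    cls = pd.Series(BOTH_MODERATE, index=pd.Index(shared, name="metabolite_id"))
    cls[lo_a & lo_b] = RETAINED
    cls[~(lo_a & lo_b) & ~hi & (lo_a | lo_b)] = DISCREPANT
    cls[hi] = SEVERE
    return pd.DataFrame(
        {"frac_a": fa.to_numpy(), "frac_b": fb.to_numpy(), "missing_class": cls}
    )


def _neighbor_distances(values: np.ndarray, min_coobserved: int) -> np.ndarray:
    """Metabolite x metabolite mean-squared-difference distance matrix.

    values is samples x metabolites with NaN for missing.  Distance between
    two metabolites is the mean over co-observed samples of the squared
    difference of their values; pairs with fewer than ``min_coobserved``
    shared samples (and the diagonal) get +inf.
    """
    X = values.T  # metabolites x samples
    obs = ~np.isnan(X)
    Z = np.where(obs, X, 0.0)
    counts = obs.astype(float) @ obs.T
    zsq = Z * Z
    ss = zsq @ obs.T + obs @ zsq.T - 2.0 * (Z @ Z.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = ss / counts
    dist[counts < min_coobserved] = np.inf
    np.fill_diagonal(dist, np.inf)
    return dist


def knn_impute(
    matrix: MetaboliteMatrix, k: int = 10, min_coobserved: int = 3
) -> MetaboliteMatrix:
    """Impute missing cells from the k nearest metabolites.

    Neighbors are metabolites, ranked by mean squared difference over
    co-observed samples (ties broken by metabolite id).  For each missing
    cell the imputed value is the mean of the first ``k`` eligible
    neighbors that are observed in that sample.  A metabolite with no
    eligible observed neighbor in a sample falls back to its own observed
    median, with a logged warning.  Observed cells are never altered;
    complete matrices come back unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    data = matrix.data
    vals = data.to_numpy(copy=True)
    nan_rows, nan_cols = np.nonzero(np.isnan(vals))
    if nan_rows.size == 0:
        return matrix.copy()
    if data.isna().all(axis=0).any():
        bad = data.columns[data.isna().all(axis=0)].tolist()
        raise ValueError(f"metabolites with zero observed values: {bad}")

    dist = _neighbor_distances(vals, min_coobserved)
    n_met = vals.shape[1]
    # lexicographic tie-break: argsort on (distance, column-id rank)
    id_rank = np.argsort(np.argsort(data.columns.to_numpy().astype(str)))
    order = np.lexsort((np.broadcast_to(id_rank, (n_met, n_met)), dist), axis=1)

    med = np.nanmedian(vals, axis=0)
    obs = ~np.isnan(vals)
    out = vals.copy()
    n_fallback = 0
    for j in np.unique(nan_cols):
        neigh = order[j]
        neigh = neigh[np.isfinite(dist[j, neigh])]
        rows = nan_rows[nan_cols == j]
        for i in rows:
            donors = neigh[obs[i, neigh]][:k]
            if donors.size:
                out[i, j] = vals[i, donors].mean()
            else:
                out[i, j] = med[j]
                n_fallback += 1
    if n_fallback:
        log.warning("kNN imputation fell back to metabolite median for %d cells",
                    n_fallback)
    return MetaboliteMatrix(
        pd.DataFrame(out, index=data.index, columns=data.columns),
        matrix.batch.copy(), matrix.cohort.copy(), scale=matrix.scale,
    )


def log2_transform(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Elementwise log2 of a complete, strictly positive matrix."""
    vals = matrix.data.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("matrix must be complete before log transform")
    if (vals <= 0).any():
        raise ValueError("nonpositive value in matrix; cannot take log2")
    return MetaboliteMatrix(
        np.log2(matrix.data), matrix.batch.copy(), matrix.cohort.copy(), scale="log2"
    )


def harmonize(
    m_a: MetaboliteMatrix, m_b: MetaboliteMatrix,
    cfg: HarmonizationConfig | None = None,
) -> tuple[MetaboliteMatrix, MetaboliteMatrix, pd.DataFrame]:
    """Run the full preprocessing pipeline on a cohort pair.

    Order is fixed: per-batch median normalization in each cohort, joint
    missingness classification (only ``retained`` metabolites proceed),
    kNN imputation per cohort, log2 transform.  Returns the processed
    matrices (complete, log2 scale, restricted to retained metabolites)
    and the missingness report.
    """
    cfg = cfg or HarmonizationConfig()
    norm_a = batch_median_normalize(m_a)
    norm_b = batch_median_normalize(m_b)
    report = classify_missingness(norm_a, norm_b, cfg)
    keep = report.index[report["missing_class"] == RETAINED].tolist()
    if not keep:
        raise ValueError("no metabolites pass the missingness filter")
    imp_a = knn_impute(norm_a.select_metabolites(keep), cfg.knn_k, cfg.min_coobserved)
    imp_b = knn_impute(norm_b.select_metabolites(keep), cfg.knn_k, cfg.min_coobserved)
    return log2_transform(imp_a), log2_transform(imp_b), report


def write_missingness_report(report: pd.DataFrame, path) -> None:
    out = report.copy()
    out[["frac_a", "frac_b"]] = out[["frac_a", "frac_b"]].round(4)
    out.to_csv(path, sep="\t")
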
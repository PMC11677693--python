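"""Univariate metabolite-phenotype associations, score-overlap testing and
pathway overrepresentation.

Associations are simple per-metabolite ordinary least squares of the
phenotype on the log2 metabolite level, with no covariates.  Signed
-log10 p values (sign of the slope times -log10 p) support the
concordance-quadrant view of age vs obstruction effects.  Overlap between
two selected-metabolite sets is tested on the 2x2 membership table
(chi-squared, with a one-sided hypergeometric tail alongside), and
pathway overrepresentation uses the one-sided hypergeometric (Fisher)
tail with Benjamini-Hochberg adjustment within each annotation level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MetaboliteMatrix, PathwayAnnotation

#: floor applied to p-values before taking log10 (keeps plots finite)
P_FLOOR = 1e-300

CONCORDANT = "concordant"
DISCORDANT = "discordant"
AGE_ONLY = "age_only"
OBSTRUCTION_ONLY = "obstruction_only"
NEITHER = "neither"


def univariate_assoc(matrix, phenotype, phenotype_name: str = "age") -> pd.DataFrame:
    """Per-metabolite OLS of phenotype on log2 metabolite level.

    Returns a frame indexed by metabolite with ``slope`` (phenotype units
    per log2 unit), ``p`` (two-sided), and ``signed_logp`` =
    sign(slope) * -log10(p).  Constant metabolites are flagged
    (``constant`` column) with slope 0 and p = NaN rather than dropped.
    """
    frame = matrix.data if isinstance(matrix, MetaboliteMatrix) else pd.DataFrame(matrix)
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != frame.shape[0]:
        raise ValueError("phenotype length does not match sample count")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    xm = X - X.mean(axis=0)
    ym = y - y.mean()
    sxx = (xm ** 2).sum(axis=0)
    syy = float((ym ** 2).sum())
    sxy = xm.T @ ym
    const = sxx == 0
    slope = np.zeros(X.shape[1])
    pvals = np.full(X.shape[1], np.nan)
    ok = ~const
    slope[ok] = sxy[ok] / sxx[ok]
    df = n - 2
    if df <= 0:
        raise ValueError("need at least 3 samples for per-metabolite OLS")
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ok & (syy > 0), sxy ** 2 / np.where(ok, sxx, 1.0) / max(syy, P_FLOOR), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        tstat = np.sqrt(df * r2 / np.maximum(1.0 - r2, 1e-16))
    pvals[ok] = 2.0 * stats.t.sf(tstat[ok], df)
    signed = np.sign(slope) * -np.log10(np.maximum(pvals, P_FLOOR))
    return pd.DataFrame(
        {
            "phenotype": phenotype_name,
            "slope": slope,
            "p": pvals,
            "signed_logp": signed,
            "constant": const,
        },
        index=pd.Index(frame.columns, name="metabolite_id"),
    )


def concordance_quadrants(
    records_age: pd.DataFrame,
    records_obstruction: pd.DataFrame,
    alpha: float = 0.05,
    obstruction_sign_flip: bool = True,
) -> pd.Series:
    """Classify metabolites by joint age/obstruction association pattern.

    A metabolite significant on both axes is ``concordant`` when its age
    slope and its *obstruction-severity* direction agree.  Because the
    obstruction phenotype is the FEV1/FVC ratio (lower = worse), the
    default orientation flips the ratio slope's sign before comparing;
    set ``obstruction_sign_flip=False`` to compare raw slopes.
    """
    if not records_age.index.equals(records_obstruction.index):
        raise ValueError("metabolite sets differ between the two association tables")
    sig_a = records_age["p"] < alpha
    sig_o = records_obstruction["p"] < alpha
    s_a = np.sign(records_age["slope"])
    s_o = np.sign(records_obstruction["slope"])
    if obstruction_sign_flip:
        s_o = -s_o
    cls = pd.Series(NEITHER, index=records_age.index, name="quadrant")
    cls[sig_a & ~sig_o] = AGE_ONLY
    cls[~sig_a & sig_o] = OBSTRUCTION_ONLY
    both = sig_a & sig_o
    cls[both & (s_a == s_o)] = CONCORDANT
    cls[both & (s_a != s_o)] = DISCORDANT
    return cls


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    n_universe: int
    observed_overlap: int
    expected_overlap: float
    chi2_statistic: float
    chi2_p: float
    hypergeom_p: float  # one-sided enrichment tail P(X >= observed)


def set_overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Test whether two metabolite sets overlap more than chance.

    Builds the 2x2 in/out membership table over the universe and applies
    the uncorrected chi-squared test; the one-sided hypergeometric tail is
    reported alongside.  Empty input sets give p = 1 with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    k = len(a & b)
    expected = len(a) * len(b) / n
    if not a or not b:
        warnings.warn("empty metabolite set; overlap test is vacuous", stacklevel=2)
        return OverlapResult(len(a), len(b), n, k, expected, 0.0, 1.0, 1.0)
    table = np.array([
        [k, len(a) - k],
        [len(b) - k, n - len(a) - len(b) + k],
    ])
    if table.min() < 0:
        raise ValueError("inconsistent set sizes")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    hg = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    return OverlapResult(len(a), len(b), n, k, float(expected),
                         float(chi2), float(p), hg)


def pathway_ora(
    selected,
    annotation: PathwayAnnotation,
    level: str = "sub",
    universe=None,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Pathway overrepresentation by the hypergeometric (Fisher) tail.

    The universe is the annotated, filter-passing metabolites (unannotated
    ones cannot contribute to any pathway and are excluded up front; pass
    ``universe`` to restrict to the metabolites that survived
    harmonization).  For each pathway at ``level`` ("sub" or "super") the
    2x2 selected x in-pathway table yields a sample odds ratio and a
    one-sided enrichment p (two-sided optional); p-values are BH-adjusted
    within the level and rows come back sorted by p.
    """
    if level not in ("sub", "super"):
        raise ValueError("level must be 'sub' or 'super'")
    members = annotation.pathways(level)
    if universe is None:
        universe = set(annotation.metabolite_ids)
    else:
        universe = set(universe)
    annotated = {m for m in universe if annotation.is_annotated(m)}
    sel = set(selected) & annotated
    rows = []
    for pw, mets in sorted(members.items()):
        in_universe = mets & annotated
        if not in_universe:
            continue  # pathway absent from this universe
        n_univ = len(annotated)
        n_path = len(in_universe)
        n_sel = len(sel)
        k = len(sel & in_universe)
        table = [[k, n_sel - k], [n_path - k, n_univ - n_path - n_sel + k]]
        alternative = "two-sided" if two_sided else "greater"
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append({
            "pathway": pw, "level": level,
            "n_pathway": n_path, "n_selected": n_sel,
            "overlap": k, "n_universe": n_univ,
            "odds_ratio": float(odds), "p": float(p),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
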
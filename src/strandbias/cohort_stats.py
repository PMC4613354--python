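"""Cohort-level statistics for the strand-bias feature table.

Every genome contributes one feature row (score, size, GC content,
leading-strand gene density, gcRF/taRF, pCOG vector, SCOG/WCOG fractions,
repair-pathway fractions, optional codon-bias S value and generation time,
phylum and obligate-intracellular metadata). This module computes:

* Spearman rank correlations of every numeric feature against the
  composition-bias score, pairwise-complete, with the asymptotic two-sided
  p (t approximation, n-2 df). Two significance conventions are annotated
  rather than corrected for: p < 0.05 overall and p < 1e-8 for the COG
  subcategory screen.
* A two-sample t-test (Welch by default) comparing obligate-intracellular
  genomes against the rest.
* Per-phylum summaries (n, mean/sd/variance of the score, means of the
  other headline features); singleton phyla report sd and variance as NA.
* Principal component regression (PCR): features are z-standardized,
  principal components extracted from their correlation structure with
  unit-norm loadings, and the regression R^2 of the score on the (all
  retained, mutually orthogonal) components is attributed back to the
  original features via squared loadings:

      R2_m = corr(component_m, score)^2
      contribution(feature f) = sum_m loading_fm^2 * R2_m

  Because the loading matrix is orthonormal the contributions sum exactly
  to the total regression R^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

logger = logging.getLogger(__name__)

P_OVERALL_DEFAULT = 0.05
P_COG_DEFAULT = 1.0e-8

#: FeatureRow columns, in canonical output order.
CORE_FEATURES = (
    "genome_size",
    "gc_content",
    "gene_density_leading",
    "gcRF",
    "taRF",
    "scog_fraction",
    "wcog_fraction",
)
OPTIONAL_FEATURES = ("s_value", "generation_time")


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    rho: float
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class GroupTestResult:
    mean_group1: float
    mean_group2: float
    t_statistic: float
    p_value: float
    n1: int
    n2: int


@dataclass(frozen=True)
class PCRResult:
    features: tuple
    contributions: tuple
    total_r2: float

    def as_dict(self) -> dict:
        return dict(zip(self.features, self.contributions))


def spearman(x, y) -> CorrelationResult:
    """Spearman rho with average ranks for ties; asymptotic two-sided p.

    Pairs with a missing value in either vector are removed first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise UndefinedStatisticError(f"Spearman needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("Spearman undefined: zero variance in an input vector")
        return CorrelationResult("", math.nan, math.nan, n)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult("", float(rho), float(p), n)


def group_t_test(
    scores_group1, scores_group2, equal_var: bool = False
) -> GroupTestResult:
    """Two-sided two-sample t-test; Welch (unequal variances) by default."""
    g1 = np.asarray(scores_group1, dtype=float)
    g2 = np.asarray(scores_group2, dtype=float)
    g1, g2 = g1[~np.isnan(g1)], g2[~np.isnan(g2)]
    if g1.size < 2 or g2.size < 2:
        raise UndefinedStatisticError("t-test needs >= 2 members per group")
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return GroupTestResult(
        mean_group1=float(g1.mean()),
        mean_group2=float(g2.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n1=int(g1.size),
        n2=int(g2.size),
    )


_SUMMARY_MEAN_COLS = (
    "genome_size",
    "gc_content",
    "gene_density_leading",
    "gcRF",
    "taRF",
)


def phylum_summaries(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-phylum n, score mean/sd/variance and headline feature means.

    Output is sorted alphabetically by phylum; phyla with a single member
    report sd and variance as NA.
    """
    if rows["phylum"].isna().any():
        raise ValueError("every row must carry a phylum label")
    out = []
    for phylum, grp in rows.groupby("phylum", sort=True):
        n = len(grp)
        rec = {
            "phylum": phylum,
            "n": n,
            "score_mean": grp["score"].mean(),
            "score_sd": grp["score"].std(ddof=1) if n > 1 else math.nan,
            "score_variance": grp["score"].var(ddof=1) if n > 1 else math.nan,
        }
        for col in _SUMMARY_MEAN_COLS:
            if col in grp:
                rec[f"{col}_mean"] = grp[col].mean()
        out.append(rec)
    return pd.DataFrame(out)


def _align_degenerate_blocks(
    eigvals: np.ndarray, loadings: np.ndarray, rtol: float = 1e-8
) -> np.ndarray:
    """Make the PCA basis deterministic under (near-)degenerate eigenvalues.

    Within a block of numerically equal eigenvalues any orthonormal basis
    of the eigenspace is a valid set of components; LAPACK returns an
    arbitrary rotation. We pick the maximally feature-aligned basis:
    project the feature axes with the largest presence in the eigenspace
    onto it and orthonormalize. For an identity correlation matrix the
    components then coincide with the features themselves, which is the
    natural convention for attributing R^2. Non-degenerate eigenvectors
    are only sign-normalized.
    """
    k = eigvals.size
    scale = max(abs(eigvals[0]), 1.0)
    out = loadings.copy()
    start = 0
    while start < k:
        end = start + 1
        while end < k and abs(eigvals[end] - eigvals[start]) <= rtol * scale:
            end += 1
        block = out[:, start:end]
        if end - start > 1:
            projector = block @ block.T
            weights = np.diag(projector)
            axes = np.sort(np.argsort(weights)[::-1][: end - start])
            q, _ = np.linalg.qr(projector[:, axes])
            block = q[:, : end - start]
        # sign convention: largest-magnitude loading positive
        for j in range(block.shape[1]):
            lead = np.argmax(np.abs(block[:, j]))
            if block[lead, j] < 0:
                block[:, j] = -block[:, j]
        out[:, start:end] = block
        start = end
    return out


def pcr_decomposition(features: pd.DataFrame, y) -> PCRResult:
    """Attribute the regression R^2 of y on the features back per feature.

    Rows with any missing value are dropped (logged). Features are
    z-standardized; components come from the eigendecomposition of the
    feature correlation matrix (unit-norm loadings); components with
    near-zero variance are dropped (rank deficiency, logged). All retained
    components enter the decomposition.
    """
    if features.shape[1] < 2:
        raise ValueError("PCR needs at least 2 features")
    y = np.asarray(y, dtype=float)
    X = features.to_numpy(dtype=float)
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("PCR: dropped %d rows with missing values", dropped)
    X, y = X[keep], y[keep]
    n, k = X.shape
    if n <= k:
        raise UndefinedStatisticError(f"PCR needs n > k (got n={n}, k={k})")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [features.columns[i] for i in np.flatnonzero(sd == 0)]
        raise UndefinedStatisticError(f"constant feature(s) in PCR input: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigvals, loadings = np.linalg.eigh(corr)  # columns are unit-norm loadings
    order = np.argsort(eigvals)[::-1]
    eigvals, loadings = eigvals[order], loadings[:, order]
    loadings = _align_degenerate_blocks(eigvals, loadings)
    keep_comp = eigvals > 1e-10 * eigvals[0]
    if not keep_comp.all():
        logger.info(
            "PCR: dropped %d zero-variance components (rank-deficient input)",
            int((~keep_comp).sum()),
        )
    eigvals, loadings = eigvals[keep_comp], loadings[:, keep_comp]
    components = Z @ loadings
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise UndefinedStatisticError("PCR undefined: response has zero variance")
    r2_per_comp = np.empty(components.shape[1])
    for m in range(components.shape[1]):
        cm = components[:, m]
        r2_per_comp[m] = (cm @ yc) ** 2 / ((cm @ cm) * ss_y)
    contributions = (loadings**2) @ r2_per_comp
    return PCRResult(
        features=tuple(features.columns),
        contributions=tuple(float(c) for c in contributions),
        total_r2=float(r2_per_comp.sum()),
    )


def run_correlation_battery(
    rows: pd.DataFrame,
    p_overall: float = P_OVERALL_DEFAULT,
    p_cog: float = P_COG_DEFAULT,
) -> pd.DataFrame:
    """Spearman of the score against every numeric feature.

    Returns a table with rho, p, n and flags for the two significance
    conventions (``significant``: p < p_overall; ``significant_strict``:
    p < p_cog, the convention used for the COG subcategory screen).
    Constant or unusable features appear as NA rows.
    """
    if len(rows) < 3:
        raise UndefinedStatisticError("correlation battery needs >= 3 rows")
    feature_cols = [
        c
        for c in rows.columns
        if c not in ("genome_id", "score", "phylum", "obligate_intracellular")
        and pd.api.types.is_numeric_dtype(rows[c])
    ]
    y = rows["score"].to_numpy(dtype=float)
    out = []
    for col in feature_cols:
        x = rows[col].to_numpy(dtype=float)
        try:
            res = spearman(x, y)
            rho, p, n = res.rho, res.p_value, res.n_pairs
        except UndefinedStatisticError as exc:
            logger.warning("feature %s: %s", col, exc)
            rho, p, n = math.nan, math.nan, int((~np.isnan(x)).sum())
        out.append(
            {
                "feature": col,
                "rho": rho,
                "p_value": p,
                "n_pairs": n,
                "significant": bool(p < p_overall) if not math.isnan(p) else False,
                "significant_strict": bool(p < p_cog) if not math.isnan(p) else False,
            }
        )
    return pd.DataFrame(out)
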
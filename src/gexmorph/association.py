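"""Gene-wise spatial correlation between regional expression and GMV change.

Each gene's regional expression profile is compared with a regional summary
of the group-difference t map using Spearman's rank correlation (robust to
expression outliers). P values come from the Student-t approximation

    t = rho * sqrt((n - 2) / (1 - rho^2)),  df = n - 2,

with an exact-permutation option for very small n. Multiple testing over
the gene universe is handled with the Benjamini-Hochberg step-up FDR, and
the empirical 2.5th / 97.5th percentiles of the rho distribution provide
reference cutoffs for "extreme" genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._validate import ValidationError, require
from .expression import RegionExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------

@dataclass
class RegionalDifferenceMap:
    """Region -> scalar summary of the group-difference t statistics."""

    values: pd.Series
    mode: str                      # "absolute" or "signed"
    contrast: str = "group"

    def validate(self) -> "RegionalDifferenceMap":
        require(self.mode in ("absolute", "signed"),
                f"mode must be 'absolute' or 'signed', got {self.mode!r}")
        require(bool(np.isfinite(self.values.to_numpy(float)).all()),
                "difference map contains non-finite values")
        return self


def summarize_tmap(tmap: pd.Series | dict, mode: str = "absolute",
                   contrast: str = "group") -> RegionalDifferenceMap:
    """Summarize t statistics per region: mean |t| (absolute) or mean t.

    ``tmap`` is either a region-level Series (one t per region, voxel
    averaging already done or not needed) or a mapping region -> array of
    voxel t values.
    """
    if isinstance(tmap, pd.Series):
        items = {r: np.atleast_1d(v) for r, v in tmap.items()}
    else:
        items = {r: np.atleast_1d(np.asarray(v, float))
                 for r, v in tmap.items()}
    out = {}
    for region, values in items.items():
        if values.size == 0:
            raise ValidationError(f"region {region!r} has no t values")
        out[region] = (np.mean(np.abs(values)) if mode == "absolute"
                       else np.mean(values))
    series = pd.Series(out, name=f"{mode}_t")
    return RegionalDifferenceMap(values=series, mode=mode,
                                 contrast=contrast).validate()


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_rho(x, y, *, method: str = "auto",
                 exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with a two-sided p value.

    Rho is the Pearson correlation of midranks (average ranks on ties).
    ``method='t-approx'`` uses the Student-t reference; ``'exact'``
    enumerates all permutations (only sensible for tiny n);
    ``'auto'`` switches to the exact test when n <= ``exact_max_n``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    require(x.shape == y.shape and x.ndim == 1, "x and y must be equal-length vectors")
    n = len(x)
    require(n >= 3, f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input: Spearman rho undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "exact" or (method == "auto" and n <= exact_max_n):
        rxc = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
        ryc = ry - ry.mean()
        ryn = np.sqrt(np.sum(ryc ** 2))
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(rxc @ ryc[list(perm)]) / ryn
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    return rho, _t_pvalue(np.array([rho]), n)[0]


def _t_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation; |rho| = 1 maps to p = 0."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(tval), n - 2)
    return np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values).

    q_(i) = min_{j >= i} ( p_(j) * n / j ), capped at 1, in input order.
    """
    p = np.asarray(pvals, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# gene-wise screen
# ---------------------------------------------------------------------------

class SpearmanScreen(BaseEstimator):
    """Rank-correlation screen of many genes against one regional map.

    ``fit(X, y)`` takes a gene x region matrix and a region-indexed summary
    Series with identical region sets. Genes with zero expression variance
    (rho undefined) are excluded and recorded.

    Attributes (after ``fit``)
    ----------
    rho_, p_, q_ : Series indexed by gene.
    excluded_ : list of genes with undefined rho.
    association_ : tidy DataFrame (gene, rho, p, q, rank).
    """

    def __init__(self, alternative: str = "two-sided"):
        self.alternative = alternative

    def fit(self, X: pd.DataFrame | RegionExpressionMatrix, y: pd.Series):
        if isinstance(X, RegionExpressionMatrix):
            X = X.values
        require(self.alternative in ("two-sided", "greater", "less"),
                f"unknown alternative {self.alternative!r}")
        xr = set(X.columns)
        yr = set(y.index)
        if xr != yr:
            raise ValidationError(
                "region mismatch between expression and difference map: "
                f"only-expression={sorted(xr - yr)[:5]}, "
                f"only-map={sorted(yr - xr)[:5]}")
        X = X[list(y.index)]
        n = X.shape[1]
        require(n >= 3, f"need >= 3 shared regions, got {n}")

        values = X.to_numpy(float)
        keep = np.ptp(values, axis=1) > 0
        excluded = list(X.index[~keep])
        if excluded:
            logger.info("excluding %d constant-expression genes", len(excluded))
        values = values[keep]

        ranks = stats.rankdata(values, axis=1)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((ranks ** 2).sum(axis=1))
        ry = stats.rankdata(y.to_numpy(float))
        ryc = ry - ry.mean()
        ryn = np.sqrt((ryc ** 2).sum())
        require(ryn > 0, "difference map is constant: rho undefined")
        rho = (ranks @ ryc) / (norms * ryn)

        p = _t_pvalue(rho, n)
        if self.alternative != "two-sided":
            one = p / 2.0
            sign_ok = rho > 0 if self.alternative == "greater" else rho < 0
            p = np.where(sign_ok, one, 1.0 - one)
        q = bh_fdr(p)

        genes = X.index[keep]
        self.n_regions_ = n
        self.rho_ = pd.Series(rho, index=genes, name="rho")
        self.p_ = pd.Series(p, index=genes, name="p")
        self.q_ = pd.Series(q, index=genes, name="q")
        self.excluded_ = excluded
        assoc = pd.DataFrame({"rho": self.rho_, "p": self.p_, "q": self.q_})
        assoc["rank"] = assoc["rho"].rank(ascending=False, method="first"
                                          ).astype(int)
        assoc.index.name = "gene"
        self.association_ = assoc
        return self


def gene_correlations(expr: RegionExpressionMatrix | pd.DataFrame,
                      diff: RegionalDifferenceMap | pd.Series) -> pd.DataFrame:
    """Per-gene (rho, p, q) table for one expression matrix and one map."""
    y = diff.values if isinstance(diff, RegionalDifferenceMap) else diff
    return SpearmanScreen().fit(expr, y).association_


def percentile_thresholds(rho_values, lower: float = 2.5,
                          upper: float = 97.5) -> dict:
    """Empirical percentile cutoffs of the gene-wise rho distribution."""
    rho = np.asarray(rho_values, float)
    require(rho.size >= 40,
            f"need >= 40 rho values for stable percentiles, got {rho.size}")
    lo, hi = np.percentile(rho, [lower, upper])
    return {
        "lower_percentile": lower,
        "upper_percentile": upper,
        "rho_lo": float(lo),
        "rho_hi": float(hi),
        "frac_below": float(np.mean(rho < lo)),
        "frac_above": float(np.mean(rho > hi)),
    }
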
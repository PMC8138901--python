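"""Longitudinal group-difference GLM with cluster-robust (sandwich) variance.

The marginal model is fit scan-wise by ordinary least squares; dependence
between a subject's repeated scans is handled purely through the variance
estimate, which aggregates residual outer products over subject blocks:

    V = (X'X)^-1 ( sum_s X_s' e_s e_s' X_s ) (X'X)^-1

with ``e_s`` the residual vector of subject ``s``. Contrast t statistics use
t = c'b / sqrt(c'Vc) referred to a Student t with df = n_subjects - rank(X),
a conservative cluster-count rule.

The design has ten columns: intercept, group indicator (case = 1), centered
age, centered age^2, group x age, sex, IQ, brain size, socioeconomic status,
and coded stuttering severity. All covariates except severity are grand-mean
centered; severity is zero for controls and mean-centered within the case
group only, so it absorbs severity-related variation without shifting the
group contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._validate import RankDeficiencyError, ValidationError, require

GROUPS = ("control", "persistent", "recovered")

DESIGN_COLUMNS = [
    "intercept", "group", "age", "age2", "group_x_age",
    "sex", "iq", "brain_size", "ses", "severity",
]

COVARIATE_COLUMNS = ["sex", "iq", "brain_size", "ses"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalDataset:
    """Per-scan covariates plus a regional gray-matter-volume response matrix.

    ``scans`` is indexed by scan id with columns ``subject_id``, ``group``
    (control / persistent / recovered), ``age`` (years), ``sex`` (0/1),
    ``iq``, ``brain_size``, ``ses`` and ``severity`` (stuttering-severity
    score; NaN for controls). ``responses`` is scan x region, arbitrary
    volume units, aligned row-for-row with ``scans``.
    """

    scans: pd.DataFrame
    responses: pd.DataFrame
    regions: list[str]

    def validate(self) -> "LongitudinalDataset":
        require(self.responses.index.equals(self.scans.index),
                "response rows do not match the scan table")
        require(list(self.responses.columns) == list(self.regions),
                "response columns do not match the region list")
        require(bool(np.isfinite(self.responses.to_numpy(float)).all()),
                "responses contain non-finite values")
        unknown = set(self.scans["group"]) - set(GROUPS)
        require(not unknown, f"unknown group labels: {sorted(unknown)}")
        ctrl = self.scans["group"] == "control"
        bad = self.scans.index[ctrl & self.scans["severity"].notna()]
        require(len(bad) == 0,
                f"control scans carry a severity score: {list(bad)[:5]}")
        bad = self.scans.index[~ctrl & self.scans["severity"].isna()]
        require(len(bad) == 0,
                f"stuttering-group scans missing severity: {list(bad)[:5]}")
        require((self.scans.groupby("subject_id").size() >= 1).all(),
                "every subject needs at least one scan")
        return self

    def subset(self, mask: pd.Series) -> "LongitudinalDataset":
        return LongitudinalDataset(
            scans=self.scans.loc[mask].copy(),
            responses=self.responses.loc[mask].copy(),
            regions=list(self.regions),
        )

    def subset_groups(self, groups: tuple[str, ...]) -> "LongitudinalDataset":
        return self.subset(self.scans["group"].isin(groups))

    @property
    def n_subjects(self) -> int:
        return self.scans["subject_id"].nunique()


@dataclass
class DesignMatrix:
    """Scan-level design with subject cluster ids and named contrasts."""

    X: pd.DataFrame                       # scans x DESIGN_COLUMNS
    clusters: pd.Series                   # scan id -> subject id
    contrasts: dict[str, np.ndarray]
    rank: int
    case_group: str
    control_group: str


@dataclass
class GLMResult:
    beta: pd.DataFrame                    # coefficients x regions
    cov: np.ndarray                       # regions x p x p sandwich covariance
    t: dict[str, pd.Series]               # contrast name -> t per region
    p: dict[str, pd.Series]
    residuals: pd.DataFrame
    df: int
    n_subjects: int
    n_scans: int
    flagged_regions: list[str] = field(default_factory=list)

    def contrast_se(self, name: str) -> pd.Series:
        c = self._contrasts[name]
        se = np.sqrt(np.einsum("i,rij,j->r", c, self.cov, c))
        return pd.Series(se, index=self.beta.columns, name="se")

    _contrasts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(dataset: LongitudinalDataset, *,
                 case_group: str = "persistent",
                 control_group: str = "control",
                 drop_covariates: tuple[str, ...] = ()) -> DesignMatrix:
    """Assemble the ten-column longitudinal design for one case/control pair.

    Age is centered at the grand mean over the included scans *before*
    squaring and interacting; the squared term and the other covariates
    (except severity) are then grand-mean centered as well, so the group
    coefficient reads as the adjusted case-control difference at mean age.

    ``drop_covariates`` removes nuisance columns that are constant in a
    subset analysis (e.g. ``("sex",)`` for a male-only fit).
    """
    data = dataset.subset_groups((case_group, control_group))
    scans = data.scans
    for grp in (case_group, control_group):
        n = scans.loc[scans["group"] == grp, "subject_id"].nunique()
        require(n >= 2, f"need >= 2 subjects in group {grp!r}, found {n}")

    missing = scans[COVARIATE_COLUMNS + ["age"]].isna().any(axis=1)
    if missing.any():
        raise ValidationError(
            "missing covariate values for scans: "
            f"{list(scans.index[missing])[:10]}")

    g = (scans["group"] == case_group).astype(float)
    a = scans["age"].astype(float) - scans["age"].astype(float).mean()
    a2 = a ** 2
    a2 = a2 - a2.mean()

    sev = scans["severity"].astype(float).copy()
    case_rows = g == 1.0
    sev.loc[~case_rows] = 0.0
    sev.loc[case_rows] = sev.loc[case_rows] - sev.loc[case_rows].mean()

    X = pd.DataFrame({
        "intercept": 1.0,
        "group": g,
        "age": a,
        "age2": a2,
        "group_x_age": g * a,
        "sex": scans["sex"].astype(float) - scans["sex"].astype(float).mean(),
        "iq": scans["iq"].astype(float) - scans["iq"].astype(float).mean(),
        "brain_size": (scans["brain_size"].astype(float)
                       - scans["brain_size"].astype(float).mean()),
        "ses": scans["ses"].astype(float) - scans["ses"].astype(float).mean(),
        "severity": sev,
    }, index=scans.index)[DESIGN_COLUMNS]

    droppable = set(COVARIATE_COLUMNS) | {"severity"}
    bad_drop = set(drop_covariates) - droppable
    require(not bad_drop, f"cannot drop non-nuisance columns: {sorted(bad_drop)}")
    columns = [c for c in DESIGN_COLUMNS if c not in set(drop_covariates)]
    X = X[columns]

    for col in columns[1:]:
        if np.allclose(X[col].to_numpy(), X[col].iloc[0]):
            raise RankDeficiencyError(f"design column {col!r} is constant")
    rank = int(np.linalg.matrix_rank(X.to_numpy()))
    if rank < X.shape[1]:
        # flagged here; fitting against a deficient design is refused in
        # fit_swe, but the matrix itself remains inspectable
        warnings.warn(f"design matrix is rank deficient "
                      f"(rank {rank} < {X.shape[1]} columns)")

    p = X.shape[1]
    contrasts = {
        "group": _unit(p, columns.index("group")),
        "group_x_age": _unit(p, columns.index("group_x_age")),
    }
    return DesignMatrix(X=X, clusters=scans["subject_id"], contrasts=contrasts,
                        rank=rank, case_group=case_group,
                        control_group=control_group)


def _unit(p: int, i: int) -> np.ndarray:
    c = np.zeros(p)
    c[i] = 1.0
    return c


# ---------------------------------------------------------------------------
# sandwich estimator
# ---------------------------------------------------------------------------

class SandwichGLM(BaseEstimator):
    """Marginal longitudinal GLM with subject-clustered sandwich covariance.

    Parameters
    ----------
    case_group, control_group : group labels entering the fit; all other
        scans are dropped. The group indicator codes ``case_group`` as 1,
        so positive contrast t means case > control.
    adjust : "none" (plain sandwich) or "cr1" (multiply the meat by the
        small-sample factor G/(G-1) * (N-1)/(N-p)).

    Attributes (after ``fit``)
    ----------
    design_ : DesignMatrix
    result_ : GLMResult
    coef_, t_, p_, df_ : convenience views of the group contrast.
    """

    def __init__(self, case_group: str = "persistent",
                 control_group: str = "control", adjust: str = "none",
                 drop_covariates: tuple[str, ...] = ()):
        self.case_group = case_group
        self.control_group = control_group
        self.adjust = adjust
        self.drop_covariates = drop_covariates

    def fit(self, X: LongitudinalDataset | DesignMatrix, y=None):
        if isinstance(X, LongitudinalDataset):
            X.validate()
            design = build_design(X, case_group=self.case_group,
                                  control_group=self.control_group,
                                  drop_covariates=tuple(self.drop_covariates))
            responses = X.subset_groups(
                (self.case_group, self.control_group)).responses
        else:
            design = X
            require(y is not None, "raw-design fit requires a response matrix")
            responses = y
        self.design_ = design
        self.result_ = fit_swe(design, responses, adjust=self.adjust)
        self.coef_ = self.result_.beta.loc["group"]
        self.t_ = self.result_.t["group"]
        self.p_ = self.result_.p["group"]
        self.df_ = self.result_.df
        return self

    def tmap(self, contrast: str = "group") -> pd.Series:
        return contrast_tmap(self.result_, contrast)


def fit_swe(design: DesignMatrix, responses: pd.DataFrame, *,
            adjust: str = "none") -> GLMResult:
    """Fit OLS per region and the subject-clustered sandwich covariance."""
    require(adjust in ("none", "cr1"), f"unknown adjustment {adjust!r}")
    if design.rank < design.X.shape[1]:
        raise RankDeficiencyError(
            f"cannot fit a rank-deficient design "
            f"(rank {design.rank} < {design.X.shape[1]} columns)")
    X = design.X.to_numpy(float)
    require(list(design.X.index) == list(responses.index),
            "design rows do not align with the response matrix")
    Y = responses.to_numpy(float)
    n, p = X.shape
    regions = list(responses.columns)
    n_regions = len(regions)

    XtX = X.T @ X
    try:
        A = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as err:
        raise RankDeficiencyError(f"singular X'X: {err}") from None
    B = A @ (X.T @ Y)                      # p x regions
    E = Y - X @ B                          # n x regions

    clusters = design.clusters.to_numpy()
    subject_ids = pd.unique(clusters)
    G = len(subject_ids)

    # meat = sum_s (X_s' e_s)(X_s' e_s)' per region, vectorized over regions
    H = np.zeros((G, p, n_regions))
    for si, s in enumerate(subject_ids):
        rows = clusters == s
        H[si] = X[rows].T @ E[rows]
    meat = np.einsum("gpr,gqr->rpq", H, H)
    if adjust == "cr1":
        meat *= (G / (G - 1)) * ((n - 1) / (n - p))
    cov = np.einsum("ij,rjk,kl->ril", A, meat, A)

    df = G - design.rank
    require(df > 0, f"nonpositive degrees of freedom ({G} subjects, rank "
                    f"{design.rank})")

    var0 = Y.var(axis=0)
    flagged = [regions[j] for j in np.flatnonzero(var0 == 0.0)]

    beta = pd.DataFrame(B, index=design.X.columns, columns=regions)
    tstats: dict[str, pd.Series] = {}
    pvals: dict[str, pd.Series] = {}
    for name, c in design.contrasts.items():
        denom = np.sqrt(np.einsum("i,rij,j->r", c, cov, c))
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = (c @ B) / denom
        tv = np.where(var0 == 0.0, np.nan, tv)
        pv = 2.0 * stats.t.sf(np.abs(tv), df)
        tstats[name] = pd.Series(tv, index=regions, name=f"t_{name}")
        pvals[name] = pd.Series(pv, index=regions, name=f"p_{name}")

    return GLMResult(
        beta=beta, cov=cov, t=tstats, p=pvals,
        residuals=pd.DataFrame(E, index=responses.index, columns=regions),
        df=df, n_subjects=G, n_scans=n, flagged_regions=flagged,
        _contrasts=dict(design.contrasts),
    )


def contrast_tmap(result: GLMResult, contrast: str = "group") -> pd.Series:
    """Ordered contrast-t vector over regions (zero-variance regions excluded).

    Sign convention: positive t means the case group exceeds controls.
    """
    if contrast not in result.t:
        raise ValidationError(
            f"unknown contrast {contrast!r}; available: {sorted(result.t)}")
    tmap = result.t[contrast].drop(index=result.flagged_regions)
    return tmap.rename("t")
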
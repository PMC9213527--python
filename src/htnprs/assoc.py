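"""Association and evaluation analytics for a standardized PRS.

Effect sizes are log odds ratios per 1 SD of the PRS from logistic models,
optionally with a sample-level random effect whose covariance is
proportional to the sparse kinship matrix (fitted by penalized
quasi-likelihood).  Predictive performance is the Mann-Whitney AUC computed
on unrelated individuals only.  Heterogeneity of stratum-specific effects is
tested with a generalized Cochran's Q that accepts a full covariance matrix
of the estimates; the covariance is taken from a single joint model with
PRS-by-stratum interactions, so relatedness across strata is reflected in
the off-diagonal terms when the kinship model is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from . import _glmm
from .genodata import KinshipGraph

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass
class AssociationEstimate:
    """Log-OR per 1 SD of PRS with Wald inference and optional AUC."""

    beta: float
    se: float
    pvalue: float
    n: int
    auc: float | None = None
    stratum: str = "all"
    sigma2: float = 0.0

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - Z975 * self.se)),
            float(np.exp(self.beta + Z975 * self.se)),
        )


def build_design(
    covars: pd.DataFrame | None,
    n: int,
    extra: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Assemble an intercept + covariate design matrix.

    String/categorical columns are dummy-coded (first level dropped);
    constant columns are removed with a log entry; rows with missing values
    are dropped listwise (count logged).  Returns (matrix, column names,
    boolean keep-mask over the n input rows).
    """
    parts = [pd.DataFrame({"intercept": np.ones(n)})]
    if extra:
        parts.append(pd.DataFrame(extra))
    if covars is not None and len(covars.columns):
        cov = covars.reset_index(drop=True)
        cat_cols = [c for c in cov.columns if cov[c].dtype == object or str(cov[c].dtype) == "category"]
        num = cov.drop(columns=cat_cols).astype(float)
        blocks = [num]
        if cat_cols:
            blocks.append(pd.get_dummies(cov[cat_cols].astype(str), drop_first=True, dtype=float))
        parts.append(pd.concat(blocks, axis=1))
    design = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)

    keep = ~design.isna().any(axis=1).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("build_design: dropped %d rows with missing covariates", n_drop)
    design = design.loc[keep]

    protected = {"intercept", *(extra or {})}
    constant = [c for c in design.columns if c not in protected and design[c].nunique() <= 1]
    if constant:
        logger.info("build_design: dropped degenerate columns %s", constant)
        design = design.drop(columns=constant)
    return design.to_numpy(dtype=float), list(design.columns), keep


def fit_logistic(
    outcome: np.ndarray,
    prs: np.ndarray,
    covars: pd.DataFrame | None = None,
    kinship: KinshipGraph | None = None,
    sample_ids: list[str] | None = None,
    variance_component: float | None = None,
    stratum: str = "all",
) -> AssociationEstimate:
    """Association of a standardized PRS with a binary outcome.

    Without ``kinship``: maximum-likelihood logistic regression
    (statsmodels GLM).  With ``kinship``: logistic model with a sample-level
    random effect, covariance ``sigma2 * K`` where K is the genetic
    relationship matrix implied by the kinship graph (2 x kinship
    coefficient off-diagonal, unit diagonal), fitted by PQL;
    ``variance_component`` fixes sigma2 instead of profiling it.
    Inference on the PRS coefficient is a Wald test.
    """
    outcome = np.asarray(outcome, dtype=float)
    prs = np.asarray(prs, dtype=float)
    n = len(outcome)
    X, names, keep = build_design(covars, n, extra={"prs": prs})
    y = outcome[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    j = names.index("prs")

    if kinship is None:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200, tol=1e-12)
        if np.abs(res.params).max() > 30:
            raise _glmm.SeparationError(
                "separation detected (diverging coefficients); consider penalized estimation"
            )
        beta, se = float(res.params[j]), float(res.bse[j])
        sigma2 = 0.0
    else:
        if sample_ids is None:
            raise ValueError("sample_ids are required for the kinship model")
        ids = [s for s, k in zip(sample_ids, keep) if k]
        K = _grm_matrix(kinship, ids)
        fit = _glmm.pql_kinship(X, y, K, sigma2=variance_component)
        beta, se = float(fit.beta[j]), float(fit.se[j])
        sigma2 = fit.sigma2

    z = beta / se
    pvalue = float(stats.chi2.sf(z * z, df=1))
    return AssociationEstimate(beta=beta, se=se, pvalue=pvalue, n=int(keep.sum()), stratum=stratum, sigma2=sigma2)


def _grm_matrix(kinship: KinshipGraph, sample_ids: list[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(sample_ids)}
    K = np.eye(len(sample_ids))
    for a, b, data in kinship.graph.edges(data=True):
        if a in idx and b in idx:
            K[idx[a], idx[b]] = K[idx[b], idx[a]] = 2.0 * data.get("kinship", 0.25)
    return K


def compute_auc(
    outcome: np.ndarray,
    score: np.ndarray,
    unrelated: set[str] | None = None,
    sample_ids: list[str] | None = None,
    kinship: KinshipGraph | None = None,
) -> float:
    """Mann-Whitney AUC of the score, on unrelated individuals only.

    Ties count one half.  If ``unrelated`` is given (with ``sample_ids``),
    the computation is restricted to that subset and, when ``kinship`` is
    also supplied, the subset is verified edge-free.
    """
    outcome = np.asarray(outcome, dtype=float)
    score = np.asarray(score, dtype=float)
    if unrelated is not None:
        if sample_ids is None:
            raise ValueError("sample_ids required when restricting to an unrelated subset")
        if kinship is not None and kinship.has_edge_within(unrelated):
            raise ValueError("unrelated subset contains a related pair")
        mask = np.array([s in unrelated for s in sample_ids])
        outcome, score = outcome[mask], score[mask]
    if len(np.unique(outcome)) < 2:
        raise ValueError("AUC undefined: one outcome class is empty")
    # rank-based Mann-Whitney U: tie ranks are dyadic halves, so the result
    # is bit-identical to the explicit pairwise computation
    ranks = stats.rankdata(score)
    n1 = int(outcome.sum())
    n0 = len(outcome) - n1
    u = ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def cochran_q(betas: np.ndarray, cov: np.ndarray) -> tuple[float, int, float]:
    """Generalized Cochran's Q for correlated stratum effects.

    Pools with GLS weights: beta_bar = (1' S^-1 1)^-1 1' S^-1 beta, then
    Q = (beta - beta_bar)' S^-1 (beta - beta_bar) on k - 1 df.  A diagonal
    covariance recovers the textbook fixed-effects Q.
    """
    betas = np.asarray(betas, dtype=float)
    cov = np.asarray(cov, dtype=float)
    k = len(betas)
    try:
        Si = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is singular") from exc
    one = np.ones(k)
    beta_bar = float(one @ Si @ betas / (one @ Si @ one))
    resid = betas - beta_bar
    q = float(resid @ Si @ resid)
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def stratum_effects_joint(
    outcome: np.ndarray,
    prs: np.ndarray,
    strata: np.ndarray,
    covars: pd.DataFrame | None = None,
    kinship: KinshipGraph | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Stratum-specific PRS effects from one joint interaction model.

    Fits a single logistic model with a separate PRS slope per stratum
    (plus stratum main effects and shared covariates); returns the stratum
    labels, the slope vector, and its covariance block from the joint
    information matrix — the input to :func:`cochran_q`.
    """
    outcome = np.asarray(outcome, dtype=float)
    prs = np.asarray(prs, dtype=float)
    strata = np.asarray(strata)
    labels = sorted(pd.unique(strata))
    extra = {f"prs:{lab}": prs * (strata == lab) for lab in labels}
    cov_in = covars.copy() if covars is not None else pd.DataFrame(index=range(len(outcome)))
    if len(labels) > 1:
        cov_in = cov_in.reset_index(drop=True)
        cov_in["_stratum"] = strata
    X, names, keep = build_design(cov_in, len(outcome), extra=extra)
    y = outcome[keep]
    idx = [names.index(f"prs:{lab}") for lab in labels]
    if kinship is None:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-12)
        beta_full, cov_full = np.asarray(res.params), np.asarray(res.cov_params())
    else:
        ids = [s for s, k in zip(sample_ids, keep) if k]
        fit = _glmm.pql_kinship(X, y, _grm_matrix(kinship, ids))
        beta_full, cov_full = fit.beta, fit.cov
    return [str(l) for l in labels], beta_full[idx], cov_full[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# decile analyses


def assign_deciles(prs: np.ndarray, seed: int = 0) -> np.ndarray:
    """Rank-based decile codes 1..10 with seeded tie-breaking."""
    prs = np.asarray(prs, dtype=float)
    n = len(prs)
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.random(n), prs))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 10) // n + 1


def decile_trend(
    prs: np.ndarray,
    categories: np.ndarray,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Linear trend in per-category counts across PRS deciles.

    For each category, the count of individuals in decile d is regressed on
    d = 1..10 by OLS; returns {category: (slope, p)}.
    """
    prs = np.asarray(prs, dtype=float)
    categories = np.asarray([getattr(c, "name", c) for c in categories])
    if len(prs) < 10:
        raise ValueError("decile trend requires at least 10 samples")
    deciles = assign_deciles(prs, seed=seed)
    out: dict[str, tuple[float, float]] = {}
    d_grid = np.arange(1, 11)
    for cat in sorted(pd.unique(categories)):
        counts = np.array([(deciles[categories == cat] == d).sum() for d in d_grid], dtype=float)
        res = stats.linregress(d_grid, counts)
        out[str(cat)] = (float(res.slope), float(res.pvalue))
    return out


def top_bottom_decile_or(
    prs: np.ndarray,
    outcome: np.ndarray,
    covars: pd.DataFrame | None = None,
    seed: int = 0,
    stratum: str = "all",
) -> AssociationEstimate:
    """OR for the top vs bottom PRS decile within the analysis stratum."""
    prs = np.asarray(prs, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    deciles = assign_deciles(prs, seed=seed)
    mask = (deciles == 1) | (deciles == 10)
    if not ((deciles == 1).any() and (deciles == 10).any()):
        raise ValueError("empty extreme decile")
    top = (deciles[mask] == 10).astype(float)
    sub_cov = covars.reset_index(drop=True).loc[mask].reset_index(drop=True) if covars is not None else None
    return fit_logistic(outcome[mask], top, covars=sub_cov, stratum=stratum)


def ancestry_strata(admixture: pd.DataFrame, threshold: float = 0.8) -> pd.Series:
    """Label each sample by its predominant genetic ancestry.

    ``admixture`` has one column per ancestry; rows must sum to 1 (±1e-6).
    A sample gets ancestry label a iff proportion(a) >= threshold and no
    other ancestry also meets the threshold; otherwise it is unlabeled (NaN).
    """
    sums = admixture.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("ancestry proportions must sum to 1 per sample")
    meets = admixture.ge(threshold)
    n_meet = meets.sum(axis=1)
    labels = admixture.idxmax(axis=1).where(n_meet == 1)
    return labels
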
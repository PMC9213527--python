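"""Age-dependent hypertension-risk trajectories within PRS strata.

Samples are assigned to strata by PRS percentile (default <10, 10-50,
50-90, >90), either over the combined sample or within group labels.
Within each stratum a logistic GLMM with a per-subject random intercept is
fitted to repeated visit-level hypertension status with fixed effects sex,
ancestry PCs, (age - 17) and (age - 17)^2 — ages are shifted by the
reference age so the curve is anchored there.  The OR-by-age curve relative
to the reference age is

    log OR(age) = d * b_age + d^2 * b_age2,    d = age - ref_age,

with delta-method variance d^2 v11 + d^4 v22 + 2 d^3 v12 from the (age,
age^2) covariance block and normal 95% bands, so OR(ref_age) = 1 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _glmm
from .assoc import Z975, build_design

logger = logging.getLogger(__name__)

DEFAULT_CUTS = (10.0, 50.0, 90.0)
REF_AGE = 17.0


@dataclass
class PRSStrata:
    """Percentile-based stratum labels (1 = bottom cut, K = top)."""

    cuts: tuple[float, ...]
    scope: str  # "combined" | "within-group"
    labels: pd.Series  # sample_id -> stratum index 1..K

    @property
    def n_strata(self) -> int:
        return len(self.cuts) + 1

    def stratum_name(self, idx: int) -> str:
        bounds = (0.0, *self.cuts, 100.0)
        return f"{bounds[idx - 1]:g}-{bounds[idx]:g}%"


@dataclass
class TrajectoryFit:
    """Quadratic-age log-odds coefficients with their covariance."""

    beta_age: float
    beta_age2: float
    cov: np.ndarray  # 2x2
    ref_age: float = REF_AGE
    stratum: str = "all"
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2) or not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("cov must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-10):
            raise ValueError("cov must be positive semi-definite")


@dataclass
class ORCurve:
    ages: np.ndarray
    or_point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    stratum: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "age": self.ages,
                "or": self.or_point,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def prs_strata(
    prs: np.ndarray,
    sample_ids: list[str],
    cuts: tuple[float, ...] = DEFAULT_CUTS,
    scope: str = "combined",
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> PRSStrata:
    """Assign samples to PRS-percentile strata.

    Ranks are computed over the combined sample or, with
    ``scope="within-group"``, inside each group label separately.  Exactly
    tied values are ordered by a seeded random key so target stratum sizes
    are met deterministically.
    """
    prs = np.asarray(prs, dtype=float)
    rng = np.random.default_rng(seed)
    labels = pd.Series(index=sample_ids, dtype=int, name="stratum")

    def assign(mask: np.ndarray) -> None:
        vals = prs[mask]
        n = len(vals)
        order = np.lexsort((rng.random(n), vals))
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        pct = (ranks + 0.5) * 100.0 / n
        stratum = np.searchsorted(np.asarray(cuts), pct, side="right") + 1
        counts = np.bincount(stratum, minlength=len(cuts) + 2)[1:]
        if (counts > 0).any() and counts.min() < 10:
            logger.warning("prs_strata: a stratum has fewer than 10 samples (%s)", counts.tolist())
        labels.iloc[np.where(mask)[0]] = stratum

    if scope == "combined":
        assign(np.ones(len(prs), dtype=bool))
    elif scope == "within-group":
        if groups is None:
            raise ValueError("within-group scope requires group labels")
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            assign(groups == g)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return PRSStrata(cuts=tuple(cuts), scope=scope, labels=labels)


def fit_trajectory(
    visits: pd.DataFrame,
    covars: pd.DataFrame | None = None,
    ref_age: float = REF_AGE,
    stratum: str = "all",
    variance_component: float | None = None,
) -> TrajectoryFit:
    """Fit the per-stratum random-intercept GLMM on visit-level status.

    ``visits`` is long-format with columns sample_id, age, htn (0/1);
    ``covars`` is per-sample (indexed by sample_id; typically sex and PCs)
    and is broadcast to visits.  Ages enter as (age - ref_age) and its
    square.  ``variance_component`` fixes the random-intercept variance
    (0 reduces to pooled ordinary logistic).
    """
    d = visits["age"].to_numpy(dtype=float) - ref_age
    extra = {"age_c": d, "age_c2": d * d}
    cov_rows = covars.loc[visits["sample_id"]].reset_index(drop=True) if covars is not None else None
    X, names, keep = build_design(cov_rows, len(visits), extra=extra)
    y = visits["htn"].to_numpy(dtype=float)[keep]
    groups = visits["sample_id"].to_numpy()[keep]
    fit = _glmm.pql_random_intercept(X, y, groups, sigma2=variance_component)
    i, j = names.index("age_c"), names.index("age_c2")
    return TrajectoryFit(
        beta_age=float(fit.beta[i]),
        beta_age2=float(fit.beta[j]),
        cov=fit.cov[np.ix_([i, j], [i, j])],
        ref_age=ref_age,
        stratum=stratum,
        sigma2=fit.sigma2,
    )


def or_by_age(fit: TrajectoryFit, ages: np.ndarray) -> ORCurve:
    """OR for hypertension at each age relative to the reference age.

    Delta-method variance of the log-OR uses the (age, age²) covariance
    block; 95% bands use the normal 1.96 quantile.
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < fit.ref_age):
        raise ValueError(f"ages must be >= ref_age ({fit.ref_age})")
    d = ages - fit.ref_age
    log_or = d * fit.beta_age + d**2 * fit.beta_age2
    v11, v22, v12 = fit.cov[0, 0], fit.cov[1, 1], fit.cov[0, 1]
    var = d**2 * v11 + d**4 * v22 + 2 * d**3 * v12
    se = np.sqrt(np.clip(var, 0.0, None))
    return ORCurve(
        ages=ages,
        or_point=np.exp(log_or),
        ci_low=np.exp(log_or - Z975 * se),
        ci_high=np.exp(log_or + Z975 * se),
        stratum=fit.stratum,
    )
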
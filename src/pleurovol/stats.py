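"""Cohort statistics for the resectable (MCR) vs unresectable (R2) comparison.

Descriptive medians with IQR, Mann-Whitney / Fisher / Spearman group
tests, univariable-to-multivariable logistic regression for predictors of
unresectability, and ROC analysis with the cut-off maximising
sensitivity + specificity (the Youden criterion).

Conventions pinned here because printed clinical tables depend on them:

* quartiles use the R-6 convention (positions ``p*(n+1)``, SPSS's
  HAVERAGE; numpy ``method="weibull"``);
* ROC cut-off candidates are the midpoints between consecutive sorted
  unique predictor values, which is why printed cut-offs land on half
  units (77.5 %, 120.5 mm); ties in the Youden index are broken toward
  higher specificity, then toward the smaller cut-off;
* classification rules use strict inequalities (``TLC < cut-off``,
  ``burden > cut-off``);
* all tests are two-sided.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
import statsmodels.api as sm

__all__ = [
    "median_iqr",
    "mann_whitney",
    "fisher_exact",
    "spearman",
    "roc_cutoff",
    "classify_at_cutoffs",
    "logistic_univariable",
    "logistic_multivariable",
    "screen_univariable",
    "CutoffResult",
    "LogisticFit",
    "PredictorEffect",
    "synthetic_cohort",
    "logistic_cohort",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# descriptive
# ---------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles (R-6 / SPSS HAVERAGE convention).

    Returns ``(median, q1, q3)``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("median_iqr of empty input")
    q1, q3 = np.percentile(x, [25, 75], method="weibull")
    return float(np.median(x)), float(q1), float(q3)


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact p for small tie-free samples,
    tie-corrected normal approximation otherwise.  Returns ``(U, p)``."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney needs two non-empty groups")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; p = 1", stacklevel=2)
        return float(a.size * b.size / 2), 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    or_defined: bool = True


def fisher_exact(table) -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    p is the two-sided sum of hypergeometric probabilities no larger than
    the observed table's; the odds ratio is the conditional maximum
    likelihood estimate.  A zero margin yields p = 1 and an undefined OR.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact needs a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(float("nan"), 1.0, or_defined=False)
    p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    orr = float(_odds_ratio(t, kind="conditional").statistic)
    return FisherResult(orr, p)


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``method``: ``"exact"`` enumerates all rank permutations (n <= 8),
    ``"approx"`` uses the t approximation, ``"auto"`` picks exact for
    n <= 8 without ties.  Constant input yields ``(nan, nan)`` with a
    warning.  Returns ``(rho, p_two_sided)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input; Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho = float(sps.spearmanr(x, y).statistic)
    n = x.size
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if method == "exact" or (method == "auto" and n <= 8 and not ties):
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    p = float(sps.spearmanr(x, y).pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# ROC / cut-offs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffResult:
    predictor: str
    direction: str       # "above": value > cutoff flags positive; "below": value < cutoff
    cutoff: float
    auc: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def roc_cutoff(values, labels, direction: str = "above", predictor: str = "") -> CutoffResult:
    """AUC (rank formulation) and the Youden-optimal cut-off.

    ``labels`` flag the positive (unresectable) class.  Candidate cut-offs
    are midpoints between consecutive sorted unique values; the returned
    cut-off maximises sensitivity + specificity, ties broken toward higher
    specificity and then toward the smaller cut-off value.
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if v.size != lab.size:
        raise ValueError("values and labels differ in length")
    n1, n0 = int(lab.sum()), int((~lab).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    if np.all(v == v[0]):
        warnings.warn("constant predictor; AUC undefined", stacklevel=2)
        return CutoffResult(predictor, direction, float("nan"), float("nan"), 0.0, 0.0)
    score = v if direction == "above" else -v
    ranks = sps.rankdata(score)
    u = float(ranks[lab].sum() - n1 * (n1 + 1) / 2)
    auc = u / (n1 * n0)

    uniq = np.unique(v)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in mids:
        pos = v > c if direction == "above" else v < c
        sens = float((pos & lab).sum()) / n1
        spec = float((~pos & ~lab).sum()) / n0
        key = (sens + spec, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cut, sens, spec = best
    return CutoffResult(predictor, direction, float(cut), auc, sens, spec)


def classify_at_cutoffs(
    cohort: pd.DataFrame,
    tlc_cut: float = 77.5,
    burden_cut: float = 120.5,
    tlc_col: str = "tlc_pct",
    burden_col: str = "burden_mm",
) -> dict[str, int]:
    """Counts of patients below the TLC cut-off, above the burden cut-off,
    and both (strict inequalities).  Rows missing a field are excluded from
    that rule with a warning."""
    tlc = pd.to_numeric(cohort[tlc_col], errors="coerce")
    burden = pd.to_numeric(cohort[burden_col], errors="coerce")
    if tlc.isna().any() or burden.isna().any():
        warnings.warn("patients with missing TLC/burden excluded from the rule counts",
                      stacklevel=2)
    below = tlc < tlc_cut
    above = burden > burden_cut
    return {
        "tlc_below": int(below.sum()),
        "burden_above": int(above.sum()),
        "both": int((below & above).sum()),
        "n": int(len(cohort)),
    }


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorEffect:
    name: str
    coef: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticFit:
    scope: str                        # "univariable" | "multivariable"
    effects: dict[str, PredictorEffect] = field(default_factory=dict)
    separation: bool = False
    converged: bool = True
    n: int = 0

    def __getitem__(self, name: str) -> PredictorEffect:
        return self.effects[name]


def _outcome_vector(cohort: pd.DataFrame, outcome_col: str, positive) -> np.ndarray:
    y = cohort[outcome_col]
    if y.dtype == bool:
        return y.to_numpy().astype(float)
    return (y == positive).to_numpy().astype(float)


def _fit_logit(y: np.ndarray, X: pd.DataFrame, scope: str) -> LogisticFit:
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    fit = LogisticFit(scope=scope, n=len(y))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception:
        fit.separation = True
        fit.converged = False
        return fit
    params = res.params
    bse = res.bse
    # Wald SEs blowing up (or absurd coefficients) signal quasi-separation
    if not res.mle_retvals.get("converged", True) or np.any(np.abs(params) > 50) or np.any(
        ~np.isfinite(bse)
    ) or np.any(bse > 1e3):
        fit.separation = True
        fit.converged = bool(res.mle_retvals.get("converged", False))
    ci = res.conf_int(alpha=ALPHA)
    for name in X.columns:
        lo, hi = float(ci.loc[name, 0]), float(ci.loc[name, 1])
        fit.effects[name] = PredictorEffect(
            name=name,
            coef=float(params[name]),
            odds_ratio=float(np.exp(params[name])),
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            p_value=float(res.pvalues[name]),
        )
    return fit


def logistic_univariable(
    cohort: pd.DataFrame, predictor: str,
    outcome_col: str = "outcome", positive="R2",
) -> LogisticFit:
    """Single-predictor logistic fit; OR is per unit of the native scale."""
    sub = cohort[[predictor, outcome_col]].dropna()
    y = _outcome_vector(sub, outcome_col, positive)
    return _fit_logit(y, sub[[predictor]].astype(float), "univariable")


def logistic_multivariable(
    cohort: pd.DataFrame, predictors: list[str],
    outcome_col: str = "outcome", positive="R2",
) -> LogisticFit:
    if not predictors:
        raise ValueError("no predictors supplied")
    sub = cohort[list(predictors) + [outcome_col]].dropna()
    y = _outcome_vector(sub, outcome_col, positive)
    return _fit_logit(y, sub[list(predictors)].astype(float), "multivariable")


def screen_univariable(
    cohort: pd.DataFrame, candidates: list[str],
    outcome_col: str = "outcome", positive="R2", alpha: float = ALPHA,
) -> list[str]:
    """Univariable screen: predictors with Wald p < alpha enter the
    multivariable model."""
    selected = []
    for name in candidates:
        f = logistic_univariable(cohort, name, outcome_col, positive)
        if not f.separation and name in f.effects and f[name].p_value < alpha:
            selected.append(name)
    return selected


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

#: per-group (median, q1, q3) used to parameterise the synthetic cohort;
#: lognormal for the skewed imaging metrics, normal for diff_pct.
_COHORT_SHAPE = {
    "tlc_pct": {"MCR": (89, 79, 97), "R2": (75, 71, 80)},
    "burden_mm": {"MCR": (57, 36, 99), "R2": (133, 70, 181)},
    "ipsilateral_volume_cm3": {"MCR": (1944, 1528, 2352), "R2": (1545, 1322, 1782)},
    "diff_pct": {"MCR": (25.28, 7.4, 41.73), "R2": (47.01, 28.39, 59.01)},
}


def synthetic_cohort(n_mcr: int = 43, n_r2: int = 15, seed: int = 0) -> pd.DataFrame:
    """A synthetic two-group cohort with marginals shaped like the study's.

    Continuous variables are drawn per group from lognormal (or, for the
    volumetric percent difference, normal) distributions whose median and
    IQR match the group summaries; no within-patient correlation structure
    beyond the group effect is simulated.
    """
    rng = np.random.default_rng(seed)
    z75 = sps.norm.ppf(0.75)
    rows = []
    for outcome, n in (("MCR", n_mcr), ("R2", n_r2)):
        cols = {}
        for name, groups in _COHORT_SHAPE.items():
            med, q1, q3 = groups[outcome]
            if name == "diff_pct":
                sd = (q3 - q1) / (2 * z75)
                cols[name] = rng.normal(med, sd, n)
            else:
                sigma = np.log(q3 / q1) / (2 * z75)
                cols[name] = rng.lognormal(np.log(med), sigma, n)
        df = pd.DataFrame(cols)
        df["outcome"] = outcome
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "id", np.arange(1, len(out) + 1))
    return out


def logistic_cohort(
    n: int,
    coefs: dict[str, tuple[float, float, float]],
    intercept: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort drawn from a known logistic model, for parameter-recovery
    checks.  ``coefs`` maps predictor name -> (beta, mean, sd) with the
    predictor drawn N(mean, sd) and P(R2) = ilogit(intercept + sum beta x).
    """
    rng = np.random.default_rng(seed)
    eta = np.full(n, float(intercept))
    cols = {}
    for name, (beta, mean, sd) in coefs.items():
        x = rng.normal(mean, sd, n)
        cols[name] = x
        eta += beta * x
    p = 1.0 / (1.0 + np.exp(-eta))
    y = rng.random(n) < p
    df = pd.DataFrame(cols)
    df["outcome"] = np.where(y, "R2", "MCR")
    return df
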
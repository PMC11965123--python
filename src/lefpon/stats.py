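"""Statistical kernel shared by every pipeline stage.

Contingency-table statistics (Pearson chi-square without continuity
correction, Woolf odds-ratio intervals), a small logistic-regression
solver with explicit separation detection, tie-corrected nonparametric
tests, and the Hardy-Weinberg equilibrium goodness-of-fit test.

Rank-based tests and the chi-square statistic are delegated to
:mod:`scipy.stats` (mid-ranks for ties, asymptotic two-sided p-values,
no continuity correction anywhere), wrapped so that degenerate inputs
fail with domain-specific errors instead of library internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import expit


class SeparationError(RuntimeError):
    """Raised when logistic-regression coefficients diverge (perfect separation)."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """R x C table of non-negative integer counts.

    Rows index outcome groups (responder first by convention), columns
    index exposure levels (reference level first).
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("table needs at least two rows and two columns")
        if counts.sum() == 0:
            raise ValueError("grand total must be positive")
        if len(self.row_labels) != counts.shape[0]:
            raise ValueError("row_labels length mismatch")
        if len(self.col_labels) != counts.shape[1]:
            raise ValueError("col_labels length mismatch")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``odds_ratios`` and their confidence limits are ``exp`` transforms of
    the coefficients; ``converged`` must be checked before reporting.
    """

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    converged: bool
    n_obs: int
    n_iter: int = 0
    alpha: float = 0.05

    def __getitem__(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        return {
            "coef": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "z": float(self.wald_z[i]),
            "p": float(self.p_values[i]),
            "or": float(self.odds_ratios[i]),
            "ci_low": float(self.or_ci_low[i]),
            "ci_high": float(self.or_ci_high[i]),
        }


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------


def pearson_chi2(table: ContingencyTable) -> Chi2Result:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts are ``row_total * col_total / N``; a zero row or
    column margin is rejected with the offending label.
    """
    counts = table.counts
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    for label, tot in zip(table.row_labels, row_tot):
        if tot == 0:
            raise ValueError(f"row margin {label!r} is zero; test undefined")
    for label, tot in zip(table.col_labels, col_tot):
        if tot == 0:
            raise ValueError(f"column margin {label!r} is zero; test undefined")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return Chi2Result(statistic=float(stat), df=int(df), p=float(p))


def odds_ratio_woolf(
    a: int, b: int, c: int, d: int, alpha: float = 0.05, haldane: bool = False
) -> OddsRatioResult:
    """Odds ratio ``(a*d)/(b*c)`` with Woolf's log-method confidence interval.

    Cell layout is the caller's responsibility (documented per use site).
    With ``haldane`` on, 0.5 is added to every cell whenever any cell is
    zero (Haldane-Anscombe correction); otherwise zero cells are an error.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(cells == 0):
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; enable haldane=True for the 0.5 correction"
            )
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_value = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1.0 / cells).sum())
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    log_or = np.log(or_value)
    return OddsRatioResult(
        or_value=float(or_value),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# logistic regression (Newton / IRLS)
# ---------------------------------------------------------------------------


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    alpha: float = 0.05,
    separation_bound: float = 15.0,
) -> LogisticFit:
    """Logistic MLE by Newton-Raphson (IRLS) with Wald standard errors.

    ``design`` must already contain the intercept column. Convergence is
    declared when the largest absolute coefficient change drops below
    ``tol``; any coefficient exceeding ``separation_bound`` in magnitude
    during iteration raises :class:`SeparationError` (quasi-complete or
    complete separation). Standard errors come from the inverse observed
    information at the optimum.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D (n_obs x n_predictors)")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("outcome length must match design rows")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be coded 0/1 (non-responder = 0)")
    if n <= p:
        raise ValueError("need more observations than predictors")
    if names is None:
        names = ["const"] + [f"x{i}" for i in range(1, p)]
    if len(names) != p:
        raise ValueError("names length must match number of predictors")

    beta = np.zeros(p)
    converged = False
    it = 0
    info = None
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            # singular information (collinear design or degenerate weights):
            # minimum-norm Newton step; SEs below use the pseudo-inverse
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        beta_new = beta + step
        if np.any(np.abs(beta_new) > separation_bound):
            raise SeparationError(
                "coefficients diverged (|coef| > "
                f"{separation_bound:g}); data are likely perfectly separated"
            )
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    zcrit = sps.norm.ppf(1.0 - alpha / 2.0)
    return LogisticFit(
        names=tuple(names),
        coefficients=beta,
        standard_errors=se,
        wald_z=z,
        p_values=pvals,
        odds_ratios=np.exp(beta),
        or_ci_low=np.exp(beta - zcrit * se),
        or_ci_high=np.exp(beta + zcrit * se),
        converged=converged,
        n_obs=n,
        n_iter=it,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties), t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square(k-1) p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical; tie correction denominator is zero")
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (x-over-y wins plus half ties), normal approximation.

    Two-sided p from the tie-corrected normal approximation without
    continuity correction, matching the two-group Kruskal-Wallis special
    case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> Chi2Result:
    """Pearson goodness-of-fit test against Hardy-Weinberg genotype proportions.

    The allele frequency is estimated from the observed counts, expected
    counts are ``N * (p^2, 2pq, q^2)``, and the statistic is referred to
    chi-square with 1 degree of freedom (one estimated parameter).
    """
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(obs < 0):
        raise ValueError("genotype counts must be non-negative")
    n = obs.sum()
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p_hat = (2 * n_AA + n_Aa) / (2.0 * n)
    if p_hat in (0.0, 1.0):
        raise ValueError("monomorphic sample; HWE test undefined")
    q_hat = 1.0 - p_hat
    expected = n * np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2])
    stat = float(((obs - expected) ** 2 / expected).sum())
    return Chi2Result(statistic=stat, df=1, p=float(sps.chi2.sf(stat, 1)))
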
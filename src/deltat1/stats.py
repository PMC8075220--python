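"""The study-level statistical layer.

Paired pre/post comparisons (paired t and matched-pairs Wilcoxon), group
comparisons (Mann-Whitney U with a median-dichotomization helper), Spearman/
Pearson correlation with optional partial correlation on residuals,
a logistic treatment model, and Benjamini-Hochberg FDR adjustment.

All tests are two-sided.  The rank tests switch between exact enumeration
(combined n <= 12, ties handled through midranks) and the tie-corrected,
continuity-corrected normal approximation above that; the exact enumerators
double as oracles for the approximations in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import DomainError

__all__ = [
    "StatResult",
    "LogisticFit",
    "compare_paired",
    "compare_groups",
    "correlate",
    "fit_treatment_logistic",
    "fdr_adjust",
    "dichotomize_by_median",
    "EXACT_N_MAX",
]

# Switchover between exact enumeration and the normal approximation.
EXACT_N_MAX = 12


@dataclass
class StatResult:
    """One test's estimate, p-value, and bookkeeping."""

    estimate: float
    p_value: float
    method: str
    n: int
    p_adjusted: float | None = None
    flagged: bool = False
    note: str = ""


def _two_sided_from_cdf(stat: float, support: np.ndarray, probs: np.ndarray) -> float:
    """Two-sided p as min(1, 2*min(P(S <= s), P(S >= s))) over a discrete law."""
    p_le = float(probs[support <= stat + 1e-12].sum())
    p_ge = float(probs[support >= stat - 1e-12].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _drop_nan_pairs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise DomainError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    return a[keep], b[keep]


def compare_paired(pre: np.ndarray, post: np.ndarray) -> tuple[StatResult, StatResult]:
    """Paired t-test and matched-pairs Wilcoxon test on post - pre.

    Returns ``(t_result, wilcoxon_result)``, both two-sided.  Zero-variance
    differences degenerate both tests; the results come back flagged with
    p = NaN rather than raising.  Wilcoxon drops zero differences and uses
    exact sign-pattern enumeration for n <= 12 nonzero differences, the
    continuity-corrected normal approximation above.
    """
    pre, post = _drop_nan_pairs(pre, post)
    if pre.size < 3:
        raise DomainError("need at least 3 complete pairs")
    diffs = post - pre
    n = diffs.size

    if np.ptp(diffs) == 0:
        t_res = StatResult(
            np.nan, np.nan, "paired t", n, flagged=True, note="zero-variance differences"
        )
    else:
        t_stat, t_p = sps.ttest_rel(post, pre)
        t_res = StatResult(float(t_stat), float(t_p), "paired t", n)

    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        w_res = StatResult(
            np.nan, np.nan, "wilcoxon", n, flagged=True, note="all differences zero"
        )
    elif nonzero.size <= EXACT_N_MAX:
        ranks = sps.rankdata(np.abs(nonzero))
        w_obs = float(ranks[nonzero > 0].sum())
        # Enumerate all 2^n sign assignments of the ranked magnitudes.
        sums = np.array(
            [sum(r for r, s in zip(ranks, signs) if s) for signs in product((0, 1), repeat=nonzero.size)]
        )
        support, counts = np.unique(sums, return_counts=True)
        p = _two_sided_from_cdf(w_obs, support, counts / counts.sum())
        w_res = StatResult(w_obs, p, "wilcoxon exact", int(nonzero.size))
    else:
        stat, p = sps.wilcoxon(
            nonzero, alternative="two-sided", correction=True, mode="approx"
        )
        w_res = StatResult(float(stat), float(p), "wilcoxon approx", int(nonzero.size))
    return t_res, w_res


def _mann_whitney_u(ranks_a_sum: float, n_a: int) -> float:
    return ranks_a_sum - n_a * (n_a + 1) / 2.0


def compare_groups(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Exact enumeration over all group assignments when the combined sample
    size is <= 12 (midranks, so ties are handled and identical samples give
    p = 1); tie-corrected normal approximation with continuity correction
    otherwise.  The reported estimate is the U statistic of sample ``a``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 observations")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _mann_whitney_u(float(ranks[:n_a].sum()), n_a)

    if n_a + n_b <= EXACT_N_MAX:
        idx = range(n_a + n_b)
        u_all = np.array(
            [
                _mann_whitney_u(float(ranks[list(subset)].sum()), n_a)
                for subset in combinations(idx, n_a)
            ]
        )
        support, counts = np.unique(u_all, return_counts=True)
        p = _two_sided_from_cdf(u_obs, support, counts / counts.sum())
        return StatResult(u_obs, p, "mann-whitney exact", n_a + n_b)

    _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return StatResult(u_obs, float(p), "mann-whitney asymptotic", n_a + n_b)


def dichotomize_by_median(
    values: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split ``values`` into (score <= median, score > median) groups."""
    values = np.asarray(values, float)
    scores = np.asarray(scores, float)
    if values.shape != scores.shape:
        raise DomainError("values and scores must have equal length")
    med = np.median(scores)
    return values[scores <= med], values[scores > med]


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "spearman",
    covariates: np.ndarray | None = None,
) -> StatResult:
    """Spearman or Pearson correlation, optionally partial.

    Partial correlation regresses both variables on the covariates (with an
    intercept) and correlates the residuals; for the Spearman flavour all
    columns are rank-transformed first.  The p-value uses a t reference with
    n - k - 2 degrees of freedom (k covariates).
    """
    x, y = _drop_nan_pairs(x, y)
    if method not in ("spearman", "pearson"):
        raise DomainError("method must be 'spearman' or 'pearson'")
    n = x.size
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise DomainError("covariate rows must match x/y length")
        k = cov.shape[1]
    else:
        cov = None
        k = 0
    if n < k + 4:
        raise DomainError(f"need at least {k + 4} observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            np.nan, np.nan, f"{method} correlation", n, flagged=True, note="constant input"
        )

    if cov is None:
        if method == "spearman":
            rho, p = sps.spearmanr(x, y)
        else:
            rho, p = sps.pearsonr(x, y)
        return StatResult(float(rho), float(p), f"{method} correlation", n)

    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        cov = np.column_stack([sps.rankdata(c) for c in cov.T])
    design = np.column_stack([np.ones(n), cov])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return StatResult(
            np.nan, np.nan, f"partial {method}", n, flagged=True, note="degenerate residuals"
        )
    r = float((rx * ry).sum() / denom)
    dof = n - k - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(dof / (1 - r_clip**2))
    p = float(2 * sps.t.sf(abs(t), dof))
    return StatResult(r, p, f"partial {method}", n)


@dataclass
class LogisticFit:
    """Treatment ~ ΔT1 (+ phenotype) logistic regression coefficients."""

    beta0: float
    beta1: float
    beta2: float | None
    p0: float
    p1: float
    p2: float | None
    converged: bool
    flagged: bool = False
    note: str = ""


def fit_treatment_logistic(
    delta_t1: np.ndarray,
    treated: np.ndarray,
    phenotype: np.ndarray | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of treatment status on NEL ΔT1.

    ``treated`` is the binary outcome (1 = on treatment); ``phenotype`` is
    an optional binary adjustment covariate (0 = relapsing-remitting,
    1 = progressive).  P-values are Wald.  Perfect separation or
    non-convergence is flagged and the coefficients withheld.
    """
    delta_t1 = np.asarray(delta_t1, float)
    outcome = np.asarray(treated, float)
    if set(np.unique(outcome)) - {0.0, 1.0}:
        raise DomainError("treated must be binary 0/1")
    if len(np.unique(outcome)) < 2:
        raise DomainError("both outcome classes must be present")
    cols = [np.ones_like(delta_t1), delta_t1]
    if phenotype is not None:
        cols.append(np.asarray(phenotype, float))
    design = np.column_stack(cols)

    try:
        fit = sm.Logit(outcome, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return LogisticFit(
            np.nan, np.nan, None, np.nan, np.nan, None,
            converged=False, flagged=True, note=f"fit failed: {exc}",
        )
    converged = bool(fit.mle_retvals.get("converged", False))
    separated = bool(np.any(np.abs(fit.params) > 1e3))
    if not converged or separated:
        return LogisticFit(
            np.nan, np.nan, None, np.nan, np.nan, None,
            converged=converged, flagged=True,
            note="perfect separation suspected" if separated else "did not converge",
        )
    params, pvals = fit.params, fit.pvalues
    has_pheno = phenotype is not None
    return LogisticFit(
        beta0=float(params[0]),
        beta1=float(params[1]),
        beta2=float(params[2]) if has_pheno else None,
        p0=float(pvals[0]),
        p1=float(pvals[1]),
        p2=float(pvals[2]) if has_pheno else None,
        converged=True,
    )


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
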
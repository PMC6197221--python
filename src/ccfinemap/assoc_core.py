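"""Core case-control association statistics.

2x2 allelic tests with Woolf confidence intervals, genotype-model coding,
an IRLS logistic-regression fitter used for conditional tests, and the
genomic inflation factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_qc import GenotypeMatrix, CASE

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "LogisticFit",
    "odds_ratio_2x2",
    "allele_table",
    "code_model",
    "logistic_fit",
    "conditional_test",
    "genomic_lambda",
]

# median of the chi-square distribution with 1 df; null expectation for lambda
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)

MODELS = ("additive", "dominant", "recessive")


@dataclass
class ContingencyTable2x2:
    """Case/control exposure counts: a,b = case exposed/unexposed; c,d = control."""

    a: float
    b: float
    c: float
    d: float
    warning: str | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def case_total(self) -> float:
        return self.a + self.b

    @property
    def control_total(self) -> float:
        return self.c + self.d


@dataclass
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    model: str = "allelic"
    method: str = "table"
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def inverse_or(self) -> float:
        return 1.0 / self.odds_ratio


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    converged: bool
    iterations: int
    column_names: list[str] = field(default_factory=list)


def odds_ratio_2x2(
    t: ContingencyTable2x2,
    haldane: bool = False,
    yates: bool = False,
    ci_level: float = 0.95,
) -> AssociationResult:
    """Odds ratio with Woolf CI and a Pearson chi-square test (1 df).

    OR = ad/bc.  The chi-square is computed without continuity correction
    unless ``yates`` is set.  With ``haldane``, 0.5 is added to every cell
    when any cell is zero (never silently).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if not haldane:
            cell = "abcd"[[a, b, c, d].index(0.0)]
            raise ZeroDivisionError(
                f"cell '{cell}' of the 2x2 table is zero; enable the Haldane-Anscombe correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5

    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(or_) - z * se))
    ci_high = float(np.exp(np.log(or_) + z * se))

    n = a + b + c + d
    exp_a = (a + b) * (a + c) / n
    exp_b = (a + b) * (b + d) / n
    exp_c = (c + d) * (a + c) / n
    exp_d = (c + d) * (b + d) / n
    obs = np.array([a, b, c, d])
    expv = np.array([exp_a, exp_b, exp_c, exp_d])
    diff = np.abs(obs - expv)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expv).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return AssociationResult(float(or_), ci_low, ci_high, chi2, p, method="table")


def allele_table(gm: GenotypeMatrix, variant: str) -> ContingencyTable2x2:
    """Minor-allele chromosome counts by phenotype for one variant.

    Complete-case: samples with missing dosage at the variant are dropped
    (contributing 0 chromosomes); every typed sample contributes 2.
    """
    j = gm.variant_index(variant)
    col = gm.dosage[:, j]
    case = gm.is_case()
    typed = ~np.isnan(col)
    if not typed.any():
        raise ValueError(f"variant {variant!r}: all dosages missing")
    if not (case & typed).any() or not (~case & typed).any():
        raise ValueError(f"variant {variant!r}: need typed samples in both groups")

    a = float(col[case & typed].sum())
    b = float(2 * (case & typed).sum() - a)
    c = float(col[~case & typed].sum())
    d = float(2 * (~case & typed).sum() - c)
    warning = None
    if a + c == 0 or b + d == 0:
        warning = "monomorphic variant: zero margin"
    return ContingencyTable2x2(a, b, c, d, warning=warning)


def code_model(dosage: np.ndarray, model: str) -> np.ndarray:
    """Recode alt-allele dosages under a genotype model; NaN propagates."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    d = np.asarray(dosage, dtype=float)
    if model == "additive":
        return d.copy()
    out = np.full(d.shape, np.nan)
    ok = ~np.isnan(d)
    if model == "dominant":
        out[ok] = (d[ok] >= 1).astype(float)
    else:  # recessive
        out[ok] = (d[ok] == 2).astype(float)
    return out


def logistic_fit(
    y: np.ndarray,
    X: np.ndarray,
    column_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 15.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` must already contain the intercept column.  Convergence is
    declared when the largest coefficient change falls below ``tol``.
    Complete separation is flagged (|beta| exceeding ``separation_bound``)
    and returned as a non-converged fit rather than raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")
    if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
        raise ValueError("y must contain both 0 and 1")
    names = column_names or [f"x{k}" for k in range(X.shape[1])]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column for the error message
        for k in range(X.shape[1]):
            others = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(f"design matrix is rank deficient: column {names[k]!r} is redundant")
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > separation_bound:
            break
        if delta < tol:
            converged = True
            break

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = beta / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    return LogisticFit(beta, se, wald, p, converged, it, names)


def conditional_test(
    target: np.ndarray,
    conditioned_on: list[np.ndarray],
    pheno: np.ndarray,
    model: str = "additive",
) -> AssociationResult:
    """Wald test of a target dosage adjusted for conditioning dosages.

    Fits phenotype ~ intercept + coded(target) + coded(conditioners) and
    reports the target's exp(beta) as OR with its Wald P.  A conditioner
    perfectly correlated with the target (r^2 = 1) yields a degenerate
    flagged result instead of an exception.
    """
    ph = np.asarray(pheno)
    if ph.dtype.kind in "OUS":
        y = np.asarray([1.0 if p == CASE else 0.0 for p in ph])
    else:
        y = ph.astype(float)
    t = code_model(np.asarray(target, float), model)
    conds = [code_model(np.asarray(c, float), model) for c in conditioned_on]

    cols = [t] + conds
    ok = ~np.isnan(np.column_stack(cols + [y])).any(axis=1)
    t_, y_ = t[ok], y[ok]
    conds_ = [c[ok] for c in conds]
    for c in conds_:
        if np.std(t_) == 0 or np.std(c) == 0 or abs(np.corrcoef(t_, c)[0, 1]) > 1 - 1e-12:
            return AssociationResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                     model=model, method="logistic", degenerate=True)
    X = np.column_stack([np.ones(ok.sum()), t_] + conds_)
    names = ["intercept", "target"] + [f"cond{k}" for k in range(len(conds_))]
    fit = logistic_fit(y_, X, column_names=names)
    beta, se = fit.coefficients[1], fit.standard_errors[1]
    z = stats.norm.ppf(0.975)
    return AssociationResult(
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        chi2=float(fit.wald_z[1] ** 2),
        p_value=float(fit.p_values[1]),
        model=model,
        method="logistic",
        degenerate=not fit.converged,
        extra={"fit": fit},
    )


def genomic_lambda(chi2_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi2 over the null median."""
    v = np.asarray(chi2_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty chi-square vector")
    if (v < 0).any():
        raise ValueError("chi-square statistics must be nonnegative")
    return float(np.median(v) / CHI2_1_MEDIAN)
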
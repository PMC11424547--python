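"""Disproportionality statistics for spontaneous-report databases.

Implements the four signal-detection algorithms routinely applied to FAERS-style
data: the Reporting Odds Ratio (ROR), the Proportional Reporting Ratio (PRR)
with its Pearson chi-square, the Bayesian Confidence Propagation Neural
Network information component (BCPNN IC), and the Multi-item Gamma-Poisson
Shrinker (MGPS) empirical-Bayes geometric mean (EBGM).

All statistics are computed from 2x2 contingency tables built per drug-term
pair against the rest of the database:

    ============== =========== ==============
                    term        not term
    ============== =========== ==============
    target drug        a            b
    other drugs        c            d
    ============== =========== ==============

The counting unit is the deduplicated report: a report contributes at most one
count per term regardless of how many times the term is mentioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ContingencyTable",
    "PriorHyperparams",
    "BcpnnPriors",
    "build_tables",
    "ror",
    "prr_chi2",
    "bcpnn_ic",
    "bcpnn_ic_mc",
    "fit_mgps_prior",
    "fit_mgps_prior_counts",
    "ebgm",
    "ebgm_counts",
    "ml_ic",
    "relative_reporting_ratio",
    "bonferroni",
    "score_tables",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cell counts for one (drug, term) pair.

    a: target-drug reports with the term; b: target-drug reports without it;
    c: other-drug reports with the term; d: other-drug reports without it.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("contingency table is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence: E = (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe cells: +0.5 on all four when any cell is zero."""
        if min(self.a, self.b, self.c, self.d) == 0:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)


@dataclass
class PriorHyperparams:
    """Two-component gamma mixture prior of the MGPS model.

    The latent reporting-rate ratio lambda of each term is drawn from
    w * Gamma(alpha1, beta1) + (1-w) * Gamma(alpha2, beta2) (shape/rate).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    converged: bool = True
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be strictly positive")
        if not 0 < self.w < 1:
            raise ValueError("mixture weight w must lie in (0, 1)")

    @property
    def prior_mean(self) -> float:
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2


@dataclass(frozen=True)
class BcpnnPriors:
    """Closed-form BCPNN prior pseudo-counts (Bate et al. defaults)."""

    alpha1_m: float = 1.0
    beta1_m: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0
    k: float = 2.0

    def __post_init__(self) -> None:
        if min(self.alpha1_m, self.beta1_m, self.alpha, self.beta, self.gamma11, self.k) <= 0:
            raise ValueError("BCPNN priors must be strictly positive")


def build_tables(
    reports: pd.DataFrame,
    reactions: pd.DataFrame,
    level: str = "PT",
    min_count: int = 5,
    unit: str = "report",
) -> list[tuple[str, ContingencyTable]]:
    """Build one 2x2 table per term against the rest of the database.

    Parameters
    ----------
    reports
        Deduplicated reports; needs columns ``primaryid`` and boolean ``target``.
    reactions
        Term mentions; needs ``primaryid`` and a term column (``pt`` for
        level="PT", ``soc`` for level="SOC").
    level
        "PT" or "SOC"; selects the term column.
    min_count
        Minimum a-cell count for a table to be emitted (default 5 reports).
    unit
        "report" (default): a report counts once per term and margins count
        reports. "pair": margins count distinct (report, term) pairs instead.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    term_col = {"PT": "pt", "SOC": "soc"}.get(level.upper())
    if term_col is None:
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    if term_col not in reactions.columns:
        raise ValueError(f"reactions lack the {term_col!r} column required at level {level}")

    pairs = reactions[["primaryid", term_col]].drop_duplicates()
    target_ids = reports.loc[reports["target"].astype(bool), "primaryid"]
    pairs = pairs.merge(
        pd.DataFrame({"primaryid": reports["primaryid"], "target": reports["target"].astype(bool)}),
        on="primaryid",
        how="inner",
    )
    with_term = pairs.groupby(term_col)["target"].agg(["sum", "count"])
    a = with_term["sum"].astype(int)
    c = (with_term["count"] - with_term["sum"]).astype(int)

    if unit == "report":
        n_target = int(reports["target"].astype(bool).sum())
        n_other = int(len(reports)) - n_target
    elif unit == "pair":
        n_target = int(pairs["target"].sum())
        n_other = int(len(pairs)) - n_target
    else:
        raise ValueError(f"unit must be 'report' or 'pair', got {unit!r}")

    out: list[tuple[str, ContingencyTable]] = []
    for term in sorted(a.index):
        ai = int(a[term])
        if ai < min_count:
            continue
        ci = int(c[term])
        out.append((term, ContingencyTable(ai, n_target - ai, ci, n_other - ci)))
    return out


def ror(
    table: ContingencyTable, correction: bool = True
) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% log-normal CI.

    ror = (a*d)/(b*c); CI = exp(ln ror -/+ 1.96*sqrt(1/a + 1/b + 1/c + 1/d)).
    Zero cells: Haldane +0.5 correction when ``correction`` is on, otherwise
    (nan, nan, nan) is returned as the undefined-statistic flag.
    """
    a, b, c, d = table.corrected() if correction else map(float, (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def prr_chi2(
    table: ContingencyTable, correction: bool = True, yates: bool = False
) -> tuple[float, float, float, float, float]:
    """Proportional reporting ratio with 95% CI, Pearson chi-square and p-value.

    prr = [a/(a+b)] / [c/(c+d)];
    CI  = exp(ln prr -/+ 1.96*sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)));
    chi2 is the 1-df Pearson statistic N(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)],
    with the Yates continuity variant behind the ``yates`` flag.
    """
    a, b, c, d = table.corrected() if correction else map(float, (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    if min(a, c) == 0 or a + b == 0 or c + d == 0:
        return math.nan, math.nan, math.nan, math.nan, math.nan
    est = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    lo, hi = est * math.exp(-Z95 * se), est * math.exp(Z95 * se)

    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return est, lo, hi, math.nan, math.nan
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2, 0.0)
    chi2 = n * dev * dev / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return est, lo, hi, chi2, p


def bcpnn_ic(
    table: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()
) -> tuple[float, float]:
    """Closed-form BCPNN information component and its lower interval bound.

    Posterior moments of IC = log2[P(drug, term) / (P(drug) P(term))] under the
    beta/Dirichlet prior structure of Bate et al.; ic025 = E(IC) - k*sqrt(V(IC))
    with k defaulting to 2 (the "IC - 2SD" convention).
    """
    a = table.a
    n1 = table.a + table.b  # drug margin
    m1 = table.a + table.c  # term margin
    nn = table.n
    p = priors
    gamma = p.gamma11 * (nn + p.alpha) * (nn + p.beta) / ((n1 + p.alpha1_m) * (m1 + p.beta1_m))
    e_ic = math.log2(
        (a + p.gamma11) * (nn + p.alpha) * (nn + p.beta)
        / ((nn + gamma) * (n1 + p.alpha1_m) * (m1 + p.beta1_m))
    )
    v_ic = (
        (nn - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + nn + gamma))
        + (nn - n1 + p.alpha - p.alpha1_m) / ((n1 + p.alpha1_m) * (1 + nn + p.alpha))
        + (nn - m1 + p.beta - p.beta1_m) / ((m1 + p.beta1_m) * (1 + nn + p.beta))
    ) / math.log(2) ** 2
    return e_ic, e_ic - p.k * math.sqrt(v_ic)


def ml_ic(table: ContingencyTable) -> float:
    """Maximum-likelihood information component log2[a*N / ((a+b)(a+c))].

    The prior-free limit of the BCPNN IC; 0 when observed equals expected,
    nan when a margin is empty.
    """
    e = table.expected
    if table.a == 0 or e == 0:
        return math.nan
    return math.log2(table.a / e)


def bcpnn_ic_mc(
    table: ContingencyTable,
    priors: BcpnnPriors = BcpnnPriors(),
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo BCPNN: posterior sampling of the observed/expected ratio.

    Samples the joint and marginal reporting probabilities from their beta
    posteriors and returns the mean and ``k``-SD lower bound of
    log2(p11 / (p1. * p.1)). Agrees with the delta-method closed form within
    Monte-Carlo error on non-degenerate tables.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    a = table.a
    n1 = table.a + table.b
    m1 = table.a + table.c
    nn = table.n
    p = priors
    gamma = p.gamma11 * (nn + p.alpha) * (nn + p.beta) / ((n1 + p.alpha1_m) * (m1 + p.beta1_m))
    p11 = rng.beta(a + p.gamma11, nn - a + gamma - p.gamma11, size=n_samples)
    p1 = rng.beta(n1 + p.alpha1_m, nn - n1 + p.alpha - p.alpha1_m, size=n_samples)
    p2 = rng.beta(m1 + p.beta1_m, nn - m1 + p.beta - p.beta1_m, size=n_samples)
    ic = np.log2(p11 / (p1 * p2))
    return float(ic.mean()), float(ic.mean() - p.k * ic.std(ddof=1))


def _mixture_loglik(
    params: np.ndarray, a: np.ndarray, e: np.ndarray
) -> float:
    """Marginal log-likelihood of counts under the gamma-mixture prior.

    Integrating Poisson(a; lambda*E) over each gamma component gives a negative
    binomial: NB(a; alpha, beta/(beta+E)).
    """
    a1, b1, a2, b2 = np.exp(params[:4])
    w = special.expit(params[4])
    l1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    l2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    return float(np.logaddexp(np.log(w) + l1, np.log1p(-w) + l2).sum())


def fit_mgps_prior(
    tables: list[tuple[str, ContingencyTable]] | list[ContingencyTable],
    start: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
) -> PriorHyperparams:
    """Fit the MGPS gamma-mixture hyperparameters by maximum marginal likelihood.

    Maximises sum_i log[w NB(a_i; a1, b1/(b1+E_i)) + (1-w) NB(a_i; a2, b2/(b2+E_i))]
    over the observed a-cells, with E_i the independence expectation of each
    table. Deterministic Nelder-Mead from the given start on log/logit-
    transformed parameters.
    """
    tabs = [t[1] if isinstance(t, tuple) else t for t in tables]
    if len(tabs) < 2:
        raise ValueError("MGPS prior fit needs at least 2 tables")
    a = np.array([t.a for t in tabs], dtype=float)
    e = np.array([t.expected for t in tabs], dtype=float)
    return fit_mgps_prior_counts(a, e, start=start)


def fit_mgps_prior_counts(
    a: np.ndarray,
    e: np.ndarray,
    start: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
) -> PriorHyperparams:
    """MGPS prior fit from observed counts ``a`` and expectations ``e`` directly."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if len(a) < 2 or len(a) != len(e):
        raise ValueError("need at least 2 (a, E) pairs of equal length")
    if np.any(e <= 0):
        raise ValueError("all tables must have positive expected counts")

    x0 = np.array([*np.log(start[:4]), special.logit(start[4])])
    res = optimize.minimize(
        lambda x: -_mixture_loglik(x, a, e),
        x0,
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    a1, b1, a2, b2 = np.exp(res.x[:4])
    w = float(special.expit(res.x[4]))
    w = min(max(w, 1e-12), 1 - 1e-12)
    return PriorHyperparams(
        alpha1=float(a1), beta1=float(b1), alpha2=float(a2), beta2=float(b2),
        w=w, converged=bool(res.success), loglik=float(-res.fun),
    )


def _posterior_weight(a: int, e: float, prior: PriorHyperparams) -> float:
    """Posterior probability that lambda came from the first mixture component."""
    l1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    l2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    return float(special.expit(math.log(prior.w) - math.log1p(-prior.w) + l1 - l2))


def ebgm(
    table: ContingencyTable, prior: PriorHyperparams, quantile: float = 0.05
) -> tuple[float, float]:
    """Empirical-Bayes geometric mean and lower posterior quantile (EBGM05).

    The posterior of the rate ratio lambda given a is the gamma mixture
    Q Gamma(alpha1+a, beta1+E) + (1-Q) Gamma(alpha2+a, beta2+E); EBGM is
    2^{E[log2 lambda | a]} via the digamma closed form, EBGM05 the 5th
    posterior percentile located by bisection on the mixture CDF.
    """
    e = table.expected
    if e <= 0:
        return math.nan, math.nan
    return ebgm_counts(table.a, e, prior, quantile=quantile)


def ebgm_counts(
    a: int, e: float, prior: PriorHyperparams, quantile: float = 0.05
) -> tuple[float, float]:
    """EBGM and lower posterior quantile from an observed count and expectation."""
    if e <= 0:
        return math.nan, math.nan
    q = _posterior_weight(a, e, prior)
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e
    mean_log = q * (special.digamma(s1) - math.log(r1)) + (1 - q) * (
        special.digamma(s2) - math.log(r2)
    )
    gm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return q * stats.gamma.cdf(x, s1, scale=1 / r1) + (1 - q) * stats.gamma.cdf(
            x, s2, scale=1 / r2
        )

    # bracket the quantile, then bisect the monotone mixture CDF
    lo, hi = 0.0, max(s1 / r1, s2 / r2) + 1.0
    while cdf(hi) < quantile:
        hi *= 2
    for _ in range(500):
        mid = 0.5 * (lo + hi)
        f = cdf(mid)
        if abs(f - quantile) <= 1e-8:
            lo = hi = mid
            break
        if f < quantile:
            lo = mid
        else:
            hi = mid
    return gm, 0.5 * (lo + hi)


def relative_reporting_ratio(table: ContingencyTable) -> float:
    """Unshrunk observed/expected ratio a/E (the quantity EBGM shrinks)."""
    e = table.expected
    return table.a / e if e > 0 else math.nan


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: min(1, p*m) with m = number of tests."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * len(p), 1.0)


def score_tables(
    tables: list[tuple[str, ContingencyTable]],
    prior: PriorHyperparams | None = None,
    bcpnn_priors: BcpnnPriors = BcpnnPriors(),
    correction: bool = True,
    yates: bool = False,
) -> pd.DataFrame:
    """Compute all four algorithms for every term; one row per term.

    Fits the MGPS prior on the supplied tables when ``prior`` is None.
    Bonferroni m is the number of tables scored (the terms passing min_count
    at this level). Returns columns term, a..d, ror/ror_lo/ror_hi, prr + CI,
    chi2, p, adjusted_p, ic, ic025, ebgm, ebgm05, rrr, n.
    """
    if not tables:
        return pd.DataFrame(
            columns=[
                "term", "a", "b", "c", "d", "n", "expected", "ror", "ror_lo", "ror_hi",
                "prr", "prr_lo", "prr_hi", "chi2", "p", "adjusted_p",
                "ic", "ic025", "ebgm", "ebgm05", "rrr",
            ]
        )
    if prior is None and len(tables) >= 2:
        prior = fit_mgps_prior(tables)
    rows = []
    for term, t in tables:
        r, r_lo, r_hi = ror(t, correction=correction)
        p_est, p_lo, p_hi, chi2, pval = prr_chi2(t, correction=correction, yates=yates)
        ic, ic025 = bcpnn_ic(t, bcpnn_priors)
        if prior is not None:
            eb, eb05 = ebgm(t, prior)
        else:
            eb, eb05 = math.nan, math.nan
        rows.append(
            {
                "term": term, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "n": t.a,
                "expected": t.expected,
                "ror": r, "ror_lo": r_lo, "ror_hi": r_hi,
                "prr": p_est, "prr_lo": p_lo, "prr_hi": p_hi,
                "chi2": chi2, "p": pval,
                "ic": ic, "ic025": ic025, "ebgm": eb, "ebgm05": eb05,
                "rrr": relative_reporting_ratio(t),
            }
        )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bonferroni(df["p"].to_numpy())
    return df
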
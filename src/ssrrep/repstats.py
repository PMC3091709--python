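"""Goodness-of-fit and independence battery for SSR contingency tables.

Observed one- and two-way tables (extracted from the four-way dataset) are
compared against a reference distribution with chi-squared statistics.  The
asymptotic chi-squared p-value is replaced by a Monte-Carlo estimate (B
multinomial draws from the null) whenever any expected cell count falls
below 5.  Significant global tests are followed by per-cell exact binomial
tests with Benjamini-Hochberg FDR control, per-category binomial envelopes
for the expected counts, a chromosome bootstrap of the chi2/df statistic,
and two-sample Kolmogorov-Smirnov comparisons of chi2 distributions across
libraries.

All stochastic operations require an explicit seed; there is no module
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CellResult",
    "BootstrapCI",
    "chi2_gof",
    "chi2_independence",
    "mc_null_pvalue",
    "global_gof",
    "restrict_to_support",
    "bh_adjust",
    "binom_two_sided",
    "cell_tests",
    "expected_envelope",
    "bootstrap_chromosome_stat",
    "ks_two_sample",
    "fraction_below",
    "CHI2_DF1_CRIT",
]

#: Upper 5% point of the chi-squared distribution with 1 df (= 3.84 at 2 dp),
#: the reference limit used when summarizing per-cell chi2 values.
CHI2_DF1_CRIT: float = float(sps.chi2.ppf(0.95, 1))

_MIN_P = 5e-324  # smallest positive float; stands in for an exact-zero p-value


@dataclass
class TestResult:
    """A chi-squared test outcome (asymptotic and/or Monte-Carlo)."""

    statistic: float
    df: int
    p_asymptotic: float
    method: str
    p_montecarlo: float | None = None
    B: int | None = None
    seed: int | None = None

    @property
    def p(self) -> float:
        """Monte-Carlo p when available, else the asymptotic p."""
        return self.p_montecarlo if self.p_montecarlo is not None else self.p_asymptotic


@dataclass(frozen=True)
class CellResult:
    """Per-cell comparison of observed vs expected counts."""

    index: tuple
    observed: int
    expected: float
    direction: str  # "over" | "under" | "none"
    p_raw: float
    p_adjusted: float


@dataclass
class BootstrapCI:
    """95% percentile interval of chi2/df over chromosome resamples."""

    r: int
    n_boot: int
    lower: float
    upper: float
    seed: int
    n_dropped: int = 0
    replicates: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _check_probs(p: np.ndarray) -> None:
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")


def chi2_gof(observed, probabilities) -> TestResult:
    """One-way chi-squared goodness of fit against given cell probabilities.

    The statistic sums (O-E)^2/E over cells with p > 0 (E = n*p) and
    df = #{p > 0} - 1.  An observation in a zero-probability cell makes the
    observed table incompatible with the null: the statistic is reported as
    infinite with method tag ``"gof-incompatible"``.
    """
    O = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    if O.shape != p.shape:
        raise ValueError("observed and probabilities must have the same size")
    _check_probs(p)
    n = O.sum()
    if n <= 0:
        raise ValueError("observed total must be positive")
    mask = p > 0
    df = int(mask.sum()) - 1
    if df < 1:
        raise ValueError("need at least two cells with positive probability")
    if (O[~mask] > 0).any():
        return TestResult(float("inf"), df, 0.0, "gof-incompatible")
    E = n * p[mask]
    stat = float(((O[mask] - E) ** 2 / E).sum())
    return TestResult(stat, df, float(sps.chi2.sf(stat, df)), "gof")


def _reduce_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("independence test needs a two-way table")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def chi2_independence(table) -> TestResult:
    """Chi-squared test of independence for a two-way table.

    All-zero rows and columns are dropped before computing expectations
    E_ab = row_a * col_b / n and df = (rows-1)(cols-1); a table degenerate
    after reduction (a single nonzero row or column) raises ``ValueError``.
    """
    t = _reduce_table(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("degenerate table: fewer than 2 nonzero rows or columns")
    n = t.sum()
    E = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    stat = float(((t - E) ** 2 / E).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult(stat, df, float(sps.chi2.sf(stat, df)), "independence")


def _independence_stats(draws: np.ndarray) -> np.ndarray:
    """Vectorized independence chi2 for a (B, r, c) stack of tables."""
    n = draws.sum(axis=(1, 2), keepdims=True)
    rows = draws.sum(axis=2, keepdims=True)
    cols = draws.sum(axis=1, keepdims=True)
    E = rows * cols / n
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(E > 0, (draws - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    return contrib.sum(axis=(1, 2))


def mc_null_pvalue(
    observed,
    reference=None,
    *,
    independence: bool = False,
    B: int = 9999,
    seed: int | None = None,
) -> TestResult:
    """Monte-Carlo p-value for the chi-squared statistic.

    GOF mode (default): B tables are drawn from Multinomial(n, reference)
    and the GOF statistic recomputed on each.  Independence mode: tables
    are drawn from the product-of-margins multinomial and the independence
    statistic (margins re-estimated per draw) recomputed.  In both modes
    p = (1 + #{draws >= observed}) / (B + 1), so p >= 1/(B+1) and the
    result is reproducible given the seed.
    """
    if seed is None:
        raise ValueError("mc_null_pvalue requires an explicit seed")
    if B < 99:
        raise ValueError("B must be >= 99")
    rng = np.random.default_rng(seed)
    if independence:
        t = _reduce_table(observed)
        base = chi2_independence(t)
        n = int(t.sum())
        p0 = np.outer(t.sum(axis=1), t.sum(axis=0)).ravel() / (n * n)
        p0 = p0 / p0.sum()
        draws = rng.multinomial(n, p0, size=B).reshape(B, *t.shape)
        stats = _independence_stats(draws.astype(float))
        method = "independence-mc"
    else:
        if reference is None:
            raise ValueError("GOF mode requires reference probabilities")
        base = chi2_gof(observed, reference)
        O = np.asarray(observed, dtype=float).ravel()
        p = np.asarray(reference, dtype=float).ravel()
        n = int(O.sum())
        ps = p[p > 0]
        # draw in sorted-probability order so the p-value is invariant to
        # category permutation (numpy's multinomial is order-dependent)
        ps = np.sort(ps)
        draws = rng.multinomial(n, ps / ps.sum(), size=B)
        E = n * ps
        stats = ((draws - E) ** 2 / E).sum(axis=1)
        method = "gof-mc"
    p_mc = float((1 + (stats >= base.statistic).sum()) / (B + 1))
    return TestResult(base.statistic, base.df, base.p_asymptotic, method, p_mc, B, seed)


def global_gof(
    observed,
    probabilities,
    B: int = 9999,
    seed: int | None = None,
    min_expected: float = 5.0,
) -> TestResult:
    """GOF test with the small-expected-count trigger.

    The asymptotic chi-squared p-value is used when every expected count on
    the support is >= *min_expected*; otherwise the Monte-Carlo null is
    invoked (a seed is then required).
    """
    O = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    E = O.sum() * p[p > 0]
    if (E >= min_expected).all():
        return chi2_gof(O, p)
    return mc_null_pvalue(O, p, B=B, seed=seed)


def restrict_to_support(observed, probabilities) -> tuple[np.ndarray, np.ndarray, int]:
    """Restrict counts to the reference support and renormalize.

    Returns (observed-on-support, renormalized probabilities, count falling
    outside the support).  Used when comparing read tables against a
    genome-digest reference whose empty cells can legitimately receive a
    read through midpoint-binning discretisation.
    """
    O = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(probabilities, dtype=float).ravel()
    if O.shape != p.shape:
        raise ValueError("observed and probabilities must have the same size")
    mask = p > 0
    outside = int(O[~mask].sum())
    return O[mask], p[mask] / p[mask].sum(), outside


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    p_(r) * m / r with cumulative-minimum monotonization from the largest
    rank down, capped at 1; output order matches input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def binom_two_sided(k, n, p, *, relative_tol: float = 1e-7) -> np.ndarray:
    """Exact two-sided binomial p-value, minimum-likelihood convention.

    p = sum of Binomial(n, p) outcome probabilities that do not exceed the
    probability of the observed outcome (within a small relative tolerance,
    matching the convention of scipy's ``binomtest``).  Vectorized over
    cells; a zero-probability cell with a positive count reports the
    smallest positive float.
    """
    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    p = np.broadcast_to(np.asarray(p, dtype=float), k.shape).copy()
    n = np.broadcast_to(np.asarray(n, dtype=np.int64), k.shape)
    out = np.ones(k.shape, dtype=float)
    out[(p == 0.0) & (k > 0)] = _MIN_P
    out[(p == 1.0) & (k < n)] = _MIN_P
    g = (p > 0.0) & (p < 1.0)
    if not g.any():
        return out
    kg, ng, pg = k[g], n[g], p[g]
    target = sps.binom.logpmf(kg, ng, pg) + np.log1p(relative_tol)
    mode = np.minimum(np.floor((ng + 1) * pg), ng).astype(np.int64)
    pv = np.zeros(kg.shape)

    right = kg >= mode
    # upper tail from k, plus the matching lower tail
    pv[right] = sps.binom.sf(kg[right] - 1, ng[right], pg[right])
    lo = np.zeros(kg.shape, dtype=np.int64)
    hi = np.where(right, mode - 1, np.int64(-1))  # search only on the right side
    while True:
        active = lo <= hi
        if not active.any():
            break
        mid = (lo + hi) // 2
        le = np.zeros(kg.shape, dtype=bool)
        le[active] = (
            sps.binom.logpmf(mid[active], ng[active], pg[active]) <= target[active]
        )
        lo = np.where(active & le, mid + 1, lo)
        hi = np.where(active & ~le, mid - 1, hi)
    j = hi  # largest index left of the mode with pmf <= pmf(k)
    has = right & (j >= 0)
    pv[has] += sps.binom.cdf(j[has], ng[has], pg[has])

    left = ~right
    pv[left] = sps.binom.cdf(kg[left], ng[left], pg[left])
    lo = np.where(left, mode, np.int64(0))
    hi = np.where(left, ng, np.int64(-1))
    while True:
        active = lo <= hi
        if not active.any():
            break
        mid = (lo + hi) // 2
        le = np.zeros(kg.shape, dtype=bool)
        le[active] = (
            sps.binom.logpmf(mid[active], ng[active], pg[active]) <= target[active]
        )
        hi = np.where(active & le, mid - 1, hi)
        lo = np.where(active & ~le, mid + 1, lo)
    j = lo  # smallest index right of the mode with pmf <= pmf(k)
    has = left & (j <= ng)
    pv[has] += sps.binom.sf(j[has] - 1, ng[has], pg[has])

    out[g] = np.minimum(pv, 1.0)
    return out


def cell_tests(
    observed,
    probabilities,
    alpha: float = 0.05,
    method: str = "binomial",
) -> list[CellResult]:
    """Per-cell tests of O_cell against Binomial(n, p_cell), BH-corrected.

    The default per-cell statistic is the exact two-sided binomial test
    (minimum-likelihood convention); ``method="ztest"`` uses the
    standardized-residual normal approximation instead.  Directions are
    assigned only to cells whose BH-adjusted p falls below *alpha*, from
    the sign of observed - expected.
    """
    O = np.asarray(observed, dtype=np.int64)
    p = np.asarray(probabilities, dtype=float)
    if O.shape != p.shape:
        raise ValueError("observed and probabilities must have the same shape")
    n = int(O.sum())
    if n <= 0:
        raise ValueError("observed total must be positive")
    shape = O.shape
    Of, pf = O.ravel(), p.ravel()
    E = n * pf
    if method == "binomial":
        p_raw = binom_two_sided(Of, n, pf)
    elif method == "ztest":
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(n * pf * (1 - pf))
            z = np.where(se > 0, (Of - E) / np.where(se > 0, se, 1.0), 0.0)
        p_raw = 2 * sps.norm.sf(np.abs(z))
        p_raw[(pf == 0) & (Of > 0)] = _MIN_P
        p_raw[(pf == 1) & (Of < n)] = _MIN_P
        p_raw = np.minimum(p_raw, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    p_adj = bh_adjust(p_raw)
    results = []
    for flat, index in enumerate(np.ndindex(shape)):
        diff = Of[flat] - E[flat]
        if p_adj[flat] < alpha and diff > 0:
            direction = "over"
        elif p_adj[flat] < alpha and diff < 0:
            direction = "under"
        else:
            direction = "none"
        results.append(
            CellResult(index, int(Of[flat]), float(E[flat]), direction,
                       float(p_raw[flat]), float(p_adj[flat]))
        )
    return results


def expected_envelope(n: int, probabilities, level: float = 0.95):
    """Central binomial envelope for the expected count in each category.

    Per category the interval is [Binomial(n, p) quantile at (1-level)/2,
    quantile at 1-(1-level)/2]; these are marginal (not simultaneous)
    intervals.  Returns (lower, upper) integer arrays.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    a = (1 - level) / 2
    lower = sps.binom.ppf(a, n, p)
    upper = sps.binom.ppf(1 - a, n, p)
    lower = np.where(p == 0, 0, lower)
    upper = np.where(p == 0, 0, upper)
    return lower.astype(np.int64), upper.astype(np.int64)


def bootstrap_chromosome_stat(
    observed,
    r: int,
    n_boot: int = 1000,
    seed: int | None = None,
    mode: str = "independence",
    reference=None,
) -> BootstrapCI:
    """Bootstrap the chi2/df statistic over resampled chromosomes.

    Per replicate, *r* chromosomes are drawn with replacement from the S
    rows of the chromosome x region table and stacked into an r-row table
    (a chromosome drawn twice contributes its row with multiplicity 2;
    the chi2 value of the stacked table equals that of the
    multiplicity-summed table, while df counts the drawn rows:
    (r-1)(cols-1) for independence).  ``mode="independence"`` computes the
    chromosome x region independence chi2/df of the resampled table;
    ``mode="reference"`` computes the chi2/df of the resampled observed
    rows against the correspondingly resampled *reference* rows
    (restricted to the reference support, support cells counted with
    multiplicity in df).  Degenerate replicates (empty tables, fewer than
    two nonzero columns) are dropped and counted; more than 50% dropped is
    an error.  The interval is the 2.5/97.5 percentile over surviving
    replicates.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observed must be a chromosome x region table")
    S = obs.shape[0]
    if not 2 <= r <= S:
        raise ValueError(f"r must lie in [2, {S}]")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if mode == "reference":
        if reference is None:
            raise ValueError("reference mode needs a reference table")
        ref = np.asarray(reference, dtype=float)
        if ref.shape != obs.shape:
            raise ValueError("reference shape must match observed")
    elif mode != "independence":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    reps: list[float] = []
    dropped = 0
    for _ in range(n_boot):
        mult = np.bincount(rng.integers(0, S, size=r), minlength=S).astype(float)
        sel = mult > 0
        if mode == "independence":
            sub = obs[sel] * mult[sel, None]
            cols = sub.sum(axis=0) > 0
            n_sub = sub.sum()
            if n_sub <= 0 or int(cols.sum()) < 2:
                dropped += 1
                continue
            sub = sub[:, cols]
            E = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / n_sub
            stat = float(((sub - E) ** 2 / np.where(E > 0, E, 1.0) * (E > 0)).sum())
            df = (r - 1) * (int(cols.sum()) - 1)
            reps.append(stat / df)
        else:
            o_sub = (obs[sel] * mult[sel, None]).ravel()
            r_sub = (ref[sel] * mult[sel, None]).ravel()
            mask = r_sub > 0
            n_sub = o_sub[mask].sum()
            # support cells counted with the multiplicity of their chromosome
            df = int((mult[sel, None] * (ref[sel] > 0)).sum()) - 1
            if n_sub <= 0 or df < 1:
                dropped += 1
                continue
            E = n_sub * r_sub[mask] / r_sub[mask].sum()
            reps.append(float(((o_sub[mask] - E) ** 2 / E).sum()) / df)
    if dropped > n_boot / 2:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap replicates degenerate")
    arr = np.asarray(reps)
    lower, upper = np.percentile(arr, [2.5, 97.5])
    return BootstrapCI(r, n_boot, float(lower), float(upper), seed, dropped, arr)


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fraction_below(statistics, threshold: float | None = None) -> float:
    """Fraction of chi2 values strictly below *threshold*.

    The default threshold is the 95th percentile of the chi-squared
    distribution with 1 df (3.84 at two decimals), the limit against which
    per-cell chi2 contributions are conventionally judged.
    """
    x = np.asarray(statistics, dtype=float)
    if x.size == 0:
        raise ValueError("statistics must be non-empty")
    if threshold is None:
        threshold = CHI2_DF1_CRIT
    return float((x < threshold).mean())
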
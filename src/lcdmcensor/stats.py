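"""Test battery for censored distance sweeps.

At every censoring step the multi-group tests (Kruskal-Wallis; one-way
ANOVA F with and without the homogeneity-of-variances assumption, the
latter as Welch's heteroscedastic one-way test) ask whether any group
differs, and the pairwise tests (Wilcoxon rank sum, Welch's t) ask which
pairs differ and in which direction.  The two-sample Kolmogorov-Smirnov
test is available but carries a caveat inside a sweep: once it fires it
tends to stay significant at later steps by construction.  Pairwise
p-values can be Holm-adjusted across the pairs *within* a step; no
adjustment is made across steps, because the object of inference is the
consecutive range of distances over which significance persists.

The data regime is pooled samples in the thousands of voxels, so the
rank tests use midranks with tie-corrected normal / chi-square
approximations and no continuity correction (making the one-sided
p-values complementary).  A test that cannot be computed at a step
yields NaN there; sweeps never abort on a degenerate step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss

from .censoring import CensoringGrid, GroupedDistances, censor

MULTIGROUP_TESTS = ("kruskal_wallis", "anova_hov", "anova_welch")
PAIRWISE_TESTS = ("wilcoxon", "welch_t", "ks_two_sample")
_ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class TestSpec:
    """One test to run at every censoring step.

    For pairwise scope, ``pair`` names an ordered group pair and
    ``alternative='less'`` means the first-named group is stochastically
    smaller (or has the smaller mean).
    """

    __test__ = False  # not a pytest class, despite the name

    name: str
    alternative: str = "two_sided"
    pair: tuple | None = None

    def __post_init__(self):
        if self.name not in MULTIGROUP_TESTS + PAIRWISE_TESTS:
            raise ValueError(f"unknown test {self.name!r}")
        if self.alternative not in _ALTERNATIVES:
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.scope == "multigroup":
            if self.alternative != "two_sided":
                raise ValueError(f"{self.name} is multigroup: two_sided only")
            if self.pair is not None:
                raise ValueError(f"{self.name} is multigroup: no pair allowed")
        else:
            if self.pair is None or len(self.pair) != 2:
                raise ValueError(f"{self.name} is pairwise: needs an ordered pair")

    @property
    def scope(self) -> str:
        return "multigroup" if self.name in MULTIGROUP_TESTS else "pairwise"

    @property
    def pair_label(self) -> str:
        return "" if self.pair is None else f"{self.pair[0]}:{self.pair[1]}"


def default_specs(group_labels, alternatives=("less",)) -> list[TestSpec]:
    """Kruskal-Wallis + both ANOVA variants + all ordered-pair Wilcoxon/Welch t."""
    specs = [TestSpec(n) for n in MULTIGROUP_TESTS]
    for a, b in itertools.combinations(group_labels, 2):
        for alt in alternatives:
            specs.append(TestSpec("wilcoxon", alt, (a, b)))
            specs.append(TestSpec("welch_t", alt, (a, b)))
    return specs


# ---------------------------------------------------------------------------
# Individual tests.  All return a p-value in [0, 1], or NaN when the test is
# undefined on the given samples.

def _scipy_alt(alternative: str) -> str:
    return "two-sided" if alternative == "two_sided" else alternative


def kruskal_wallis(samples) -> float:
    """Kruskal-Wallis p-value (midranks, tie-corrected, chi-square reference).

    When every value across the groups is identical the statistic is 0 and
    p = 1; an empty group yields NaN.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        return float("nan")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 1.0  # H = 0 by definition; scipy's tie correction divides 0/0
    with np.errstate(invalid="ignore"):
        return float(ss.kruskal(*samples).pvalue)


def anova_f(samples, assume_hov: bool = True) -> float:
    """One-way ANOVA p-value; Welch's heteroscedastic variant when not HOV."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        return float("nan")
    if assume_hov:
        if sum(len(s) for s in samples) <= len(samples):
            return float("nan")
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            return 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ss.f_oneway(*samples).pvalue
        return float(p)
    if any(len(s) < 2 for s in samples) or all(np.ptp(s) == 0 for s in samples):
        return float("nan")  # Welch needs a variance estimate per group
    from statsmodels.stats.oneway import anova_oneway

    with np.errstate(invalid="ignore", divide="ignore"):
        res = anova_oneway(samples, use_var="unequal", welch_correction=True)
    return float(res.pvalue)


def wilcoxon_rank_sum(g1, g2, alternative: str = "two_sided",
                      method: str = "asymptotic") -> float:
    """Wilcoxon (Mann-Whitney) rank sum p-value.

    Default is the tie-corrected normal approximation without continuity
    correction, so the 'less' and 'greater' p-values sum to one.
    ``method='exact'`` enables the exact small-sample null distribution
    (no ties), used by test oracles only.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        return float("nan")
    pooled = np.concatenate([g1, g2])
    if np.all(pooled == pooled[0]):
        return float("nan") if alternative != "two_sided" else 1.0
    with np.errstate(invalid="ignore"):
        res = ss.mannwhitneyu(g1, g2, alternative=_scipy_alt(alternative),
                              method=method, use_continuity=False)
    return float(res.pvalue)


def welch_t(g1, g2, alternative: str = "two_sided") -> float:
    """Welch's unequal-variance t-test p-value (Welch-Satterthwaite df)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        return float("nan")
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        if g1[0] == g2[0]:
            return 1.0 if alternative == "two_sided" else 0.5
        return float("nan")  # zero spread, nonzero difference: t undefined
    with np.errstate(invalid="ignore", divide="ignore"):
        res = ss.ttest_ind(g1, g2, equal_var=False,
                           alternative=_scipy_alt(alternative))
    return float(res.pvalue)


def ks_two_sample(g1, g2, alternative: str = "two_sided",
                  method: str = "auto") -> float:
    """Two-sample Kolmogorov-Smirnov p-value.

    Inside a censoring sweep this test is misleading: it flags the first
    step where distributions differ and then tends to stay significant at
    all later steps because censored sets only grow.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        return float("nan")
    res = ss.ks_2samp(g1, g2, alternative=_scipy_alt(alternative), method=method)
    return float(res.pvalue)


def lilliefors(sample) -> float:
    """Lilliefors normality p-value (K-S with estimated mean and variance).

    Returns NaN for n < 4 or a constant sample.  The reference tables are
    bounded, so extreme evidence is reported as the table limit p = 0.001.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4 or np.ptp(x) == 0:
        return float("nan")
    from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

    return float(sm_lilliefors(x, dist="norm", pvalmethod="table")[1])


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment, capped at 1, with NaN passed through."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.sum():
        from statsmodels.stats.multitest import multipletests

        out[finite] = multipletests(p[finite], method="holm")[1]
    return out


_TEST_FUNCS = {
    "kruskal_wallis": lambda groups, alt: kruskal_wallis(groups),
    "anova_hov": lambda groups, alt: anova_f(groups, assume_hov=True),
    "anova_welch": lambda groups, alt: anova_f(groups, assume_hov=False),
    "wilcoxon": wilcoxon_rank_sum,
    "welch_t": welch_t,
    "ks_two_sample": ks_two_sample,
}


# ---------------------------------------------------------------------------
# Sweep


@dataclass
class SweepResult:
    """Per-step p-values for every requested test.

    ``table`` is long-format with columns k, gamma_mm, test, pair,
    alternative, p, p_holm, reliable, n_per_group.
    """

    table: pd.DataFrame
    grid: CensoringGrid
    group_labels: list

    def curve(self, spec: TestSpec) -> pd.DataFrame:
        """The p-value curve (one row per step) for one test spec."""
        t = self.table
        m = ((t["test"] == spec.name) & (t["pair"] == spec.pair_label)
             & (t["alternative"] == spec.alternative))
        return t[m].sort_values("k").reset_index(drop=True)


@dataclass(frozen=True)
class PValueCurve:
    """A single test's p-values over the censoring steps."""

    spec: TestSpec
    k: np.ndarray
    gamma: np.ndarray
    p: np.ndarray
    p_holm: np.ndarray | None = None


@dataclass(frozen=True)
class SignificanceRun:
    """A maximal interval of consecutive significant censoring steps."""

    spec: TestSpec
    direction: str
    d_start: float
    d_end: float
    steps: int
    reliable: bool


def run_sweep(
    grouped: GroupedDistances,
    grid: CensoringGrid,
    specs: list[TestSpec] | None = None,
    holm: bool = True,
    steps=None,
) -> SweepResult:
    """Run every test in ``specs`` at every censoring step.

    ``steps`` restricts evaluation to a subset of step indices (the full
    grid by default).  Holm adjustment, when enabled, is applied across
    the pairwise comparisons sharing (step, test, alternative) — never
    across steps.
    """
    labels = grouped.group_labels
    if specs is None:
        specs = default_specs(labels)
    if not specs:
        raise ValueError("specs must be nonempty")
    thresholds = grid.thresholds
    if steps is None:
        steps = range(len(thresholds))
    rows = []
    for k in steps:
        gamma = thresholds[k]
        cens = censor(grouped, gamma)
        counts = cens.counts()
        n_str = "|".join(f"{g}={counts[g]}" for g in labels)
        for spec in specs:
            if spec.scope == "multigroup":
                args = ([cens.groups[g] for g in labels], spec.alternative)
            else:
                a, b = spec.pair
                args = (cens.groups[a], cens.groups[b], spec.alternative)
            p = _TEST_FUNCS[spec.name](*args)
            rows.append((int(k), float(gamma), spec.name, spec.pair_label,
                         spec.alternative, p, np.nan,
                         grid.reliable(gamma), n_str))
    table = pd.DataFrame(rows, columns=["k", "gamma_mm", "test", "pair",
                                        "alternative", "p", "p_holm",
                                        "reliable", "n_per_group"])
    if holm:
        pairwise = table["test"].isin(PAIRWISE_TESTS)
        for _, idx in table[pairwise].groupby(["k", "test", "alternative"]).groups.items():
            table.loc[idx, "p_holm"] = holm_adjust(table.loc[idx, "p"].to_numpy())
    return SweepResult(table, grid, labels)


def extract_runs(
    sweep: SweepResult,
    alpha: float = 0.05,
    min_run_steps: int = 5,
    use_adjusted: bool = False,
) -> list[SignificanceRun]:
    """Maximal runs of consecutive significant steps per p-value curve.

    A two-sided curve is significant where p < alpha.  A one-sided curve
    is additionally read against the 1 - alpha mirror line: p > 1 - alpha
    is reported as a run in the opposite direction.  Runs never span NaN
    steps or gaps in the evaluated step indices, and runs shorter than
    ``min_run_steps`` are discarded.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_run_steps < 1:
        raise ValueError("min_run_steps must be >= 1")
    col = "p_holm" if use_adjusted else "p"
    runs: list[SignificanceRun] = []
    tab = sweep.table
    for (name, pair, alt), sub in tab.groupby(["test", "pair", "alternative"]):
        sub = sub.sort_values("k")
        spec = TestSpec(name, alt, tuple(pair.split(":")) if pair else None)
        p = sub[col].to_numpy(dtype=float)
        kk = sub["k"].to_numpy()
        gam = sub["gamma_mm"].to_numpy()
        directions = [(p < alpha, alt)]
        if alt in ("less", "greater"):
            opposite = "greater" if alt == "less" else "less"
            directions.append((p > 1 - alpha, opposite))
        for sig, direction in directions:
            sig = sig & np.isfinite(p)
            start = None
            for i in range(len(sig) + 1):
                contiguous = (i < len(sig) and sig[i]
                              and (start is None or kk[i] == kk[i - 1] + 1))
                if contiguous and start is None:
                    start = i
                elif not contiguous and start is not None:
                    end = i - 1
                    if end - start + 1 >= min_run_steps:
                        runs.append(SignificanceRun(
                            spec, direction, float(gam[start]), float(gam[end]),
                            end - start + 1,
                            sweep.grid.reliable(gam[start])))
                    start = i if (i < len(sig) and sig[i]) else None
    return runs


def runs_table(runs: list[SignificanceRun]) -> pd.DataFrame:
    rows = [(r.spec.name, r.spec.pair_label, r.direction,
             round(r.d_start, 6), round(r.d_end, 6), r.steps, r.reliable)
            for r in runs]
    return pd.DataFrame(rows, columns=["test", "pair", "direction",
                                       "d_start_mm", "d_end_mm", "steps",
                                       "reliable"])


# ---------------------------------------------------------------------------
# Kernel density export


def kernel_density_export(
    grouped: GroupedDistances,
    lo: float = -0.5,
    hi: float = 5.5,
    n_points: int = 601,
    fallback_bandwidth: float = 0.1,
):
    """Gaussian-kernel density estimate per group on a shared grid.

    Bandwidth follows the normal-reference (Scott) rule and is recorded in
    the output.  The evaluation grid spans the retention interval,
    extended by four bandwidths beyond the data range so each density
    integrates to ~1 on the grid.  Degenerate groups (n < 2 or zero
    spread) fall back to a fixed ``fallback_bandwidth`` (mm); empty
    groups are omitted with a warning.

    Returns (x, densities, bandwidths): the shared grid, a dict
    group -> density array, and a dict group -> bandwidth (mm).
    """
    import warnings

    kdes, bws = {}, {}
    for g, d in grouped.groups.items():
        d = np.asarray(d, dtype=float)
        if len(d) == 0:
            warnings.warn(f"group {g!r} is empty; omitted from density export")
            continue
        if len(d) < 2 or np.ptp(d) == 0:
            bws[g] = fallback_bandwidth
            kdes[g] = ("manual", d)
        else:
            kde = ss.gaussian_kde(d)  # Scott's normal-reference factor
            bws[g] = float(kde.factor * d.std(ddof=1))
            kdes[g] = ("kde", kde)
    if not kdes:
        raise ValueError("no nonempty groups to estimate densities for")
    span_lo, span_hi = lo, hi
    for g, d in grouped.groups.items():
        if g in bws and len(d):
            span_lo = min(span_lo, float(np.min(d)) - 4 * bws[g])
            span_hi = max(span_hi, float(np.max(d)) + 4 * bws[g])
    x = np.linspace(span_lo, span_hi, n_points)
    densities = {}
    for g, (kind, obj) in kdes.items():
        if kind == "kde":
            densities[g] = obj(x)
        else:
            h = bws[g]
            densities[g] = np.mean(
                [ss.norm.pdf(x, loc=v, scale=h) for v in obj], axis=0)
    return x, densities, bws
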
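"""Division-symmetry / fate calls and contingency statistics.

At the 8->16 division a mother blastomere divides **symmetrically** when
both daughters re-form an apical domain, **asymmetrically** when exactly
one does.  A 16-cell-stage daughter is assigned to the trophectoderm (TE)
when it is an outer cell positive for the TE reporter; all other cells are
inner-cell-mass (ICM).

The module also carries the standard tests used on the resulting
contingency tables: a two-tailed Fisher exact test (probability-mass
convention), a pooled two-proportion z-test, a Monte-Carlo binomial
goodness-of-fit test for the cell-autonomy of early polarization, and the
normality-driven test-selection decision tree.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateTestError,
    InsufficientDataError,
    InvalidInputError,
    MissingInputError,
)

__all__ = [
    "ContingencyResult",
    "BinomialFitResult",
    "division_symmetry",
    "te_assignment",
    "proportion_table",
    "proportions_from_counts",
    "fisher_exact",
    "two_proportion_ztest",
    "binomial_independence_test",
    "test_selector",
]


@dataclass
class ContingencyResult:
    """A 2x2 contingency table with per-group proportions and a test."""

    table: np.ndarray                    # rows = groups, cols = (success, failure)
    group_labels: tuple
    proportions_pct: tuple               # 100 * successes / group total
    test_name: str = ""
    statistic: float = np.nan
    p_value: float = np.nan
    notes: list = field(default_factory=list)

    def display_pct(self) -> tuple:
        """Proportions rounded to one decimal, as printed in reports."""
        return tuple(round(p, 1) for p in self.proportions_pct)


@dataclass
class BinomialFitResult:
    """Goodness of fit of per-embryo EP counts to Binomial(n_cells, p-hat)."""

    p_hat: float
    observed: np.ndarray        # counts of embryos with k = 0..n_cells EP cells
    expected: np.ndarray
    statistic: float
    p_value: float | None
    n_replicates: int
    note: str = ""


def division_symmetry(daughter1_polar: bool, daughter2_polar: bool) -> str:
    """'symmetric', 'asymmetric', or 'anomalous' (neither daughter polar).

    Anomalous divisions are recorded but excluded from two-class tables.
    """
    n = int(bool(daughter1_polar)) + int(bool(daughter2_polar))
    return {2: "symmetric", 1: "asymmetric", 0: "anomalous"}[n]


def te_assignment(position: str, marker_positive: bool) -> str:
    """TE iff the daughter is an outer, reporter-positive cell; else ICM."""
    if position not in ("outer", "inner"):
        raise MissingInputError(f"position must be 'outer' or 'inner', got {position!r}")
    return "TE" if (position == "outer" and bool(marker_positive)) else "ICM"


def proportions_from_counts(x1: int, n1: int, x2: int, n2: int,
                            labels=("group1", "group2")) -> ContingencyResult:
    """Build a ContingencyResult (with Fisher test) from raw counts."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    return _finish_table(table, labels)


def _finish_table(table: np.ndarray, labels) -> ContingencyResult:
    if np.any(table < 0):
        raise InvalidInputError("counts must be non-negative")
    totals = table.sum(axis=1)
    if np.any(totals == 0):
        raise InvalidInputError("empty group: proportion undefined")
    props = tuple(100.0 * table[i, 0] / totals[i] for i in range(2))
    p = fisher_exact(table)
    return ContingencyResult(
        table=table,
        group_labels=tuple(labels),
        proportions_pct=props,
        test_name="fisher_exact_two_tailed",
        statistic=float((table[0, 0] * table[1, 1]) / max(table[0, 1] * table[1, 0], 1)),
        p_value=p,
    )


def proportion_table(records: pd.DataFrame, group_field: str, outcome_field: str,
                     success=True) -> ContingencyResult:
    """Per-group success proportions for a binary outcome over two groups."""
    groups = sorted(records[group_field].dropna().unique())
    if len(groups) != 2:
        raise InvalidInputError(f"need exactly 2 groups, got {groups}")
    rows = []
    for g in groups:
        sub = records.loc[records[group_field] == g, outcome_field]
        x = int((sub == success).sum())
        rows.append([x, int(len(sub) - x)])
    return _finish_table(np.array(rows), groups)


def fisher_exact(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table.

    Probability-mass convention: the p-value is the sum of probabilities of
    all tables (with the observed margins) no more probable than the
    observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidInputError("table must be 2x2")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise InvalidInputError("counts must be non-negative integers")
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p)


def two_proportion_ztest(x1, n1, x2, n2):
    """Pooled two-proportion z-test; returns (z, two-tailed p).

    Accepts scalars or aligned arrays (vectorized for simulation studies).
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise InvalidInputError("group sizes must be positive")
    pooled = (x1 + x2) / (n1 + n2)
    if np.any((pooled <= 0) | (pooled >= 1)):
        raise DegenerateTestError("pooled proportion must lie strictly in (0, 1)")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    if np.ndim(z) == 0:
        return float(z), float(p)
    return z, p


def binomial_independence_test(
    ep_counts,
    cells_per_embryo: int = 8,
    *,
    n_replicates: int = 10000,
    rng=None,
) -> BinomialFitResult:
    """Does the per-embryo EP-count distribution match independent cells?

    Fits p-hat = total EP / total cells, compares the observed embryo-count
    histogram over k = 0..cells_per_embryo with Binomial(cells, p-hat)
    expectations via a chi-square statistic, and calibrates the p-value by
    parametric bootstrap (p-hat re-estimated per replicate) to respect the
    small expected counts in the upper tail.
    """
    counts = np.asarray(list(ep_counts), int)
    if counts.size < 10:
        raise InsufficientDataError("need at least 10 embryos")
    if counts.min() < 0 or counts.max() > cells_per_embryo:
        raise InvalidInputError("EP counts outside [0, cells_per_embryo]")
    n = counts.size
    m = cells_per_embryo
    p_hat = counts.sum() / (n * m)
    ks = np.arange(m + 1)
    obs = np.bincount(counts, minlength=m + 1)
    if p_hat == 0.0:
        return BinomialFitResult(
            p_hat=0.0, observed=obs, expected=np.eye(1, m + 1, 0)[0] * n,
            statistic=0.0, p_value=None, n_replicates=0,
            note="degenerate: no EP cells observed; test skipped",
        )
    rng = np.random.default_rng(rng)

    def chi2(hist, p):
        exp = n * sps.binom.pmf(ks, m, p)
        keep = exp > 0
        return ((hist[keep] - exp[keep]) ** 2 / exp[keep]).sum(), exp

    stat, expected = chi2(obs, p_hat)
    sims = rng.binomial(m, p_hat, size=(n_replicates, n))
    sim_stats = np.empty(n_replicates)
    for r in range(n_replicates):
        h = np.bincount(sims[r], minlength=m + 1)
        sim_stats[r], _ = chi2(h, h @ ks / (n * m) if h @ ks else p_hat)
    p_value = (1.0 + np.sum(sim_stats >= stat)) / (n_replicates + 1.0)
    return BinomialFitResult(
        p_hat=float(p_hat),
        observed=obs,
        expected=expected,
        statistic=float(stat),
        p_value=float(p_value),
        n_replicates=n_replicates,
    )


def test_selector(groups, alpha: float = 0.05) -> str:
    """Choose the significance test the analysis decision tree prescribes.

    Normality of every group is assessed with D'Agostino's K-squared test;
    normal data get a t-test (Welch-corrected when an F-test finds unequal
    variances) or a one-way ANOVA for >2 groups; non-normal data get a
    Mann-Whitney U or Kruskal-Wallis (with Dunn post-hoc) instead.  Groups
    too small for the normality test (n < 8) default to the rank-based
    branch.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    k = len(groups)
    if any(len(g) < 8 for g in groups):
        return "mann_whitney_u" if k == 2 else "kruskal_wallis_dunn"
    normal = all(sps.normaltest(g).pvalue > alpha for g in groups)
    if not normal:
        return "mann_whitney_u" if k == 2 else "kruskal_wallis_dunn"
    if k > 2:
        return "one_way_anova"
    v1, v2 = np.var(groups[0], ddof=1), np.var(groups[1], ddof=1)
    if v1 <= 0 or v2 <= 0:
        return "t_test"
    f = v1 / v2
    d1, d2 = len(groups[0]) - 1, len(groups[1]) - 1
    p_f = 2.0 * min(sps.f.cdf(f, d1, d2), sps.f.sf(f, d1, d2))
    return "welch_t_test" if p_f < alpha else "t_test"
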
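"""Group comparison and cross-platform concordance statistics.

Per-CpG methylation proportions are compared across sample groups with the
Kruskal-Wallis rank test (tie-corrected H, chi-square p with k-1 degrees of
freedom).  With the small replicate numbers typical of bisulphite profiling
(three biological replicates per group) the chi-square approximation is poor,
so for total N <= 10 the exact permutation p-value is computed by enumerating
every assignment of the pooled values to the group sizes, and that exact p is
the significance source.  No multiple-testing correction is applied across
CpGs; per-CpG flags are raw p < alpha.

Concordance between trace-derived estimates and pyrosequencing percent
methylation is summarised by ordinary least squares (slope, intercept, R²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import LocusProfile

logger = logging.getLogger(__name__)

#: largest pooled N for which the exact permutation p-value is computed
EXACT_N_MAX = 10


class NotAssessableError(ValueError):
    """Raised when a statistic is undefined on the given data."""


@dataclass
class GroupComparison:
    """Kruskal-Wallis comparison of one CpG across groups.

    ``p_value`` is the significance source: the exact permutation p when
    available (N <= EXACT_N_MAX), else the chi-square approximation.
    """

    groups: dict[str, list[float]]
    H: float
    df: int
    p_chisq: float
    p_exact: Optional[float]
    alpha: float

    @property
    def p_value(self) -> float:
        return self.p_exact if self.p_exact is not None else self.p_chisq

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class ConcordanceResult:
    n: int
    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]
    assessable: bool = True


def _h_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    """Tie-corrected H from pooled midranks split consecutively by sizes."""
    n_total = len(ranks)
    h = 0.0
    start = 0
    for size in sizes:
        rank_sum = ranks[start : start + size].sum()
        h += rank_sum * rank_sum / size
        start += size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    return h / tie_term


def _tie_term(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return correction


def exact_kruskal_p(groups: Sequence[Sequence[float]], h_observed: float) -> float:
    """Exact permutation p: fraction of group assignments with H >= observed.

    Enumerates every way of assigning the pooled values to groups of the given
    sizes.  Ranks are computed once on the pooled sample, so ties are handled
    identically in every permutation.
    """
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    n = len(pooled)
    tie = _tie_term(pooled)
    if tie == 0.0:  # all values identical: H == 0 in every permutation
        return 1.0
    ranks = sps.rankdata(pooled)
    count = 0
    total = 0
    for assignment in _assignments(tuple(range(n)), sizes):
        perm_ranks = ranks[np.fromiter(assignment, dtype=int)]
        if _h_statistic(perm_ranks, sizes, tie) >= h_observed - 1e-12:
            count += 1
        total += 1
    return count / total


def _assignments(indices: tuple[int, ...], sizes: Sequence[int]):
    """Yield each split of ``indices`` into consecutive groups of ``sizes``."""
    if len(sizes) == 1:
        yield indices
        return
    for first in combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(first))
        for tail in _assignments(rest, sizes[1:]):
            yield first + tail


def kruskal_wallis(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
    exact_n_max: int = EXACT_N_MAX,
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis test across >= 2 groups.

    All-identical pooled values give H = 0, p = 1 (the tie correction would
    otherwise degenerate).  For total N <= ``exact_n_max`` the exact
    permutation p-value is also computed and used for significance.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i + 1}": g for i, g in enumerate(groups)}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) == 0 for a in arrays.values()):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(list(arrays.values()))
    if len(pooled) < 3:
        raise ValueError("need total N >= 3")
    df = len(arrays) - 1
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            {k: list(v) for k, v in arrays.items()}, 0.0, df, 1.0, 1.0, alpha
        )
    h, p_chisq = sps.kruskal(*arrays.values())
    p_exact = None
    if len(pooled) <= exact_n_max:
        p_exact = exact_kruskal_p(list(arrays.values()), h)
    return GroupComparison(
        {k: list(v) for k, v in arrays.items()}, float(h), df, float(p_chisq), p_exact, alpha
    )


def compare_profile(
    profile: LocusProfile,
    mode: str = "overall",
    control: str = "control",
    alpha: float = 0.05,
    exact_n_max: int = EXACT_N_MAX,
) -> pd.DataFrame:
    """Per-CpG Kruskal-Wallis tests over a locus profile.

    Modes: ``overall`` tests all groups jointly; ``pooled`` tests the control
    group against all other samples pooled; ``pairwise`` tests the control
    against each other group separately (long format, one row per contrast).
    Sites where any group has no finite value are not assessable (p NaN).
    The resulting table is attached to ``profile.stats`` for overall/pooled.
    """
    if mode not in {"overall", "pooled", "pairwise"}:
        raise ValueError(f"unknown contrast mode {mode!r}")
    by_group: dict[str, list[str]] = {}
    for sample, group in profile.groups.items():
        by_group.setdefault(group, []).append(sample)
    if mode in {"pooled", "pairwise"} and control not in by_group:
        raise ValueError(f"control group {control!r} not present in profile groups")

    contrasts: list[tuple[str, dict[str, list[str]]]] = []
    if mode == "overall":
        contrasts.append(("overall", by_group))
    elif mode == "pooled":
        others = [s for g, ss in by_group.items() if g != control for s in ss]
        contrasts.append(
            (f"{control}_vs_pooled", {control: by_group[control], "pooled": others})
        )
    else:
        for group, samples in by_group.items():
            if group != control:
                contrasts.append(
                    (
                        f"{control}_vs_{group}",
                        {control: by_group[control], group: samples},
                    )
                )

    rows = []
    for tss_relative, row in profile.proportions.iterrows():
        for name, groups in contrasts:
            values = {
                g: [row[s] for s in samples if np.isfinite(row[s])]
                for g, samples in groups.items()
            }
            base = {"tss_relative": tss_relative, "contrast": name}
            if any(len(v) == 0 for v in values.values()) or sum(map(len, values.values())) < 3:
                rows.append(
                    {**base, "H": np.nan, "df": np.nan, "p_chisq": np.nan,
                     "p_exact": np.nan, "p_value": np.nan, "significant": False,
                     "assessable": False}
                )
                continue
            cmp = kruskal_wallis(values, alpha=alpha, exact_n_max=exact_n_max)
            rows.append(
                {**base, "H": cmp.H, "df": cmp.df, "p_chisq": cmp.p_chisq,
                 "p_exact": np.nan if cmp.p_exact is None else cmp.p_exact,
                 "p_value": cmp.p_value, "significant": cmp.significant,
                 "assessable": True}
            )
    table = pd.DataFrame(rows).set_index("tss_relative")
    if mode in {"overall", "pooled"}:
        profile.stats = table
    return table


def fraction_significant(
    p_values: Iterable[float] | pd.DataFrame, alpha: float = 0.05
) -> float:
    """Fraction of assessable per-CpG comparisons with p < alpha.

    Accepts an iterable of p-values (NaN = not assessable) or a comparison
    table with a ``p_value`` column.  Not-assessable sites are excluded from
    the denominator (logged); with none assessable the fraction is undefined.
    """
    if isinstance(p_values, pd.DataFrame):
        p_values = p_values["p_value"]
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        raise NotAssessableError("no comparisons supplied")
    assessable = np.isfinite(p)
    if not assessable.any():
        raise NotAssessableError("no assessable comparisons")
    n_excluded = int((~assessable).sum())
    if n_excluded:
        logger.info("fraction_significant: %d not-assessable sites excluded", n_excluded)
    return float((p[assessable] < alpha).sum() / assessable.sum())


def concordance(
    trace_percent: Sequence[float], pyro_percent: Sequence[float]
) -> ConcordanceResult:
    """OLS concordance between trace-derived and pyrosequencing percentages.

    Returns slope, intercept and R² = 1 - SS_res/SS_tot; not assessable when
    either variable is constant or fewer than 3 pairs are given.
    """
    x = np.asarray(trace_percent, dtype=float)
    y = np.asarray(pyro_percent, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired value arrays must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ConcordanceResult(n, None, None, None, assessable=False)
    fit = sps.linregress(x, y)
    return ConcordanceResult(
        n, float(fit.slope), float(fit.intercept), float(fit.rvalue**2), assessable=True
    )
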
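"""Group-comparison statistics: one-way ANOVA, Duncan's multiple range
test with a letter display, the equal-variance two-tailed t-test, and
the 2x2 Pearson chi-square.

Duncan's multiple range test compares ranked group means stepwise. The
least significant range for a stretch spanning ``p`` ordered means is

    R_p = q(1 - (1 - alpha)^(p - 1), p, df_error) * sqrt(MSE / n_h)

where ``q`` is the studentized-range quantile at Duncan's special
protection level and ``n_h`` is the harmonic mean of the two compared
group sizes (the Kramer extension for unequal n). Comparisons are
protected stepwise: a range is never declared significant when it lies
inside a wider non-significant range. Groups sharing any letter in the
display are not significantly different at ``alpha``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from polyacomp.errors import DegenerateInputError


@dataclass
class GroupSample:
    """A labelled sample of per-species values (contents or ratios)."""

    group_id: str
    values: list[float]

    def __post_init__(self):
        self.values = [float(v) for v in self.values]
        if not self.values:
            raise ValueError(f"group {self.group_id!r} has no values")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"group {self.group_id!r} has non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class AnovaResult:
    F: float
    p: float
    mse: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    degenerate: bool = False


def anova_oneway(groups: Sequence[GroupSample]) -> AnovaResult:
    """Classical fixed-effects one-way decomposition.

    Degenerate case (zero between- AND within-group variance) yields
    F=0, p=1 with the ``degenerate`` flag set.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n_total = sum(g.n for g in groups)
    k = len(groups)
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = sum(sum(g.values) for g in groups) / n_total
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ssw = sum(sum((v - g.mean) ** 2 for v in g.values) for g in groups)
    df_b, df_w = k - 1, n_total - k
    msb, msw = ssb / df_b, ssw / df_w
    means = {g.group_id: g.mean for g in groups}
    if ssw == 0 and ssb == 0:
        return AnovaResult(0.0, 1.0, 0.0, df_b, df_w, means, degenerate=True)
    if ssw == 0:
        return AnovaResult(math.inf, 0.0, 0.0, df_b, df_w, means, degenerate=True)
    F = msb / msw
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F, p, msw, df_b, df_w, means)


@lru_cache(maxsize=4096)
def duncan_critical_q(alpha: float, span: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level for a span."""
    level = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1.0 - level, span, df))


@dataclass
class DuncanResult:
    """Ranked means with their minimal shared-letter display."""

    order: list[str]                    # group ids by descending mean
    means: dict[str, float]
    letters: dict[str, str]
    alpha: float
    mse: float
    df_error: int
    nonsig: dict[tuple[str, str], bool] = field(default_factory=dict)


def duncan_mrt(
    groups: Sequence[GroupSample],
    alpha: float = 0.05,
    anova: Optional[AnovaResult] = None,
) -> DuncanResult:
    """Duncan's multiple range test over the supplied groups.

    Shares MSE and error df with the one-way ANOVA on the same data
    (computed here when not supplied). With zero MSE the comparison
    degenerates to exact equality of means.
    """
    if len(groups) < 2:
        raise ValueError("Duncan's test needs at least 2 groups")
    if anova is None:
        anova = anova_oneway(groups)
    ranked = sorted(groups, key=lambda g: (-g.mean, g.group_id))
    k = len(ranked)
    df = anova.df_within
    mse = anova.mse

    # nonsig[i][j]: ordered means i..j (i<j) not significantly different.
    nonsig = [[False] * k for _ in range(k)]
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(
                nonsig[a][b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (a, b) != (i, j) and b - a + 1 > span - 1
            ):
                # protected: inside a wider non-significant range
                nonsig[i][j] = True
                continue
            diff = ranked[i].mean - ranked[j].mean
            if mse == 0:
                nonsig[i][j] = diff == 0
                continue
            n_h = 2.0 / (1.0 / ranked[i].n + 1.0 / ranked[j].n)
            r_p = duncan_critical_q(alpha, span, df) * math.sqrt(mse / n_h)
            nonsig[i][j] = diff <= r_p

    # Maximal non-significant stretches -> letters (standard insertion).
    reach = list(range(k))
    for i in range(k):
        for j in range(k - 1, i, -1):
            if nonsig[i][j]:
                reach[i] = j
                break
    letters: dict[str, list[str]] = {g.group_id: [] for g in ranked}
    letter_idx = 0
    prev_end = -1
    for i in range(k):
        if reach[i] > prev_end or (reach[i] == i and i > prev_end):
            sym = _letter(letter_idx)
            letter_idx += 1
            for m in range(i, reach[i] + 1):
                letters[ranked[m].group_id].append(sym)
            prev_end = reach[i]
    return DuncanResult(
        order=[g.group_id for g in ranked],
        means={g.group_id: g.mean for g in ranked},
        letters={gid: "".join(ls) for gid, ls in letters.items()},
        alpha=alpha,
        mse=mse,
        df_error=df,
        nonsig={
            (ranked[i].group_id, ranked[j].group_id): nonsig[i][j]
            for i in range(k)
            for j in range(i + 1, k)
        },
    )


def _letter(idx: int) -> str:
    out = ""
    idx += 1
    while idx > 0:
        idx, rem = divmod(idx - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def duncan_letters_protected(
    groups: Sequence[GroupSample], alpha: float = 0.05
) -> DuncanResult:
    """ANOVA-protected letter display.

    Duncan's ranges are stepped through only when the one-way F test is
    significant at ``alpha``; otherwise every group shares one letter.
    """
    anova = anova_oneway(groups)
    if anova.p >= alpha:
        ranked = sorted(groups, key=lambda g: (-g.mean, g.group_id))
        return DuncanResult(
            order=[g.group_id for g in ranked],
            means={g.group_id: g.mean for g in ranked},
            letters={g.group_id: "A" for g in ranked},
            alpha=alpha,
            mse=anova.mse,
            df_error=anova.df_within,
        )
    return duncan_mrt(groups, alpha=alpha, anova=anova)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def t_test_equal_var(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Student's two-sample pooled-variance t-test, two-tailed."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.inf if np.mean(a) > np.mean(b) else -math.inf,
                           df, 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), df, float(p))


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray


def chi_square_2x2(counts) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Expected counts from the product of marginals (spreadsheet CHITEST
    semantics). All marginals must be positive.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero marginal in 2x2 table")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(chi2), int(dof), float(p), expected)


def duncan_report_tsv(result: DuncanResult, ns: dict[str, int], path) -> None:
    """Table-style report: row = unit, n, mean, Duncan letters."""
    with open(path, "wt") as out:
        out.write("unit\tn\tmean\tduncan\n")
        for gid in result.order:
            out.write(f"{gid}\t{ns.get(gid, '')}\t{result.means[gid]:.6f}\t"
                      f"{result.letters[gid]}\n")


def stats_report_json(payload: dict, path) -> None:
    with open(path, "wt") as out:
        json.dump(payload, out, indent=2, default=float)
        out.write("\n")
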
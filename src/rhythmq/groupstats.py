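"""One-way ANOVA across sampling times with SNK post hoc letters.

Expression (or glucose) values at the seven sampling times are compared by a
one-way ANOVA, preceded when necessary by a normalising transformation chosen
from the ladder identity -> log -> sqrt (first transform whose within-group
residuals pass Shapiro-Wilk and whose groups pass Levene at alpha = 0.05).
Pairwise structure comes from the Student-Newman-Keuls multiple-range test:
means are ordered and each range of p consecutive ordered means is tested
against the studentized-range critical value q(alpha, p, df_within), stepping
down from the full range; once a range is declared non-significant every
nested range is too (the blocking rule).  The pairwise outcomes are summarised
as a compact letter display — two sampling times share a letter exactly when
their SNK comparison is non-significant — matching the letter annotations of
daily-profile figures.

Unequal group sizes (5-7 fish per time) are handled with the harmonic mean of
the two compared groups' n in the range standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "LetterAssignment",
    "apply_transform",
    "one_way_anova",
    "q_critical",
    "select_transform",
    "snk_test",
]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    transform_used: str = "identity"
    series_id: str | None = field(default=None, compare=False)


@dataclass(frozen=True)
class LetterAssignment:
    """Compact letter display plus the pairwise SNK significance matrix.

    ``significant[(a, b)]`` is True when groups a and b differ (keys are
    stored in both orders).  Groups share at least one letter iff their
    comparison is non-significant.
    """

    letters: dict[str, str]
    significant: dict[tuple[str, str], bool]
    means: dict[str, float]

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def apply_transform(values, transform: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if transform == "identity":
        return x
    if transform == "log":
        return np.log(x)
    if transform == "sqrt":
        return np.sqrt(x)
    raise ValueError(f"unknown transform {transform!r}")


def _as_groups(values_by_group) -> dict[str, np.ndarray]:
    groups = {k: np.asarray(v, dtype=float).ravel() for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    return groups


def select_transform(values_by_group, *, alpha: float = 0.05) -> str:
    """Choose a normalising transformation from the identity/log/sqrt ladder.

    Picks the first candidate for which Shapiro-Wilk on the pooled
    within-group residuals and Levene's test across groups both give
    p > alpha; falls back to identity with a warning when none qualifies.
    Log and sqrt are skipped when the data leave their domain.
    """
    groups = _as_groups(values_by_group)
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("need >= 3 values per group to assess normality")
    pooled = np.concatenate(list(groups.values()))
    candidates = ["identity"]
    if np.all(pooled > 0):
        candidates.append("log")
    if np.all(pooled >= 0):
        candidates.append("sqrt")
    for cand in candidates:
        tg = [apply_transform(v, cand) for v in groups.values()]
        resid = np.concatenate([v - v.mean() for v in tg])
        scale = max(1.0, float(np.ptp(np.concatenate(tg))))
        if np.ptp(resid) <= 1e-10 * scale:
            return cand  # (numerically) flat residuals: nothing to normalise
        sw_p = stats.shapiro(resid).pvalue
        lev_p = stats.levene(*tg).pvalue
        if sw_p > alpha and lev_p > alpha:
            return cand
    warnings.warn(
        "no transformation achieved normality and homoscedasticity; "
        "falling back to identity",
        stacklevel=2,
    )
    return "identity"


def one_way_anova(
    values_by_group,
    *,
    transform: str = "identity",
    series_id: str | None = None,
) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition) across groups."""
    groups = _as_groups(values_by_group)
    tg = {k: apply_transform(v, transform) for k, v in groups.items()}
    pooled = np.concatenate(list(tg.values()))
    n_total = pooled.size
    k = len(tg)
    if n_total - k < 1:
        raise ValueError("no residual degrees of freedom")
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: ANOVA undefined")
    ss_within = sum(float(((v - v.mean()) ** 2).sum()) for v in tg.values())
    means = {g: float(v.mean()) for g, v in tg.items()}
    grand = float(pooled.mean())
    ss_between = sum(v.size * (means[g] - grand) ** 2 for g, v in tg.items())
    # ss_within can be ~1e-30 instead of exactly 0 from mean round-off
    if ss_within <= 1e-20 * max(ss_between, 1.0):
        raise ValueError("zero within-group variance with unequal means: infinite F")
    f_stat, p_value = stats.f_oneway(*tg.values())
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p_value),
        ms_within=ss_within / (n_total - k),
        group_means=means,
        group_ns={g: int(v.size) for g, v in tg.items()},
        transform_used=transform,
        series_id=series_id,
    )


@lru_cache(maxsize=4096)
def q_critical(alpha: float, n_means: int, df: int) -> float:
    """Upper critical value of the studentized range, q(alpha, p, df).

    Computed numerically from the studentized-range distribution (no
    interpolation tables).
    """
    return float(stats.studentized_range.ppf(1.0 - alpha, n_means, df))


def snk_test(
    anova: AnovaResult,
    values_by_group,
    *,
    alpha: float = 0.05,
) -> LetterAssignment:
    """Student-Newman-Keuls multiple-range test with compact letter display.

    Values are compared on the scale recorded in ``anova.transform_used`` (the
    same one the ANOVA used).  Each span of p consecutive ordered means is
    tested with q(alpha, p, df_within); the standard error of a range uses
    MS_within and the harmonic mean of the two compared groups' sizes.  The
    blocking rule declares every range nested in a non-significant range
    non-significant, which guarantees a consistent letter display.
    """
    if anova.df_within < 1 or anova.ms_within <= 0:
        raise ValueError("degenerate ANOVA: SNK needs positive MS_within and df")
    groups = _as_groups(values_by_group)
    tg = {k: apply_transform(v, anova.transform_used) for k, v in groups.items()}
    order = sorted(tg, key=lambda g: float(np.mean(tg[g])))  # ascending means
    means = [float(np.mean(tg[g])) for g in order]
    ns = [len(tg[g]) for g in order]
    k = len(order)

    significant: dict[tuple[str, str], bool] = {}
    blocked: list[tuple[int, int]] = []
    for p in range(k, 1, -1):
        for i in range(0, k - p + 1):
            j = i + p - 1
            if any(bi <= i and j <= bj for bi, bj in blocked):
                sig = False
            else:
                n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
                q_stat = (means[j] - means[i]) / np.sqrt(anova.ms_within / n_h)
                sig = q_stat > q_critical(alpha, p, anova.df_within)
                if not sig:
                    blocked.append((i, j))
            significant[(order[i], order[j])] = sig
            significant[(order[j], order[i])] = sig

    letters = _insert_absorb(order, significant)
    return LetterAssignment(
        letters=letters,
        significant=significant,
        means=dict(zip(order, means)),
    )


def _insert_absorb(order: list[str], significant) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm."""
    sets: list[set[str]] = [set(order)]
    for a_i in range(len(order)):
        for b_i in range(a_i + 1, len(order)):
            a, b = order[a_i], order[b_i]
            if not significant[(a, b)]:
                continue
            nxt: list[set[str]] = []
            for s in sets:
                if a in s and b in s:
                    nxt.append(s - {a})
                    nxt.append(s - {b})
                else:
                    nxt.append(s)
            # absorb sets contained in another
            nxt.sort(key=len, reverse=True)
            sets = []
            for s in nxt:
                if s and not any(s <= t for t in sets):
                    sets.append(s)
    # letter 'a' goes to the set containing the highest mean
    sets.sort(key=lambda s: -max(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for s, ch in zip(sets, alphabet):
        for g in s:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in order}
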
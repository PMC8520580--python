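"""The interval-valued Kruskal-Wallis statistics, p-values and decision rule.

For each component (lower endpoints, upper endpoints) the tie-corrected
H statistic is

    H = (n - 1) (S_k^2 - C) / (S_r^2 - C),

with S_k^2 = sum_i R_i^2 / n_i over the k group rank sums, S_r^2 the sum
of squared midranks over all n observations, and correction term
C = n (n + 1)^2 / 4.  Without ties S_r^2 = n(n+1)(2n+1)/6 and H collapses
to the familiar 12 S_k^2 / (n(n+1)) - 3(n+1).  Under the null, H is
asymptotically chi-square with k - 1 degrees of freedom; for small samples
a permutation null (exhaustive where feasible, otherwise Monte-Carlo) is
offered instead.

The pair (H_L, H_U) is summarized as H_L + H_U * I with the indeterminacy
I ranging over [0, (H_U - H_L)/H_U]; the decision is three-valued: reject
when both components exceed the critical value, fail to reject when
neither does, indeterminate otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.stats import chi2

from neutrokw.interval_data import ComponentPair, GroupedNeutrosophicData
from neutrokw.ranking import RankTable, component_ranks, midranks, rank_sums

__all__ = [
    "DegenerateSampleError",
    "NeutrosophicForm",
    "NeutrosophicKWResult",
    "s_k_squared",
    "s_r_squared",
    "s_r_squared_no_ties",
    "correction_term",
    "h_statistic",
    "h_statistic_no_ties",
    "chi_square_p",
    "permutation_p",
    "indeterminacy_measure",
    "neutrosophic_form",
    "decide",
    "neutrosophic_kruskal_wallis",
]

EXHAUSTIVE_CAP = 200_000

Decision = Literal["reject", "fail_to_reject", "indeterminate"]
Component = Literal["lower", "upper"]
PMethod = Literal["chi_square", "permutation"]


class DegenerateSampleError(ValueError):
    """All pooled values of a component are identical; H is undefined."""


def s_k_squared(
    rank_sums_: Sequence[float], group_sizes: Sequence[int]
) -> float:
    """Sum over groups of (rank sum)^2 / (group size)."""
    if len(rank_sums_) != len(group_sizes):
        raise ValueError(
            f"{len(rank_sums_)} rank sums but {len(group_sizes)} group sizes"
        )
    if any(n <= 0 for n in group_sizes):
        raise ValueError("group sizes must be positive")
    return float(sum(r * r / n for r, n in zip(rank_sums_, group_sizes)))


def s_r_squared(rank_table: RankTable) -> ComponentPair:
    """Sum of squared midranks over all observations, per component."""
    return ComponentPair(
        float(sum(r * r for r in rank_table.ranks_lower)),
        float(sum(r * r for r in rank_table.ranks_upper)),
    )


def s_r_squared_no_ties(n: int) -> float:
    """Closed form n(n+1)(2n+1)/6, valid when no ties occur."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return n * (n + 1) * (2 * n + 1) / 6


def correction_term(n: int) -> float:
    """Correction term C = n(n+1)^2/4."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return n * (n + 1) ** 2 / 4


def h_statistic(n: int, s_k2: float, s_r2: float, c: float) -> float:
    """Tie-corrected H = (n-1)(S_k^2 - C)/(S_r^2 - C); nonnegative."""
    if s_r2 == c:
        raise DegenerateSampleError(
            "sum of squared ranks equals the correction term: all pooled "
            "values are identical and H is undefined"
        )
    return (n - 1) * (s_k2 - c) / (s_r2 - c)


def h_statistic_no_ties(n: int, s_k2: float) -> float:
    """Tie-free form H = 12 S_k^2 / (n(n+1)) - 3(n+1)."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return 12 * s_k2 / (n * (n + 1)) - 3 * (n + 1)


def chi_square_p(h: float, df: int) -> float:
    """Upper-tail probability P(chi2_df >= h)."""
    if h < 0:
        raise ValueError(f"H must be nonnegative, got {h}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(chi2.sf(h, df))


def _h_from_rank_assignment(
    ranks: np.ndarray,
    group_slices: Sequence[tuple[int, int]],
    n: int,
    s_r2: float,
    c: float,
) -> float:
    sums = [float(ranks[a:b].sum()) for a, b in group_slices]
    return h_statistic(n, s_k_squared(sums, [b - a for a, b in group_slices]), s_r2, c)


def _exhaustive_assignments(
    indices: tuple[int, ...], sizes: Sequence[int]
) -> Iterator[tuple[tuple[int, ...], ...]]:
    """All ordered ways to split ``indices`` into groups of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    first, rest = sizes[0], sizes[1:]
    for chosen in combinations(indices, first):
        chosen_set = set(chosen)
        remaining = tuple(i for i in indices if i not in chosen_set)
        for tail in _exhaustive_assignments(remaining, rest):
            yield (chosen,) + tail


def _multinomial(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def permutation_p(
    data: GroupedNeutrosophicData,
    component: Component = "lower",
    n_permutations: int | Literal["exhaustive"] = 9999,
    seed: int = 0,
) -> float:
    """Permutation p-value for one component's H statistic.

    Group labels are shuffled over the pooled observations; the ranks
    themselves are permutation-invariant, so only the assignment of ranks
    to groups is re-drawn.  ``n_permutations="exhaustive"`` enumerates all
    distinct assignments (allowed while the multinomial count is at most
    ``EXHAUSTIVE_CAP``); the observed assignment is part of the
    enumeration, so p > 0.  Monte-Carlo sampling adds the observed
    assignment to both numerator and denominator for the same guarantee.
    """
    values = data.component_values(component)
    ranks = np.asarray(midranks(values))
    n = data.n
    sizes = data.group_sizes
    slices: list[tuple[int, int]] = []
    start = 0
    for s in sizes:
        slices.append((start, start + s))
        start += s
    s_r2 = float(np.sum(ranks**2))
    c = correction_term(n)
    if s_r2 == c:
        # All pooled values identical: H = 0 for every relabeling, so the
        # observed statistic can never be exceeded.
        return 1.0
    h_obs = _h_from_rank_assignment(ranks, slices, n, s_r2, c)
    # Guard against float jitter when comparing permuted H to the observed.
    threshold = h_obs - 1e-12 * max(1.0, abs(h_obs))

    if n_permutations == "exhaustive":
        count = _multinomial(sizes)
        if count > EXHAUSTIVE_CAP:
            raise ValueError(
                f"exhaustive enumeration needs {count} assignments "
                f"(cap {EXHAUSTIVE_CAP}); use Monte-Carlo instead"
            )
        hits = 0
        for assignment in _exhaustive_assignments(tuple(range(n)), sizes):
            sums = [float(ranks[list(g)].sum()) for g in assignment]
            h = h_statistic(n, s_k_squared(sums, sizes), s_r2, c)
            if h >= threshold:
                hits += 1
        return hits / count

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(ranks)
        if _h_from_rank_assignment(perm, slices, n, s_r2, c) >= threshold:
            hits += 1
    return (1 + hits) / (1 + int(n_permutations))


def indeterminacy_measure(H: ComponentPair) -> float:
    """Relative gap |H_U - H_L| / |H_U| of the interval statistic.

    Zero when both components vanish; undefined (raises) when only the
    upper component is zero.
    """
    h_l, h_u = H.lower_component, H.upper_component
    if h_u == 0:
        if h_l == 0:
            return 0.0
        raise ValueError(
            "indeterminacy undefined: upper-component H is 0 but lower is not"
        )
    return abs(h_u - h_l) / abs(h_u)


@dataclass(frozen=True)
class NeutrosophicForm:
    """H expressed as determinate term + indeterminate coefficient * I."""

    determinate_term: float  # H_L
    indeterminate_coefficient: float  # H_U
    indeterminacy_interval: tuple[float, float]  # [0, I_U]

    def to_dict(self) -> dict:
        return {
            "determinate_term": self.determinate_term,
            "indeterminate_coefficient": self.indeterminate_coefficient,
            "indeterminacy_interval": list(self.indeterminacy_interval),
        }


def neutrosophic_form(H: ComponentPair) -> NeutrosophicForm:
    """Express the interval statistic as H_L + H_U * I, I in [0, I_U].

    Self-consistent: determinate_term + indeterminate_coefficient * I_U
    recovers the upper component (exactly, when H_U >= H_L).
    """
    i_u = indeterminacy_measure(H)
    return NeutrosophicForm(H.lower_component, H.upper_component, (0.0, i_u))


def decide(H: ComponentPair, critical_value: float) -> Decision:
    """Three-valued decision against a critical value.

    Reject when both components exceed it, fail to reject when neither
    does, indeterminate when the interval straddles it.
    """
    if critical_value <= 0:
        raise ValueError(f"critical value must be positive, got {critical_value}")
    above_l = H.lower_component > critical_value
    above_u = H.upper_component > critical_value
    if above_l and above_u:
        return "reject"
    if not above_l and not above_u:
        return "fail_to_reject"
    return "indeterminate"


@dataclass(frozen=True)
class NeutrosophicKWResult:
    """Full output of the interval-valued Kruskal-Wallis test."""

    labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    rank_sums: tuple[ComponentPair, ...]
    s_k2: ComponentPair
    s_r2: ComponentPair
    correction: ComponentPair
    H: ComponentPair
    df: int
    p: ComponentPair
    indeterminacy: float
    form: NeutrosophicForm
    alpha: float
    critical_value: float
    decision: Decision
    p_method: PMethod

    def to_dict(self) -> dict:
        """JSON-ready representation with stable field names."""
        return {
            "groups": list(self.labels),
            "group_sizes": list(self.group_sizes),
            "rank_sums": [list(r.as_tuple()) for r in self.rank_sums],
            "s_k2_lower": self.s_k2.lower_component,
            "s_k2_upper": self.s_k2.upper_component,
            "s_r2_lower": self.s_r2.lower_component,
            "s_r2_upper": self.s_r2.upper_component,
            "correction": self.correction.lower_component,
            "H_lower": self.H.lower_component,
            "H_upper": self.H.upper_component,
            "df": self.df,
            "p_lower": self.p.lower_component,
            "p_upper": self.p.upper_component,
            "indeterminacy": self.indeterminacy,
            "neutrosophic_form": self.form.to_dict(),
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "decision": self.decision,
            "p_method": self.p_method,
        }


def neutrosophic_kruskal_wallis(
    data: GroupedNeutrosophicData,
    alpha: float = 0.05,
    p_method: PMethod = "chi_square",
    n_permutations: int | Literal["exhaustive"] = 9999,
    seed: int = 0,
) -> NeutrosophicKWResult:
    """Run the interval-valued Kruskal-Wallis test end to end.

    Midranks each component of the pooled data, forms the per-group rank
    sums, evaluates the tie-corrected H per component, attaches p-values
    (chi-square with k-1 df, or permutation) and the chi-square critical
    value at level ``alpha``, and reduces the H interval to the
    three-valued decision.  On all-degenerate data (every interval of zero
    width) both components coincide and the result equals the classical
    tie-corrected test.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    table = component_ranks(data)
    sums = rank_sums(table, data)
    sizes = data.group_sizes
    n = data.n
    c = correction_term(n)
    s_k2 = ComponentPair(
        s_k_squared([r.lower_component for r in sums], sizes),
        s_k_squared([r.upper_component for r in sums], sizes),
    )
    s_r2 = s_r_squared(table)
    H = ComponentPair(
        h_statistic(n, s_k2.lower_component, s_r2.lower_component, c),
        h_statistic(n, s_k2.upper_component, s_r2.upper_component, c),
    )
    df = data.k - 1
    if p_method == "chi_square":
        p = ComponentPair(
            chi_square_p(H.lower_component, df), chi_square_p(H.upper_component, df)
        )
    elif p_method == "permutation":
        p = ComponentPair(
            permutation_p(data, "lower", n_permutations, seed),
            permutation_p(data, "upper", n_permutations, seed),
        )
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    critical = float(chi2.ppf(1 - alpha, df))
    try:
        indeterminacy = indeterminacy_measure(H)
        form = neutrosophic_form(H)
    except ValueError:
        # H_U == 0 with H_L != 0: the relative-gap measure has no finite
        # value; report NaN rather than fail the whole test run.
        indeterminacy = float("nan")
        form = NeutrosophicForm(
            H.lower_component, H.upper_component, (0.0, float("nan"))
        )
    return NeutrosophicKWResult(
        labels=data.labels,
        group_sizes=sizes,
        rank_sums=tuple(sums),
        s_k2=s_k2,
        s_r2=s_r2,
        correction=ComponentPair(c, c),
        H=H,
        df=df,
        p=p,
        indeterminacy=indeterminacy,
        form=form,
        alpha=alpha,
        critical_value=critical,
        decision=decide(H, critical),
        p_method=p_method,
    )
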
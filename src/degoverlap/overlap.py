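"""Overlap significance for gene lists.

Three complementary tools for deciding whether gene lists share more members
than chance:

* a **size-matched permutation test** on the Jaccard index — random lists of
  the focal list's size are drawn uniformly from the background universe, the
  Jaccard index against the fixed comparator is recomputed for each draw, and
  the observed index is placed on that null via a z-score and an add-one
  empirical p-value;
* **analytic null moments** of the Jaccard index under independence, computed
  exactly from the hypergeometric law of the intersection size (serves as an
  independent check on the permutation machinery);
* the **exact k-way intersection distribution**: when each of k lists is an
  independent uniform draw of its size from the universe, the distribution of
  the k-way intersection size follows by iterated hypergeometric convolution,
  giving an exact tail probability for the observed multi-set overlap.

All randomness flows through explicit integer seeds; identical inputs and
seed give bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from ._util import child_seed
from .errors import InvalidArgumentError, MembershipError
from .synthetic import DIRECTIONS, Direction, GeneUniverse
from .deg import ExperimentDE

__all__ = [
    "jaccard", "permutation_overlap", "analytic_null_moments",
    "exact_multiset_test", "directional_suite", "triple_overlap",
    "venn_counts", "OverlapResult", "MultiSetResult", "DirectionalComparison",
    "TripleOverlap",
]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard similarity |a∩b| / |a∪b|; 0.0 when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


# ---------------------------------------------------------------------------
# Pairwise permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    """Observed pairwise overlap plus its size-matched permutation null.

    ``z_score`` is NaN when the null distribution is degenerate
    (``null_sd == 0``); ``empirical_p`` remains valid in that case.
    """

    set_a_size: int
    set_b_size: int
    intersection_size: int
    union_size: int
    jaccard: float
    null_mean: float
    null_sd: float
    z_score: float
    empirical_p: float
    n_perm: int
    seed: int
    shared_genes: tuple[str, ...]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "set_a_size", "set_b_size", "intersection_size", "union_size",
            "jaccard", "null_mean", "null_sd", "z_score", "empirical_p",
            "n_perm", "seed")}
        d["shared_genes"] = list(self.shared_genes)
        return d


def _check_membership(genes: set[str], universe: GeneUniverse, which: str) -> None:
    outside = genes - universe.as_set()
    if outside:
        raise MembershipError(outside, which=which)


def _null_jaccards(
    rng: np.random.Generator,
    universe_size: int,
    n_a: int,
    n_b: int,
    b_mask: np.ndarray | None,
    n_perm: int,
    randomize_both: bool,
) -> np.ndarray:
    """Jaccard index of each permuted draw.

    Each draw is a genuine uniform size-``n_a`` subset of the universe
    (partial Fisher–Yates via ``Generator.choice`` without replacement), not
    a shortcut through the intersection-count distribution — the analytic
    hypergeometric route stays an independent check.
    """
    counts = np.empty(n_perm, dtype=np.int64)
    if n_a == 0 or n_b == 0:
        counts[:] = 0
    elif randomize_both:
        scratch = np.zeros(universe_size, dtype=bool)
        for i in range(n_perm):
            idx_a = rng.choice(universe_size, size=n_a, replace=False)
            idx_b = rng.choice(universe_size, size=n_b, replace=False)
            scratch[idx_a] = True
            counts[i] = int(scratch[idx_b].sum())
            scratch[idx_a] = False
    else:
        for i in range(n_perm):
            idx = rng.choice(universe_size, size=n_a, replace=False)
            counts[i] = int(b_mask[idx].sum())
    union = n_a + n_b - counts
    with np.errstate(invalid="ignore"):
        j = np.where(union > 0, counts / np.maximum(union, 1), 0.0)
    return j


def permutation_overlap(
    a: Iterable[str],
    b: Iterable[str],
    universe: GeneUniverse,
    n_perm: int = 10_000,
    seed: int = 0,
    randomize: Literal["a", "b", "both"] = "a",
) -> OverlapResult:
    """Significance of the Jaccard overlap of ``a`` and ``b`` by permutation.

    ``n_perm`` random gene lists of the same size as the randomized set are
    drawn uniformly (without replacement within each draw) from the universe
    while the other set is held fixed; the Jaccard index of each draw gives
    the null distribution. The observed index is summarized as a z-score
    against the null mean and SD (population SD over the permuted values) and
    as an add-one empirical p-value ``(r + 1) / (n_perm + 1)`` where ``r``
    counts permuted values >= observed (ties inclusive).

    ``randomize`` chooses which list is size-matched and redrawn: ``"a"``
    (default — put the focal experiment first), ``"b"``, or ``"both"``.
    """
    a, b = set(a), set(b)
    _check_membership(a, universe, "set a")
    _check_membership(b, universe, "set b")
    if n_perm < 1:
        raise InvalidArgumentError(f"n_perm must be >= 1, got {n_perm}")
    if randomize not in ("a", "b", "both"):
        raise InvalidArgumentError(f"randomize must be 'a', 'b' or 'both', got {randomize!r}")

    inter = a & b
    union_size = len(a | b)
    observed = len(inter) / union_size if union_size else 0.0

    if randomize == "b":
        fixed, redrawn = a, b
    else:
        fixed, redrawn = b, a
    b_mask = np.zeros(universe.N, dtype=bool)
    if fixed:
        b_mask[universe.indices_of(fixed)] = True

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    null = _null_jaccards(
        rng, universe.N, len(redrawn), len(fixed), b_mask, n_perm,
        randomize_both=(randomize == "both"),
    )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))  # the permuted collection IS the null
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    r = int(np.sum(null >= observed))
    empirical_p = (r + 1) / (n_perm + 1)

    return OverlapResult(
        set_a_size=len(a),
        set_b_size=len(b),
        intersection_size=len(inter),
        union_size=union_size,
        jaccard=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        empirical_p=empirical_p,
        n_perm=n_perm,
        seed=int(seed),
        shared_genes=tuple(sorted(inter)),
    )


def analytic_null_moments(n_a: int, n_b: int, N: int) -> tuple[float, float]:
    """Exact mean and SD of the Jaccard index under independent uniform draws.

    For independent uniform size-``n_a`` and size-``n_b`` subsets of an
    ``N``-gene universe the intersection size X is Hypergeometric(N, n_a,
    n_b) and J = X / (n_a + n_b − X) is a deterministic monotone function of
    X, so the moments follow by summing over the hypergeometric support.
    """
    if N < 1:
        raise InvalidArgumentError("N must be >= 1")
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise InvalidArgumentError("set sizes must lie in [0, N]")
    if n_a == 0 and n_b == 0:
        return 0.0, 0.0
    lo = max(0, n_a + n_b - N)
    hi = min(n_a, n_b)
    x = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(x, N, n_a, n_b)
    pmf = pmf / pmf.sum()
    union = n_a + n_b - x
    j = np.where(union > 0, x / np.maximum(union, 1), 0.0)
    mean = float(np.sum(j * pmf))
    if len(x) == 1:
        return mean, 0.0
    var = max(float(np.sum(pmf * (j - mean) ** 2)), 0.0)
    return mean, math.sqrt(var)


# ---------------------------------------------------------------------------
# Exact multi-set intersection statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiSetResult:
    """Exact statistics of a k-way intersection under independent draws.

    ``expected`` is N·∏(nᵢ/N); ``exact_p`` is P(X >= observed) under the
    exact null where each set is an independent uniform draw of its size.
    ``pmf_support`` holds the full distribution of X on 0..min(sizes).
    """

    k: int
    set_sizes: tuple[int, ...]
    N: int
    observed: int
    expected: float
    fold_enrichment: float
    exact_p: float
    pmf_support: np.ndarray = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "k": self.k, "set_sizes": list(self.set_sizes), "N": self.N,
            "observed": self.observed, "expected": self.expected,
            "fold_enrichment": self.fold_enrichment, "exact_p": self.exact_p,
        }


def _hg_logpmf(x: np.ndarray, N: int, m: np.ndarray, n: int) -> np.ndarray:
    """Vectorized hypergeometric log-pmf from the binomial-coefficient form.

    log C(m,x) + log C(N-m, n-x) - log C(N, n), with -inf outside the
    support. Used for the large transition grids of the convolution, where
    an elementwise library pmf would dominate the runtime.
    """
    x, m = np.broadcast_arrays(x, m)
    valid = (x >= np.maximum(0, m + n - N)) & (x <= np.minimum(m, n))
    xs = np.where(valid, x, 0)
    ms = np.where(valid, m, n)
    out = (gammaln(ms + 1) - gammaln(xs + 1) - gammaln(ms - xs + 1)
           + gammaln(N - ms + 1) - gammaln(n - xs + 1) - gammaln(N - ms - n + xs + 1)
           - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))
    return np.where(valid, out, -np.inf)


def multiset_intersection_pmf(set_sizes: Sequence[int], N: int) -> np.ndarray:
    """Exact pmf of the k-way intersection size by hypergeometric convolution.

    Start with X₂ ~ Hypergeometric(N, n₁, n₂); for each further set of size
    nᵢ, condition on the running intersection m:
    P(Xᵢ = x) = Σₘ P(Xᵢ₋₁ = m) · HypergeomPmf(x; N, m, nᵢ).
    Computed in linear space (the k = 2 base case is the closed-form
    hypergeometric pmf, bit-for-bit); if mass is lost to underflow the
    convolution is redone in log space.
    """
    sizes = [int(n) for n in set_sizes]
    if len(sizes) < 2:
        raise InvalidArgumentError("need at least 2 sets")
    if any(n < 0 or n > N for n in sizes):
        raise InvalidArgumentError("set sizes must lie in [0, N]")

    # The running intersection after i sets has support 0..min(sizes[:i]):
    # truncate only as each new set is folded in, never in advance.
    hi = min(sizes[0], sizes[1])
    pmf = stats.hypergeom.pmf(np.arange(hi + 1), N, sizes[0], sizes[1])
    for n_i in sizes[2:]:
        new_hi = min(hi, n_i)
        m = np.arange(hi + 1)[:, None]        # running intersection size
        x = np.arange(new_hi + 1)[None, :]    # next intersection size
        pmf = pmf @ np.exp(_hg_logpmf(x, N, m, n_i))
        hi = new_hi
    total = float(pmf.sum())
    if not math.isfinite(total) or abs(total - 1.0) > 1e-9:
        pmf = np.exp(_multiset_logpmf(sizes, N))
    return pmf


def _multiset_logpmf(sizes: list[int], N: int) -> np.ndarray:
    """Log-space variant of the convolution, for underflow-prone regimes."""
    hi = min(sizes[0], sizes[1])
    logpmf = stats.hypergeom.logpmf(np.arange(hi + 1), N, sizes[0], sizes[1])
    for n_i in sizes[2:]:
        new_hi = min(hi, n_i)
        m = np.arange(hi + 1)[:, None]
        x = np.arange(new_hi + 1)[None, :]
        trans = _hg_logpmf(x, N, m, n_i)
        with np.errstate(invalid="ignore"):
            logpmf = logsumexp(logpmf[:, None] + trans, axis=0)
        hi = new_hi
    return logpmf - logsumexp(logpmf)


def exact_multiset_test(
    sets: Sequence[Iterable[str]],
    universe: GeneUniverse,
    names: Sequence[str] | None = None,
) -> MultiSetResult:
    """Exact significance of the k-way intersection of gene sets.

    Null model: each set is an independent uniform draw of its size from the
    universe; the intersection-size distribution is exact (iterated
    hypergeometric convolution), as is the upper-tail probability at the
    observed size.
    """
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise InvalidArgumentError("exact_multiset_test needs k >= 2 sets")
    for i, s in enumerate(sets):
        label = names[i] if names else f"set {i}"
        _check_membership(s, universe, label)

    sizes = tuple(len(s) for s in sets)
    observed = len(set.intersection(*sets))
    N = universe.N
    pmf = multiset_intersection_pmf(sizes, N)
    exact_p = float(min(1.0, pmf[observed:].sum()))
    if exact_p <= 0.0:
        # Tail vanished to 0 in linear space; recover it in log space.
        logpmf = _multiset_logpmf(list(sizes), N)
        exact_p = float(np.exp(logsumexp(logpmf[observed:])))
    expected = N * float(np.prod([n / N for n in sizes]))
    fold = observed / expected if expected > 0 else float("nan")
    return MultiSetResult(
        k=len(sets), set_sizes=sizes, N=N, observed=observed,
        expected=expected, fold_enrichment=fold, exact_p=exact_p,
        pmf_support=pmf,
    )


# ---------------------------------------------------------------------------
# Directional comparison suites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionalComparison:
    """All four ordered direction pairs between two experiments.

    Keys of ``results``: ("over","over"), ("under","under"), ("over","under"),
    ("under","over") — concordant pairs first, then the cross-direction pairs
    that serve as a specificity control.
    """

    name_a: str
    name_b: str
    results: Mapping[tuple[Direction, Direction], OverlapResult]
    significant: Mapping[tuple[Direction, Direction], bool]
    alpha: float
    dual_direction_a: int
    dual_direction_b: int

    PAIRS = (("over", "over"), ("under", "under"), ("over", "under"), ("under", "over"))


def directional_suite(
    exp_a: ExperimentDE,
    exp_b: ExperimentDE,
    universe: GeneUniverse | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    z_cut: float | None = None,
    randomize: Literal["a", "b", "both"] = "a",
) -> DirectionalComparison:
    """Run the permutation overlap test for all four ordered direction pairs.

    Each pair gets an independent sub-seeded RNG stream, all with the same
    universe and ``n_perm``. A result is flagged significant when
    ``empirical_p < alpha`` (and ``z_score > z_cut`` if a z cut is given).
    Dual-direction gene counts of both experiments are carried along so
    reports can flag them.
    """
    universe = universe or exp_a.universe
    results: dict[tuple[Direction, Direction], OverlapResult] = {}
    significant: dict[tuple[Direction, Direction], bool] = {}
    for d_a, d_b in DirectionalComparison.PAIRS:
        sub = child_seed(seed, "pair", exp_a.name, d_a, exp_b.name, d_b) % (2 ** 63)
        res = permutation_overlap(
            getattr(exp_a, d_a), getattr(exp_b, d_b), universe,
            n_perm=n_perm, seed=sub, randomize=randomize,
        )
        sig = res.empirical_p < alpha
        if z_cut is not None:
            sig = sig and (not math.isnan(res.z_score)) and res.z_score > z_cut
        results[(d_a, d_b)] = res
        significant[(d_a, d_b)] = sig
    return DirectionalComparison(
        name_a=exp_a.name, name_b=exp_b.name,
        results=results, significant=significant, alpha=alpha,
        dual_direction_a=len(exp_a.dual_direction),
        dual_direction_b=len(exp_b.dual_direction),
    )


@dataclass(frozen=True)
class TripleOverlap:
    """Three-way directional intersection with its exact test."""

    names: tuple[str, str, str]
    direction: Direction
    shared_genes: tuple[str, ...]
    result: MultiSetResult


def triple_overlap(
    exp_a: ExperimentDE,
    exp_b: ExperimentDE,
    exp_c: ExperimentDE,
    direction: Direction,
    universe: GeneUniverse | None = None,
) -> TripleOverlap:
    """Intersect one direction of three experiments and test it exactly."""
    if direction not in DIRECTIONS:
        raise InvalidArgumentError(f"direction must be 'over' or 'under', got {direction!r}")
    universe = universe or exp_a.universe
    sets = [getattr(e, direction) for e in (exp_a, exp_b, exp_c)]
    names = [e.name for e in (exp_a, exp_b, exp_c)]
    result = exact_multiset_test(sets, universe, names=names)
    shared = tuple(sorted(set.intersection(*map(set, sets)))) if all(sets) else ()
    return TripleOverlap(
        names=(exp_a.name, exp_b.name, exp_c.name),
        direction=direction,
        shared_genes=shared,
        result=result,
    )


def venn_counts(named_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Counts of all 2^k − 1 exclusive Venn regions of k named sets.

    Each row is one region: membership flags per set and the number of genes
    belonging to exactly that combination of sets.
    """
    names = list(named_sets)
    sets = {n: set(named_sets[n]) for n in names}
    everything = set().union(*sets.values()) if sets else set()
    rows = []
    for mask in range(1, 2 ** len(names)):
        inside = [n for i, n in enumerate(names) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set.intersection(*(sets[n] for n in inside)) if inside else set(everything)
        for n in outside:
            region = region - sets[n]
        rows.append({**{n: (n in inside) for n in names}, "count": len(region)})
    return pd.DataFrame(rows)
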
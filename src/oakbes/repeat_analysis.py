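"""Repeat statistics: binomial null model, novel-repeat families, densities.

The significance model treats the all-vs-all self-comparison of a BES
set as a sequence of Bernoulli trials.  Under the null hypothesis that
the genome is non-repetitive random sequence, the probability that two
100-bp windows align at >=90% identity is

    p0 = (sum_i f_i^2) ** 90

where ``f_i`` are the base frequencies and sum f_i^2 the per-position
match probability of two independent draws.  The number of matches a
read accrues over n comparisons is then Binomial(n, p0), and the
repeat-call threshold T is the smallest match count whose upper tail
probability is below the chosen Type-I error bound.  With realistic base
compositions p0 is astronomically small, so T = 1: a single passing
match already certifies a repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import binom, poisson

from oakbes._util import round_half_up
from oakbes.match_engine import AlignmentHit, MatchCounts

#: below this expected count the exact binomial tail is replaced by the
#: analytic small-p / Poisson form (documented switch; avoids underflow)
_POISSON_SWITCH = 1e-3


@dataclass(frozen=True)
class NullModel:
    """Binomial null model for repeat calling."""

    base_freqs: tuple[float, float, float, float]
    w: int = 100
    k: int = 90
    n_trials: int = 19_999
    alpha: float = 0.05

    @property
    def p0(self) -> float:
        return null_match_probability(self.base_freqs, self.w, self.k / self.w)

    @property
    def threshold(self) -> int:
        return match_count_threshold(self.p0, self.n_trials, self.alpha)


@dataclass
class RepeatFamily:
    """A cluster of reads sharing one novel repetitive element."""

    family_id: str
    members: list[str]
    representative_read: str
    representative_start: int
    representative_end: int
    covered_bp: int
    genome_copy_estimate: int | None = None

    @property
    def bes_copy_count(self) -> int:
        return len(self.members)

    @property
    def representative_length(self) -> int:
        return self.representative_end - self.representative_start + 1


@dataclass(frozen=True)
class RepeatDensityReport:
    known_density: float  # percent of BES nucleotides in known repeats
    novel_density: float  # percent in ab-initio families
    total_density: float = field(init=False)

    def __post_init__(self) -> None:
        if self.known_density < 0 or self.novel_density < 0:
            raise ValueError("densities must be non-negative")
        object.__setattr__(
            self, "total_density", round_half_up(self.known_density + self.novel_density, 2)
        )


def null_match_probability(
    base_freqs, w: int = 100, min_identity: float = 0.90
) -> float:
    """Per-pair probability that two w-bp windows match at >= min_identity.

    Independence model: the per-position match probability of two
    independent draws, ``sum_i f_i^2``, raised to the required number of
    matching positions ``ceil(min_identity * w)``.  Evaluated in log
    space.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must be non-negative and sum to 1")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    k = math.ceil(min_identity * w)
    p_match = float(np.sum(freqs**2))
    if p_match >= 1.0:
        return 1.0
    return math.exp(k * math.log(p_match))


def _upper_tail(t: int, n_trials: int, p0: float) -> float:
    """P(X >= t) for X ~ Binomial(n_trials, p0), stable for tiny p0."""
    if t <= 0:
        return 1.0
    if p0 <= 0.0:
        return 0.0
    mu = n_trials * p0
    if mu < _POISSON_SWITCH:
        if t == 1:  # exact: 1 - (1 - p0)^n, in log space
            return -math.expm1(n_trials * math.log1p(-p0))
        return float(poisson.sf(t - 1, mu))
    return float(binom.sf(t - 1, n_trials, p0))


def match_count_threshold(p0: float, n_trials: int, alpha: float = 0.05) -> int:
    """Smallest T with P(X >= T) <= alpha for X ~ Binomial(n_trials, p0).

    A read with at least T passing matches is called repetitive at
    Type-I error <= alpha.  Binary search over the monotone tail.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lo, hi = 0, n_trials + 1  # tail(0) = 1 > alpha; tail(n+1) = 0 <= alpha
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _upper_tail(mid, n_trials, p0) <= alpha:
            hi = mid
        else:
            lo = mid
    return hi


def repeat_density(masked_bp: int, total_bp: int) -> float:
    """Percent of BES nucleotides annotated as repeat (2 decimals)."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    if not 0 <= masked_bp <= total_bp:
        raise ValueError("require 0 <= masked_bp <= total_bp")
    return round_half_up(100.0 * masked_bp / total_bp, 2)


def candidate_repeats(counts: MatchCounts, min_matches: int = 6) -> set[str]:
    """Reads matching at least `min_matches` distinct other reads."""
    return {rid for rid, c in counts.counts.items() if c >= min_matches}


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def _largest_block(intervals: list[tuple[int, int]]) -> tuple[int, int]:
    best, cur_s, cur_e = None, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None and (best is None or cur_e - cur_s > best[1] - best[0]):
                best = (cur_s, cur_e)
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None and (best is None or cur_e - cur_s > best[1] - best[0]):
        best = (cur_s, cur_e)
    return best


def cluster_families(
    candidates: set[str], hits: list[AlignmentHit]
) -> list[RepeatFamily]:
    """Group candidate reads into families by single-linkage clustering.

    Families are the connected components of the match graph restricted
    to candidate reads (hits are assumed pre-filtered by the window
    rule).  Per family, ``covered_bp`` is the union of hit spans over the
    member reads and the representative is the largest covered block of
    the member with the most covered sequence.
    """
    if not candidates:
        return []
    ids = sorted(candidates)
    idx = {rid: i for i, rid in enumerate(ids)}
    rows, cols = [], []
    spans: dict[str, list[tuple[int, int]]] = {rid: [] for rid in ids}
    for h in hits:
        if h.query_id in idx and h.subject_id in idx and h.query_id != h.subject_id:
            rows.append(idx[h.query_id])
            cols.append(idx[h.subject_id])
            spans[h.query_id].append((h.q_start, h.q_end))
            spans[h.subject_id].append((h.s_start, h.s_end))
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
    )
    n_comp, labels = connected_components(graph, directed=False)
    families: list[RepeatFamily] = []
    for comp in range(n_comp):
        members = [ids[i] for i in range(len(ids)) if labels[i] == comp]
        covered = {m: _merged_length(spans[m]) for m in members if spans[m]}
        if not covered:  # isolated candidate without intra-candidate hits
            continue
        rep = max(covered, key=lambda m: (covered[m], m))
        rs, re = _largest_block(spans[rep])
        families.append(
            RepeatFamily(
                family_id="",
                members=sorted(members),
                representative_read=rep,
                representative_start=rs,
                representative_end=re,
                covered_bp=sum(covered.values()),
            )
        )
    families.sort(key=lambda f: (-f.bes_copy_count, f.members[0]))
    for i, fam in enumerate(families):
        fam.family_id = f"ORE{i + 1:03d}"
    return families


def extrapolate_copies(bes_copies: int, genome_size_bp: float, total_bes_bp: float) -> int:
    """Scale a family's BES copy count to whole-genome copy number.

    The BES set is a random sample of ``total_bes_bp`` of the genome, so
    observed copies scale by ``genome_size / total_bes_bp``.
    """
    if total_bes_bp <= 0:
        raise ValueError("total_bes_bp must be positive")
    return round(bes_copies * genome_size_bp / total_bes_bp)


def total_repeat_accounting(
    known_density: float, novel_density: float
) -> RepeatDensityReport:
    """Combine known-repeat and ab-initio densities (same denominator)."""
    return RepeatDensityReport(known_density=known_density, novel_density=novel_density)


def families_tsv(families: list[RepeatFamily]) -> str:
    header = "family_id\tsize\trepresentative\trep_length\tcovered_bp\tgenome_copy_estimate\n"
    rows = [
        "\t".join(
            [
                f.family_id,
                str(f.bes_copy_count),
                f"{f.representative_read}:{f.representative_start}-{f.representative_end}",
                str(f.representative_length),
                str(f.covered_bp),
                str(f.genome_copy_estimate if f.genome_copy_estimate is not None else "NA"),
            ]
        )
        for f in families
    ]
    return header + "\n".join(rows) + ("\n" if rows else "")
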
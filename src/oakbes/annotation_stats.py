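"""GO-term counting and chi-square category comparison.

Counts per-term and per-namespace annotation coverage of a BES set, and
compares the observed distribution over top-level categories against a
reference distribution (e.g. the whole Gene Ontology database) with
per-category one-vs-rest chi-square goodness-of-fit tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

from scipy.stats import chi2

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")


@dataclass(frozen=True)
class GoAssignment:
    bes_id: str
    go_id: str
    namespace: str
    top_level_term: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown GO namespace {self.namespace!r}")


@dataclass(frozen=True)
class TermComparison:
    term: str
    observed: int
    expected: float
    reference_proportion: float
    chi2_statistic: float
    p_value: float
    direction: str  # "over" | "under" | "equal"
    significant: bool
    low_expected: bool  # expected cell < 5: asymptotic test unreliable


@dataclass
class TermCounts:
    per_term: dict[str, int]
    per_namespace: dict[str, int]  # distinct annotated reads per namespace
    n_annotated_reads: int
    n_assignments: int


def read_assignments(stream: TextIO | Iterable[str]) -> list[GoAssignment]:
    """Parse the 4-column TSV (bes_id, go_id, namespace, top_level_term)."""
    out = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"line {lineno}: expected 4 columns, got {len(fields)}")
        out.append(GoAssignment(*fields))
    return out


def count_terms(assignments: list[GoAssignment]) -> TermCounts:
    """Tally term occurrences and per-read annotation coverage.

    A read annotated with k distinct terms contributes to k term counts
    but only once to the annotated-read coverage (and once per namespace
    it appears in).
    """
    per_term: dict[str, int] = {}
    reads_by_ns: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
    annotated: set[str] = set()
    for a in assignments:
        per_term[a.go_id] = per_term.get(a.go_id, 0) + 1
        reads_by_ns[a.namespace].add(a.bes_id)
        annotated.add(a.bes_id)
    return TermCounts(
        per_term=per_term,
        per_namespace={ns: len(s) for ns, s in reads_by_ns.items()},
        n_annotated_reads=len(annotated),
        n_assignments=len(assignments),
    )


def chi2_category_compare(
    observed: dict[str, int],
    reference: dict[str, float],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[TermComparison]:
    """Per-category over/under-representation tests.

    Each category is tested one-vs-rest: observed cells [x, n - x]
    against expected [n*p, n*(1-p)] where p is the category's reference
    proportion, giving a df=1 chi-square statistic
    ``(x - n p)^2 / (n p (1 - p))``.  No multiple-testing correction by
    default; ``bonferroni=True`` divides alpha by the number of
    categories.  Categories with an expected cell below 5 are flagged
    rather than dropped.
    """
    terms = sorted(observed)
    missing = [t for t in terms if t not in reference]
    if missing:
        raise ValueError(f"reference proportions missing for {missing}")
    total_p = sum(reference[t] for t in terms)
    if abs(total_p - 1.0) > 1e-6:
        raise ValueError(f"reference proportions sum to {total_p}, expected 1")
    n = sum(observed.values())
    if n <= 0:
        raise ValueError("observed total must be positive")
    threshold = alpha / len(terms) if bonferroni else alpha
    results = []
    for term in terms:
        x = observed[term]
        p = reference[term]
        expected = n * p
        if p in (0.0, 1.0):
            stat = float("inf") if x != expected else 0.0
            pval = 0.0 if x != expected else 1.0
        else:
            stat = (x - expected) ** 2 / (n * p * (1 - p))
            pval = float(chi2.sf(stat, df=1))
        direction = "over" if x > expected else ("under" if x < expected else "equal")
        results.append(
            TermComparison(
                term=term,
                observed=x,
                expected=expected,
                reference_proportion=p,
                chi2_statistic=stat,
                p_value=pval,
                direction=direction,
                significant=pval < threshold,
                low_expected=min(expected, n - expected) < 5,
            )
        )
    return results


def read_reference(stream: TextIO | Iterable[str]) -> dict[str, float]:
    """Parse the 2-column reference TSV (term, proportion)."""
    ref = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        ref[fields[0]] = float(fields[1])
    return ref


def comparison_tsv(results: list[TermComparison]) -> str:
    header = "term\tobserved\texpected\tchi2\tp_value\tdirection\tsignificant\tlow_expected\n"
    rows = [
        f"{r.term}\t{r.observed}\t{r.expected:.2f}\t{r.chi2_statistic:.4g}\t"
        f"{r.p_value:.4g}\t{r.direction}\t{int(r.significant)}\t{int(r.low_expected)}"
        for r in results
    ]
    return header + "\n".join(rows) + ("\n" if rows else "")
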
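"""Mate-pair microsynteny classification against a reference genome.

Both end reads of a BAC clone are mapped to a reference; the pair is
classified by how the two ends' hits relate:

    no_hit      neither end has a hit
    single_end  exactly one end has hits
    paired_end  both ends have hits (anywhere)
    colocalized >=1 forward/reverse hit combination on the same target
    gapped      colocalized, but no combination spans 15-250 kb
    non_gapped  >=1 same-target combination spans 15-250 kb
    collinear   the best in-range combination is oriented as inward-facing
                BAC ends (opposite strands, plus-strand hit 5' of the
                minus-strand hit)
    rearranged  non_gapped but not in the expected orientation

The span of a combination is the footprint between the outermost
coordinates of the two hits, approximating the insert length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from oakbes.bes_io import MatePairSet
from oakbes.match_engine import AlignmentHit

CATEGORIES = (
    "no_hit",
    "single_end",
    "paired_end",
    "colocalized",
    "gapped",
    "non_gapped",
    "collinear",
    "rearranged",
)


@dataclass(frozen=True)
class SyntenyParams:
    min_span: int = 15_000
    max_span: int = 250_000

    def validate(self) -> None:
        if not 0 < self.min_span < self.max_span:
            raise ValueError("require 0 < min_span < max_span")


@dataclass(frozen=True)
class PairClassification:
    clone_id: str
    category: str
    forward_hit: AlignmentHit | None = None
    reverse_hit: AlignmentHit | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def orientation_consistent(hit_f: AlignmentHit, hit_r: AlignmentHit) -> bool:
    """Are two same-target hits oriented as inward-facing BAC ends?

    TRUE iff the hits are on opposite strands and the plus-strand hit
    lies 5' (lower target coordinate) of the minus-strand hit.
    """
    if hit_f.subject_id != hit_r.subject_id:
        raise ValueError("orientation is defined only for hits on the same target")
    if hit_f.subject_strand == hit_r.subject_strand:
        return False
    plus, minus = (hit_f, hit_r) if hit_f.subject_strand == "+" else (hit_r, hit_f)
    return plus.s_start < minus.s_start


def _span(a: AlignmentHit, b: AlignmentHit) -> int:
    return max(a.s_end, b.s_end) - min(a.s_start, b.s_start)


def classify_pair(
    hits_f: list[AlignmentHit],
    hits_r: list[AlignmentHit],
    params: SyntenyParams | None = None,
    clone_id: str = "",
) -> PairClassification:
    """Assign the most specific synteny category to one mate pair.

    Hits are expected pre-filtered (E-value and window rule).  Among
    in-range same-target combinations, the best one (maximal summed hit
    length, then lowest target coordinate) decides collinear versus
    rearranged.
    """
    params = params or SyntenyParams()
    params.validate()
    if not hits_f and not hits_r:
        return PairClassification(clone_id, "no_hit")
    if not hits_f or not hits_r:
        return PairClassification(clone_id, "single_end")

    combos = [
        (f, r)
        for f in hits_f
        for r in hits_r
        if f.subject_id == r.subject_id
    ]
    if not combos:
        return PairClassification(clone_id, "paired_end")

    in_range = [
        (f, r) for f, r in combos if params.min_span <= _span(f, r) <= params.max_span
    ]
    if not in_range:
        return PairClassification(clone_id, "gapped")

    def sort_key(combo):
        f, r = combo
        total = (f.q_end - f.q_start + 1) + (r.q_end - r.q_start + 1)
        return (-total, min(f.s_start, r.s_start))

    best_f, best_r = min(in_range, key=sort_key)
    category = "collinear" if orientation_consistent(best_f, best_r) else "rearranged"
    return PairClassification(clone_id, category, forward_hit=best_f, reverse_hit=best_r)


def classify_dataset(
    pairs: MatePairSet,
    hits: list[AlignmentHit],
    params: SyntenyParams | None = None,
) -> tuple[list[PairClassification], dict[str, int]]:
    """Classify every mate pair and tabulate the category counts.

    The summary reports the specific category of each pair plus the
    cumulative counts implied by the hierarchy, satisfying

        colocalized == gapped + non_gapped
        non_gapped  == collinear + rearranged
        paired_end  >= colocalized
    """
    params = params or SyntenyParams()
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)

    results = [
        classify_pair(
            by_query.get(f.read_id, []), by_query.get(r.read_id, []), params, clone_id
        )
        for clone_id, (f, r) in sorted(pairs.pairs.items())
    ]
    specific = {c: 0 for c in CATEGORIES}
    for res in results:
        specific[res.category] += 1
    summary = {
        "pairs_total": len(results),
        "no_hit": specific["no_hit"],
        "single_end": specific["single_end"],
        "paired_end": sum(
            specific[c]
            for c in ("paired_end", "colocalized", "gapped", "non_gapped", "collinear", "rearranged")
        ),
        "colocalized": sum(
            specific[c] for c in ("colocalized", "gapped", "non_gapped", "collinear", "rearranged")
        ),
        "gapped": specific["gapped"],
        "non_gapped": sum(specific[c] for c in ("non_gapped", "collinear", "rearranged")),
        "collinear": specific["collinear"],
        "rearranged": specific["rearranged"],
    }
    return results, summary


def summary_json(summary: dict[str, int]) -> str:
    return json.dumps(summary, indent=2)


def classifications_tsv(results: list[PairClassification]) -> str:
    header = "clone_id\tcategory\ttarget\tspan\n"
    rows = []
    for res in results:
        if res.forward_hit and res.reverse_hit:
            target = res.forward_hit.subject_id
            span = str(_span(res.forward_hit, res.reverse_hit))
        else:
            target, span = "NA", "NA"
        rows.append(f"{res.clone_id}\t{res.category}\t{target}\t{span}")
    return header + "\n".join(rows) + ("\n" if rows else "")
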
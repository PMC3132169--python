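"""Gene-content estimation from homology hits.

The genic fraction of the BES nucleotides (reads with a protein hit,
times the mean read length, over total BES length) is scaled to the
genome and divided by a mean gene length:

    genes ~= (n_hit_bes * mean_bes_len / total_bes_bp) * GS / mean_gene_len

Organelle-matching reads are excluded from the genic count and reported
as contamination fractions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from oakbes._util import round_half_up
from oakbes.match_engine import AlignmentHit, window_identity_pass


@dataclass(frozen=True)
class HitFilterParams:
    """Stringency cutoffs for homology searches.

    Protein (BLASTX-style) hits keep E <= 1e-4; nucleotide (EST/unigene)
    hits keep E <= 1e-50 and must additionally pass the 100-bp/90%
    sliding-window identity rule.
    """

    protein_evalue_max: float = 1e-4
    est_evalue_max: float = 1e-50
    window_rule: bool = True
    w: int = 100
    min_identity: float = 0.90

    def validate(self) -> None:
        if self.protein_evalue_max <= 0 or self.est_evalue_max <= 0:
            raise ValueError("E-value cutoffs must be positive")


@dataclass(frozen=True)
class GeneEstimateParams:
    n_hit_bes: int
    mean_bes_len: float
    total_bes_bp: float
    genome_size: float
    mean_gene_len: float = 2_000.0
    novel_fraction: float = 0.11

    def validate(self) -> None:
        if min(self.mean_bes_len, self.total_bes_bp, self.genome_size, self.mean_gene_len) <= 0:
            raise ValueError("lengths and sizes must be positive")
        if self.n_hit_bes < 0:
            raise ValueError("n_hit_bes must be >= 0")


def filter_hits(
    hits: list[AlignmentHit], params: HitFilterParams, mode: str = "protein"
) -> list[AlignmentHit]:
    """Retain hits passing the cutoffs for the given search mode.

    ``mode='protein'``: E-value cutoff only.  ``mode='nucleotide'``:
    E-value cutoff plus the sliding-window identity rule (requires a
    match_vector on each hit).  Hits without an E-value are an error.
    """
    params.validate()
    if mode not in ("protein", "nucleotide"):
        raise ValueError("mode must be 'protein' or 'nucleotide'")
    cutoff = params.protein_evalue_max if mode == "protein" else params.est_evalue_max
    kept = []
    for h in hits:
        if h.evalue is None:
            raise ValueError(f"hit {h.query_id} -> {h.subject_id} has no E-value")
        if h.evalue > cutoff:
            continue
        if mode == "nucleotide" and params.window_rule:
            if not window_identity_pass(h, params.w, params.min_identity):
                continue
        kept.append(h)
    return kept


def organelle_fraction(n_matching: int, n_total_reads: int) -> float:
    """Percent of reads matching organelle references (2 decimals)."""
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    if not 0 <= n_matching <= n_total_reads:
        raise ValueError("require 0 <= n_matching <= n_total_reads")
    return round_half_up(100.0 * n_matching / n_total_reads, 2)


def estimate_gene_number(params: GeneEstimateParams) -> int:
    """Genome-wide gene-number estimate from the genic BES fraction."""
    params.validate()
    genic_fraction = params.n_hit_bes * params.mean_bes_len / params.total_bes_bp
    return round(genic_fraction * params.genome_size / params.mean_gene_len)


def adjust_for_novel(estimate: int, novel_fraction: float) -> int:
    """Correct a homology-based estimate for genes with no detectable
    homolog: if a fraction f of genes leaves no homology signal, the
    homology count sees only (1 - f) of the genes, so the total is
    estimate / (1 - f)."""
    if not 0.0 <= novel_fraction < 1.0:
        raise ValueError("novel_fraction must be in [0, 1)")
    return round(estimate / (1.0 - novel_fraction))


def gene_report(params: GeneEstimateParams, n_cp: int = 0, n_mt: int = 0, n_reads: int | None = None) -> str:
    """JSON report: estimate, homology-adjusted estimate, organelle rates."""
    params.validate()
    est = estimate_gene_number(params)
    out = {
        "n_hit_bes": params.n_hit_bes,
        "mean_bes_len": params.mean_bes_len,
        "total_bes_bp": params.total_bes_bp,
        "genome_size": params.genome_size,
        "mean_gene_len": params.mean_gene_len,
        "gene_estimate": est,
        "novel_fraction": params.novel_fraction,
        "gene_estimate_with_novel": adjust_for_novel(est, params.novel_fraction),
    }
    if n_reads:
        out["cp_fraction_pct"] = organelle_fraction(n_cp, n_reads)
        out["mt_fraction_pct"] = organelle_fraction(n_mt, n_reads)
    return json.dumps(out, indent=2)
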
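"""BAC-library coverage mathematics.

The Clarke–Carbon relation links the number of clones N, insert size I,
genome size GS and the probability P of recovering any given locus:

    N = ln(1 - P) / ln(1 - I/GS)        <=>        P = 1 - (1 - I/GS)^N

Fold coverage (genome equivalents) is the effective cloned length over
the genome size, after discounting empty and organelle-derived clones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from scipy.stats import beta

from oakbes._util import round_half_up


@dataclass(frozen=True)
class LibraryParams:
    n_clones: float
    insert_size: float  # bp
    genome_size: float  # bp
    empty_fraction: float = 0.0
    organelle_fraction: float = 0.0

    def validate(self) -> None:
        if not 0 < self.insert_size < self.genome_size:
            raise ValueError("require 0 < insert_size < genome_size")
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")
        for f in (self.empty_fraction, self.organelle_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


def clarke_carbon_clones(p: float, insert_size: float, genome_size: float) -> float:
    """Clones needed to recover any locus with probability `p`."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if not 0 < insert_size < genome_size:
        raise ValueError("require 0 < insert_size < genome_size")
    return math.log1p(-p) / math.log1p(-insert_size / genome_size)


def recovery_probability(n_clones: float, insert_size: float, genome_size: float) -> float:
    """Probability that a given locus is present in at least one clone."""
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if not 0 < insert_size < genome_size:
        raise ValueError("require 0 < insert_size < genome_size")
    return -math.expm1(n_clones * math.log1p(-insert_size / genome_size))


def coverage_depth(params: LibraryParams) -> float:
    """Genome equivalents held by the library.

    Empty clones and organelle contaminants contribute no nuclear
    coverage, so the clone count is discounted by both fractions before
    multiplying by insert size.
    """
    params.validate()
    effective = (
        params.n_clones
        * (1.0 - params.empty_fraction)
        * (1.0 - params.organelle_fraction)
    )
    return effective * params.insert_size / params.genome_size


def contamination_rate(
    positives: int, screened: int, ci: bool = False, conf: float = 0.95
) -> float | tuple[float, float, float]:
    """Contamination percentage from a PCR screen.

    Point estimate is ``100 * positives / screened`` rounded half-up to
    one decimal.  With ``ci=True`` an exact (Clopper–Pearson) binomial
    confidence interval is appended, as (rate, lo%, hi%).
    """
    if screened <= 0:
        raise ZeroDivisionError("contamination rate undefined for zero screened clones")
    if not 0 <= positives <= screened:
        raise ValueError("require 0 <= positives <= screened")
    rate = round_half_up(100.0 * positives / screened, 1)
    if not ci:
        return rate
    alpha = 1.0 - conf
    lo = 0.0 if positives == 0 else float(beta.ppf(alpha / 2, positives, screened - positives + 1))
    hi = (
        1.0
        if positives == screened
        else float(beta.ppf(1 - alpha / 2, positives + 1, screened - positives))
    )
    return rate, 100.0 * lo, 100.0 * hi


def coverage_report(params: LibraryParams) -> str:
    """JSON coverage summary: depth and locus-recovery probability."""
    params.validate()
    effective = params.n_clones * (1.0 - params.empty_fraction) * (
        1.0 - params.organelle_fraction
    )
    return json.dumps(
        {
            "n_clones": params.n_clones,
            "effective_clones": effective,
            "insert_size_bp": params.insert_size,
            "genome_size_bp": params.genome_size,
            "coverage_depth": coverage_depth(params),
            "recovery_probability": recovery_probability(
                effective, params.insert_size, params.genome_size
            ),
        },
        indent=2,
    )
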
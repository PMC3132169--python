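"""Pairwise local alignment and the 100-bp / 90%-identity window rule.

Three ways to obtain hits feed the rest of the pipeline:

* a built-in desk-scale aligner (exact-word seeding gate + Smith-Waterman
  local extension) for self-comparison of BES sets;
* a reader for 12-column tabular search output (BLAST ``-outfmt 6``
  style), standing in for external homology searches;
* the window-identity filter: a hit survives only if every 100-column
  sliding window of its alignment has at least 90% identical columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, TextIO

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from oakbes._util import revcomp
from oakbes.bes_io import BesRead


@dataclass
class AlignmentHit:
    """One pairwise local alignment, 1-based inclusive coordinates.

    Reverse-strand hits are stored canonicalized: ``s_start <= s_end``
    with ``subject_strand == '-'``.  ``match_vector`` has one boolean per
    alignment column; gap columns count as mismatches.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_strand: str  # '+' or '-'
    match_vector: np.ndarray | None
    score: float | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError("hit coordinates must satisfy start <= end")
        if self.subject_strand not in ("+", "-"):
            raise ValueError("subject_strand must be '+' or '-'")
        if self.match_vector is not None:
            self.match_vector = np.asarray(self.match_vector, dtype=bool)

    @property
    def n_columns(self) -> int:
        if self.match_vector is None:
            raise ValueError("hit has no match_vector")
        return len(self.match_vector)

    @property
    def identity(self) -> float:
        return float(np.mean(self.match_vector))


@dataclass(frozen=True)
class AlignParams:
    """Built-in aligner scoring: +1 match, -2 mismatch; a gap costs 5 for
    its first column and 2 for each further column.  Pairs are aligned
    only when they share an exact word of ``word_size``; hits scoring
    below ``min_score`` are discarded."""

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    min_score: int = 28


@dataclass
class MatchCounts:
    """Per-read count of distinct other reads with >=1 passing hit."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_matching(self) -> int:
        return sum(1 for c in self.counts.values() if c >= 1)

    def __getitem__(self, read_id: str) -> int:
        return self.counts.get(read_id, 0)


class TabularParseError(ValueError):
    """Malformed 12-column hit line (message carries the line number)."""


_ALPHABET = "ACGTN"


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    # N is a hard mismatch against everything, including itself, so that
    # masked (N-substituted) regions can neither seed nor extend.
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            matrix[a, b] = params.match if (a == b and a != "N") else params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _kmers(seq: str, k: int) -> set[str]:
    return {
        seq[i : i + k] for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]
    }


def _columns_from_alignment(aln, q: str, s: str) -> tuple[np.ndarray, int, int, int, int]:
    """Match vector and 1-based end-inclusive coords from a Bio.Align result."""
    coords = aln.coordinates
    qs, ss = coords[0], coords[1]
    cols: list[bool] = []
    for i in range(len(qs) - 1):
        dq, ds = qs[i + 1] - qs[i], ss[i + 1] - ss[i]
        if dq and ds:  # aligned block
            for a, b in zip(q[qs[i] : qs[i + 1]], s[ss[i] : ss[i + 1]]):
                cols.append(a == b and a != "N")
        else:  # gap in one sequence
            cols.extend([False] * int(dq + ds))
    return np.array(cols, dtype=bool), int(qs[0]) + 1, int(qs[-1]), int(ss[0]) + 1, int(ss[-1])


def local_align(
    query: str,
    subject: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """Best local alignment per strand between two sequences.

    A strand is attempted only when the two sequences share at least one
    exact ``word_size``-mer on it (the seeding gate); the extension is an
    exact Smith-Waterman local alignment, so reported hits are locally
    maximal.  Hits scoring below ``min_score`` are dropped.  Returns hits
    sorted by descending score (at most one per strand).
    """
    params = params or AlignParams()
    if not query or not subject:
        raise ValueError("cannot align empty sequences")
    query, subject = query.upper(), subject.upper()
    aligner = _aligner(params)
    qmers = _kmers(query, params.word_size)
    hits: list[AlignmentHit] = []
    for strand in "+-":
        target = subject if strand == "+" else revcomp(subject)
        if not qmers & _kmers(target, params.word_size):
            continue
        alignments = aligner.align(query, target)
        if alignments.score < params.min_score:
            continue
        aln = alignments[0]
        mv, q1, q2, s1, s2 = _columns_from_alignment(aln, query, target)
        if strand == "-":
            s1, s2 = len(subject) - s2 + 1, len(subject) - s1 + 1
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                q_start=q1,
                q_end=q2,
                s_start=s1,
                s_end=s2,
                subject_strand=strand,
                match_vector=mv,
                score=float(alignments.score),
            )
        )
    hits.sort(key=lambda h: -(h.score or 0.0))
    return hits


def window_identity_pass(
    hit: AlignmentHit, w: int = 100, min_identity: float = 0.90
) -> bool:
    """Does every w-column sliding window reach the identity floor?

    TRUE iff the alignment spans at least ``w`` columns and every
    contiguous window of ``w`` columns (step 1) contains at least
    ``ceil(min_identity * w)`` matching columns.  Alignments shorter than
    one full window never pass.
    """
    if w <= 0:
        raise ValueError("window length must be positive")
    mv = hit.match_vector
    if mv is None:
        raise ValueError("window rule requires a match_vector")
    if len(mv) < w:
        return False
    need = ceil(min_identity * w)
    sums = np.convolve(mv.astype(int), np.ones(w, dtype=int), mode="valid")
    return bool(sums.min() >= need)


def read_tabular_hits(
    stream: TextIO | Iterable[str], approximate: bool = False
) -> list[AlignmentHit]:
    """Parse 12-column tab-separated search output.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Reverse-strand subject hits (sstart >
    send) are canonicalized to ``s_start <= s_end`` with strand '-'.

    With ``approximate=True`` a match_vector is reconstructed by spreading
    the non-identical columns uniformly along the alignment, allowing
    window filtering of external hits that carry no alignment string.
    Otherwise ``match_vector`` is None and window filtering requires hits
    from the built-in aligner.
    """
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise TabularParseError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            length = int(fields[3])
            q1, q2 = int(fields[6]), int(fields[7])
            s1, s2 = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
            score = float(fields[11])
        except ValueError as exc:
            raise TabularParseError(f"line {lineno}: {exc}") from exc
        strand = "+"
        if s1 > s2:
            strand = "-"
            s1, s2 = s2, s1
        mv = None
        if approximate:
            n_match = round(pident / 100.0 * length)
            mv = np.ones(length, dtype=bool)
            n_mm = length - n_match
            if n_mm > 0:
                idx = (np.arange(n_mm) + 0.5) * length / n_mm
                mv[idx.astype(int)] = False
        hits.append(
            AlignmentHit(
                query_id=fields[0],
                subject_id=fields[1],
                q_start=q1,
                q_end=q2,
                s_start=s1,
                s_end=s2,
                subject_strand=strand,
                match_vector=mv,
                score=score,
                evalue=evalue,
            )
        )
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], handle: TextIO) -> None:
    """Emit hits in the same 12-column dialect read_tabular_hits consumes."""
    for h in hits:
        if h.match_vector is not None:
            length = h.n_columns
            pident = 100.0 * h.identity
            mism = int(length - h.match_vector.sum())
        else:
            length = h.q_end - h.q_start + 1
            pident, mism = 100.0, 0
        s1, s2 = (h.s_start, h.s_end) if h.subject_strand == "+" else (h.s_end, h.s_start)
        handle.write(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{pident:.2f}",
                    str(length),
                    str(mism),
                    "0",
                    str(h.q_start),
                    str(h.q_end),
                    str(s1),
                    str(s2),
                    f"{h.evalue if h.evalue is not None else 0.0:.2g}",
                    f"{h.score if h.score is not None else 0.0:.1f}",
                ]
            )
            + "\n"
        )


def _apply_mask(seq: str, intervals: list[tuple[int, int]]) -> str:
    """Replace 1-based inclusive intervals with N (excludes them from
    seeding and from matching columns)."""
    arr = list(seq)
    for s, e in intervals:
        for i in range(max(0, s - 1), min(len(arr), e)):
            arr[i] = "N"
    return "".join(arr)


def self_match_counts(
    reads: list[BesRead],
    params: AlignParams | None = None,
    mask: dict[str, list[tuple[int, int]]] | None = None,
    w: int = 100,
    min_identity: float = 0.90,
    collect_hits: bool = False,
) -> MatchCounts | tuple[MatchCounts, list[AlignmentHit]]:
    """All-vs-all self-comparison of a BES set.

    For every unordered read pair sharing an exact word (either strand),
    the built-in aligner is run; the pair counts as matching when at
    least one hit passes the window-identity rule.  Counts are symmetric
    and self-matches are excluded.  ``mask`` maps read ids to known-repeat
    intervals (1-based inclusive) that are N-substituted before
    comparison.  With ``collect_hits=True`` the passing hits are returned
    as well (used for repeat-family clustering).
    """
    params = params or AlignParams()
    mask = mask or {}
    seqs = {
        r.read_id: _apply_mask(r.sequence, mask[r.read_id]) if r.read_id in mask else r.sequence
        for r in reads
    }
    ids = [r.read_id for r in reads]
    k = params.word_size

    index: dict[str, list[int]] = {}
    for i, rid in enumerate(ids):
        for kmer in _kmers(seqs[rid], k):
            index.setdefault(kmer, []).append(i)

    candidates: set[tuple[int, int]] = set()
    for i, rid in enumerate(ids):
        partners: set[int] = set()
        for kmer in _kmers(seqs[rid], k):
            partners.update(index.get(kmer, ()))
        for kmer in _kmers(revcomp(seqs[rid]), k):
            partners.update(index.get(kmer, ()))
        for j in partners:
            if j != i:
                candidates.add((min(i, j), max(i, j)))

    counts = MatchCounts(counts={rid: 0 for rid in ids})
    passing: list[AlignmentHit] = []
    for i, j in sorted(candidates):
        hits = local_align(
            seqs[ids[i]], seqs[ids[j]], params, query_id=ids[i], subject_id=ids[j]
        )
        good = [h for h in hits if window_identity_pass(h, w, min_identity)]
        if good:
            counts.counts[ids[i]] += 1
            counts.counts[ids[j]] += 1
            passing.extend(good)
    if collect_hits:
        return counts, passing
    return counts
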
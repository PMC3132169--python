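"""Synthetic genomes, BAC libraries and BES reads with planted truth.

Every downstream stage of the pipeline (self-matching, repeat discovery,
SSR detection, gene-content estimation, synteny classification) is
validated against data generated here, where the true repeat copies,
SSR loci, gene segments and clone coordinates are known exactly.

The generator emulates the structure of a real BAC-library end-sequencing
project: a background genome of i.i.d. nucleotides at the dataset's base
composition, interspersed repeat families with per-copy divergence,
perfect microsatellites, gene-sized segments, chloroplast contamination,
clone inserts drawn from a truncated normal, and paired end reads with a
configurable retention rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from oakbes._util import revcomp, to_bed_interval
from oakbes.bes_io import BesRead, NamingConvention

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RepeatFamilySpec:
    family_id: str
    consensus_len: int
    copy_number: int
    divergence: float  # per-base substitution rate of each copy vs consensus


@dataclass(frozen=True)
class SsrPlantSpec:
    motif: str
    copies: int  # tandem copies of the motif per locus
    count: int  # number of loci to plant


@dataclass
class GenomeSpec:
    """Blueprint for a synthetic genome with planted features.

    Default base frequencies reproduce a 35.33% GC composition
    (A/T 0.32335 each, C/G 0.17665 each).
    """

    genome_len: int
    base_freqs: tuple[float, float, float, float] = (0.32335, 0.17665, 0.17665, 0.32335)
    repeat_families: list[RepeatFamilySpec] = field(default_factory=list)
    ssr_plants: list[SsrPlantSpec] = field(default_factory=list)
    n_genes: int = 0
    gene_len: int = 2_000
    cp_seq_len: int = 150_000
    mt_seq_len: int = 0

    def validate(self) -> None:
        if self.genome_len <= 0:
            raise ValueError("genome_len must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


@dataclass
class LibrarySimSpec:
    """Parameters of the simulated BAC library and end-sequencing run.

    Defaults are the study conditions of the library being emulated:
    135 kb mean insert in [50, 205] kb, 7% empty clones, 2.2% chloroplast
    clones, 599 bp reads retained at 66.96%.
    """

    n_clones: int
    insert_mean: int = 135_000
    insert_sd: int = 30_000
    insert_min: int = 50_000
    insert_max: int = 205_000
    empty_rate: float = 0.07
    cp_rate: float = 0.022
    read_len_mean: int = 599
    read_retention: float = 0.6696
    seed: int = 0

    def validate(self) -> None:
        for r in (self.empty_rate, self.cp_rate, self.read_retention):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not self.insert_min <= self.insert_mean <= self.insert_max:
            raise ValueError("insert_min <= insert_mean <= insert_max required")


@dataclass(frozen=True)
class CloneInterval:
    clone_id: str
    start: int  # 1-based inclusive on the genome (reinterpreted for cp clones)
    end: int
    is_empty: bool
    is_cp: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthTracks:
    """Planted-feature intervals, 1-based inclusive, with labels.

    ``cp_sequence``/``mt_sequence`` hold the organelle molecules that
    contaminating clones are drawn from.
    """

    repeats: list[tuple[int, int, str]] = field(default_factory=list)
    ssrs: list[tuple[int, int, str]] = field(default_factory=list)
    genes: list[tuple[int, int, str]] = field(default_factory=list)
    consensus: dict[str, str] = field(default_factory=dict)
    cp_sequence: str = ""
    mt_sequence: str = ""

    def all_intervals(self) -> list[tuple[int, int, str]]:
        return sorted(self.repeats + self.ssrs + self.genes)

    def to_bed(self) -> str:
        """All truth intervals as BED (0-based half-open) on 'genome'."""
        lines = []
        for track, items in (("repeat", self.repeats), ("ssr", self.ssrs), ("gene", self.genes)):
            for s, e, label in items:
                b0, b1 = to_bed_interval(s, e)
                lines.append(f"genome\t{b0}\t{b1}\t{track}:{label}")
        return "\n".join(lines) + ("\n" if lines else "")


class CapacityError(ValueError):
    """Planted features do not fit in the genome without overlap."""


def _random_seq(rng: np.random.Generator, n: int, freqs) -> str:
    return rng.choice(_BASES, size=n, p=list(freqs)).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute each base independently with probability `divergence`."""
    if divergence <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < divergence
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _place_intervals(
    rng: np.random.Generator, genome_len: int, lengths: list[int], occupied: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Sample non-overlapping 1-based intervals by rejection."""
    placed = []
    taken = sorted(occupied)
    for L in lengths:
        if L > genome_len:
            raise CapacityError(f"feature of length {L} exceeds genome ({genome_len} bp)")
        for _ in range(10_000):
            s = int(rng.integers(1, genome_len - L + 2))
            e = s + L - 1
            if all(e < ts or s > te for ts, te in taken):
                taken.append((s, e))
                placed.append((s, e))
                break
        else:
            raise CapacityError(
                "could not place all planted features without overlap; "
                "reduce feature load or enlarge the genome"
            )
    return placed


def build_genome(spec: GenomeSpec, seed: int) -> tuple[str, TruthTracks]:
    """Generate a genome string and the truth tracks of its planted features.

    Background bases are i.i.d. from ``spec.base_freqs``.  Each repeat copy
    is the family consensus with independent per-base substitutions at the
    family's divergence rate.  SSR loci are exact tandem repetitions of
    their motif.  Gene segments carry background composition and exist as
    truth intervals (their coordinates, not their sequence, are what the
    gene-content estimator is tested against).  Deterministic given seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    genome = np.frombuffer(
        _random_seq(rng, spec.genome_len, spec.base_freqs).encode(), dtype="S1"
    ).copy()
    truth = TruthTracks()

    feature_payloads: list[tuple[str, str, str | None]] = []  # (track, label, sequence)
    for fam in spec.repeat_families:
        consensus = _random_seq(rng, fam.consensus_len, spec.base_freqs)
        truth.consensus[fam.family_id] = consensus
        for _ in range(fam.copy_number):
            feature_payloads.append(
                ("repeat", fam.family_id, _mutate(rng, consensus, fam.divergence))
            )
    for plant in spec.ssr_plants:
        locus_seq = (plant.motif * plant.copies).upper()
        for _ in range(plant.count):
            feature_payloads.append(("ssr", plant.motif.upper(), locus_seq))
    for g in range(spec.n_genes):
        feature_payloads.append(("gene", f"gene{g + 1:04d}", None))

    total = sum(
        len(seq) if seq is not None else spec.gene_len for _, _, seq in feature_payloads
    )
    if total > spec.genome_len:
        raise CapacityError(
            f"planted features ({total} bp) exceed genome capacity ({spec.genome_len} bp)"
        )
    lengths = [len(seq) if seq is not None else spec.gene_len for _, _, seq in feature_payloads]
    intervals = _place_intervals(rng, spec.genome_len, lengths, [])

    for (track, label, seq), (s, e) in zip(feature_payloads, intervals):
        if seq is not None:
            genome[s - 1 : e] = np.frombuffer(seq.encode(), dtype="S1")
        getattr(truth, track + "s").append((s, e, label))
    for tr in (truth.repeats, truth.ssrs, truth.genes):
        tr.sort()

    if spec.cp_seq_len:
        truth.cp_sequence = _random_seq(rng, spec.cp_seq_len, spec.base_freqs)
    if spec.mt_seq_len:
        truth.mt_sequence = _random_seq(rng, spec.mt_seq_len, spec.base_freqs)
    return genome.tobytes().decode(), truth


def sample_clones(genome_len: int, spec: LibrarySimSpec) -> list[CloneInterval]:
    """Draw BAC clone inserts uniformly from the genome.

    Insert lengths follow a truncated normal (mean ``insert_mean``, sd
    ``insert_sd``) bounded to [insert_min, insert_max]; empty and
    chloroplast-contaminant flags are independent Bernoulli draws at the
    spec rates.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    if spec.insert_max > genome_len:
        raise ValueError("insert_max exceeds genome length")
    rng = np.random.default_rng(spec.seed)
    if spec.insert_sd > 0 and spec.insert_min < spec.insert_max:
        a = (spec.insert_min - spec.insert_mean) / spec.insert_sd
        b = (spec.insert_max - spec.insert_mean) / spec.insert_sd
        lengths = truncnorm.rvs(
            a, b, loc=spec.insert_mean, scale=spec.insert_sd,
            size=spec.n_clones, random_state=rng,
        ).astype(int)
    else:
        lengths = np.full(spec.n_clones, spec.insert_mean, dtype=int)
    starts = rng.integers(1, genome_len - lengths + 2)
    empty = rng.random(spec.n_clones) < spec.empty_rate
    is_cp = rng.random(spec.n_clones) < spec.cp_rate
    return [
        CloneInterval(
            clone_id=f"C{i + 1:06d}",
            start=int(starts[i]),
            end=int(starts[i] + lengths[i] - 1),
            is_empty=bool(empty[i]),
            is_cp=bool(is_cp[i] and not empty[i]),
        )
        for i in range(spec.n_clones)
    ]


def simulate_bes_reads(
    clones: list[CloneInterval],
    spec: LibrarySimSpec,
    genome: str,
    cp_sequence: str = "",
    naming: NamingConvention | None = None,
) -> tuple[list[BesRead], dict[str, tuple[int, int, str]]]:
    """Sequence both ends of each non-empty clone.

    The forward read is the plus strand of the leftmost ``read_len_mean``
    bases of the insert; the reverse read is the reverse complement of the
    rightmost bases, so mates face inward as BAC ends do.  Each read is
    independently retained with probability ``read_retention``.

    Chloroplast clones draw their insert from the organelle molecule:
    the insert is capped at its length and the start is folded into its
    coordinate range deterministically.

    Returns the retained reads and a truth map
    ``read_id -> (start, end, strand)`` of genomic reads (cp reads map to
    the cp molecule and are keyed with strand 'cp+'/'cp-').
    """
    naming = naming or NamingConvention()
    rng = np.random.default_rng(spec.seed + 1)
    reads: list[BesRead] = []
    truth_map: dict[str, tuple[int, int, str]] = {}
    L = spec.read_len_mean
    for clone in clones:
        if clone.is_empty:
            continue
        if clone.is_cp:
            if not cp_sequence:
                continue
            src, tag = cp_sequence, "cp"
            ins_len = min(clone.length, len(src))
            start = 1 + (clone.start - 1) % (len(src) - ins_len + 1)
            end = start + ins_len - 1
        else:
            src, tag = genome, ""
            start, end = clone.start, clone.end
        rlen = min(L, end - start + 1)
        for end_label in ("F", "R"):
            if rng.random() >= spec.read_retention:
                continue
            if end_label == "F":
                s, e = start, start + rlen - 1
                seq, strand = src[s - 1 : e], "+"
            else:
                s, e = end - rlen + 1, end
                seq, strand = revcomp(src[s - 1 : e]), "-"
            read_id = naming.format(clone.clone_id, end_label)
            reads.append(BesRead(read_id, clone.clone_id, end_label, seq))
            truth_map[read_id] = (s, e, tag + strand)
    return reads, truth_map


def simulate_marker_screen(
    clones: list[CloneInterval], n_markers: int, genome_len: int, seed: int
) -> np.ndarray:
    """PCR-screen simulation: how many clones cover each of n random loci.

    Markers are single-bp loci placed uniformly at random; a clone scores
    positive for a marker iff its insert interval covers the locus.  Empty
    and organelle clones never score.  Returns per-marker positive counts.
    """
    rng = np.random.default_rng(seed)
    markers = rng.integers(1, genome_len + 1, size=n_markers)
    genomic = [c for c in clones if not c.is_empty and not c.is_cp]
    if not genomic:
        return np.zeros(n_markers, dtype=int)
    starts = np.sort(np.array([c.start for c in genomic]))
    ends = np.sort(np.array([c.end for c in genomic]))
    # covering clones = #(start <= m) - #(end < m)
    return np.searchsorted(starts, markers, side="right") - np.searchsorted(
        ends, markers, side="left"
    )
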
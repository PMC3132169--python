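"""BES FASTA I/O, clone/end naming, mate pairing and dataset statistics.

A BAC end sequence (BES) is a single Sanger read from one end of a BAC
insert.  Read names encode the clone and which end (forward F or reverse
R) the read comes from; two reads of the same clone form a mate pair.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from oakbes._util import round_half_up

_VALID = set("ACGTN")


class FastaParseError(ValueError):
    """Malformed FASTA input (carries the offending record index)."""


class NamingError(ValueError):
    """Read header does not follow the configured clone/end convention."""


class PairingError(ValueError):
    """Duplicate (clone, end) combination while pairing mates."""


@dataclass(frozen=True)
class NamingConvention:
    """How clone identity and end label are encoded in a read header.

    The default is ``<clone><sep><end>`` with ``sep='.'`` and end tokens
    ``F``/``R``, e.g. ``QR001A01.F``.  The separator must occur in the
    header; the part after the LAST separator must be one of the two end
    tokens.
    """

    separator: str = "."
    forward_token: str = "F"
    reverse_token: str = "R"

    def parse(self, read_id: str) -> tuple[str, str]:
        """Split a read id into (clone_id, end_label in {F, R})."""
        clone, sep, token = read_id.rpartition(self.separator)
        if not sep or not clone:
            raise NamingError(
                f"header {read_id!r} does not contain separator {self.separator!r}"
            )
        if token == self.forward_token:
            return clone, "F"
        if token == self.reverse_token:
            return clone, "R"
        raise NamingError(
            f"header {read_id!r}: end token {token!r} is neither "
            f"{self.forward_token!r} nor {self.reverse_token!r}"
        )

    def format(self, clone_id: str, end_label: str) -> str:
        token = self.forward_token if end_label == "F" else self.reverse_token
        return f"{clone_id}{self.separator}{token}"


@dataclass(frozen=True)
class BesRead:
    """One BAC end sequence with its clone identity and end label."""

    read_id: str
    clone_id: str
    end_label: str  # "F" or "R"
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has empty sequence")
        if self.end_label not in ("F", "R"):
            raise ValueError(f"end_label must be F or R, got {self.end_label!r}")
        if not self.clone_id:
            raise ValueError(f"read {self.read_id!r} has empty clone_id")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MatePairSet:
    """Clones with both ends sequenced, and the leftover single-end reads."""

    pairs: dict[str, tuple[BesRead, BesRead]] = field(default_factory=dict)
    singletons: list[BesRead] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return 2 * len(self.pairs) + len(self.singletons)

    @property
    def paired_fraction(self) -> float:
        """Fraction of retained reads that belong to a complete mate pair."""
        n = self.n_reads
        return 2 * len(self.pairs) / n if n else 0.0


@dataclass(frozen=True)
class DatasetStats:
    n_reads: int
    total_bp: int
    min_len: int
    max_len: int
    mean_len: float
    gc_fraction: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def to_tsv(self) -> str:
        lines = [f"{k}\t{v}" for k, v in self.__dict__.items()]
        return "\n".join(lines) + "\n"


def parse_bes_fasta(
    stream: TextIO | str,
    naming: NamingConvention | None = None,
    on_invalid: str = "reject",
) -> list[BesRead]:
    """Parse BES reads from FASTA, deriving clone/end structure from headers.

    Parameters
    ----------
    stream
        Open text handle or a path to a FASTA file.
    naming
        Header convention; defaults to ``<clone>.<F|R>``.
    on_invalid
        ``"reject"`` raises on residues outside {A,C,G,T,N};
        ``"mask"`` maps them to N.
    """
    naming = naming or NamingConvention()
    if on_invalid not in ("reject", "mask"):
        raise ValueError("on_invalid must be 'reject' or 'mask'")
    handle = io.StringIO(stream) if isinstance(stream, str) and "\n" in stream else stream
    reads: list[BesRead] = []
    for idx, record in enumerate(SeqIO.parse(handle, "fasta")):
        seq = str(record.seq).upper()
        if not seq:
            raise FastaParseError(f"record {idx} ({record.id!r}) is empty")
        bad = set(seq) - _VALID
        if bad:
            if on_invalid == "reject":
                raise FastaParseError(
                    f"record {idx} ({record.id!r}) has invalid residues {sorted(bad)}"
                )
            seq = "".join(c if c in _VALID else "N" for c in seq)
        clone_id, end_label = naming.parse(record.id)
        reads.append(BesRead(record.id, clone_id, end_label, seq))
    return reads


def write_bes_fasta(reads: Iterable[BesRead], handle: TextIO, width: int = 70) -> None:
    """Write reads as multi-record FASTA (wrap at `width` columns)."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads
    ]
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(records)


def pair_reads(reads: list[BesRead]) -> MatePairSet:
    """Group reads into mate pairs by clone.

    A clone with exactly one forward and one reverse read becomes a pair;
    every other read is a singleton.  Duplicate (clone, end) combinations
    are an input error.
    """
    by_clone: dict[str, dict[str, BesRead]] = {}
    for r in reads:
        ends = by_clone.setdefault(r.clone_id, {})
        if r.end_label in ends:
            raise PairingError(
                f"clone {r.clone_id!r} has more than one {r.end_label} read"
            )
        ends[r.end_label] = r
    result = MatePairSet()
    for clone_id, ends in by_clone.items():
        if len(ends) == 2:
            result.pairs[clone_id] = (ends["F"], ends["R"])
        else:
            result.singletons.extend(ends.values())
    return result


def dataset_stats(reads: list[BesRead]) -> DatasetStats:
    """Summary statistics of a BES set (lengths and GC content).

    GC is computed over unambiguous bases only: N is excluded from both
    numerator and denominator.
    """
    if not reads:
        raise ValueError("dataset_stats requires at least one read")
    lengths = [r.length for r in reads]
    gc = at = 0
    for r in reads:
        s = r.sequence
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    denom = gc + at
    return DatasetStats(
        n_reads=len(reads),
        total_bp=sum(lengths),
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=sum(lengths) / len(lengths),
        gc_fraction=gc / denom if denom else 0.0,
    )


def retention_rate(n_clones_attempted: int, n_reads_retained: int) -> float:
    """Percent of attempted end reads that survived trimming/QC.

    Both ends of every clone are attempted, so the denominator is
    ``2 * n_clones_attempted``.  Returned as a percentage rounded
    half-up to 2 decimals.
    """
    if n_clones_attempted < 0 or n_reads_retained < 0:
        raise ValueError("counts must be non-negative")
    if n_clones_attempted == 0:
        raise ZeroDivisionError("retention rate undefined for zero attempted clones")
    if n_reads_retained > 2 * n_clones_attempted:
        raise ValueError("cannot retain more reads than 2 x attempted clones")
    return round_half_up(100.0 * n_reads_retained / (2 * n_clones_attempted), 2)
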
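"""Core domain records shared across the package.

All genomic coordinates are 0-based, half-open ``[start, end)``.  Dialect
conversion (1-based callers such as BreakDancer and VCF) happens only at the
parse and write boundaries in :mod:`dmgraph.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """Raised when a record violates one of its invariants."""


#: Recognised structural-variant classes.  CTX denotes an inter-chromosomal
#: translocation, ITX an intra-chromosomal one; BND is an untyped breakend
#: pair (used when a source format carries no type column).
SV_TYPES = frozenset({"DEL", "INV", "ITX", "CTX", "DUP", "BND"})


@dataclass(frozen=True)
class Breakend:
    """One end of a rearrangement: a position on a chromosome.

    ``orient`` is the strand of the supporting reads where the source format
    reports one ('+', '-') and 'unknown' otherwise; the detection algorithms
    use positions only.
    """

    chrom: str
    pos: int
    orient: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("breakend chromosome must be non-empty")
        if self.pos < 0:
            raise ValidationError(f"breakend position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class SVCall:
    """A two-breakend structural-variant prediction.

    Instances are canonically ordered: on a shared chromosome ``end1.pos <=
    end2.pos``; across chromosomes ``end1.chrom <= end2.chrom``.  Use
    :meth:`make` to build calls without worrying about end order.
    """

    end1: Breakend
    end2: Breakend
    svtype: str
    score: Optional[float] = None
    support: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"unknown SV type {self.svtype!r}")
        if self.end1.chrom == self.end2.chrom:
            if self.end1.pos > self.end2.pos:
                raise ValidationError("SVCall ends not canonically ordered")
            if self.svtype == "CTX":
                raise ValidationError("CTX requires ends on different chromosomes")

    @classmethod
    def make(
        cls,
        end1: Breakend,
        end2: Breakend,
        svtype: str,
        score: Optional[float] = None,
        support: Optional[int] = None,
        source: str = "",
    ) -> "SVCall":
        """Build a canonically ordered call, swapping ends if needed."""
        if (end1.chrom, end1.pos) > (end2.chrom, end2.pos):
            end1, end2 = end2, end1
        return cls(end1, end2, svtype, score=score, support=support, source=source)


@dataclass(frozen=True)
class RawCnvCall:
    """An amplified-copy-number call before merging.

    ``coverage`` is the mean mapping coverage (reads per base) over the
    interval, or ``None`` when the source file carries no coverage column.
    """

    chrom: str
    start: int
    end: int
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.coverage is not None and self.coverage < 0:
            raise ValidationError("coverage must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Amplicon:
    """A merged amplified interval; a vertex of the amplicon graph.

    Ids are dense from 0, assigned in sorted genomic order
    ``(chrom, start, end)`` so that vertex id order is genome order.
    """

    id: int
    chrom: str
    start: int
    end: int
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValidationError("amplicon id must be >= 0")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class InsertSizeModel:
    """Insert-size parameters of the sequencing library.

    Two breakends are 'proximal' when their distance is at most
    ``L = mean + k * stdev``, i.e. within the span a discordant read pair can
    bridge.  ``k`` controls how many standard deviations of insert-size
    variation are tolerated (k=3 covers ~99.7% of a Gaussian library).
    """

    mean: float
    stdev: float
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.mean < 0 or self.stdev < 0 or self.k < 0:
            raise ValidationError("insert-size parameters must be >= 0")

    @property
    def L(self) -> float:
        return self.mean + self.k * self.stdev


@dataclass
class DMPrediction:
    """A predicted double minute: an ordered walk over amplicons.

    For a cyclic prediction ``amplicons`` lists the cycle in order (the edge
    from the last member back to the first closes the circle); for an acyclic
    one it lists the weakly connected component in ascending id order.
    ``junctions`` maps each supporting undirected edge ``(u, v)`` (amplicon
    ids, u < v) to its SV evidence.
    """

    dm_id: int
    amplicons: list  # list[Amplicon], walk order
    junctions: list  # list[tuple[tuple[int, int], list[SVCall]]]
    cyclic: bool

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)

    @property
    def amplicon_ids(self) -> list:
        return [a.id for a in self.amplicons]

    def coverage_stats(self):
        """(min, max, mean) coverage over members, or None if any is missing."""
        covs = [a.coverage for a in self.amplicons]
        if any(c is None for c in covs) or not covs:
            return None
        return min(covs), max(covs), sum(covs) / len(covs)


@dataclass(frozen=True)
class DetectParams:
    """Tunable thresholds of the detection stage."""

    min_amplicons: int = 7
    coverage_filter: bool = True
    coverage_filter_acyclic: bool = True
    allow_singleton: bool = False

    def __post_init__(self) -> None:
        if self.min_amplicons < 1:
            raise ValidationError("min_amplicons must be >= 1")
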
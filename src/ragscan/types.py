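"""Core domain records shared by every analysis stage.

All genomic coordinates held in these records are 0-based and intervals are
half-open, matching BED/bedGraph conventions.  File dialects that use 1-based
positions (the junction-table TSV) are converted on read and write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = ("+", "-")


@dataclass(frozen=True)
class JunctionRecord:
    """One recovered bait--prey junction from a translocation-sequencing library."""

    library_id: str
    chrom: str
    junction_pos: int  # 0-based
    prey_orientation: str  # "+" or "-"
    bait_id: str
    read_id: str

    def __post_init__(self) -> None:
        if self.prey_orientation not in STRANDS:
            raise ValueError(
                f"prey_orientation must be one of {STRANDS}, got {self.prey_orientation!r}"
            )
        if self.junction_pos < 0:
            raise ValueError(f"junction_pos must be nonnegative, got {self.junction_pos}")


@dataclass(frozen=True)
class BaitSpec:
    """The fixed bait of a library: cleavage position, orientation and the
    self-ligation exclusion interval removed before 3C normalization."""

    bait_id: str
    chrom: str
    cleavage_pos: int
    orientation: str
    self_ligation_exclusion: tuple[int, int]  # half-open, on bait chrom

    def __post_init__(self) -> None:
        if self.orientation not in STRANDS:
            raise ValueError(f"orientation must be one of {STRANDS}")
        s, e = self.self_ligation_exclusion
        if not e > s:
            raise ValueError("self_ligation_exclusion interval must be nonempty")


@dataclass
class JunctionLibrary:
    """One sequencing library: junction records plus the germline read count.

    Germline (unjoined bait-side) reads carry no coordinates; only their count
    matters, because library size for normalization is junctions + germline.
    """

    library_id: str
    records: list[JunctionRecord]
    germline_read_count: int
    bait: Optional[BaitSpec] = None
    repeat_id: str = "rep1"

    def __post_init__(self) -> None:
        if self.germline_read_count < 0:
            raise ValueError("germline_read_count must be nonnegative")

    @property
    def total_reads(self) -> int:
        return len(self.records) + self.germline_read_count


@dataclass(frozen=True)
class SegmentSpec:
    """An annotated gene segment and its recombination signal sequence (RSS).

    ``rss_cleavage_pos`` is the first base of the heptamer read in the site's
    orientation (the base adjacent to the coding flank).  ``strength`` is a
    simulation weight standing in for empirical RSS utilisation.
    """

    segment_id: str
    chrom: str
    rss_cleavage_pos: int
    orientation: str
    rss_kind: int  # 12 or 23 (spacer length class)
    strength: float = 1.0
    domain_label: str = "other"

    def __post_init__(self) -> None:
        if self.orientation not in STRANDS:
            raise ValueError("orientation must be '+' or '-'")
        if self.rss_kind not in (12, 23):
            raise ValueError("rss_kind must be 12 or 23")
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")


@dataclass(frozen=True)
class RSSSite:
    """A candidate or annotated RSS found by the genome scanner.

    ``cleavage_pos`` follows the same convention as :class:`SegmentSpec`:
    first base of the heptamer in site orientation.
    """

    chrom: str
    cleavage_pos: int
    orientation: str
    spacer_class: int  # 12 or 23
    mismatches: int

    def __post_init__(self) -> None:
        if self.orientation not in STRANDS:
            raise ValueError("orientation must be '+' or '-'")
        if self.spacer_class not in (12, 23):
            raise ValueError("spacer_class must be 12 or 23")
        if not 0 <= self.mismatches <= 13:
            raise ValueError("mismatches must be in [0, 13]")


@dataclass(frozen=True)
class CacSite:
    """A cryptic cleavage site: a bare CAC trinucleotide. ``pos`` is the first
    base of the CAC read in the site's orientation."""

    chrom: str
    pos: int
    orientation: str


@dataclass
class CrypticPeak:
    """Coding-end junctions collapsed onto one cryptic CAC cleavage site."""

    chrom: str
    cac_pos: int
    orientation: str
    member_offsets: list[int] = field(default_factory=list)

    @property
    def junction_count(self) -> int:
        return len(self.member_offsets)


@dataclass
class PeakRegion:
    """A called 3C interaction peak: span, summit and its statistics."""

    chrom: str
    start: int
    end: int  # half-open
    summit_pos: int
    summit_raw_p: float
    summit_adj_p: float
    support: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start <= self.summit_pos < self.end:
            raise ValueError("summit must lie inside the peak span")


@dataclass(frozen=True)
class MotifHit:
    """A PWM placement above threshold. ``start`` is the forward-strand start
    of the motif window regardless of strand."""

    chrom: str
    start: int
    strand: str
    score: float
    width: int


@dataclass
class PeakFeatures:
    """Feature annotation of one robust interaction peak (window = peak +/- flank).

    Labels: C = >=1 reliable CTCF-binding element, E = max E2A signal >= 0.5,
    T = transcribed (GRO max >= 40 or mean >= 10 in >= 2 repeats), U = none.
    """

    peak_name: str
    cbe_count: int
    cbe_orientations: list[str]
    e2a_max: float
    transcription: bool
    labels: frozenset[str]
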
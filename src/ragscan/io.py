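"""Readers and writers for the project's file dialects.

Dialects:

* junction-table TSV — header comment ``#germline_reads=<int>`` (optionally
  ``#repeat_id=<label>``), then a tab-separated header
  ``library_id chrom junction_pos strand bait_id read_id``; positions in the
  file are 1-based and converted to the internal 0-based convention on read.
* BED6 / bedGraph — 0-based half-open, as the standards define.
* JASPAR count matrix — parsed through Bio.motifs.

Parsers reject malformed input with the offending line number; they never
silently repair.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .types import JunctionLibrary, JunctionRecord, PeakRegion

JUNCTION_COLUMNS = ["library_id", "chrom", "junction_pos", "strand", "bait_id", "read_id"]


class ParseError(ValueError):
    """Malformed input; message always carries a line number."""


def parse_junction_table(path: str) -> JunctionLibrary:
    """Read one library from a junction-table TSV (1-based positions in file)."""
    germline = None
    repeat_id = "rep1"
    records: list[JunctionRecord] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#germline_reads="):
                    try:
                        germline = int(line.split("=", 1)[1])
                    except ValueError:
                        raise ParseError(f"line {lineno}: non-integer germline_reads value")
                elif line.startswith("#repeat_id="):
                    repeat_id = line.split("=", 1)[1]
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != JUNCTION_COLUMNS:
                    raise ParseError(
                        f"line {lineno}: expected header {JUNCTION_COLUMNS}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != len(JUNCTION_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(JUNCTION_COLUMNS)} columns, got {len(fields)}"
                )
            lib_id, chrom, pos_s, strand, bait_id, read_id = fields
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer junction_pos {pos_s!r}")
            if pos1 < 1:
                raise ParseError(f"line {lineno}: 1-based junction_pos must be >= 1, got {pos1}")
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
            records.append(
                JunctionRecord(
                    library_id=lib_id,
                    chrom=chrom,
                    junction_pos=pos1 - 1,
                    prey_orientation=strand,
                    bait_id=bait_id,
                    read_id=read_id,
                )
            )
    if not header_seen:
        raise ParseError("line 1: missing header line")
    if germline is None:
        raise ParseError("line 1: missing required '#germline_reads=<int>' header comment")
    library_id = records[0].library_id if records else "unknown"
    return JunctionLibrary(
        library_id=library_id,
        records=records,
        germline_read_count=germline,
        repeat_id=repeat_id,
    )


def write_junction_table(lib: JunctionLibrary, path: str) -> None:
    """Write a library in the junction-table TSV dialect (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(f"#germline_reads={lib.germline_read_count}\n")
        fh.write(f"#repeat_id={lib.repeat_id}\n")
        fh.write("\t".join(JUNCTION_COLUMNS) + "\n")
        for r in lib.records:
            fh.write(
                "\t".join(
                    [
                        r.library_id,
                        r.chrom,
                        str(r.junction_pos + 1),
                        r.prey_orientation,
                        r.bait_id,
                        r.read_id,
                    ]
                )
                + "\n"
            )


def _bed_score(raw_p: float) -> int:
    if raw_p <= 0:
        return 1000
    return min(1000, round(-10.0 * math.log10(raw_p)))


def write_peaks_bed(peaks: Sequence[PeakRegion], path: str) -> None:
    """Write peaks as BED6 plus a ``<path>.stats.tsv`` sidecar with full statistics.

    Score = round(-10*log10(summit raw P)) capped at 1000. Input must be sorted
    by (chrom, start).
    """
    keys = [(p.chrom, p.start) for p in peaks]
    if keys != sorted(keys):
        raise ValueError("peaks must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{_bed_score(p.summit_raw_p)}\t.\n"
            )
    with open(path + ".stats.tsv", "w") as fh:
        fh.write("name\tchrom\tstart\tend\tsummit_pos\tsummit_raw_p\tsummit_adj_p\tsupport\n")
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            fh.write(
                f"{name}\t{p.chrom}\t{p.start}\t{p.end}\t{p.summit_pos}"
                f"\t{p.summit_raw_p:.6g}\t{p.summit_adj_p:.6g}\t{p.support}\n"
            )


class StepSignal:
    """A step-function signal over the genome (bedGraph semantics).

    Uncovered bases have value 0.  Intervals within one chromosome must not
    overlap.  Supports max and mean over any query interval.
    """

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # intervals: chrom -> (starts, ends, values), will be sorted by start
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted interval")
            if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping intervals in signal track")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path: str) -> "StepSignal":
        per_chrom: dict[str, list[list]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"line {lineno}: bedGraph needs 4 columns, got {len(fields)}")
                chrom = fields[0]
                try:
                    start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric bedGraph fields")
                per_chrom.setdefault(chrom, [[], [], []])
                per_chrom[chrom][0].append(start)
                per_chrom[chrom][1].append(end)
                per_chrom[chrom][2].append(value)
        return cls(
            {
                c: (np.array(s), np.array(e), np.array(v))
                for c, (s, e, v) in per_chrom.items()
            }
        )

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._data):
                starts, ends, values = self._data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def _overlaps(self, chrom: str, start: int, end: int):
        if chrom not in self._data or end <= start:
            return None
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return None
        return starts[lo:hi], ends[lo:hi], values[lo:hi]

    def max(self, chrom: str, start: int, end: int) -> float:
        """Max signal over [start, end); 0 if nothing covered (value floor is 0)."""
        ov = self._overlaps(chrom, start, end)
        if ov is None:
            return 0.0
        covered = int(np.sum(np.minimum(ov[1], end) - np.maximum(ov[0], start)))
        m = float(ov[2].max())
        if covered < end - start:  # some uncovered bases contribute value 0
            m = max(m, 0.0)
        return m

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over [start, end), uncovered bases counting as 0."""
        if end <= start:
            raise ValueError("empty query interval")
        ov = self._overlaps(chrom, start, end)
        if ov is None:
            return 0.0
        widths = np.minimum(ov[1], end) - np.maximum(ov[0], start)
        return float(np.sum(widths * ov[2]) / (end - start))


def parse_motif_matrix(path: str) -> np.ndarray:
    """Parse a JASPAR-format count matrix into a (4, width) array, rows A/C/G/T."""
    with open(path) as fh:
        try:
            motif = bio_motifs.read(fh, "jaspar")
        except Exception as exc:
            raise ParseError(f"line 1: cannot parse JASPAR matrix: {exc}")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ParseError("line 1: JASPAR matrix must have 4 base rows")
    if np.any(counts < 0):
        raise ParseError("line 1: JASPAR matrix contains negative counts")
    return counts


def parse_bed_intervals(path: str) -> dict[str, np.ndarray]:
    """Read a BED file of intervals into chrom -> (n, 2) sorted array.

    Only the first three columns are used (enough for ChIP peak sets).
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer BED coordinates")
            if end <= start:
                raise ParseError(f"line {lineno}: empty/inverted BED interval")
            per_chrom.setdefault(fields[0], []).append((start, end))
    return {c: np.array(sorted(iv), dtype=np.int64) for c, iv in per_chrom.items()}


def write_bed_intervals(intervals: Mapping[str, np.ndarray], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")
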
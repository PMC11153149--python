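"""Cryptic-RSS analysis of RAG off-target junctions.

A recombination signal sequence (RSS) is a heptamer (consensus CACAGTG), a
12- or 23-bp spacer, and a nonamer (consensus ACAAAAACC).  RAG cleaves between
the coding flank and the heptamer, so the cleavage coordinate used throughout
is the first base of the heptamer read in the site's orientation.

The off-target workflow:

1. score candidate windows against the ideal RSS (CAC gate, then Hamming
   mismatches over the remaining heptamer AGTG and the nonamer);
2. scan the genome for unannotated near-consensus sites (<= 4 mismatches) --
   these behave as bona fide RSSs and are eliminated from cryptic analyses;
3. split a junction library into on-target / cryptic / removed;
4. collapse cryptic coding-end junctions within 15 bp onto their CAC cleavage
   site;
5. classify each junction as deletional (prey convergent with bait) or
   inversional (prey in the same orientation as bait) and summarise fractions
   per region across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, revcomp
from .types import CacSite, CrypticPeak, JunctionLibrary, JunctionRecord, RSSSite, SegmentSpec

IDEAL_HEPTAMER = "CACAGTG"
IDEAL_NONAMER = "ACAAAAACC"
# full element span for the longer (23-bp) spacer: 7 + 23 + 9
RSS_WINDOW = len(IDEAL_HEPTAMER) + 23 + len(IDEAL_NONAMER)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def mismatch_to_ideal_rss(window: str, orientation: str = "+") -> Optional[tuple[int, int]]:
    """Score a genomic window against the ideal RSS.

    ``window`` is forward-strand sequence.  For orientation "+" the element
    starts at the first base of the window; for "-" it ends at the last base
    (the window is reverse-complemented internally).  Returns
    ``(spacer_class, mismatch_count)`` where mismatches are counted over the
    13 positions heptamer[4:7+1] vs AGTG and the 9 nonamer bases vs ACAAAAACC,
    with both spacer lengths tried (tie broken toward 12).  Returns ``None``
    (no call) unless the first three bases are exactly CAC.
    """
    if orientation not in ("+", "-"):
        raise ValueError("orientation must be '+' or '-'")
    if len(window) < RSS_WINDOW:
        raise ValueError(f"window must be >= {RSS_WINDOW} bases, got {len(window)}")
    w = window if orientation == "+" else revcomp(window)
    if w[0:3] != "CAC":
        return None
    mm_hept = _hamming(w[3:7], "AGTG")
    best = None
    for spacer in (12, 23):
        non = w[7 + spacer : 7 + spacer + 9]
        mm = mm_hept + _hamming(non, IDEAL_NONAMER)
        if best is None or mm < best[1]:
            best = (spacer, mm)
    return best


def _scan_forward(seq: str, chrom: str, orientation: str, length: int, max_mismatch: int):
    """Scan one strand's heptamer-first representation for near-consensus RSSs.

    ``seq`` is the strand sequence read 5'->3' in site orientation; yielded
    index i is the heptamer start on that representation.
    """
    out = []
    i = seq.find("CAC")
    while i != -1:
        if i + RSS_WINDOW <= length:
            call = mismatch_to_ideal_rss(seq[i : i + RSS_WINDOW], "+")
            if call is not None and call[1] <= max_mismatch:
                out.append((i, call[0], call[1]))
        i = seq.find("CAC", i + 1)
    return out


def scan_unannotated_rss(genome: GenomeModel, max_mismatch: int = 4) -> list[RSSSite]:
    """Find every position/orientation scoring <= max_mismatch to the ideal RSS.

    Output is sorted by (chrom, cleavage_pos, orientation) and deterministic.
    """
    sites: list[RSSSite] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        n = len(seq)
        for i, spacer, mm in _scan_forward(seq, chrom, "+", n, max_mismatch):
            sites.append(RSSSite(chrom, i, "+", spacer, mm))
        rc = revcomp(seq)
        for i, spacer, mm in _scan_forward(rc, chrom, "-", n, max_mismatch):
            # heptamer start on reverse strand index i maps to forward coord n-1-i
            sites.append(RSSSite(chrom, n - 1 - i, "-", spacer, mm))
    sites.sort(key=lambda s: (s.chrom, s.cleavage_pos, s.orientation))
    return sites


@dataclass
class SplitResult:
    """Partition of a junction library into on-target / cryptic / removed."""

    on_target: list[JunctionRecord]
    on_target_segment: list[str]  # segment_id per on-target record, parallel list
    cryptic: list[JunctionRecord]
    removed: list[JunctionRecord]

    def counts(self) -> tuple[int, int, int]:
        return len(self.on_target), len(self.cryptic), len(self.removed)


def _nearest(positions: np.ndarray, pos: int) -> tuple[int, int]:
    """Index and distance of the element of sorted ``positions`` nearest to
    ``pos``; exact ties resolved to the leftmost (smaller coordinate)."""
    j = int(np.searchsorted(positions, pos))
    best_idx, best_d = -1, None
    for k in (j - 1, j):
        if 0 <= k < positions.size:
            d = abs(int(positions[k]) - pos)
            if best_d is None or d < best_d:
                best_idx, best_d = k, d
    return best_idx, best_d if best_d is not None else -1


def split_on_off_target(
    lib: JunctionLibrary,
    annotated: Sequence[SegmentSpec],
    unannotated: Sequence[RSSSite],
    tolerance: int = 50,
) -> SplitResult:
    """Partition junctions by proximity to annotated and unannotated RSSs.

    A junction is on-target iff it lies within ``tolerance`` bp of an annotated
    RSS cleavage site with consistent orientation (prey orientation equal to
    the segment's RSS orientation).  Junctions within tolerance of an
    unannotated near-consensus site (any orientation) are removed from cryptic
    analyses.  Everything else is cryptic.  The three outputs partition input.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ann_idx: dict[tuple[str, str], tuple[np.ndarray, list[str]]] = {}
    for key_chrom in {s.chrom for s in annotated}:
        for orient in ("+", "-"):
            segs = sorted(
                (s for s in annotated if s.chrom == key_chrom and s.orientation == orient),
                key=lambda s: s.rss_cleavage_pos,
            )
            if segs:
                ann_idx[(key_chrom, orient)] = (
                    np.array([s.rss_cleavage_pos for s in segs], dtype=np.int64),
                    [s.segment_id for s in segs],
                )
    unann_idx: dict[str, np.ndarray] = {}
    for chrom in {s.chrom for s in unannotated}:
        unann_idx[chrom] = np.array(
            sorted(s.cleavage_pos for s in unannotated if s.chrom == chrom), dtype=np.int64
        )

    res = SplitResult([], [], [], [])
    for rec in lib.records:
        hit = ann_idx.get((rec.chrom, rec.prey_orientation))
        if hit is not None:
            idx, d = _nearest(hit[0], rec.junction_pos)
            if idx >= 0 and d <= tolerance:
                res.on_target.append(rec)
                res.on_target_segment.append(hit[1][idx])
                continue
        upos = unann_idx.get(rec.chrom)
        if upos is not None and upos.size:
            _, d = _nearest(upos, rec.junction_pos)
            if d <= tolerance:
                res.removed.append(rec)
                continue
        res.cryptic.append(rec)
    return res


def collapse_cryptic(
    cryptic: Sequence[JunctionRecord],
    cac_catalog: Sequence[CacSite],
    radius: int = 15,
) -> tuple[list[CrypticPeak], list[JunctionRecord]]:
    """Collapse coding-end junctions within ``radius`` bp onto CAC cleavage sites.

    Each junction is assigned to the nearest CAC site of matching orientation;
    exact distance ties go to the leftmost site coordinate.  Junctions not
    within radius of any matching-orientation CAC are returned unassigned.
    Total junction count is conserved: sum of peak counts + unassigned = input.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    cac_idx: dict[tuple[str, str], np.ndarray] = {}
    for chrom, orient in {(c.chrom, c.orientation) for c in cac_catalog}:
        cac_idx[(chrom, orient)] = np.array(
            sorted(c.pos for c in cac_catalog if c.chrom == chrom and c.orientation == orient),
            dtype=np.int64,
        )
    peaks: dict[tuple[str, int, str], CrypticPeak] = {}
    unassigned: list[JunctionRecord] = []
    for rec in cryptic:
        positions = cac_idx.get((rec.chrom, rec.prey_orientation))
        if positions is None or positions.size == 0:
            unassigned.append(rec)
            continue
        idx, d = _nearest(positions, rec.junction_pos)
        if d > radius:
            unassigned.append(rec)
            continue
        key = (rec.chrom, int(positions[idx]), rec.prey_orientation)
        peaks.setdefault(key, CrypticPeak(*key)).member_offsets.append(d)
    ordered = [peaks[k] for k in sorted(peaks)]
    return ordered, unassigned


def classify_orientation(bait_orientation: str, prey_orientation: str) -> str:
    """Deletional if prey RSS is convergent (opposite strand) with the bait RSS,
    inversional if in the same orientation."""
    for o in (bait_orientation, prey_orientation):
        if o not in ("+", "-"):
            raise ValueError(f"invalid orientation {o!r}")
    return "inversional" if bait_orientation == prey_orientation else "deletional"


def orientation_fractions(
    per_repeat_records: Mapping[str, Sequence[JunctionRecord]],
    bait_orientation: str,
    regions: Mapping[str, tuple[str, int, int]],
    known_chroms: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Percent deletional / inversional cryptic junctions per region, across repeats.

    Returns one row per region with per-repeat percentages aggregated as
    mean +/- s.e.m. (sample sd / sqrt(n_repeats)).  A region with no junctions
    in any repeat is flagged ``empty`` rather than reported as 0/0.
    """
    if not per_repeat_records:
        raise ValueError("need at least one repeat")
    if known_chroms is not None:
        known = set(known_chroms)
        for name, (chrom, _, _) in regions.items():
            if chrom not in known:
                raise ValueError(f"region {name!r} is on unknown chromosome {chrom!r}")
    rows = []
    for name, (chrom, start, end) in regions.items():
        del_pcts, inv_pcts, totals = [], [], []
        for rep_id in sorted(per_repeat_records):
            recs = [
                r
                for r in per_repeat_records[rep_id]
                if r.chrom == chrom and start <= r.junction_pos < end
            ]
            n = len(recs)
            totals.append(n)
            if n == 0:
                continue
            n_del = sum(
                classify_orientation(bait_orientation, r.prey_orientation) == "deletional"
                for r in recs
            )
            del_pcts.append(100.0 * n_del / n)
            inv_pcts.append(100.0 * (n - n_del) / n)
        empty = len(del_pcts) == 0
        def _summ(vals):
            if not vals:
                return np.nan, np.nan
            arr = np.asarray(vals, dtype=float)
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            return float(arr.mean()), sem
        dm, dsem = _summ(del_pcts)
        im, isem = _summ(inv_pcts)
        rows.append(
            {
                "region": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_junctions_total": int(sum(totals)),
                "n_repeats_nonempty": len(del_pcts),
                "pct_deletional_mean": dm,
                "pct_deletional_sem": dsem,
                "pct_inversional_mean": im,
                "pct_inversional_sem": isem,
                "is_empty": empty,
            }
        )
    return pd.DataFrame(rows)
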
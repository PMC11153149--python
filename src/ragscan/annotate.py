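"""Feature annotation of robust interaction peaks.

Each robust peak, extended by a 1 kb flank on both sides, is annotated with:

* C -- at least one reliable CTCF-binding element (CBE): a PWM hit with
  log-odds score above threshold (default > 13, calibrated to the FIMO scale
  of the JASPAR CTCF matrix, configurable) that overlaps a ChIP peak in >= 2
  repeats; orientations are reported as rightward (+) / leftward (-);
* E -- maximum E2A ChIP signal in the window >= 0.5;
* T -- transcribed: GRO-seq max >= 40 or mean >= 10 within the window, in
  >= 2 repeats;
* U -- none of the above.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .genome import GenomeModel, revcomp
from .io import StepSignal
from .types import MotifHit, PeakFeatures, PeakRegion

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def pwm_log_odds(counts: np.ndarray) -> np.ndarray:
    """Log-odds matrix from a position count matrix.

    Per column i with total T_i, the pseudocount is eps = 0.01 * T_i and the
    score of base b is log2(((c_ib + eps) / (T_i + 4 eps)) / 0.25).  A column
    with zero total is an error.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x width")
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero-total column in count matrix")
    eps = 0.01 * totals
    probs = (counts + eps) / (totals + 4 * eps)
    return np.log2(probs / 0.25)


def _scan_strand(seq: str, lo: np.ndarray) -> np.ndarray:
    """Scores of every placement of the log-odds matrix along one strand.

    Placements containing N score -inf (never a hit).
    """
    w = lo.shape[1]
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.full(256, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[ord(b)] = i
    coded = idx[code]
    if coded.size < w:
        return np.empty(0)
    lo_ext = np.vstack([lo, np.full((1, w), -np.inf)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(coded, w)
    return lo_ext[windows, np.arange(w)].sum(axis=1)


def pwm_scan(
    genome: GenomeModel, counts: np.ndarray, threshold: float = 13.0
) -> list[MotifHit]:
    """Scan both strands for PWM placements with log-odds score > threshold.

    Hit coordinates are forward-strand starts of the motif window for both
    strands.  Output sorted by (chrom, start, strand).
    """
    lo = pwm_log_odds(counts)
    w = lo.shape[1]
    if w < 4:
        raise ValueError("matrix width must be >= 4")
    hits: list[MotifHit] = []
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        n = len(seq)
        fwd = _scan_strand(seq, lo)
        for p in np.flatnonzero(fwd > threshold):
            hits.append(MotifHit(chrom, int(p), "+", float(fwd[p]), w))
        rev = _scan_strand(revcomp(seq), lo)
        for q in np.flatnonzero(rev > threshold):
            hits.append(MotifHit(chrom, int(n - w - q), "-", float(rev[q]), w))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def _overlaps_any(intervals: np.ndarray, start: int, end: int) -> bool:
    """Whether [start, end) overlaps any interval in a (n, 2) sorted array."""
    if intervals.size == 0:
        return False
    i = int(np.searchsorted(intervals[:, 0], end, side="left"))
    return bool(np.any(intervals[:i, 1] > start))


def reliable_cbes(
    hits: Sequence[MotifHit],
    chip_peak_sets: Sequence[Mapping[str, np.ndarray]],
    score_threshold: float = 13.0,
    min_repeats: int = 2,
) -> list[MotifHit]:
    """Keep motif hits with score > threshold that overlap a ChIP peak in
    >= min_repeats repeats.  Orientation is carried by the hit strand
    (+ = rightward, - = leftward)."""
    if len(chip_peak_sets) < 2:
        raise ValueError("need at least 2 ChIP repeats")
    kept = []
    for h in hits:
        if h.score <= score_threshold:
            continue
        n_sup = sum(
            _overlaps_any(
                np.asarray(peaks.get(h.chrom, np.empty((0, 2), dtype=np.int64))).reshape(-1, 2),
                h.start,
                h.start + h.width,
            )
            for peaks in chip_peak_sets
        )
        if n_sup >= min_repeats:
            kept.append(h)
    return kept


def cbe_orientation(hit: MotifHit) -> str:
    return "rightward" if hit.strand == "+" else "leftward"


def annotate_peaks(
    peaks: Sequence[PeakRegion],
    cbes: Sequence[MotifHit],
    e2a_track: StepSignal,
    gro_tracks: Sequence[StepSignal],
    flank: int = 1000,
    e2a_threshold: float = 0.5,
    gro_max_threshold: float = 40.0,
    gro_mean_threshold: float = 10.0,
    gro_min_repeats: int = 2,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[PeakFeatures]:
    """Assign C/E/T/U labels to each peak over the window [start-flank, end+flank).

    A GRO repeat supports transcription if its max >= 40 OR its mean >= 10
    within the window; T requires >= gro_min_repeats supporting repeats.
    The window is clipped at chromosome bounds when lengths are given.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for i, peak in enumerate(peaks):
        start = max(0, peak.start - flank)
        end = peak.end + flank
        if chrom_lengths is not None and peak.chrom in chrom_lengths:
            end = min(end, chrom_lengths[peak.chrom])
        in_window = [
            h
            for h in cbes
            if h.chrom == peak.chrom and h.start < end and h.start + h.width > start
        ]
        e2a_max = e2a_track.max(peak.chrom, start, end)
        n_transcribed = sum(
            1
            for g in gro_tracks
            if g.max(peak.chrom, start, end) >= gro_max_threshold
            or g.mean(peak.chrom, start, end) >= gro_mean_threshold
        )
        labels = set()
        if in_window:
            labels.add("C")
        if e2a_max >= e2a_threshold:
            labels.add("E")
        transcription = n_transcribed >= gro_min_repeats
        if transcription:
            labels.add("T")
        if not labels:
            labels.add("U")
        out.append(
            PeakFeatures(
                peak_name=peak.name or f"peak_{i + 1}",
                cbe_count=len(in_window),
                cbe_orientations=[cbe_orientation(h) for h in in_window],
                e2a_max=e2a_max,
                transcription=transcription,
                labels=frozenset(labels),
            )
        )
    return out
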
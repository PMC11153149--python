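"""Seeded generators emulating the statistical structure of the two library types.

``make_synthetic_locus`` builds a random locus with planted bona fide RSSs
(exact consensus heptamer + 12/23 spacer + consensus nonamer), bare cryptic
CAC sites, CATG restriction sites, and optional CTCF-motif / E2A /
transcription features.  Any accidental background window that would pass the
<=4-mismatch bona fide filter is rewritten, so the planted catalog is exactly
the set of filter-passing sites (this closure is what makes exact-equality
scanner tests possible).

``simulate_vdj_library`` draws on-target junctions multinomially over segment
strengths and cryptic junctions at CAC sites under one of two modes:

* scanning -- cryptic joins only at CACs convergent with the bait, between the
  recombination centre and a planted impediment, with intensity decaying with
  distance (the linear-tracking picture);
* diffusion -- both orientations, restricted to a radius around the
  recombination centre (the 3D-capture picture).

``simulate_3c_library`` draws bait-anchored junction counts at restriction
sites with a power-law distance decay, planted anchor enrichments, and a
self-ligation spike inside the bait exclusion interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome import GenomeModel, RestrictionMap, revcomp
from .io import StepSignal
from .rss import IDEAL_HEPTAMER, IDEAL_NONAMER, RSS_WINDOW, scan_unannotated_rss
from .types import BaitSpec, CacSite, JunctionLibrary, JunctionRecord, SegmentSpec

# a sharp CTCF-like consensus used when planting CBE features
DEFAULT_CBE_CONSENSUS = "TGGCCACCAGGGGGCGCTA"


@dataclass
class SimConfig:
    """Parameters of the generative model (one seeded draw per library).

    Junction totals default to the 500,000-read convention used for absolute
    V(D)J level comparisons; 3C libraries default to 60,000 junctions so that
    min-library normalization is exercised.
    """

    mode: str = "scanning"  # or "diffusion"
    locus_length: int = 200_000
    chrom: str = "chrSim"
    n_total_reads: int = 500_000
    junction_fraction: float = 0.2  # junctions / total reads before germline
    cryptic_rate: float = 0.05  # fraction of junctions at cryptic CACs
    scan_impediment_pos: Optional[int] = None  # default 0.3 * locus_length
    diffusion_radius: int = 60_000
    decay_exponent: float = 1.0  # 3C background: lambda ~ (1+d)^-decay
    anchors: tuple[tuple[int, float], ...] = ()  # (site index, enrichment >= 1)
    restriction_spacing: int = 250
    n_segments: int = 24
    n_cryptic_pairs: int = 150  # CAC sites planted as +/- pairs (orientation symmetry)
    segment_strengths: Optional[tuple[float, ...]] = None
    n_3c_junctions: int = 60_000
    self_ligation_weight: float = 0.15  # expected fraction of 3C reads in the spike
    jitter_3c: int = 0  # optional +/- jitter of 3C junction positions (<= 3)
    cbe_positions: tuple[int, ...] = ()
    e2a_positions: tuple[int, ...] = ()
    transcription_positions: tuple[int, ...] = ()
    cbe_consensus: str = DEFAULT_CBE_CONSENSUS

    def __post_init__(self) -> None:
        if self.mode not in ("scanning", "diffusion"):
            raise ValueError("mode must be 'scanning' or 'diffusion'")
        for p in (self.junction_fraction, self.cryptic_rate, self.self_ligation_weight):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if any(f < 1 for _, f in self.anchors):
            raise ValueError("anchor enrichment factors must be >= 1")
        if not 0 <= self.jitter_3c <= 3:
            raise ValueError("3C jitter must be in [0, 3]")


@dataclass
class SyntheticLocus:
    """One generated locus and its ground truth."""

    genome: GenomeModel
    segments: list[SegmentSpec]
    cac_catalog: list[CacSite]
    rmap: RestrictionMap
    bait: BaitSpec
    config: SimConfig
    cbe_positions: tuple[int, ...] = ()
    e2a_positions: tuple[int, ...] = ()
    transcription_positions: tuple[int, ...] = ()


def _plant(seq: np.ndarray, pos: int, element: str) -> None:
    seq[pos : pos + len(element)] = np.frombuffer(element.encode(), dtype=np.uint8)


def _element_for(orientation: str, spacer_len: int, rng: np.random.Generator) -> str:
    spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))
    elem = IDEAL_HEPTAMER + spacer + IDEAL_NONAMER
    return elem if orientation == "+" else revcomp(elem)


def _footprint(pos: int, orientation: str, length: int) -> tuple[int, int]:
    """Forward-strand half-open span of an element whose oriented first base is
    at ``pos`` (elements on '-' extend leftward)."""
    return (pos, pos + length) if orientation == "+" else (pos - length + 1, pos + 1)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _compared_positions(site_pos: int, orientation: str, spacer: int) -> list[tuple[int, str]]:
    """(forward coordinate, forbidden forward base) for every position the
    mismatch filter reads: CAC gate first (breaking it removes the site
    outright), then heptamer AGTG, then the nonamer for the site's spacer
    class.  The forbidden base is the one that would match the consensus."""
    consensus = IDEAL_HEPTAMER + "." * spacer + IDEAL_NONAMER
    offsets = list(range(0, 7)) + list(range(7 + spacer, 7 + spacer + 9))
    out = []
    for o in offsets:
        c = consensus[o]
        if orientation == "+":
            out.append((site_pos + o, c))
        else:
            out.append((site_pos - o, _COMPLEMENT[c]))
    return out


def make_synthetic_locus(config: SimConfig, seed: int) -> SyntheticLocus:
    """Generate a locus whose filter-passing RSS set is exactly the planted set."""
    if config.locus_length < 50_000:
        raise ValueError("requested locus length must be >= 50 kb")
    rng = np.random.default_rng(seed)
    L = config.locus_length
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L)

    # --- layout ------------------------------------------------------------
    bait_pos = int(0.88 * L)
    impediment = (
        config.scan_impediment_pos
        if config.scan_impediment_pos is not None
        else int(0.30 * L)
    )
    if not 0 <= impediment < L:
        raise ValueError("scan impediment position outside locus")

    n_seg = config.n_segments
    seg_positions = np.linspace(int(0.08 * L), int(0.72 * L), n_seg).astype(int)
    if config.segment_strengths is not None:
        if len(config.segment_strengths) != n_seg:
            raise ValueError("segment_strengths length must equal n_segments")
        strengths = np.asarray(config.segment_strengths, dtype=float)
    else:
        strengths = np.exp(rng.uniform(np.log(0.5), np.log(5.0), size=n_seg))
    terciles = np.array_split(np.arange(n_seg), 3)
    domain = {}
    for label, idxs in zip(("distal", "middle", "proximal"), terciles):
        for i in idxs:
            domain[i] = label

    segments = [
        SegmentSpec(
            segment_id=f"V{i + 1}",
            chrom=config.chrom,
            rss_cleavage_pos=int(p),
            orientation="-",
            rss_kind=12,
            strength=float(strengths[i]),
            domain_label=domain[i],
        )
        for i, p in enumerate(seg_positions)
    ]
    # the bait RSS is a planted bona fide site too (strength 0: never drawn)
    segments.append(
        SegmentSpec(
            segment_id="J1",
            chrom=config.chrom,
            rss_cleavage_pos=bait_pos,
            orientation="+",
            rss_kind=23,
            strength=0.0,
        )
    )

    # --- plant, checking footprint overlap ----------------------------------
    protected: list[tuple[int, int]] = []

    def _collides(span: tuple[int, int], margin: int = 0) -> bool:
        return any(span[0] - margin < e and s < span[1] + margin for s, e in protected)

    def _claim(span: tuple[int, int], what: str) -> None:
        if span[0] < 0 or span[1] > L:
            raise ValueError(f"{what}: planted element outside locus {span}")
        if _collides(span):
            raise ValueError(f"planted elements overlapping: {what} at {span}")
        protected.append(span)

    for seg in segments:
        length = 7 + seg.rss_kind + 9
        span = _footprint(seg.rss_cleavage_pos, seg.orientation, length)
        _claim(span, seg.segment_id)
        elem = _element_for(seg.orientation, seg.rss_kind, rng)
        _plant(seq, span[0], elem)
    for p in config.cbe_positions:
        span = (p, p + len(config.cbe_consensus))
        _claim(span, f"CBE@{p}")
        _plant(seq, p, config.cbe_consensus)

    # cryptic CAC sites planted as close +/- pairs so that any window around
    # the recombination centre contains exactly balanced orientations; the
    # auto-layout nudges pairs off already-claimed elements and keeps an
    # 80-bp margin from them so cryptic junctions (jittered up to 14 bp) can
    # never fall within the on-target assignment tolerance of a planted RSS
    pair_positions = np.linspace(int(0.05 * L), int(0.84 * L), config.n_cryptic_pairs).astype(int)
    cac_catalog: list[CacSite] = []
    for p0 in pair_positions:
        placed = False
        for shift in range(0, 400, 40):
            p = int(p0) + shift
            pair_span = (p - 2, p + 23)  # covers both members' footprints
            if pair_span[1] > L or _collides(pair_span, margin=80):
                continue
            _claim((p, p + 3), f"CAC+@{p}")
            _plant(seq, p, "CAC")
            _claim((p + 18, p + 21), f"CAC-@{p + 20}")
            _plant(seq, p + 18, "GTG")
            cac_catalog.append(CacSite(config.chrom, p, "+"))
            cac_catalog.append(CacSite(config.chrom, p + 20, "-"))
            placed = True
            break
        if not placed:  # crowded stretch: drop this pair rather than collide
            continue

    # restriction sites at roughly the requested mean spacing (natural CATG
    # occurrences in the random background add to these; the map is scanned
    # from the final sequence)
    pos = int(rng.integers(config.restriction_spacing // 2, config.restriction_spacing))
    protected_arr = sorted(protected)
    while pos + 4 <= L:
        span = (pos, pos + 4)
        if not any(span[0] < e and s < span[1] for s, e in protected_arr):
            _plant(seq, pos, "CATG")
        pos += int(
            rng.integers(config.restriction_spacing // 2, config.restriction_spacing * 3 // 2)
        )

    # --- rejection-rewrite: background must contain no filter-passing site ---
    planted_keys = {(s.chrom, s.rss_cleavage_pos, s.orientation) for s in segments}
    protected_set: set[int] = set()
    for s, e in protected:
        protected_set.update(range(s, e))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _ in range(40):
        genome = GenomeModel({config.chrom: seq.tobytes().decode()})
        offenders = [
            s
            for s in scan_unannotated_rss(genome, max_mismatch=4)
            if (s.chrom, s.cleavage_pos, s.orientation) not in planted_keys
        ]
        if not offenders:
            break
        for off in offenders:
            mutated = False
            for fp, forbidden in _compared_positions(
                off.cleavage_pos, off.orientation, off.spacer_class
            ):
                if fp in protected_set or not 0 <= fp < L:
                    continue
                cur = seq[fp]
                # only rewrite a position that currently MATCHES the consensus:
                # changing it then strictly increases the site's mismatch count
                # (or breaks its CAC gate); touching an already-mismatched base
                # would leave the score unchanged
                if cur != ord(forbidden):
                    continue
                seq[fp] = rng.choice(bases[bases != cur])
                mutated = True
                break
            if not mutated:
                raise RuntimeError(
                    f"cannot rewrite accidental RSS at {off.cleavage_pos}{off.orientation}: "
                    "all compared positions are inside planted elements"
                )
    else:
        raise RuntimeError("rejection-rewrite did not converge")

    genome = GenomeModel({config.chrom: seq.tobytes().decode()})
    rmap = RestrictionMap.from_genome(genome)
    bait = BaitSpec(
        bait_id="J1_bait",
        chrom=config.chrom,
        cleavage_pos=bait_pos,
        orientation="+",
        self_ligation_exclusion=(bait_pos + 60, bait_pos + 220),
    )
    return SyntheticLocus(
        genome=genome,
        segments=segments,
        cac_catalog=cac_catalog,
        rmap=rmap,
        bait=bait,
        config=config,
        cbe_positions=config.cbe_positions,
        e2a_positions=config.e2a_positions,
        transcription_positions=config.transcription_positions,
    )


def _jitter_positions(
    cleavage: np.ndarray, orientations: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Coding-end resection jitter: uniform on [0, 15) bp on the coding-flank
    side (away from the heptamer: lower coordinates for '+', higher for '-')."""
    offsets = rng.integers(0, 15, size=cleavage.size)
    signs = np.where(np.asarray(orientations) == "+", -1, 1)
    return cleavage + signs * offsets


def simulate_vdj_library(
    locus: SyntheticLocus,
    config: SimConfig,
    seed: int,
    repeat_id: str = "rep1",
    library_id: Optional[str] = None,
) -> JunctionLibrary:
    """Draw one bait-anchored V(D)J junction library from the locus truth."""
    if config.n_total_reads <= 0:
        raise ValueError("n_total_reads must be > 0")
    if not locus.segments:
        raise ValueError("segment catalog is empty")
    rng = np.random.default_rng(seed)
    L = locus.genome.length(locus.config.chrom)
    chrom = locus.config.chrom
    bait = locus.bait
    impediment = (
        config.scan_impediment_pos
        if config.scan_impediment_pos is not None
        else int(0.30 * L)
    )
    if not 0 <= impediment < L:
        raise ValueError("scan impediment position outside locus")

    n_junctions = int(round(config.n_total_reads * config.junction_fraction))
    n_cryptic = int(rng.binomial(n_junctions, config.cryptic_rate))
    n_on = n_junctions - n_cryptic

    # on-target joins: multinomial over segments, probability ~ strength
    strengths = np.array([s.strength for s in locus.segments], dtype=float)
    if strengths.sum() <= 0:
        raise ValueError("all segment strengths are zero")
    seg_counts = rng.multinomial(n_on, strengths / strengths.sum())
    positions, orientations = [], []
    for seg, c in zip(locus.segments, seg_counts):
        positions.extend([seg.rss_cleavage_pos] * c)
        orientations.extend([seg.orientation] * c)

    # cryptic joins at CAC sites, mode-dependent candidate set and intensity
    rc = bait.cleavage_pos
    if config.mode == "scanning":
        lo, hi = min(impediment, rc), max(impediment, rc)
        cands = [
            c
            for c in locus.cac_catalog
            if c.orientation != bait.orientation and lo <= c.pos < hi
        ]
        if not cands:
            raise ValueError("no convergent CAC sites between impediment and bait")
        d = np.array([abs(c.pos - rc) for c in cands], dtype=float)
        weights = np.exp(-d / ((hi - lo) / 2.0))
    else:  # diffusion
        within = [c for c in locus.cac_catalog if abs(c.pos - rc) <= config.diffusion_radius]
        # balance the candidate set by orientation (drop the most distant
        # extras) so the generative orientation symmetry is exact, not just
        # approximate at the radius boundary
        by_orient = {
            o: sorted(
                (c for c in within if c.orientation == o), key=lambda c: abs(c.pos - rc)
            )
            for o in ("+", "-")
        }
        k = min(len(by_orient["+"]), len(by_orient["-"]))
        if k == 0:
            raise ValueError("no CAC sites of both orientations within the diffusion radius")
        cands = by_orient["+"][:k] + by_orient["-"][:k]
        weights = np.ones(len(cands))
    cac_counts = rng.multinomial(n_cryptic, weights / weights.sum())
    for cac, c in zip(cands, cac_counts):
        positions.extend([cac.pos] * c)
        orientations.extend([cac.orientation] * c)

    positions = _jitter_positions(np.asarray(positions, dtype=np.int64), orientations, rng)
    np.clip(positions, 0, L - 1, out=positions)
    lib_id = library_id or f"vdj_{config.mode}_{repeat_id}"
    records = [
        JunctionRecord(
            library_id=lib_id,
            chrom=chrom,
            junction_pos=int(p),
            prey_orientation=o,
            bait_id=bait.bait_id,
            read_id=f"r{i:08d}",
        )
        for i, (p, o) in enumerate(zip(positions, orientations))
    ]
    return JunctionLibrary(
        library_id=lib_id,
        records=records,
        germline_read_count=config.n_total_reads - n_junctions,
        bait=bait,
        repeat_id=repeat_id,
    )


def simulate_3c_library(
    rmap: RestrictionMap,
    bait: BaitSpec,
    config: SimConfig,
    seed: int,
    n_junctions: Optional[int] = None,
    repeat_id: str = "rep1",
    library_id: Optional[str] = None,
) -> JunctionLibrary:
    """Draw one bait-anchored 3C junction library over the restriction map.

    Per-site intensity is A * (1 + d)^(-decay_exponent) in distance d from the
    bait, times the planted anchor enrichment; a self-ligation spike sits
    inside the bait exclusion interval; the requested junction total is
    allocated multinomially (so totals are conserved exactly).
    """
    sites = rmap.positions(bait.chrom)
    if sites.size < 500:
        raise ValueError(f"need >= 500 restriction sites on {bait.chrom}, got {sites.size}")
    n = int(n_junctions if n_junctions is not None else config.n_3c_junctions)
    if n <= 0:
        raise ValueError("junction count must be > 0")
    rng = np.random.default_rng(seed)
    d = np.abs(sites - bait.cleavage_pos).astype(float)
    weights = (1.0 + d) ** (-config.decay_exponent)
    for idx, factor in config.anchors:
        if not 0 <= idx < sites.size:
            raise ValueError(f"anchor site index {idx} out of range [0, {sites.size})")
        weights[idx] *= factor
    slw = config.self_ligation_weight
    spike_pos = (bait.self_ligation_exclusion[0] + bait.self_ligation_exclusion[1]) // 2
    spike_weight = slw / (1.0 - slw) * weights.sum() if slw > 0 else 0.0
    full = np.append(weights, spike_weight)
    counts = rng.multinomial(n, full / full.sum())
    all_pos = np.append(sites, spike_pos)
    positions = np.repeat(all_pos, counts)
    if config.jitter_3c > 0:
        positions = positions + rng.integers(
            -config.jitter_3c, config.jitter_3c + 1, size=positions.size
        )
    orientations = rng.choice(["+", "-"], size=positions.size)
    lib_id = library_id or f"3c_{repeat_id}"
    records = [
        JunctionRecord(
            library_id=lib_id,
            chrom=bait.chrom,
            junction_pos=int(p),
            prey_orientation=str(o),
            bait_id=bait.bait_id,
            read_id=f"r{i:08d}",
        )
        for i, (p, o) in enumerate(zip(positions, orientations))
    ]
    return JunctionLibrary(
        library_id=lib_id,
        records=records,
        germline_read_count=0,
        bait=bait,
        repeat_id=repeat_id,
    )


def simulate_site_count_track(
    n_sites: int,
    lam0: float,
    anchors: Sequence[tuple[int, float]],
    seed: int | np.random.Generator,
    spacing: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson background counts over evenly spaced restriction
    sites, with optional anchor enrichments -- the minimal input of the peak
    caller, used for calibration (null false-positive rate, planted-anchor
    recovery)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = np.arange(n_sites, dtype=np.int64) * spacing + spacing
    counts = rng.poisson(lam0, size=n_sites)
    for idx, factor in anchors:
        if not 0 <= idx < n_sites:
            raise ValueError(f"anchor index {idx} out of range")
        counts[idx] = rng.poisson(lam0 * factor)
    return positions, counts


@dataclass
class TrackSet:
    """Simulated annotation inputs: per-repeat ChIP peak sets, an E2A signal
    track, and per-repeat GRO (nascent transcription) tracks."""

    chip_repeats: list[dict[str, np.ndarray]]
    e2a: StepSignal
    gro_repeats: list[StepSignal]


def simulate_tracks(
    locus: SyntheticLocus,
    seed: int,
    n_chip_repeats: int = 3,
    n_gro_repeats: int = 3,
) -> TrackSet:
    """Emit annotation tracks matching the locus's planted features.

    Planted CBE features get ChIP peaks in every repeat (reliable); planted E2A
    features get signal 2.0 (>= the 0.5 threshold); planted transcription
    features get GRO max 60 (>= 40) in every repeat.  Everywhere else there is
    only sub-threshold noise, and per-repeat noise ChIP peaks are placed in
    disjoint zones so no noise peak can reach 2-repeat support.
    """
    rng = np.random.default_rng(seed)
    chrom = locus.config.chrom
    L = locus.genome.length(chrom)
    for kind, plist in (
        ("cbe", locus.cbe_positions),
        ("e2a", locus.e2a_positions),
        ("transcription", locus.transcription_positions),
    ):
        for p in plist:
            if not 0 <= p < L:
                raise ValueError(f"{kind} feature at {p} outside locus")
    w = len(locus.config.cbe_consensus)

    chip_repeats = []
    for r in range(n_chip_repeats):
        intervals = [(max(0, p - 150), min(L, p + w + 150)) for p in locus.cbe_positions]
        # noise peaks unique to this repeat (never >= 2-repeat support)
        for k in range(4):
            s = int((0.02 + 0.24 * k) * L + r * 1500)
            intervals.append((s, s + 120))
        chip_repeats.append({chrom: np.array(sorted(intervals), dtype=np.int64)})

    def _signal(features: Sequence[int], half_width: int, value: float, noise: float) -> StepSignal:
        spans = sorted((max(0, p - half_width), min(L, p + half_width)) for p in features)
        starts, ends, values = [], [], []
        cursor = 0
        for s, e in spans:
            if s > cursor:
                starts.append(cursor)
                ends.append(s)
                values.append(noise)
            starts.append(s)
            ends.append(e)
            values.append(value)
            cursor = e
        if cursor < L:
            starts.append(cursor)
            ends.append(L)
            values.append(noise)
        return StepSignal({chrom: (np.array(starts), np.array(ends), np.array(values))})

    e2a = _signal(locus.e2a_positions, 100, 2.0, 0.05)
    gro_repeats = [
        _signal(
            locus.transcription_positions,
            300,
            60.0 + float(rng.uniform(-5, 5)),
            0.5,
        )
        for _ in range(n_gro_repeats)
    ]
    return TrackSet(chip_repeats=chip_repeats, e2a=e2a, gro_repeats=gro_repeats)


__all__ = [
    "SimConfig",
    "SyntheticLocus",
    "TrackSet",
    "make_synthetic_locus",
    "simulate_vdj_library",
    "simulate_3c_library",
    "simulate_site_count_track",
    "simulate_tracks",
]
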
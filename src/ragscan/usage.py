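"""Library normalization, segment-usage quantification and comparison statistics.

Absolute V(D)J recombination levels are compared after down-sampling every
library to a common total read count (junctions + germline reads; the
convention used here is 500,000 by default).  Relative usage divides each
segment's junction count by the library's total on-target count.  Libraries
are compared with Pearson correlation (usage patterns) and Welch's unpaired
two-sided t-test (total rearrangement levels); signal tracks are summarised as
mean +/- s.e.m. of the per-repeat bin maxima over 1,000 (or 200) bins.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import StepSignal
from .types import JunctionLibrary, JunctionRecord, SegmentSpec

DEFAULT_TOTAL_READS = 500_000


def downsample_library(
    lib: JunctionLibrary,
    total_reads: int = DEFAULT_TOTAL_READS,
    seed: int | np.random.Generator = 0,
    allow_smaller: bool = False,
) -> JunctionLibrary:
    """Down-sample to ``total_reads`` total reads (junctions + germline).

    Junction records and germline pseudo-reads form one urn sampled uniformly
    without replacement, so the retained junction count is hypergeometric.
    Deterministic given the seed.  A library smaller than the target is an
    error unless ``allow_smaller``, which passes it through with a warning.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if lib.total_reads < total_reads:
        if allow_smaller:
            warnings.warn(
                f"library {lib.library_id} has {lib.total_reads} < {total_reads} reads; "
                "passing through unchanged"
            )
            return lib
        raise ValueError(
            f"library {lib.library_id} has only {lib.total_reads} reads (< {total_reads})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_j = len(lib.records)
    # reads 0..n_j-1 are junctions, the rest germline
    chosen = rng.choice(lib.total_reads, size=total_reads, replace=False)
    kept_junctions = np.sort(chosen[chosen < n_j])
    records = [lib.records[i] for i in kept_junctions]
    return JunctionLibrary(
        library_id=lib.library_id,
        records=records,
        germline_read_count=total_reads - len(records),
        bait=lib.bait,
        repeat_id=lib.repeat_id,
    )


def segment_usage(
    on_target: Sequence[JunctionRecord],
    segment_ids: Sequence[str],
    catalog: Sequence[SegmentSpec],
) -> pd.DataFrame:
    """Per-segment absolute counts and relative percentages.

    ``segment_ids`` gives the assigned segment for each on-target record
    (parallel sequences, as produced by ``split_on_off_target``).  Zero-count
    segments from the catalog are retained with count 0.  Relative percent is
    100 * count / total on-target count and sums to 100 when any junction
    exists.
    """
    if len(on_target) != len(segment_ids):
        raise ValueError("on_target records and segment_ids must be parallel")
    known = [s.segment_id for s in catalog]
    known_set = set(known)
    counts = dict.fromkeys(known, 0)
    for sid in segment_ids:
        if sid not in known_set:
            raise ValueError(f"record assigned to unknown segment {sid!r}")
        counts[sid] += 1
    total = sum(counts.values())
    rows = []
    for seg in catalog:
        c = counts[seg.segment_id]
        rows.append(
            {
                "segment_id": seg.segment_id,
                "chrom": seg.chrom,
                "rss_cleavage_pos": seg.rss_cleavage_pos,
                "domain_label": seg.domain_label,
                "absolute_count": c,
                "relative_percent": 100.0 * c / total if total else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["total_on_target"] = total
    return df


def pearson_usage(u: Sequence[float], v: Sequence[float]) -> tuple[float, float, int]:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    The p-value refers r*sqrt((n-2)/(1-r^2)) to a t distribution with n-2
    degrees of freedom.  Constant input vectors are an error (r undefined).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("usage vectors must be 1-D and of equal length")
    n = u.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    du, dv = u - u.mean(), v - v.mean()
    su = np.sqrt(np.sum(du**2))
    sv = np.sqrt(np.sum(dv**2))
    if su == 0 or sv == 0:
        raise ValueError("correlation undefined for a constant vector")
    if np.array_equal(du, dv):  # exact identity up to shift: r is exactly 1
        r = 1.0
    elif np.array_equal(du, -dv):
        r = -1.0
    else:
        r = float(np.sum(du * dv) / (su * sv))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def welch_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired two-sided Welch's t-test; returns (t, df, p).

    df is the Welch--Satterthwaite approximation.  Each group needs n >= 2
    and positive variance in at least one group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate variance: both groups are constant")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def binned_profile(
    tracks: Mapping[str, StepSignal],
    region: tuple[str, int, int],
    nbins: int = 1000,
) -> pd.DataFrame:
    """Mean +/- s.e.m. of the per-repeat maximum signal in each bin.

    The region is divided into ``nbins`` equal half-open bins (the last bin
    absorbs any remainder); within each bin the per-repeat value is the MAX of
    the signal, and bins are summarised as mean and s.e.m. (sd/sqrt(n_repeats),
    0 for a single repeat) across repeats.
    """
    if nbins <= 0:
        raise ValueError("nbins must be > 0")
    chrom, start, end = region
    length = end - start
    if length < nbins:
        raise ValueError(f"region length {length} shorter than nbins {nbins}")
    width = length // nbins
    edges = [start + i * width for i in range(nbins)] + [end]
    rep_ids = sorted(tracks)
    values = np.empty((len(rep_ids), nbins))
    for i, rep in enumerate(rep_ids):
        sig = tracks[rep]
        for j in range(nbins):
            values[i, j] = sig.max(chrom, edges[j], edges[j + 1])
    mean = values.mean(axis=0)
    if len(rep_ids) > 1:
        sem = values.std(axis=0, ddof=1) / np.sqrt(len(rep_ids))
    else:
        sem = np.zeros(nbins)
    df = pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mean": mean,
            "sem": sem,
        }
    )
    df.attrs["n_repeats"] = len(rep_ids)
    df.attrs["chrom"] = chrom
    return df
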
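"""Cryptic-RSS off-target profile: chromatin scanning vs 3D diffusion.

Simulates one library under each RAG exploration mode, splits junctions into
on-target / cryptic, collapses cryptic coding-end junctions (within 15 bp)
onto their CAC cleavage sites, and reports the deletional (convergent) vs
inversional (same-orientation) fractions -- the readout that distinguishes
linear chromatin scanning from diffusional capture.
"""

from ragscan import (
    SimConfig,
    collapse_cryptic,
    make_synthetic_locus,
    orientation_fractions,
    simulate_vdj_library,
    split_on_off_target,
)

locus = make_synthetic_locus(SimConfig(locus_length=120_000), seed=1)

for mode in ("scanning", "diffusion"):
    cfg = SimConfig(
        locus_length=120_000, n_total_reads=50_000, junction_fraction=0.4,
        cryptic_rate=0.5, mode=mode,
    )
    per_repeat = {}
    for rep in (1, 2):
        lib = simulate_vdj_library(locus, cfg, seed=10 * rep, repeat_id=f"rep{rep}")
        split = split_on_off_target(lib, locus.segments, [], tolerance=50)
        per_repeat[f"rep{rep}"] = split.cryptic
    peaks, unassigned = collapse_cryptic(per_repeat["rep1"], locus.cac_catalog, radius=15)
    df = orientation_fractions(
        per_repeat, locus.bait.orientation,
        {"whole locus": (cfg.chrom, 0, cfg.locus_length)},
    )
    row = df.iloc[0]
    print(f"{mode:9s}: {len(peaks)} cryptic CAC peaks "
          f"({sum(p.junction_count for p in peaks)} junctions collapsed, "
          f"{len(unassigned)} unassigned)")
    print(f"{'':9s}  deletional {row.pct_deletional_mean:.1f} "
          f"+/- {row.pct_deletional_sem:.1f} %, "
          f"inversional {row.pct_inversional_mean:.1f} "
          f"+/- {row.pct_inversional_sem:.1f} % (mean +/- s.e.m., 2 repeats)")
# Scanning gives ~100% deletional junctions confined between the impediment
# and the recombination centre; diffusion gives ~50/50 in both orientations.
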
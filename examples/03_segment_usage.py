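"""Segment-usage quantification with library normalization and statistics.

Two libraries are down-sampled to a common total read count (junctions +
germline), junctions are assigned to annotated segments, and the usage
patterns are compared with Pearson correlation; total rearrangement levels
are compared with Welch's t-test across simulated repeats.
"""

from ragscan import (
    SimConfig,
    downsample_library,
    make_synthetic_locus,
    pearson_usage,
    segment_usage,
    simulate_vdj_library,
    split_on_off_target,
    welch_test,
)

cfg = SimConfig(locus_length=120_000, n_total_reads=600_000, cryptic_rate=0.05)
locus = make_synthetic_locus(cfg, seed=1)

tables, totals = [], []
for rep in range(1, 5):
    lib = simulate_vdj_library(locus, cfg, seed=rep, repeat_id=f"rep{rep}")
    lib = downsample_library(lib, total_reads=500_000, seed=100 + rep)
    split = split_on_off_target(lib, locus.segments, [], tolerance=50)
    table = segment_usage(split.on_target, split.on_target_segment, locus.segments)
    tables.append(table)
    totals.append(table.attrs["total_on_target"])

top = tables[0].nlargest(3, "relative_percent")
print("top segments in repeat 1 (after 500,000-read down-sampling):")
for _, row in top.iterrows():
    print(f"  {row.segment_id:4s} {row.domain_label:8s} "
          f"count={row.absolute_count:6d}  {row.relative_percent:5.2f} %")

r, p, n = pearson_usage(
    tables[0].relative_percent.to_numpy(), tables[1].relative_percent.to_numpy()
)
print(f"usage pattern similarity rep1 vs rep2: Pearson r = {r:.3f}, "
      f"two-sided p = {p:.2e} (n = {n} segments)")

t, df, p = welch_test(totals[:2], totals[2:])
print(f"total rearrangement, reps 1-2 vs 3-4: Welch t = {t:.2f}, "
      f"df = {df:.1f}, p = {p:.2f}")
# Repeats drawn from the same locus truth: r close to 1 and a
# non-significant Welch p are the expected outcome.
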
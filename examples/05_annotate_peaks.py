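"""C/E/T/U feature annotation of interaction peaks.

A locus is built with one planted CTCF-binding element (CBE), one E2A site and
one transcribed region; simulated ChIP/GRO tracks then drive the annotation
rules: C = reliable CBE within peak +/- 1 kb (motif score > 13 and ChIP peak
in >= 2 repeats), E = max E2A signal >= 0.5, T = GRO max >= 40 or mean >= 10
in >= 2 repeats, U = none of these.
"""

import numpy as np

from ragscan import (
    PeakRegion,
    SimConfig,
    annotate_peaks,
    make_synthetic_locus,
    pwm_scan,
    reliable_cbes,
    simulate_tracks,
)

cfg = SimConfig(
    locus_length=100_000,
    cbe_positions=(20_000,),
    e2a_positions=(35_000,),
    transcription_positions=(70_000,),
)
locus = make_synthetic_locus(cfg, seed=7)
tracks = simulate_tracks(locus, seed=8)

# count matrix matching the planted CBE consensus
idx = {"A": 0, "C": 1, "G": 2, "T": 3}
matrix = np.ones((4, len(cfg.cbe_consensus)))
for i, b in enumerate(cfg.cbe_consensus):
    matrix[idx[b], i] = 100.0

hits = pwm_scan(locus.genome, matrix, threshold=13.0)
cbes = reliable_cbes(hits, tracks.chip_repeats)
print(f"motif hits: {len(hits)}, reliable CBEs (>=2 ChIP repeats): {len(cbes)}")

peaks = [
    PeakRegion(cfg.chrom, p - 100, p + 100, p, 1e-9, 1e-7, support=2, name=name)
    for p, name in [(20_000, "at_cbe"), (35_000, "at_e2a"),
                    (70_000, "at_txn"), (90_000, "featureless")]
]
for f in annotate_peaks(peaks, cbes, tracks.e2a, tracks.gro_repeats):
    print(f"  {f.peak_name:12s} labels={''.join(sorted(f.labels))} "
          f"cbe={f.cbe_count} ({','.join(f.cbe_orientations) or '-'}) "
          f"e2a_max={f.e2a_max:.2f} transcribed={f.transcription}")
# Each planted feature yields exactly its own label; the bare peak is "U".
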
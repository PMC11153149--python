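"""Genome container, FASTA round-trip, and restriction-site maps.

The genome is held in memory as plain upper-case strings (loci analysed here
are hundreds of kilobases, not whole genomes).  All coordinates are 0-based,
intervals half-open.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_RC)[::-1]


class GenomeModel:
    """Reference sequences keyed by chromosome name.

    Sequences must contain only A/C/G/T/N.  Every coordinate used elsewhere in
    the package is checked against these lengths.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid bases: {sorted(bad)}")
            self.sequences[name] = seq

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"interval {chrom}:{start}-{end} outside [0, {len(seq)})")
        return seq[start:end]

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeModel":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path: str, line_width: int = 70) -> None:
        recs = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(recs)


class RestrictionMap:
    """Sorted positions of a restriction motif (default CATG, NlaIII) per chromosome.

    Positions are the 0-based start of the motif occurrence.
    """

    def __init__(self, sites: Mapping[str, Iterable[int]], motif: str = "CATG"):
        self.motif = motif
        self.sites: dict[str, np.ndarray] = {}
        for chrom, pos in sites.items():
            arr = np.asarray(sorted(pos), dtype=np.int64)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"duplicate restriction positions on {chrom}")
            self.sites[chrom] = arr

    @classmethod
    def from_genome(cls, genome: GenomeModel, motif: str = "CATG") -> "RestrictionMap":
        sites = {}
        for chrom, seq in genome.sequences.items():
            positions = []
            i = seq.find(motif)
            while i != -1:
                positions.append(i)
                i = seq.find(motif, i + 1)
            sites[chrom] = positions
        return cls(sites, motif=motif)

    def positions(self, chrom: str) -> np.ndarray:
        return self.sites.get(chrom, np.empty(0, dtype=np.int64))

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions(chrom).size)
        return int(sum(arr.size for arr in self.sites.values()))
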
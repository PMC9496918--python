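"""Genome coordinate infrastructure: contigs, fixed-width bins, arm boundaries.

All coordinates are 0-based half-open internally (BED convention); 1-based
positions appear only at VCF-dialect I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# GRCh38 primary-assembly contig lengths (bp).
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559, "chr4": 190214555,
    "chr5": 181538259, "chr6": 170805979, "chr7": 159345973, "chr8": 145138636,
    "chr9": 138394717, "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189, "chr16": 90338345,
    "chr17": 83257441, "chr18": 80373285, "chr19": 58617616, "chr20": 64444167,
    "chr21": 46709983, "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
}

# Approximate GRCh38 centromere midpoints (bp); the p/q arm boundary per contig.
GRCH38_CENTROMERES: dict[str, int] = {
    "chr1": 123400000, "chr2": 93900000, "chr3": 90900000, "chr4": 50000000,
    "chr5": 48800000, "chr6": 59800000, "chr7": 60100000, "chr8": 45200000,
    "chr9": 43000000, "chr10": 39800000, "chr11": 53400000, "chr12": 35500000,
    "chr13": 17700000, "chr14": 17200000, "chr15": 19000000, "chr16": 36800000,
    "chr17": 25100000, "chr18": 18500000, "chr19": 26200000, "chr20": 28100000,
    "chr21": 12000000, "chr22": 15000000, "chrX": 60600000, "chrY": 10400000,
}

# Short-arm material on these chromosomes is heterochromatic/rDNA; the q arm
# alone determines whole-chromosome calls.
ACROCENTRIC: frozenset[str] = frozenset({"chr13", "chr14", "chr15", "chr21", "chr22"})

SEX_CONTIGS: frozenset[str] = frozenset({"chrX", "chrY"})

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


def baseline_copy_number(contig: str, sex: str) -> int:
    """Germline copy number of a contig for a given sex ('female'/'male')."""
    if contig == "chrX":
        return 1 if sex == "male" else 2
    if contig == "chrY":
        return 1 if sex == "male" else 0
    return 2


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-width tiling of a genome into bins.

    Bins tile each contig without gap or overlap; the last bin of a contig may
    be shorter than ``bin_width``.

    Parameters
    ----------
    contig_lengths
        Ordered mapping of contig name to length in bp.
    bin_width
        Target bin width in bp.
    centromeres
        p/q boundary per contig (bp). Contigs absent from the table have no
        arm annotation and cannot take part in arm-level karyotype calls.
    """

    contig_lengths: dict[str, int]
    bin_width: int
    centromeres: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for contig, boundary in self.centromeres.items():
            length = self.contig_lengths.get(contig)
            if length is not None and not (0 < boundary < length):
                raise ValueError(f"centromere for {contig} outside contig bounds")

    @property
    def bins(self) -> pd.DataFrame:
        """Bin table with columns contig/start/end (0-based half-open)."""
        rows = []
        for contig, length in self.contig_lengths.items():
            starts = np.arange(0, length, self.bin_width, dtype=np.int64)
            ends = np.minimum(starts + self.bin_width, length)
            rows.append(pd.DataFrame({"contig": contig, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    @property
    def n_bins(self) -> int:
        return int(sum(-(-length // self.bin_width) for length in self.contig_lengths.values()))

    def contig_bin_range(self, contig: str) -> tuple[int, int]:
        """Half-open range of global bin indices belonging to ``contig``."""
        offset = 0
        for name, length in self.contig_lengths.items():
            n = -(-length // self.bin_width)
            if name == contig:
                return offset, offset + n
            offset += n
        raise KeyError(contig)

    def bin_index(self, contig: str, position: int) -> int:
        """Global bin index containing a 0-based position."""
        lo, hi = self.contig_bin_range(contig)
        if not 0 <= position < self.contig_lengths[contig]:
            raise ValueError(f"position {position} outside {contig}")
        idx = lo + position // self.bin_width
        assert idx < hi
        return idx

    def autosomal_mask(self) -> np.ndarray:
        """Boolean mask over bins: True for autosomal bins."""
        return self.bins["contig"].isin(AUTOSOMES).to_numpy()

    def contig_of_bins(self) -> np.ndarray:
        return self.bins["contig"].to_numpy()

    def arm_of_bins(self) -> np.ndarray:
        """Per-bin arm label 'p'/'q' ('' where no centromere is tabulated).

        A bin straddling the boundary is assigned to the arm holding the
        larger share of the bin.
        """
        bins = self.bins
        labels = np.full(len(bins), "", dtype=object)
        for contig, boundary in self.centromeres.items():
            sel = bins["contig"] == contig
            mid = (bins.loc[sel, "start"] + bins.loc[sel, "end"]) / 2.0
            labels[np.flatnonzero(sel)] = np.where(mid < boundary, "p", "q")
        return labels


def default_binning(bin_width: int = 1_000_000) -> GenomeBinning:
    """GRCh38 binning at the default 1 Mb resolution (~3,100 bins)."""
    return GenomeBinning(dict(GRCH38_LENGTHS), bin_width, dict(GRCH38_CENTROMERES))


def toy_binning(n_contigs: int = 2, contig_length: int = 10_000, bin_width: int = 1_000,
                centromere_fraction: float = 0.5) -> GenomeBinning:
    """Small synthetic binning for tests and examples (contigs named chr1..)."""
    lengths = {f"chr{i + 1}": contig_length for i in range(n_contigs)}
    centromeres = {c: int(length * centromere_fraction) for c, length in lengths.items()}
    return GenomeBinning(lengths, bin_width, centromeres)
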
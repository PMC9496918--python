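"""Bin-count profiles, panel-of-normals construction and read-depth ratios.

The karyotyping signal is per-bin read depth from ultra-low-coverage WGS
(<0.5x). A tumor profile is normalized against a panel of normals (PON): each
normal is converted to per-bin count fractions, the per-bin median fraction
across normals is the reference level m_i and the median absolute deviation
d_i its dispersion. Bins with no reference signal (m_i = 0) or excessive
normal-to-normal variability (d_i/m_i above a cutoff) are masked from all
downstream ratio computations. Sex chromosomes are referenced within sex
strata (X per declared sex, Y from male donors only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome import GenomeBinning, SEX_CONTIGS

SEXES = ("female", "male")


@dataclass
class BinCountProfile:
    """Per-bin integer read counts for one sample."""

    sample_id: str
    sex: str
    counts: np.ndarray
    binning: GenomeBinning
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if len(self.counts) != self.binning.n_bins:
            raise ValueError(
                f"count vector length {len(self.counts)} != bin count {self.binning.n_bins}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.binning.bins
        df["count"] = self.counts
        return df


def bin_alignments(records: Iterable[tuple[str, int, int]], binning: GenomeBinning,
                   sample_id: str = "sample", sex: str = "female",
                   mapq_min: int = 20) -> BinCountProfile:
    """Tally aligned-read start positions into genome bins.

    ``records`` yields ``(contig, 1-based position, mapping quality)``. Reads
    below ``mapq_min`` are dropped into a discard tally; reads on contigs not
    in the binning are skipped and counted, never fatal. Tallies are available
    in the returned profile's ``meta`` under ``n_low_mapq`` and
    ``n_unknown_contig``.
    """
    counts = np.zeros(binning.n_bins, dtype=np.int64)
    n_low_mapq = 0
    n_unknown = 0
    for contig, pos, mapq in records:
        if mapq < mapq_min:
            n_low_mapq += 1
            continue
        if contig not in binning.contig_lengths:
            n_unknown += 1
            continue
        counts[binning.bin_index(contig, pos - 1)] += 1
    return BinCountProfile(
        sample_id, sex, counts, binning,
        meta={"n_low_mapq": n_low_mapq, "n_unknown_contig": n_unknown,
              "mapq_min": mapq_min},
    )


def iter_sam_alignments(path: str) -> Iterator[tuple[str, int, int]]:
    """Yield (contig, 1-based pos, mapq) from a SAM/BAM file via pysam.

    Optional reader path; unmapped and secondary/supplementary records are
    skipped. pysam is imported lazily so the core package works without it.
    """
    import pysam  # local import: optional reader path

    with pysam.AlignmentFile(path) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield rec.reference_name, rec.reference_start + 1, rec.mapping_quality


def _median_mad(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise median and raw median absolute deviation."""
    med = np.median(matrix, axis=0)
    mad = np.median(np.abs(matrix - med), axis=0)
    return med, mad


@dataclass
class PanelOfNormals:
    """Per-bin reference level and dispersion built from normal donors.

    ``median`` / ``mad`` / ``usable`` are keyed by sex because X and Y bins
    are referenced within sex strata; autosomal entries are identical across
    the two keys. Reference levels are count fractions rescaled so the usable
    autosomal reference sums to exactly 1, which makes the tumor/PON ratio an
    identity (log2 ratio 0) whenever the tumor is proportional to the
    reference.
    """

    binning: GenomeBinning
    median: dict[str, np.ndarray]
    mad: dict[str, np.ndarray]
    usable: dict[str, np.ndarray]
    n_samples: int
    n_female: int
    n_male: int
    variability_cutoff: float

    def reference(self, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(median, mad, usable-mask) arrays appropriate for a sample's sex."""
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        return self.median[sex], self.mad[sex], self.usable[sex]

    def expected_profile(self, sex: str, total_reads: int) -> np.ndarray:
        """Expected bin counts of a normal sample of ``sex`` at a given depth."""
        m, _, usable = self.reference(sex)
        auto = self.binning.autosomal_mask()
        scale = total_reads / m[usable & auto].sum()
        out = np.where(usable, m * scale, 0.0)
        return out

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str) -> None:
        bins = self.binning.bins
        df = pd.DataFrame({
            "contig": bins["contig"], "start": bins["start"], "end": bins["end"],
            "m_female": self.median["female"], "d_female": self.mad["female"],
            "usable_female": self.usable["female"].astype(int),
            "m_male": self.median["male"], "d_male": self.mad["male"],
            "usable_male": self.usable["male"].astype(int),
        })
        with open(path, "w") as fh:
            fh.write(f"#pon\tn_samples={self.n_samples}\tn_female={self.n_female}"
                     f"\tn_male={self.n_male}\tvariability_cutoff={self.variability_cutoff}"
                     f"\tbin_width={self.binning.bin_width}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, binning: GenomeBinning) -> "PanelOfNormals":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#pon"):
                raise ValueError(f"{path}: not a PON file (missing #pon header)")
            meta = dict(item.split("=", 1) for item in header.strip().split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        if len(df) != binning.n_bins:
            raise ValueError(f"{path}: {len(df)} rows != binning's {binning.n_bins} bins")
        return cls(
            binning=binning,
            median={"female": df["m_female"].to_numpy(), "male": df["m_male"].to_numpy()},
            mad={"female": df["d_female"].to_numpy(), "male": df["d_male"].to_numpy()},
            usable={"female": df["usable_female"].to_numpy(dtype=bool),
                    "male": df["usable_male"].to_numpy(dtype=bool)},
            n_samples=int(meta["n_samples"]), n_female=int(meta["n_female"]),
            n_male=int(meta["n_male"]),
            variability_cutoff=float(meta["variability_cutoff"]),
        )


def build_panel_of_normals(profiles: list[BinCountProfile],
                           variability_cutoff: float = 0.3) -> PanelOfNormals:
    """Build the per-bin reference from >= 2 normal-donor profiles.

    Each profile is converted to count fractions (count over the sample's
    autosomal total); per bin, the reference level is the median fraction and
    the dispersion the raw median absolute deviation. Bins are masked when the
    reference level is zero or the relative dispersion d_i/m_i exceeds
    ``variability_cutoff``. X bins are referenced per sex stratum and Y bins
    from males only (Y is masked entirely in the female reference).
    """
    if len(profiles) < 2:
        raise ValueError("a panel of normals needs at least 2 profiles")
    binning = profiles[0].binning
    if any(p.binning != binning for p in profiles):
        raise ValueError("all PON profiles must share one binning")

    auto = binning.autosomal_mask()
    contigs = binning.contig_of_bins()
    is_x = contigs == "chrX"
    is_y = contigs == "chrY"

    counts = np.stack([p.counts for p in profiles]).astype(float)
    auto_totals = counts[:, auto].sum(axis=1)
    if (auto_totals == 0).any():
        raise ValueError("a PON profile has zero autosomal reads")
    fractions = counts / auto_totals[:, None]

    sexes = np.array([p.sex for p in profiles])
    median: dict[str, np.ndarray] = {}
    mad: dict[str, np.ndarray] = {}
    usable: dict[str, np.ndarray] = {}
    m_auto, d_auto = _median_mad(fractions)
    for sex in SEXES:
        m = m_auto.copy()
        d = d_auto.copy()
        stratum = fractions[sexes == sex]
        if stratum.shape[0] > 0:
            m[is_x], d[is_x] = _median_mad(stratum[:, is_x])
        else:
            m[is_x] = 0.0
        males = fractions[sexes == "male"]
        if sex == "male" and males.shape[0] > 0:
            m[is_y], d[is_y] = _median_mad(males[:, is_y])
        else:
            m[is_y] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(m > 0, d / np.where(m > 0, m, 1.0), np.inf)
        ok = (m > 0) & (rel <= variability_cutoff)
        # rescale so the usable autosomal reference sums to 1 (ratio identity)
        scale = m[ok & auto].sum()
        if scale <= 0:
            raise ValueError("no usable autosomal bins remain after masking; "
                             "raise variability_cutoff or check the profiles")
        median[sex] = m / scale
        mad[sex] = d / scale
        usable[sex] = ok

    return PanelOfNormals(
        binning=binning, median=median, mad=mad, usable=usable,
        n_samples=len(profiles),
        n_female=int((sexes == "female").sum()), n_male=int((sexes == "male").sum()),
        variability_cutoff=variability_cutoff,
    )


@dataclass
class RatioProfile:
    """Per-bin log2 tumor/PON read-depth ratio with validity mask."""

    log2: np.ndarray
    valid: np.ndarray
    binning: GenomeBinning
    sex: str
    sample_id: str = "sample"
    gc_corrected: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2[self.valid]).all():
            raise ValueError("log2 ratios must be finite on valid bins")


def compute_log2_ratios(tumor: BinCountProfile, pon: PanelOfNormals,
                        gc_correct: bool = False,
                        gc_per_bin: np.ndarray | None = None,
                        min_log2: float = -5.0) -> RatioProfile:
    """Normalize a tumor profile against the PON.

    On usable bins r_i = log2((c_i / C) / m_i), with C the tumor's total count
    over usable autosomal bins and m_i the sex-appropriate reference level.
    Zero-count bins are floored at ``min_log2``. With ``gc_correct`` the
    per-GC-decile median of r over valid autosomal bins is subtracted
    (self-normalizing; no external smoother).
    """
    if tumor.binning != pon.binning:
        raise ValueError("tumor binning does not match PON binning")
    m, _, usable = pon.reference(tumor.sex)
    auto = tumor.binning.autosomal_mask()
    c = tumor.counts.astype(float)
    C = c[usable & auto].sum()
    if C == 0:
        raise ValueError("tumor has zero reads on usable autosomal bins")

    r = np.full(tumor.binning.n_bins, np.nan)
    valid = usable.copy()
    with np.errstate(divide="ignore"):
        r[valid] = np.log2((c[valid] / C) / m[valid])
    r[valid & (c == 0)] = min_log2
    np.maximum(r, min_log2, out=r, where=valid)

    if gc_correct:
        if gc_per_bin is None:
            raise ValueError("gc_correct requires gc_per_bin")
        gc = np.asarray(gc_per_bin, dtype=float)
        deciles = np.clip((gc * 10).astype(int), 0, 9)
        for dec in range(10):
            sel = valid & auto & (deciles == dec)
            if sel.any():
                r[valid & (deciles == dec)] -= np.median(r[sel])

    return RatioProfile(log2=r, valid=valid, binning=tumor.binning,
                        sex=tumor.sex, sample_id=tumor.sample_id,
                        gc_corrected=gc_correct)
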
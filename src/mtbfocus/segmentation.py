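"""Segmentation of log2 read-depth ratios and copy-number state calling.

Segmentation is recursive binary splitting per chromosome: the candidate
breakpoint maximizing the two-sample t statistic between left and right means
is accepted when the statistic exceeds a threshold and both sides retain a
minimum number of valid bins; recursion continues on accepted halves. When no
single breakpoint passes, a circular refinement (the CBS idea) tests the best
interior segment against the rest of the region, so short focal events inside
long neutral stretches are still recovered. Each
resulting segment then receives a continuous copy number 2 * 2**r (for
germline-diploid contigs) and a categorical state label from configurable
log2-ratio thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import baseline_copy_number
from .profiles import RatioProfile

STATE_LABELS = ("deep_loss", "loss", "neutral", "gain", "amplification")
GAIN_STATES = frozenset({"gain", "amplification"})
LOSS_STATES = frozenset({"loss", "deep_loss"})


@dataclass(frozen=True)
class StateThresholds:
    """Log2-ratio thresholds for the five copy-number state labels.

    Defaults place neutral at |r| < 0.2, single-copy-scale loss/gain beyond
    that band, and deep loss / amplification beyond one log2 unit.
    """

    neutral_band: float = 0.2
    loss: float = -0.2
    deep_loss: float = -1.0
    gain: float = 0.2
    amplification: float = 1.0

    def __post_init__(self) -> None:
        ordered = (self.deep_loss < self.loss <= -self.neutral_band
                   < self.neutral_band <= self.gain < self.amplification)
        if not ordered:
            raise ValueError(
                "thresholds must satisfy deep_loss < loss <= -neutral_band "
                "< neutral_band <= gain < amplification"
            )

    def label(self, r: float) -> str:
        if r <= self.deep_loss:
            return "deep_loss"
        if r <= self.loss:
            return "loss"
        if r >= self.amplification:
            return "amplification"
        if r >= self.gain:
            return "gain"
        return "neutral"


@dataclass(frozen=True, eq=False)
class SegmentCall:
    """A contiguous constant-copy-number region.

    ``start_bin``/``end_bin`` are global bin indices, half-open;
    ``valid_bins`` lists the global indices of the valid bins the segment
    summarizes. ``cn`` (continuous), ``cn_integer`` and ``label`` are absent
    until :func:`call_states` assigns them.
    """

    contig: str
    start_bin: int
    end_bin: int
    mean_log2: float
    start_bp: int
    end_bp: int
    valid_bins: np.ndarray = field(repr=False)
    cn: float | None = None
    cn_integer: int | None = None
    label: str | None = None

    @property
    def n_valid(self) -> int:
        return len(self.valid_bins)


def best_split(x: np.ndarray, min_size: int) -> tuple[int, float]:
    """Best binary split of ``x``: (index k, t statistic).

    k partitions ``x`` into x[:k] / x[k:]; only splits leaving ``min_size``
    elements on each side are candidates. Returns (-1, 0.0) when no candidate
    exists. A zero pooled variance with unequal means yields t = inf.
    """
    n = len(x)
    if n < 2 * min_size:
        return -1, 0.0
    ks = np.arange(min_size, n - min_size + 1)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total, total_sq = csum[-1], csq[-1]
    nl = ks.astype(float)
    nr = n - nl
    sum_l = csum[ks - 1]
    mean_l = sum_l / nl
    mean_r = (total - sum_l) / nr
    ss_l = np.maximum(csq[ks - 1] - sum_l**2 / nl, 0.0)
    ss_r = np.maximum((total_sq - csq[ks - 1]) - (total - sum_l) ** 2 / nr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = (ss_l + ss_r) / (n - 2)
        t = np.abs(mean_l - mean_r) / np.sqrt(pooled * (1 / nl + 1 / nr))
    t[np.isnan(t)] = 0.0  # zero variance, equal means
    best = int(np.argmax(t))
    return int(ks[best]), float(t[best])


def best_interior_segment(x: np.ndarray, min_size: int) -> tuple[int, int, float]:
    """Best interior segment vs rest: (i, j, t statistic), circular-CBS style.

    Considers all [i, j) with at least ``min_size`` bins inside and outside;
    returns (-1, -1, 0.0) when no candidate exists. A single breakpoint is a
    special case (i = 0 or j = n), so this statistic dominates the plain
    binary split.
    """
    n = len(x)
    if n < 2 * min_size:
        return -1, -1, 0.0
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x * x)])
    total, total_sq = csum[-1], csq[-1]
    i = np.arange(0, n - min_size + 1)
    j = np.arange(min_size, n + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    size_in = (jj - ii).astype(float)
    size_out = n - size_in
    # each flank must be empty or itself a viable segment
    left_ok = (ii == 0) | (ii >= min_size)
    right_ok = (jj == n) | (n - jj >= min_size)
    ok = (size_in >= min_size) & (size_out >= min_size) & left_ok & right_ok
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_in = csum[jj] - csum[ii]
        sq_in = csq[jj] - csq[ii]
        mean_in = sum_in / size_in
        mean_out = (total - sum_in) / size_out
        ss_in = np.maximum(sq_in - sum_in**2 / size_in, 0.0)
        ss_out = np.maximum((total_sq - sq_in) - (total - sum_in) ** 2 / size_out, 0.0)
        pooled = (ss_in + ss_out) / (n - 2)
        t = np.abs(mean_in - mean_out) / np.sqrt(pooled * (1 / size_in + 1 / size_out))
    t[~ok | np.isnan(t)] = 0.0
    flat = int(np.argmax(t))
    bi, bj = np.unravel_index(flat, t.shape)
    return int(i[bi]), int(j[bj]), float(t[bi, bj])


def _recurse(x: np.ndarray, lo: int, hi: int, min_size: int, threshold: float,
             out: list[tuple[int, int]]) -> None:
    k, t = best_split(x[lo:hi], min_size)
    if k > 0 and t > threshold:
        _recurse(x, lo, lo + k, min_size, threshold, out)
        _recurse(x, lo + k, hi, min_size, threshold, out)
        return
    i, j, t_seg = best_interior_segment(x[lo:hi], min_size)
    if t_seg > threshold and 0 < i and j < hi - lo:
        _recurse(x, lo, lo + i, min_size, threshold, out)
        _recurse(x, lo + i, lo + j, min_size, threshold, out)
        _recurse(x, lo + j, hi, min_size, threshold, out)
        return
    out.append((lo, hi))


def segment_ratios(ratios: RatioProfile, min_seg_bins: int = 3,
                   split_threshold: float = 4.0) -> list[SegmentCall]:
    """Partition each contig's valid bins into constant-ratio segments.

    The output covers every valid bin; a constant input yields exactly one
    segment per contig with valid bins.
    """
    if min_seg_bins < 2:
        raise ValueError("min_seg_bins must be >= 2")
    binning = ratios.binning
    bins = binning.bins
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()

    segments: list[SegmentCall] = []
    for contig in binning.contig_lengths:
        c_lo, c_hi = binning.contig_bin_range(contig)
        idx = np.flatnonzero(ratios.valid[c_lo:c_hi]) + c_lo
        if len(idx) == 0:
            continue
        x = ratios.log2[idx]
        pieces: list[tuple[int, int]] = []
        _recurse(x, 0, len(x), min_seg_bins, split_threshold, pieces)
        for lo, hi in sorted(pieces):
            span = idx[lo:hi]
            segments.append(SegmentCall(
                contig=contig,
                start_bin=int(span[0]), end_bin=int(span[-1]) + 1,
                mean_log2=float(x[lo:hi].mean()),
                start_bp=int(starts[span[0]]), end_bp=int(ends[span[-1]]),
                valid_bins=span,
            ))
    return segments


def call_states(segments: list[SegmentCall], ratios: RatioProfile,
                thresholds: StateThresholds | None = None) -> list[SegmentCall]:
    """Assign continuous/integer copy number and a state label per segment.

    Continuous CN = baseline * 2**r where baseline is the germline copy
    number of the contig for the sample's sex (2 on autosomes). Integer CN
    rounds half-up and is floored at 0.
    """
    thresholds = thresholds or StateThresholds()
    called = []
    for seg in segments:
        base = baseline_copy_number(seg.contig, ratios.sex)
        cn = base * 2.0 ** seg.mean_log2
        called.append(replace(
            seg,
            cn=cn,
            cn_integer=max(0, int(np.floor(cn + 0.5))),
            label=thresholds.label(seg.mean_log2),
        ))
    return called


def segments_frame(segments: list[SegmentCall]) -> pd.DataFrame:
    """Segments as a BED-like table (contig, start, end, mean_log2, CN, label)."""
    return pd.DataFrame([{
        "contig": s.contig, "start": s.start_bp, "end": s.end_bp,
        "n_valid_bins": s.n_valid, "mean_log2": s.mean_log2,
        "cn": s.cn, "cn_integer": s.cn_integer, "label": s.label,
    } for s in segments])
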
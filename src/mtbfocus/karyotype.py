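"""Numerical karyotype estimation and per-gene copy-number annotation.

An arm is called gained/lost when at least ``arm_fraction`` of its valid bins
lie in segments of that direction; a chromosome is whole-gained/lost when
both arms are (q alone suffices on acrocentric chromosomes). Non-neutral
segments that do not drive an arm call become sub-arm add/del events with bp
coordinates. The estimated total chromosome count is 46 plus whole-chromosome
gains minus losses, and the karyotype is rendered as an ISCN-flavoured string
("47,XY,+8,del(1p),add(4q)(52.0-58.0Mb)"); band-level notation would need a
cytoband table and is not attempted.

The module also exposes a statsmodels-style front end:
``ReadDepthKaryotypeModel(tumor, pon).fit()`` returns a
:class:`KaryotypeResults` holding ratios, segments, the numerical karyotype
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ACROCENTRIC, GenomeBinning, baseline_copy_number
from .profiles import BinCountProfile, PanelOfNormals, RatioProfile, compute_log2_ratios
from .segmentation import (GAIN_STATES, LOSS_STATES, SegmentCall, StateThresholds,
                           call_states, segment_ratios, segments_frame)


@dataclass(frozen=True)
class KaryotypeEvent:
    """One aneuploidy event: whole-chromosome, arm, or sub-arm add/del."""

    kind: str  # whole_gain | whole_loss | arm_gain | arm_loss | add | del
    contig: str
    arm: str = ""
    start_bp: int | None = None
    end_bp: int | None = None

    def render(self) -> str:
        chrom = self.contig.removeprefix("chr")
        if self.kind == "whole_gain":
            return f"+{chrom}"
        if self.kind == "whole_loss":
            return f"-{chrom}"
        if self.kind == "arm_gain":
            return f"add({chrom}{self.arm})"
        if self.kind == "arm_loss":
            return f"del({chrom}{self.arm})"
        span = f"({self.start_bp / 1e6:.1f}-{self.end_bp / 1e6:.1f}Mb)"
        return f"{self.kind}({chrom}{self.arm}){span}"


@dataclass
class NumericalKaryotype:
    """Estimated chromosome count plus the event list that produced it."""

    total_count: int
    sex: str
    events: list[KaryotypeEvent] = field(default_factory=list)

    @property
    def string(self) -> str:
        sex_part = "XX" if self.sex == "female" else "XY"
        parts = [f"{self.total_count},{sex_part}"]
        parts.extend(ev.render() for ev in self.events)
        return ",".join(parts)


def _chrom_sort_key(contig: str) -> tuple[int, str]:
    name = contig.removeprefix("chr")
    return (int(name), "") if name.isdigit() else (100, name)


def estimate_karyotype(state_segments: list[SegmentCall], binning: GenomeBinning,
                       sex: str, arm_fraction: float = 0.6,
                       acrocentric: frozenset[str] = ACROCENTRIC) -> NumericalKaryotype:
    """Summarize state segments into a numerical karyotype.

    Raises if a contig carrying non-neutral segments has no arm boundary in
    the binning's centromere table.
    """
    arms = binning.arm_of_bins()
    by_contig: dict[str, list[SegmentCall]] = {}
    for seg in state_segments:
        by_contig.setdefault(seg.contig, []).append(seg)

    events: list[KaryotypeEvent] = []
    gains = losses = 0
    for contig in sorted(by_contig, key=_chrom_sort_key):
        segs = by_contig[contig]
        if all(s.label == "neutral" for s in segs):
            continue
        if contig not in binning.centromeres:
            raise ValueError(f"no arm boundary tabulated for {contig} "
                             "but it carries non-neutral segments")
        # per-arm tallies of valid bins by direction
        arm_calls: dict[str, str] = {}
        for arm in ("p", "q"):
            n_arm = n_gain = n_loss = 0
            for seg in segs:
                in_arm = int((arms[seg.valid_bins] == arm).sum())
                n_arm += in_arm
                if seg.label in GAIN_STATES:
                    n_gain += in_arm
                elif seg.label in LOSS_STATES:
                    n_loss += in_arm
            if n_arm == 0:
                arm_calls[arm] = "empty"
            elif n_gain / n_arm >= arm_fraction:
                arm_calls[arm] = "gain"
            elif n_loss / n_arm >= arm_fraction:
                arm_calls[arm] = "loss"
            else:
                arm_calls[arm] = "neutral"

        whole = None
        if contig in acrocentric:
            whole = arm_calls["q"] if arm_calls["q"] in ("gain", "loss") else None
        elif arm_calls["p"] == arm_calls["q"] and arm_calls["p"] in ("gain", "loss"):
            whole = arm_calls["p"]
        # an empty arm (no valid bins) defers to the other arm
        elif "empty" in arm_calls.values():
            other = next((c for c in arm_calls.values() if c != "empty"), None)
            whole = other if other in ("gain", "loss") else None

        if whole == "gain":
            gains += 1
            events.append(KaryotypeEvent("whole_gain", contig))
        elif whole == "loss":
            losses += 1
            events.append(KaryotypeEvent("whole_loss", contig))
        else:
            for arm in ("p", "q"):
                if arm_calls[arm] == "gain":
                    events.append(KaryotypeEvent("arm_gain", contig, arm))
                elif arm_calls[arm] == "loss":
                    events.append(KaryotypeEvent("arm_loss", contig, arm))

        # sub-arm events: non-neutral segments not absorbed by an arm/whole call
        for seg in segs:
            if seg.label == "neutral":
                continue
            direction = "gain" if seg.label in GAIN_STATES else "loss"
            seg_arms = set(arms[seg.valid_bins])
            absorbed = whole == direction or all(
                arm_calls.get(a) == direction for a in seg_arms
            )
            if not absorbed:
                kind = "add" if direction == "gain" else "del"
                arm_label = seg_arms.pop() if len(seg_arms) == 1 else ""
                events.append(KaryotypeEvent(kind, contig, arm_label,
                                             seg.start_bp, seg.end_bp))

    karyotype = NumericalKaryotype(total_count=46 + gains - losses, sex=sex,
                                   events=events)
    assert karyotype.total_count == 46 + gains - losses
    return karyotype


def annotate_gene_cn(state_segments: list[SegmentCall], genes: pd.DataFrame,
                     thresholds: StateThresholds | None = None,
                     sex: str = "female") -> pd.DataFrame:
    """Per-gene copy number from overlap-length-weighted segment CNs.

    ``genes`` needs columns gene/contig/start/end (0-based half-open, same
    build as the segments). A gene overlapping no valid segment is reported
    with label ``no_call``. The label derives from the weighted CN converted
    back to the log2 scale, using the same thresholds as segment calling.
    """
    thresholds = thresholds or StateThresholds()
    rows = []
    for rec in genes.itertuples(index=False):
        weights = []
        cns = []
        for seg in state_segments:
            if seg.contig != rec.contig or seg.cn is None:
                continue
            overlap = min(seg.end_bp, rec.end) - max(seg.start_bp, rec.start)
            if overlap > 0:
                weights.append(overlap)
                cns.append(seg.cn)
        if not weights:
            rows.append({"gene": rec.gene, "cn": np.nan, "label": "no_call"})
            continue
        cn = float(np.average(cns, weights=weights))
        base = baseline_copy_number(rec.contig, sex)
        r = np.log2(cn / base) if cn > 0 else -np.inf
        rows.append({"gene": rec.gene, "cn": cn, "label": thresholds.label(r)})
    return pd.DataFrame(rows, columns=["gene", "cn", "label"])


class ReadDepthKaryotypeModel:
    """Read-depth copy-number model for one tumor against a panel of normals.

    Parameters
    ----------
    tumor
        Bin-count profile of the tumor sample.
    pon
        Panel of normals sharing the tumor's binning.
    gc_per_bin
        Optional per-bin GC fraction enabling GC-decile correction at fit
        time.

    Examples
    --------
    >>> model = ReadDepthKaryotypeModel(tumor, pon)
    >>> res = model.fit()
    >>> print(res.karyotype.string)
    """

    def __init__(self, tumor: BinCountProfile, pon: PanelOfNormals,
                 gc_per_bin: np.ndarray | None = None):
        if tumor.binning != pon.binning:
            raise ValueError("tumor and PON binnings differ")
        self.tumor = tumor
        self.pon = pon
        self.gc_per_bin = gc_per_bin

    def fit(self, gc_correct: bool = False, min_seg_bins: int = 3,
            split_threshold: float = 4.0,
            thresholds: StateThresholds | None = None,
            arm_fraction: float = 0.6,
            min_log2: float = -5.0) -> "KaryotypeResults":
        thresholds = thresholds or StateThresholds()
        ratios = compute_log2_ratios(self.tumor, self.pon, gc_correct=gc_correct,
                                     gc_per_bin=self.gc_per_bin, min_log2=min_log2)
        segments = call_states(
            segment_ratios(ratios, min_seg_bins=min_seg_bins,
                           split_threshold=split_threshold),
            ratios, thresholds)
        karyotype = estimate_karyotype(segments, self.tumor.binning,
                                       self.tumor.sex, arm_fraction=arm_fraction)
        return KaryotypeResults(self, ratios, segments, karyotype, thresholds)


class KaryotypeResults:
    """Fitted read-depth karyotype: ratios, segments, events, summary."""

    def __init__(self, model: ReadDepthKaryotypeModel, ratios: RatioProfile,
                 segments: list[SegmentCall], karyotype: NumericalKaryotype,
                 thresholds: StateThresholds):
        self.model = model
        self.ratios = ratios
        self.segments = segments
        self.karyotype = karyotype
        self.thresholds = thresholds

    @property
    def segments_(self) -> pd.DataFrame:
        return segments_frame(self.segments)

    def gene_cn(self, genes: pd.DataFrame) -> pd.DataFrame:
        return annotate_gene_cn(self.segments, genes, self.thresholds,
                                sex=self.model.tumor.sex)

    def summary(self) -> str:
        n_nonneutral = sum(s.label != "neutral" for s in self.segments)
        lines = [
            "Read-depth karyotype results",
            "=" * 44,
            f"sample:            {self.model.tumor.sample_id}",
            f"declared sex:      {self.model.tumor.sex}",
            f"total reads:       {self.model.tumor.total}",
            f"usable bins:       {int(self.ratios.valid.sum())}",
            f"segments:          {len(self.segments)} ({n_nonneutral} non-neutral)",
            f"chromosome count:  {self.karyotype.total_count}",
            f"karyotype:         {self.karyotype.string}",
        ]
        if self.karyotype.events:
            lines.append("events:")
            lines.extend(f"  {ev.render():<24s}[{ev.kind}]"
                         for ev in self.karyotype.events)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Genome-wide log2-ratio scatter with segment means overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(14, 4))
        idx = np.flatnonzero(self.ratios.valid)
        ax.scatter(idx, self.ratios.log2[idx], s=2, c="0.6", rasterized=True)
        for seg in self.segments:
            color = {"neutral": "k", "gain": "tab:red", "amplification": "darkred",
                     "loss": "tab:blue", "deep_loss": "navy"}[seg.label or "neutral"]
            ax.hlines(seg.mean_log2, seg.start_bin, seg.end_bin, color=color, lw=2)
        boundaries = [self.model.tumor.binning.contig_bin_range(c)[0]
                      for c in self.model.tumor.binning.contig_lengths]
        for b in boundaries[1:]:
            ax.axvline(b, color="0.85", lw=0.5)
        ax.set_xlabel("genome bin")
        ax.set_ylabel("log2 ratio")
        ax.set_title(self.karyotype.string)
        return ax
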
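"""Panel-vs-genome copy-number concordance accounting.

Gene-level CNAs reported by the targeted panel are reconciled with the
genome-wide ulcWGS segments: a panel call is *confirmed* when a sufficient
fraction of its gene interval overlaps segments of agreeing direction
(gain/amplification vs loss/deep-loss). Non-neutral ulcWGS segments not
explained by any panel call are *additional* events, partitioned into
on-panel and off-panel by overlap with the panel's target regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .outcomes import round_half_up
from .segmentation import GAIN_STATES, LOSS_STATES, SegmentCall


@dataclass(frozen=True)
class PanelCnaCall:
    """A gene-level CNA from the targeted panel, on the diploid-relative
    scale (CN 1 = two copies; gain > 1, loss < 1)."""

    gene: str
    contig: str
    start: int
    end: int
    cn_relative: float
    direction: str  # gain | loss

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        consistent = (self.cn_relative > 1) if self.direction == "gain" \
            else (self.cn_relative < 1)
        if not consistent:
            raise ValueError(
                f"{self.gene}: direction {self.direction} inconsistent with "
                f"relative CN {self.cn_relative}")


@dataclass(frozen=True)
class CnaMatch:
    call: PanelCnaCall
    confirmed: bool
    matched_segments: tuple[SegmentCall, ...]
    overlap_fraction: float


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _segment_direction(label: str | None) -> str | None:
    if label in GAIN_STATES:
        return "gain"
    if label in LOSS_STATES:
        return "loss"
    return None


def match_cna_calls(panel_calls: list[PanelCnaCall],
                    ulc_segments: list[SegmentCall],
                    min_overlap_fraction: float = 0.5) -> list[CnaMatch]:
    """Flag each panel call confirmed/unconfirmed against ulcWGS segments.

    Confirmed means at least ``min_overlap_fraction`` of the gene interval
    overlaps segments whose state direction agrees with the panel call.
    """
    matches = []
    for call in panel_calls:
        gene_len = call.end - call.start
        agreeing = []
        covered = 0
        for seg in ulc_segments:
            if seg.contig != call.contig:
                continue
            if _segment_direction(seg.label) != call.direction:
                continue
            ov = _overlap(call.start, call.end, seg.start_bp, seg.end_bp)
            if ov > 0:
                agreeing.append(seg)
                covered += ov
        frac = covered / gene_len if gene_len > 0 else 0.0
        matches.append(CnaMatch(call, frac >= min_overlap_fraction,
                                tuple(agreeing), frac))
    return matches


@dataclass(frozen=True)
class AdditionalCall:
    segment: SegmentCall
    off_panel: bool


def find_ulc_only_calls(ulc_segments: list[SegmentCall],
                        panel_calls: list[PanelCnaCall],
                        panel_target_regions: pd.DataFrame
                        ) -> list[AdditionalCall]:
    """Non-neutral ulcWGS segments unmatched by any panel call.

    Each additional segment is off-panel iff it overlaps none of the panel's
    target regions (a table with contig/start/end columns).
    """
    targets = panel_target_regions
    additional = []
    for seg in ulc_segments:
        if _segment_direction(seg.label) is None:
            continue
        explained = any(
            seg.contig == call.contig
            and _segment_direction(seg.label) == call.direction
            and _overlap(call.start, call.end, seg.start_bp, seg.end_bp) > 0
            for call in panel_calls
        )
        if explained:
            continue
        on_panel = any(
            seg.contig == t.contig
            and _overlap(t.start, t.end, seg.start_bp, seg.end_bp) > 0
            for t in targets.itertuples(index=False)
        )
        additional.append(AdditionalCall(seg, off_panel=not on_panel))
    return additional


@dataclass(frozen=True)
class ConcordanceSummary:
    n_panel_calls: int
    n_confirmed: int
    confirmation_pct: int | None
    n_ulc_only: int
    n_ulc_only_off_panel: int
    off_panel_pct: int | None

    def to_dict(self) -> dict:
        return dict(vars(self))

    def render(self) -> str:
        conf = "NA" if self.confirmation_pct is None else f"{self.confirmation_pct}%"
        offp = "NA" if self.off_panel_pct is None else f"{self.off_panel_pct}%"
        return (f"panel CNAs: {self.n_panel_calls}, confirmed by ulcWGS: "
                f"{self.n_confirmed} ({conf})\n"
                f"additional ulcWGS-only CNAs: {self.n_ulc_only}, "
                f"off-panel: {self.n_ulc_only_off_panel} ({offp})")


def concordance_summary(matches: list[CnaMatch],
                        additional: list[AdditionalCall]) -> ConcordanceSummary:
    """Counts with integer half-up percentages (None when undefined)."""
    n_panel = len(matches)
    n_conf = sum(m.confirmed for m in matches)
    n_add = len(additional)
    n_off = sum(a.off_panel for a in additional)
    conf_pct = None if n_panel == 0 else int(round_half_up(100.0 * n_conf / n_panel, 0))
    off_pct = None if n_add == 0 else int(round_half_up(100.0 * n_off / n_add, 0))
    return ConcordanceSummary(n_panel, n_conf, conf_pct, n_add, n_off, off_pct)
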
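"""Synthetic-data generators with known ground truth.

Every downstream stage is testable without external data: this module
generates (i) ultra-low-coverage bin-count profiles for a panel of normal
donors and for tumors with injected integer-copy-number events at a given
tumor purity, (ii) short-variant tables with pass/fail labels computed by
direct evaluation of the depth/VAF/population-frequency predicates (an
oracle independent of the triage implementation), and (iii) cohort outcome
records with PFS1/PFS2 pairs and censoring.

Counts are Poisson per bin by default (negative binomial with configurable
overdispersion as an option); GC bias enters as a deterministic
multiplicative factor per GC decile. Every generator is byte-deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBinning, baseline_copy_number
from .outcomes import PatientOutcome
from .profiles import BinCountProfile


@dataclass(frozen=True)
class CnEvent:
    """One true copy-number event: integer CN per tumor cell over a region."""

    contig: str
    start: int
    end: int
    cn: int

    def __post_init__(self) -> None:
        if self.cn < 0 or self.cn != int(self.cn):
            raise ValueError("event CN must be a non-negative integer")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


@dataclass(frozen=True)
class KaryotypeTruth:
    """Ground-truth copy-number state of a simulated tumor.

    Background copy number is the sex-appropriate germline state (2 on
    autosomes); ``purity`` is the tumor-cell fraction.
    """

    events: tuple[CnEvent, ...]
    purity: float
    sex: str = "female"

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        by_contig: dict[str, list[CnEvent]] = {}
        for ev in self.events:
            by_contig.setdefault(ev.contig, []).append(ev)
        for contig, evs in by_contig.items():
            evs = sorted(evs, key=lambda e: e.start)
            for prev, nxt in zip(evs, evs[1:]):
                if nxt.start < prev.end:
                    raise ValueError(f"overlapping events on {contig}")

    def validate_against(self, binning: GenomeBinning) -> None:
        for ev in self.events:
            length = binning.contig_lengths.get(ev.contig)
            if length is None:
                raise ValueError(f"event contig {ev.contig} not in binning")
            if ev.start < 0 or ev.end > length:
                raise ValueError(f"event {ev} outside {ev.contig} bounds")


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs of the bin-count simulators.

    ``total_reads`` defaults to 2e6, which at 2x150 bp reads corresponds to
    roughly 0.2x genome coverage — inside the ultra-low-coverage regime the
    karyotyper targets. ``gc_bias`` holds ten multiplicative per-GC-decile
    factors (all 1 = no bias); ``overdispersion`` > 0 switches the count
    noise from Poisson to negative binomial with that dispersion.
    """

    seed: int = 0
    total_reads: int = 2_000_000
    n_normals: int = 20  # half male, half female
    gc_bias: tuple[float, ...] = (1.0,) * 10
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if len(self.gc_bias) != 10 or any(g <= 0 for g in self.gc_bias):
            raise ValueError("gc_bias must be 10 positive per-decile factors")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


def _gc_factors(config: SimulationConfig, gc_per_bin: np.ndarray | None,
                n_bins: int) -> np.ndarray:
    if gc_per_bin is None:
        return np.ones(n_bins)
    deciles = np.clip((np.asarray(gc_per_bin, float) * 10).astype(int), 0, 9)
    return np.asarray(config.gc_bias, float)[deciles]


def expected_normal_counts(binning: GenomeBinning, config: SimulationConfig,
                           sex: str, gc_per_bin: np.ndarray | None = None) -> np.ndarray:
    """Expected bin counts of a normal sample: proportional to bin width and
    GC factor, with sex-appropriate X/Y dosage, scaled to ``total_reads``."""
    bins = binning.bins
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    dosage = np.array([baseline_copy_number(c, sex) / 2.0
                       for c in bins["contig"]])
    lam = widths * dosage * _gc_factors(config, gc_per_bin, len(bins))
    return lam * (config.total_reads / lam.sum())


def _draw_counts(lam: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.overdispersion > 0:
        # NB with mean lam and variance lam * (1 + overdispersion * lam)
        r = 1.0 / config.overdispersion
        with np.errstate(divide="ignore"):
            p = r / (r + lam)
        counts = np.where(lam > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
        return counts.astype(np.int64)
    return rng.poisson(lam).astype(np.int64)


def simulate_normal_profiles(binning: GenomeBinning, config: SimulationConfig,
                             gc_per_bin: np.ndarray | None = None
                             ) -> list[BinCountProfile]:
    """Draw the panel-of-normals donor profiles (alternating male/female)."""
    rng = np.random.default_rng(config.seed)
    profiles = []
    for i in range(config.n_normals):
        sex = "male" if i % 2 == 0 else "female"
        lam = expected_normal_counts(binning, config, sex, gc_per_bin)
        profiles.append(BinCountProfile(
            sample_id=f"normal_{i + 1:02d}", sex=sex,
            counts=_draw_counts(lam, config, rng), binning=binning,
            meta={"seed": config.seed, "total_reads": config.total_reads},
        ))
    return profiles


def tumor_expected_counts(binning: GenomeBinning, truth: KaryotypeTruth,
                          config: SimulationConfig,
                          gc_per_bin: np.ndarray | None = None,
                          rescale: bool = False) -> np.ndarray:
    """Expected tumor bin counts before noise.

    Each bin's normal expectation is multiplied by
    (purity * CN / base + (1 - purity)), where CN is the event copy number
    (overlap-weighted for bins partially covered) and base the germline copy
    number; base is 2 on autosomes, recovering the diploid mixture formula.
    With ``rescale`` the expectations are renormalized to ``total_reads``.
    """
    truth.validate_against(binning)
    lam = expected_normal_counts(binning, config, truth.sex, gc_per_bin)
    bins = binning.bins
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    mult = np.ones(len(bins))
    for ev in truth.events:
        lo, hi = binning.contig_bin_range(ev.contig)
        overlap = (np.minimum(ends[lo:hi], ev.end)
                   - np.maximum(starts[lo:hi], ev.start)).clip(min=0)
        frac = overlap / (ends[lo:hi] - starts[lo:hi])
        base = baseline_copy_number(ev.contig, truth.sex)
        if base == 0:
            continue
        cn_eff = frac * ev.cn + (1 - frac) * base
        mult[lo:hi] *= truth.purity * cn_eff / base + (1 - truth.purity)
    lam = lam * mult
    if rescale:
        lam *= config.total_reads / lam.sum()
    return lam


def simulate_tumor_profile(binning: GenomeBinning, truth: KaryotypeTruth,
                           config: SimulationConfig,
                           gc_per_bin: np.ndarray | None = None,
                           rescale: bool = False,
                           sample_id: str = "tumor"
                           ) -> tuple[BinCountProfile, KaryotypeTruth]:
    """Simulate one tumor profile; returns the truth alongside."""
    lam = tumor_expected_counts(binning, truth, config, gc_per_bin, rescale)
    rng = np.random.default_rng(config.seed)
    profile = BinCountProfile(
        sample_id=sample_id, sex=truth.sex,
        counts=_draw_counts(lam, config, rng), binning=binning,
        meta={"seed": config.seed, "total_reads": config.total_reads,
              "purity": truth.purity, "rescaled": rescale},
    )
    return profile, truth


# ---------------------------------------------------------------------------
# variant tables


def variant_pass_oracle(depth: np.ndarray, vaf: np.ndarray, popfreq: np.ndarray,
                        min_depth_exclusive: float = 100.0,
                        min_vaf: float = 0.05,
                        max_popfreq_exclusive: float = 0.05) -> np.ndarray:
    """Direct evaluation of the three filter predicates (missing popfreq = 0)."""
    pf = np.where(np.isnan(popfreq), 0.0, popfreq)
    return ((depth > min_depth_exclusive)
            & (vaf >= min_vaf)
            & (pf < max_popfreq_exclusive))


_GENES = ("TP53", "CDKN2A", "KRAS", "ERBB2", "MYC", "APC", "BRAF", "EGFR",
          "IDH1", "FBXW7", "ATM", "ARID1A", "RET", "KIT", "PDGFRA", "KDR")


def simulate_variant_table(n: int, config: SimulationConfig,
                           boundary_fraction: float = 0.2
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Random variant table straddling the filter thresholds, plus oracle labels.

    ``boundary_fraction`` of the rows take exact boundary values (depth 100,
    VAF 0.05, population frequency 0.05) or a missing population frequency,
    so both sides of every predicate are exercised.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(config.seed)
    depth = rng.integers(20, 400, size=n).astype(float)
    vaf = np.round(rng.uniform(0.0, 0.6, size=n), 4)
    popfreq = np.round(10.0 ** rng.uniform(-5, -0.5, size=n), 6)

    boundary = rng.random(n) < boundary_fraction
    which = rng.integers(0, 4, size=n)
    depth[boundary & (which == 0)] = 100.0
    vaf[boundary & (which == 1)] = 0.05
    popfreq[boundary & (which == 2)] = 0.05
    popfreq[boundary & (which == 3)] = np.nan

    table = pd.DataFrame({
        "gene": rng.choice(_GENES, size=n),
        "contig": rng.choice([f"chr{i}" for i in range(1, 23)], size=n),
        "position": rng.integers(1, 50_000_000, size=n),
        "ref": rng.choice(list("ACGT"), size=n),
        "alt": rng.choice(list("ACGT"), size=n),
        "depth": depth.astype(int),
        "vaf": vaf,
        "popfreq": popfreq,
        "protein_change": [f"p.X{i + 1}Y" for i in range(n)],
    })
    labels = variant_pass_oracle(depth, vaf, popfreq)
    return table, labels


# ---------------------------------------------------------------------------
# cohorts


DEFAULT_PFS_DISTRIBUTIONS = {
    # the study conditions the generator emulates: exponential PFS2 with the
    # observed arm medians (months); PFS1 shared across arms
    "matched": {"family": "exponential", "median": 4.3},
    "other": {"family": "exponential", "median": 1.9},
    "pfs1": {"family": "exponential", "median": 3.0},
}


def _draw_times(dist: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    median = float(dist["median"])
    family = dist.get("family", "exponential")
    if family == "exponential":
        return rng.exponential(median / np.log(2), size=size)
    if family == "weibull":
        shape = float(dist.get("shape", 1.0))
        scale = median / np.log(2) ** (1 / shape)
        return scale * rng.weibull(shape, size=size)
    raise ValueError(f"unknown PFS family {family!r}")


def simulate_cohort(n_matched: int, n_other: int, config: SimulationConfig,
                    pfs_distributions: dict | None = None,
                    censor_rate: float = 0.0,
                    response_rate: float = 0.2,
                    toxicity_stop_rate: float = 0.05,
                    off_label_rate: float = 0.8) -> list[PatientOutcome]:
    """Simulate a post-MTB outcome cohort with known generating distributions.

    Each record carries PFS1 > 0, an observed PFS2 with event indicator
    (censoring truncates the true progression time uniformly with probability
    ``censor_rate``), follow-up length, and response/toxicity flags at the
    stated frequencies (never both on one record).
    """
    if n_matched < 0 or n_other < 0:
        raise ValueError("cohort sizes must be >= 0")
    dists = {**DEFAULT_PFS_DISTRIBUTIONS, **(pfs_distributions or {})}
    rng = np.random.default_rng(config.seed)
    records: list[PatientOutcome] = []
    for arm, n in (("matched", n_matched), ("other", n_other)):
        true_t = _draw_times(dists[arm], n, rng)
        pfs1 = np.maximum(_draw_times(dists["pfs1"], n, rng), 0.1)
        censored = rng.random(n) < censor_rate
        obs = np.where(censored, true_t * rng.uniform(0.1, 1.0, size=n), true_t)
        response = rng.random(n) < response_rate
        toxicity = (~response) & (rng.random(n) < toxicity_stop_rate)
        off_label = rng.random(n) < off_label_rate
        for i in range(n):
            records.append(PatientOutcome(
                patient_id=f"{arm}_{i + 1:03d}",
                pfs1=float(np.round(pfs1[i], 2)),
                pfs2=float(np.round(max(obs[i], 0.05), 2)),
                event=not censored[i],
                follow_up=float(np.round(max(obs[i], 0.05), 2)),
                arm=arm,
                label_status="off" if off_label[i] else "on",
                clinical_response=bool(response[i]),
                toxicity_stop=bool(toxicity[i]),
            ))
    return records


def cohort_frame(records: list[PatientOutcome]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
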
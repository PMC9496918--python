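"""Simulation studies validating the pipeline against known ground truth.

These studies are the package's substitute for re-running the original
clinical samples, which are not distributable: whole-arm aneuploidy recovery
across simulated tumors, recovery of a sarcoma-like pattern (1p loss plus a
focal 4q12 amplification covering PDGFRA/KIT/KDR and a partial 4q loss over
FBXW7), and the power of the log-rank comparison on cohorts generated at the
observed arm medians.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import ACROCENTRIC, default_binning
from .karyotype import ReadDepthKaryotypeModel
from .outcomes import logrank_test
from .profiles import build_panel_of_normals
from .simulate import (CnEvent, KaryotypeTruth, SimulationConfig,
                       simulate_cohort, simulate_normal_profiles,
                       simulate_tumor_profile)
from .triage import _data_path

_MAX_SEED = 2**31 - 1


def _build_pon(binning, seed: int, total_reads: int):
    cfg = SimulationConfig(seed=seed, total_reads=total_reads)
    return build_panel_of_normals(simulate_normal_profiles(binning, cfg))


def arm_recovery_study(n_tumors: int = 20, seed: int = 0,
                       bin_width: int = 1_000_000,
                       total_reads: int = 2_000_000,
                       min_purity: float = 0.5) -> dict:
    """Inject whole-arm events and measure recovery by the karyotyper.

    Each simulated tumor carries two whole-arm events (single-copy gain or
    loss) on distinct autosomes at a purity drawn uniformly from
    [min_purity, 1]. An event counts as recovered when the estimated
    karyotype contains an arm- or whole-chromosome event of the correct
    direction on that chromosome arm; a spurious call is a whole-chromosome
    event on an unaffected chromosome.
    """
    rng = np.random.default_rng(seed)
    binning = default_binning(bin_width)
    pon = _build_pon(binning, int(rng.integers(_MAX_SEED)), total_reads)

    autosomes = [f"chr{i}" for i in range(1, 23)]
    n_events = n_recovered = 0
    n_unaffected = n_spurious_free = 0
    for _ in range(n_tumors):
        chroms = rng.choice(autosomes, size=2, replace=False)
        events, truth_arms = [], []
        for contig in chroms:
            arm = "q" if contig in ACROCENTRIC else rng.choice(["p", "q"])
            boundary = binning.centromeres[contig]
            lo, hi = (0, boundary) if arm == "p" else (boundary,
                                                       binning.contig_lengths[contig])
            cn = int(rng.choice([1, 3]))
            events.append(CnEvent(contig, lo, hi, cn))
            truth_arms.append((contig, arm, "gain" if cn > 2 else "loss"))
        truth = KaryotypeTruth(events=tuple(events),
                               purity=float(rng.uniform(min_purity, 1.0)))
        cfg = SimulationConfig(seed=int(rng.integers(_MAX_SEED)),
                               total_reads=total_reads)
        tumor, _ = simulate_tumor_profile(binning, truth, cfg)
        kt = ReadDepthKaryotypeModel(tumor, pon).fit().karyotype

        for contig, arm, direction in truth_arms:
            n_events += 1
            hit = any(
                (e.kind == f"arm_{direction}" and e.contig == contig and e.arm == arm)
                or (e.kind == f"whole_{direction}" and e.contig == contig)
                for e in kt.events)
            n_recovered += hit
        affected = {c for c, _, _ in truth_arms}
        for contig in autosomes:
            if contig in affected:
                continue
            n_unaffected += 1
            spurious = any(e.kind in ("whole_gain", "whole_loss")
                           and e.contig == contig for e in kt.events)
            n_spurious_free += not spurious

    return {
        "n_tumors": n_tumors,
        "n_events": n_events,
        "recovery_rate": n_recovered / n_events,
        "n_unaffected_chromosomes": n_unaffected,
        "spurious_free_rate": n_spurious_free / n_unaffected,
    }


def sarcoma_pattern_study(seed: int = 0, bin_width: int = 1_000_000,
                          total_reads: int = 2_000_000,
                          purity: float = 0.8) -> dict:
    """End-to-end recovery of the sarcoma-like copy-number pattern.

    Simulates a tumor with a heterozygous 1p deletion (covering ARID1A and
    NRAS), a focal high-level 4q12 amplification covering PDGFRA, KIT and
    KDR, and a partial 4q single-copy loss covering FBXW7, then checks each
    feature in the fitted karyotype and gene-level annotation.
    """
    rng = np.random.default_rng(seed)
    binning = default_binning(bin_width)
    pon = _build_pon(binning, int(rng.integers(_MAX_SEED)), total_reads)
    truth = KaryotypeTruth(events=(
        CnEvent("chr1", 0, 123_000_000, 1),
        CnEvent("chr4", 52_000_000, 58_000_000, 10),
        CnEvent("chr4", 140_000_000, 170_000_000, 1),
    ), purity=purity)
    cfg = SimulationConfig(seed=int(rng.integers(_MAX_SEED)),
                           total_reads=total_reads)
    tumor, _ = simulate_tumor_profile(binning, truth, cfg)
    res = ReadDepthKaryotypeModel(tumor, pon).fit()
    kt = res.karyotype

    genes = pd.read_csv(_data_path("genes_grch38.tsv"), sep="\t", comment="#")
    gene_cn = res.gene_cn(genes).set_index("gene")
    amplified = {"PDGFRA", "KIT", "KDR"}
    return {
        "karyotype": kt.string,
        "del_1p": any(e.kind == "arm_loss" and e.contig == "chr1" and e.arm == "p"
                      for e in kt.events),
        "add_4q_focal": any(e.kind == "add" and e.contig == "chr4" and e.arm == "q"
                            for e in kt.events),
        "target_genes_amplified": all(
            gene_cn.loc[g, "label"] == "amplification" for g in amplified),
        "fbxw7_loss": gene_cn.loc["FBXW7", "label"] == "loss",
        "gene_cn": gene_cn["cn"].to_dict(),
    }


def logrank_power_study(n_replicates: int = 100, seed: int = 0,
                        n_matched: int = 30, n_other: int = 17) -> dict:
    """Fraction of simulated cohorts where the arm comparison reaches p < 0.05.

    Cohorts are generated at the default study conditions (exponential PFS2,
    arm medians 4.3 and 1.9 months, no censoring).
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, _MAX_SEED, size=n_replicates)
    p_values = []
    for s in child_seeds:
        records = simulate_cohort(n_matched, n_other, SimulationConfig(seed=int(s)))
        arms = {}
        for arm in ("matched", "other"):
            sub = [r for r in records if r.arm == arm]
            arms[arm] = ([r.pfs2 for r in sub], [r.event for r in sub])
        p_values.append(logrank_test(arms["matched"], arms["other"]).p_value)
    p_values = np.asarray(p_values)
    return {
        "n_replicates": n_replicates,
        "fraction_significant": float((p_values < 0.05).mean()),
        "median_p": float(np.median(p_values)),
    }
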
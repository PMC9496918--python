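"""File formats and run provenance.

Genome coordinates are 0-based half-open internally and on disk (BED
convention); 1-based coordinates appear only in VCF-dialect input and in
position tables ingested with an explicit ``one_based`` dialect. Tabular
schemas are validated with file/line/column-naming errors. Every writer can
drop a sidecar JSON manifest recording seed, parameters and a config hash so
runs are reproducible from their outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .genome import GenomeBinning
from .outcomes import PatientOutcome
from .profiles import BinCountProfile

SCHEMA_VERSION = "1"

VARIANT_COLUMNS = ("gene", "contig", "position", "ref", "alt", "depth", "vaf",
                   "popfreq")
COHORT_COLUMNS = ("patient_id", "pfs1", "pfs2", "event", "follow_up", "arm",
                  "label_status", "clinical_response", "toxicity_stop")


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def write_sidecar(path: str | Path, seed: int | None, params: dict) -> Path:
    """Write ``<path>.json`` recording seed and parameters next to an output."""
    side = Path(str(path) + ".json")
    payload = {"schema_version": SCHEMA_VERSION, "seed": seed, "params": params}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:16]
    side.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return side


# -- bin counts -------------------------------------------------------------


def write_bin_counts(profile: BinCountProfile, path: str | Path,
                     seed: int | None = None) -> None:
    df = profile.to_frame()
    df.to_csv(path, sep="\t", index=False)
    write_sidecar(path, seed, {"sample_id": profile.sample_id,
                               "sex": profile.sex, **profile.meta})


def read_bin_counts(path: str | Path, binning: GenomeBinning,
                    sample_id: str = "sample", sex: str = "female"
                    ) -> BinCountProfile:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("contig", "start", "end", "count"), path)
    if len(df) != binning.n_bins:
        raise ValueError(f"{path}: {len(df)} rows != binning's {binning.n_bins} bins")
    expected = binning.bins
    if not (df["contig"].to_numpy() == expected["contig"].to_numpy()).all() \
            or not (df["start"].to_numpy() == expected["start"].to_numpy()).all():
        raise ValueError(f"{path}: bin coordinates do not match the binning")
    return BinCountProfile(sample_id, sex, df["count"].to_numpy(), binning)


# -- BED-like intervals -----------------------------------------------------


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write contig/start/end (+ extra columns) as headered BED-like TSV."""
    _require_columns(df, ("contig", "start", "end"), path)
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ("contig", "start", "end"), path)
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"{path}, line {bad[0] + 2}: end <= start")
    return df


# -- position tables --------------------------------------------------------


def read_position_table(path: str | Path, one_based: bool = True
                        ) -> Iterator[tuple[str, int, int]]:
    """Yield (contig, 1-based position, mapq) records for bin counting.

    Columns: contig, position, mapq. With ``one_based`` False the stored
    positions are 0-based and are shifted to the 1-based convention the bin
    counter expects.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("contig", "position", "mapq"), path)
    shift = 0 if one_based else 1
    for rec in df.itertuples(index=False):
        yield rec.contig, int(rec.position) + shift, int(rec.mapq)


def write_position_table(records: list[tuple[str, int, int]], path: str | Path,
                         one_based: bool = True) -> None:
    shift = 0 if one_based else -1
    pd.DataFrame(
        [(c, p + shift, q) for c, p, q in records],
        columns=["contig", "position", "mapq"],
    ).to_csv(path, sep="\t", index=False)


# -- variants ---------------------------------------------------------------


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, VARIANT_COLUMNS[:7], path)  # popfreq may be absent
    if "popfreq" not in df.columns:
        df["popfreq"] = np.nan
    for i, vaf in enumerate(df["vaf"]):
        if not (0 <= vaf <= 1):
            raise ValueError(f"{path}, line {i + 2}, column vaf: {vaf} outside [0, 1]")
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path,
                        seed: int | None = None, **params) -> None:
    df.to_csv(path, sep="\t", index=False)
    write_sidecar(path, seed, params)


def read_vcf_variants(path: str | Path,
                      info_keys: dict[str, str] | None = None) -> pd.DataFrame:
    """Minimal VCF reader: CHROM/POS/REF/ALT plus depth/VAF/popfreq/gene from
    INFO keys named in ``info_keys`` (defaults DP/AF/GNOMAD_AF/GENE)."""
    from cyvcf2 import VCF  # optional reader path

    keys = {"depth": "DP", "vaf": "AF", "popfreq": "GNOMAD_AF", "gene": "GENE",
            **(info_keys or {})}
    rows = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        pf = info.get(keys["popfreq"])
        rows.append({
            "gene": info.get(keys["gene"], ""),
            "contig": rec.CHROM, "position": rec.POS,  # VCF dialect: 1-based
            "ref": rec.REF, "alt": rec.ALT[0] if rec.ALT else "",
            "depth": int(info.get(keys["depth"], 0)),
            "vaf": float(info.get(keys["vaf"], 0.0)),
            "popfreq": float(pf) if pf is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))


# -- cohorts ----------------------------------------------------------------


def write_cohort_csv(records: list[PatientOutcome], path: str | Path,
                     seed: int | None = None, **params) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)
    write_sidecar(path, seed, params)


def read_cohort_csv(path: str | Path) -> list[PatientOutcome]:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    records = []
    for i, rec in enumerate(df.itertuples(index=False)):
        try:
            pfs1 = None if (isinstance(rec.pfs1, float) and math.isnan(rec.pfs1)) \
                else float(rec.pfs1)
            records.append(PatientOutcome(
                patient_id=str(rec.patient_id), pfs1=pfs1, pfs2=float(rec.pfs2),
                event=bool(rec.event), follow_up=float(rec.follow_up),
                arm=str(rec.arm), label_status=str(rec.label_status),
                clinical_response=bool(rec.clinical_response),
                toxicity_stop=bool(rec.toxicity_stop)))
        except ValueError as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return records
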
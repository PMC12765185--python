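"""Readers and writers for the pipeline's plain-text interchange formats.

Prescriptions, sample sheets and dosage matrices travel as TSV; genotypes
may also arrive as VCF 4.x (GT hard calls or DS dosages), read with cyvcf2.
Every table the pipeline writes carries a ``#`` provenance header (config
hash, seed, package version) so runs are auditable and diff-able.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_prescriptions",
    "read_samples",
    "read_dosage_tsv",
    "read_vcf",
    "read_genotypes",
    "write_table",
    "provenance_header",
    "config_hash",
]

SUMSTATS_COLUMNS = [
    "CHR", "POS", "ID", "EA", "OA", "EAF", "N", "BETA", "SE", "P",
    "OR", "CI_L", "CI_U", "STRATUM", "MODEL",
]


def read_prescriptions(path: str | Path) -> pd.DataFrame:
    """Read a prescriptions TSV with columns person_id, date, atc_code."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"person_id", "date", "atc_code"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV (person_id, sex, optional covariates)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "person_id" not in df.columns:
        raise ValueError(f"{path}: missing person_id column")
    df["person_id"] = df["person_id"].astype(str)
    return df


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    """Read a variant-by-person dosage TSV into a person-by-variant frame."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    geno = df.T
    geno.columns.name = None
    geno.index.name = "person_id"
    geno.index = geno.index.astype(str)
    bad = [(v, float(geno[v].min()), float(geno[v].max()))
           for v in geno.columns
           if geno[v].min() < 0 or geno[v].max() > 2]
    if bad:
        raise ValueError(f"doses outside [0, 2] for variants: {bad}")
    return geno


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read GT (preferred) or DS from a VCF into a person-by-variant dose frame.

    Missing genotypes become NaN — they are flagged, never silently zero.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    persons = list(vcf.samples)
    doses: dict[str, np.ndarray] = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        gts = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if (gts != 2).any():
            d = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        else:
            ds = rec.format("DS")
            d = (
                np.asarray(ds, dtype=float).reshape(-1)
                if ds is not None
                else np.full(len(persons), np.nan)
            )
        doses[vid] = d
    out = pd.DataFrame(doses, index=pd.Index(persons, name="person_id"))
    out.index = out.index.astype(str)
    return out


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .vcf/.vcf.gz via cyvcf2, otherwise dosage TSV."""
    p = Path(path)
    if p.name.endswith((".vcf", ".vcf.gz")):
        return read_vcf(p)
    return read_dosage_tsv(p)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance_header(config: dict, seed: int) -> str:
    from . import __version__

    return (
        f"# rxswitch v{__version__}\n"
        f"# config_hash: {config_hash(config)}\n"
        f"# seed: {seed}\n"
    )


def write_table(df: pd.DataFrame, path: str | Path, config: dict, seed: int) -> None:
    """Write a TSV with the provenance header and stable float formatting."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
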
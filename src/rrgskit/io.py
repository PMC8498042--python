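"""Readers, writers and validation for the toolkit's file dialects.

Genotypes travel as a VCF v4.2 subset (biallelic SNPs, GT field, genetic
position in an INFO ``cM`` key) or as a CSV dosage matrix (individuals as
rows, marker ids as header); phenotypes as the long-format CSV defined by
the generator; environment profiles as location/date/evi/paw CSV. All
writers are deterministic and round trips are lossless. VCF parsing goes
through cyvcf2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import PHENOTYPE_COLUMNS, EnvironmentProfile, GenotypeMatrix

__all__ = [
    "Dataset",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_csv",
    "read_phenotypes",
    "write_phenotypes",
    "read_env_profiles",
    "write_env_profiles",
    "filter_markers",
    "validate_dataset",
]

_MISSING = "NA"


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2: CHROM, POS, ID, REF=A, ALT=T, INFO cM, GT.

    POS is the 1-based marker ordinal within its chromosome; the genetic
    position in centimorgans lives in INFO.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=cM,Number=1,Type=Float,Description="Genetic map position in centimorgans">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.individual_ids),
    ]
    ordinal: dict[str, int] = {}
    gt_map = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}
    for j, mid in enumerate(genotypes.marker_ids):
        c = str(genotypes.chrom[j])
        ordinal[c] = ordinal.get(c, 0) + 1
        calls = [
            gt_map.get(genotypes.dosage[i, j], "./.")
            for i in range(genotypes.n_individuals)
        ]
        lines.append(
            f"{c}\t{ordinal[c]}\t{mid}\tA\tT\t.\t.\tcM={genotypes.pos_cm[j]:.6g}\tGT\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_genotypes_csv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Dosage matrix CSV with a two-row map header (chrom, pos_cM)."""
    frame = pd.DataFrame(
        genotypes.dosage, index=genotypes.individual_ids, columns=genotypes.marker_ids
    )
    header = pd.DataFrame(
        [genotypes.chrom, genotypes.pos_cm],
        index=["#chrom", "#pos_cM"],
        columns=genotypes.marker_ids,
    )
    out = pd.concat([header, frame])
    out.to_csv(path, na_rep=_MISSING, index_label="id")


def _read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    raw = pd.read_csv(path, index_col=0, na_values=[_MISSING])
    chrom = raw.loc["#chrom"].to_numpy(dtype=str)
    pos = raw.loc["#pos_cM"].to_numpy(dtype=float)
    body = raw.drop(index=["#chrom", "#pos_cM"])
    return GenotypeMatrix(
        individual_ids=list(map(str, body.index)),
        marker_ids=list(map(str, body.columns)),
        chrom=chrom,
        pos_cm=pos,
        dosage=body.to_numpy(dtype=float),
    )


def read_genotypes(
    path: str | Path, format: str | None = None
) -> tuple[GenotypeMatrix, list[dict]]:
    """Read genotypes from VCF or dosage CSV.

    Returns the matrix and a log of skipped records (multi-allelic sites are
    dropped with a reason). The format is inferred from the suffix when not
    given.
    """
    path = Path(path)
    fmt = format or ("vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "csv")
    log: list[dict] = []
    if fmt == "csv":
        return _read_genotypes_csv(path), log
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, chrom, pos, rows = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            log.append(
                {
                    "marker": variant.ID or f"{variant.CHROM}:{variant.POS}",
                    "reason": "multi-allelic site dropped",
                }
            )
            continue
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chrom.append(variant.CHROM)
        cm = variant.INFO.get("cM")
        pos.append(float(cm) if cm is not None else float(variant.POS))
        dos = []
        for a1, a2, *_ in variant.genotypes:
            if a1 < 0 or a2 < 0:
                dos.append(np.nan)
            else:
                dos.append(2.0 - a1 - a2)  # reference-allele copies
        rows.append(dos)
    vcf.close()
    dosage = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return (
        GenotypeMatrix(samples, marker_ids, np.asarray(chrom), np.asarray(pos), dosage),
        log,
    )


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False, na_rep=_MISSING)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, na_values=[_MISSING], keep_default_na=False)
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns {sorted(missing)}")
    return table[PHENOTYPE_COLUMNS]


def write_env_profiles(profiles: list[EnvironmentProfile], path: str | Path) -> None:
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, index=False, na_rep=_MISSING
    )


def read_env_profiles(
    path: str | Path, evi_min: float = 0.0, evi_max: float = 1.0
) -> list[EnvironmentProfile]:
    """Load profiles from CSV; reference extremes default to [0, 1] unless given."""
    raw = pd.read_csv(path, na_values=[_MISSING])
    profiles = []
    for loc, grp in raw.groupby("location", sort=True):
        grp = grp.sort_values("date")
        paw = grp["paw"].to_numpy(dtype=float) if "paw" in grp else None
        profiles.append(
            EnvironmentProfile(
                location_id=str(loc),
                dates=grp["date"].to_numpy(),
                evi=grp["evi"].to_numpy(dtype=float),
                evi_min=evi_min,
                evi_max=evi_max,
                paw=paw,
            )
        )
    return profiles


def filter_markers(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.05,
    require_polymorphic: bool = True,
    drop_duplicates: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Marker quality control: missingness, polymorphism, uniqueness.

    Markers with a missing fraction above ``max_missing`` are removed, then
    monomorphic markers (when requested), then duplicate dosage columns are
    collapsed to one surviving representative. The filter log accounts for
    every dropped marker with a reason.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    log_rows = []
    keep = np.ones(genotypes.n_markers, dtype=bool)
    missing_frac = np.isnan(genotypes.dosage).mean(axis=0)
    for j in np.flatnonzero(missing_frac > max_missing):
        keep[j] = False
        log_rows.append(
            {
                "marker": genotypes.marker_ids[j],
                "reason": f"missing fraction {missing_frac[j]:.3f} > {max_missing}",
            }
        )
    if require_polymorphic:
        freq = np.nanmean(genotypes.dosage, axis=0) / 2.0
        for j in np.flatnonzero(keep & ((freq == 0) | (freq == 1))):
            keep[j] = False
            log_rows.append(
                {"marker": genotypes.marker_ids[j], "reason": "monomorphic"}
            )
    if drop_duplicates:
        seen: dict[bytes, str] = {}
        for j in np.flatnonzero(keep):
            key = genotypes.dosage[:, j].tobytes()
            if key in seen:
                keep[j] = False
                log_rows.append(
                    {
                        "marker": genotypes.marker_ids[j],
                        "reason": f"duplicate of {seen[key]}",
                    }
                )
            else:
                seen[key] = genotypes.marker_ids[j]
    if not keep.any():
        raise ValueError("all markers removed by filtering")
    return genotypes.subset(marker_mask=keep), pd.DataFrame(
        log_rows, columns=["marker", "reason"]
    )


@dataclass
class Dataset:
    """Bundle of genotypes, phenotypes and environment profiles."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    profiles: list[EnvironmentProfile] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def validate_dataset(dataset: Dataset) -> dict[str, dict]:
    """Machine-readable consistency report; validation reports, never raises.

    Rules: dosage values in {0, 1, 2} or missing; every phenotyped hybrid's
    parents genotyped; hybrids carry both parents and lines none; record
    keys unique; profile locations cover phenotyped locations.
    """
    report: dict[str, dict] = {}
    geno = dataset.genotypes
    pheno = dataset.phenotypes

    with np.errstate(invalid="ignore"):
        bad = ~(np.isnan(geno.dosage) | np.isin(geno.dosage, (0.0, 1.0, 2.0)))
    coords = [
        (geno.individual_ids[i], geno.marker_ids[j]) for i, j in zip(*np.where(bad))
    ]
    report["dosage_values"] = {"passed": not coords, "violations": coords[:20]}

    genotyped = set(geno.individual_ids)
    hybrids = pheno[pheno["role"] == "hybrid"]
    missing_parents = sorted(
        set(hybrids["female_parent"].dropna()) | set(hybrids["male_parent"].dropna())
    )
    missing_parents = [p for p in missing_parents if p not in genotyped]
    report["hybrid_parents_genotyped"] = {
        "passed": not missing_parents,
        "violations": missing_parents[:20],
    }

    bad_hybrid = hybrids[
        hybrids["female_parent"].isna() | hybrids["male_parent"].isna()
    ]["genotype_id"].unique()
    non_hybrids = pheno[pheno["role"] != "hybrid"]
    bad_line = non_hybrids[
        non_hybrids["female_parent"].notna() | non_hybrids["male_parent"].notna()
    ]["genotype_id"].unique()
    report["parent_annotation"] = {
        "passed": len(bad_hybrid) == 0 and len(bad_line) == 0,
        "violations": list(bad_hybrid[:10]) + list(bad_line[:10]),
    }

    dup = pheno.duplicated(subset=["genotype_id", "location", "year", "block"])
    report["unique_records"] = {
        "passed": not dup.any(),
        "violations": pheno.loc[dup, "genotype_id"].tolist()[:20],
    }

    if dataset.profiles:
        prof_locs = {p.location_id for p in dataset.profiles}
        missing_locs = sorted(set(pheno["location"].unique()) - prof_locs)
        report["profile_coverage"] = {
            "passed": not missing_locs,
            "violations": missing_locs,
        }
    return report
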
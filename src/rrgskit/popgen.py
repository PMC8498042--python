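"""Synthetic breeding-population generator.

Simulates the raw material of a two-pool hybrid wheat program: fully inbred
founder genomes on a wheat-like genetic map, round-robin crossing plans,
meiosis under the Haldane (no-interference) map function, single-seed
descent, additive + dominance trait architectures, multi-environment
phenotypes with a tunable genotype-by-environment regime including a
drought-stressed "outgroup" of locations, and per-location EVI profiles.

Phase matters for linkage, so simulated individuals are carried as pairs of
haplotypes; the dosage view used by the prediction machinery is their sum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    PHENOTYPE_COLUMNS,
    CrossingPlan,
    EnvironmentProfile,
    GenotypeMatrix,
    TraitArchitecture,
    TrialDesign,
)

__all__ = [
    "make_founders",
    "make_map",
    "round_robin",
    "cross",
    "cross_haplotypes",
    "meiosis",
    "self_ssd",
    "make_architecture",
    "genetic_value",
    "simulate_phenotypes",
    "simulate_env_profiles",
]


def make_map(
    n_markers: int, n_chromosomes: int, chrom_length_cm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced markers on ``n_chromosomes`` of equal length."""
    base = n_markers // n_chromosomes
    counts = [base + (1 if c < n_markers % n_chromosomes else 0) for c in range(n_chromosomes)]
    chrom, pos = [], []
    for c, k in enumerate(counts, start=1):
        chrom.extend([f"chr{c}"] * k)
        # midpoints of k equal bins, so spacing is uniform and ends are interior
        pos.extend(chrom_length_cm * (np.arange(k) + 0.5) / k)
    return np.asarray(chrom), np.asarray(pos, dtype=float)


def make_founders(
    n_individuals: int,
    n_markers: int,
    n_chromosomes: int = 21,
    chrom_length_cm: float = 150.0,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int | np.random.Generator = 0,
    prefix: str = "L",
) -> GenotypeMatrix:
    """Simulate fully inbred founder lines.

    Per-marker reference-allele frequencies are drawn uniformly within the
    requested minor-allele-frequency band (randomly reflected to the upper
    half so reference and alternative alleles are exchangeable); each inbred
    founder is homozygous, dosage 2 with probability equal to the marker
    frequency.
    """
    if n_individuals <= 0 or n_markers <= 0 or n_chromosomes <= 0:
        raise ValueError("counts must be positive")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    chrom, pos = make_map(n_markers, n_chromosomes, chrom_length_cm)
    maf = rng.uniform(maf_low, maf_high, size=n_markers)
    flip = rng.random(n_markers) < 0.5
    freq = np.where(flip, 1.0 - maf, maf)
    dosage = 2.0 * (rng.random((n_individuals, n_markers)) < freq)
    ids = [f"{prefix}{i + 1:03d}" for i in range(n_individuals)]
    return GenotypeMatrix(ids, [f"M{j + 1:05d}" for j in range(n_markers)], chrom, pos, dosage)


def round_robin(parent_ids: list[str]) -> CrossingPlan:
    """Single round-robin plan: A x B, B x C, ..., last x first.

    Every parent appears in exactly two crosses; n parents give n crosses.
    """
    ids = list(parent_ids)
    if len(ids) < 3:
        raise ValueError("a round robin needs at least 3 parents")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate parent ids")
    crosses = [(ids[i], ids[(i + 1) % len(ids)]) for i in range(len(ids))]
    return CrossingPlan(crosses, kind="round_robin")


def cross(parent1: np.ndarray, parent2: np.ndarray) -> np.ndarray:
    """Exact F1 dosage of two fully inbred parents: (p1 + p2) / 2."""
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    if np.any(p1 == 1) or np.any(p2 == 1):
        raise ValueError("exact F1 requires fully inbred parents")
    return (p1 + p2) / 2.0


def cross_haplotypes(parent1: np.ndarray, parent2: np.ndarray) -> np.ndarray:
    """F1 haplotype pair (2 x m) from two inbred parental dosage rows."""
    return np.stack([np.asarray(parent1) / 2.0, np.asarray(parent2) / 2.0]).astype(float)


def meiosis(
    haplotypes: np.ndarray,
    chrom: np.ndarray,
    pos_cm: np.ndarray,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """One gamete from a phased individual under the Haldane model.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in Morgans; crossover positions are uniform. ``haplotypes`` is a
    (2, m) array; a 1-D dosage row is accepted for fully homozygous
    individuals, where phase is immaterial.
    """
    rng = np.random.default_rng(rng)
    hap = np.asarray(haplotypes, dtype=float)
    if hap.ndim == 1:
        if np.any(hap == 1):
            raise ValueError("unphased heterozygous input; supply a (2, m) haplotype pair")
        hap = np.stack([hap / 2.0, hap / 2.0])
    if hap.shape[1] != len(pos_cm) or len(chrom) != len(pos_cm):
        raise ValueError("map and genotype are not conformable")
    gamete = np.empty(hap.shape[1], dtype=float)
    for c in pd.unique(np.asarray(chrom)):
        idx = np.flatnonzero(np.asarray(chrom) == c)
        p = pos_cm[idx]
        length_m = (p.max() - p.min()) / 100.0 if len(p) > 1 else 0.0
        n_co = rng.poisson(length_m)
        breaks = np.sort(rng.uniform(p.min(), p.max(), size=n_co))
        phase0 = rng.integers(0, 2)
        phase = (phase0 + np.searchsorted(breaks, p, side="right")) % 2
        gamete[idx] = hap[:, idx][phase, np.arange(len(idx))]
    return gamete


def _self_once(
    hap: np.ndarray, chrom: np.ndarray, pos_cm: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    return np.stack([meiosis(hap, chrom, pos_cm, rng), meiosis(hap, chrom, pos_cm, rng)])


def self_ssd(
    haplotypes: np.ndarray,
    chrom: np.ndarray,
    pos_cm: np.ndarray,
    n_generations: int,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Single-seed descent: one selfed offspring per generation.

    Each generation draws two independent meioses from the current plant.
    Returns the final (2, m) haplotype pair; expected heterozygosity halves
    per generation.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(rng)
    hap = np.asarray(haplotypes, dtype=float)
    if hap.ndim == 1:
        if np.any(hap == 1):
            raise ValueError("unphased heterozygous input; supply a (2, m) haplotype pair")
        hap = np.stack([hap / 2.0, hap / 2.0])
    for _ in range(n_generations):
        hap = _self_once(hap, chrom, pos_cm, rng)
    return hap


def make_architecture(
    n_markers: int,
    n_qtl: int,
    var_additive: float = 1.0,
    dominance_ratio: float = 0.5,
    intercept: float = 90.0,
    seed: int | np.random.Generator = 0,
) -> TraitArchitecture:
    """Random sparse additive + dominance architecture.

    ``n_qtl`` markers receive normal additive effects scaled so the sum of
    squared effects equals ``var_additive``; dominance effects at the same
    loci are normal with standard deviation ``dominance_ratio`` times the
    additive scale (mean degree of dominance 0, spread ``dominance_ratio``).
    The default intercept of 90 trait units mirrors a winter-wheat grain
    yield level in dt/ha.
    """
    rng = np.random.default_rng(seed)
    a = np.zeros(n_markers)
    d = np.zeros(n_markers)
    qtl = rng.choice(n_markers, size=min(n_qtl, n_markers), replace=False)
    if len(qtl):
        raw = rng.normal(size=len(qtl))
        scale = np.sqrt(var_additive / np.sum(raw**2))
        a[qtl] = raw * scale
        d[qtl] = rng.normal(scale=dominance_ratio * scale, size=len(qtl))
    return TraitArchitecture(intercept=intercept, additive=a, dominance=d)


def genetic_value(dosage: np.ndarray, arch: TraitArchitecture) -> np.ndarray | float:
    """mu + sum a_m (x_m - 1) + sum d_m [x_m == 1], vectorized over rows."""
    x = np.asarray(dosage, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing dosages must be imputed before scoring")
    val = arch.intercept + (x - 1.0) @ arch.additive + (x == 1.0) @ arch.dominance
    return float(val) if np.ndim(dosage) == 1 else val


def simulate_phenotypes(
    individuals: pd.DataFrame,
    design: TrialDesign,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Long-format trial records for a set of genotyped entries.

    ``individuals`` needs columns ``genotype_id``, ``role``,
    ``female_parent``, ``male_parent`` and ``gvalue`` (total genetic value).
    Per record: genetic value + location-year effect + block-in-environment
    effect + iid genotype-by-environment deviation + residual. In stress
    locations the genotype's own value is replaced by a draw correlated only
    ``stress_rho`` with its value elsewhere, so rankings decorrelate there.
    """
    if not design.environments:
        raise ValueError("empty trial design")
    rng = np.random.default_rng(seed)
    g = individuals["gvalue"].to_numpy(dtype=float)
    n = len(g)
    mu = g.mean()
    sd = g.std(ddof=0)
    # independent stress regime, correlation stress_rho with the main values
    if sd > 0:
        z = (g - mu) / sd
        g_stress = mu + sd * (
            design.stress_rho * z
            + np.sqrt(1.0 - design.stress_rho**2) * rng.normal(size=n)
        )
    else:
        g_stress = g.copy()

    records = []
    for loc, yr in design.environments:
        env_eff = rng.normal(scale=np.sqrt(design.var_location))
        stressed = loc in design.stress_locations
        base = g_stress if stressed else g
        # one G x E deviation per genotype-environment cell, shared by blocks
        gxe = rng.normal(scale=np.sqrt(design.var_gxe), size=n)
        for b in range(1, design.n_blocks + 1):
            blk_eff = rng.normal(scale=np.sqrt(design.var_block))
            res = rng.normal(scale=np.sqrt(design.var_residual), size=n)
            y = base + env_eff + blk_eff + gxe + res
            records.append(
                pd.DataFrame(
                    {
                        "genotype_id": individuals["genotype_id"].to_numpy(),
                        "role": individuals["role"].to_numpy(),
                        "female_parent": individuals["female_parent"].to_numpy(),
                        "male_parent": individuals["male_parent"].to_numpy(),
                        "location": loc,
                        "year": yr,
                        "block": b,
                        "value": y,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)[PHENOTYPE_COLUMNS]


def simulate_env_profiles(
    design: TrialDesign,
    n_timepoints: int = 23,
    seed: int | np.random.Generator = 0,
    stress_depression: float = 0.45,
    noise_sd: float = 0.03,
) -> list[EnvironmentProfile]:
    """Seasonal EVI trajectories per location, depressed at stress sites.

    Non-stress locations share a sinusoidal green-up template (EVI ~0.2 in
    winter to ~0.7 at canopy closure) plus iid noise; stress locations sit
    on a lowered baseline with the seasonal amplitude multiplied by
    ``1 - stress_depression``, so they stay below the others throughout the
    season in expectation.
    Reference extremes for the VCI rescaling span the template range. A PAW
    series (% plant-available water) with the same stress structure is
    attached.
    """
    if len(design.locations) < 2:
        raise ValueError("need at least 2 locations")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints, dtype=float)
    season = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / n_timepoints))  # 0..1..0
    profiles = []
    for loc in design.locations:
        stressed = loc in design.stress_locations
        amp = 0.5 * (1.0 - (stress_depression if stressed else 0.0))
        base = 0.2 - (0.04 if stressed else 0.0)
        evi = base + amp * season + rng.normal(scale=noise_sd, size=n_timepoints)
        paw = (60.0 if not stressed else 25.0) + 15.0 * season + rng.normal(
            scale=3.0, size=n_timepoints
        )
        profiles.append(
            EnvironmentProfile(
                location_id=loc,
                dates=t,
                evi=evi,
                evi_min=0.15,
                evi_max=0.75,
                paw=paw,
            )
        )
    return profiles
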
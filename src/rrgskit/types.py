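"""Shared domain containers for the RRGS toolkit.

The central objects are a dosage-coded genotype matrix with a genetic map,
a marker-effect trait architecture (additive + dominance), crossing plans,
multi-environment trial designs, and per-location environmental profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitArchitecture",
    "CrossingPlan",
    "TrialDesign",
    "EnvironmentProfile",
    "PHENOTYPE_COLUMNS",
]

#: Column order of the long-format phenotype table used throughout.
PHENOTYPE_COLUMNS = [
    "genotype_id",
    "role",
    "female_parent",
    "male_parent",
    "location",
    "year",
    "block",
    "value",
]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers, dosage-coded {0, 1, 2}.

    Dosage counts copies of the reference allele; missing values are NaN.
    ``chrom`` and ``pos_cm`` carry the genetic map (centimorgan positions,
    non-decreasing within each chromosome).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos_cm: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.marker_ids):
            raise ValueError("dosage shape does not match id lists")
        if len(self.chrom) != m or len(self.pos_cm) != m:
            raise ValueError("map length does not match marker count")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")
        for c in np.unique(self.chrom):
            p = self.pos_cm[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"pos_cM not non-decreasing on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def row(self, individual_id: str) -> np.ndarray:
        return self.dosage[self.individual_ids.index(individual_id)]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker reference-allele frequency, ignoring missing calls."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def is_inbred(self) -> np.ndarray:
        """Boolean per individual: no heterozygous (dosage 1) calls."""
        with np.errstate(invalid="ignore"):
            return ~np.any(self.dosage == 1.0, axis=1)

    def subset(
        self,
        individuals: list[str] | None = None,
        marker_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ids = self.individual_ids if individuals is None else list(individuals)
        rows = [self.individual_ids.index(i) for i in ids]
        mask = (
            np.ones(self.n_markers, dtype=bool) if marker_mask is None else marker_mask
        )
        return GenotypeMatrix(
            individual_ids=ids,
            marker_ids=[m for m, k in zip(self.marker_ids, mask) if k],
            chrom=self.chrom[mask],
            pos_cm=self.pos_cm[mask],
            dosage=self.dosage[np.ix_(rows, mask)],
        )

    @staticmethod
    def vstack(parts: list["GenotypeMatrix"]) -> "GenotypeMatrix":
        first = parts[0]
        for p in parts[1:]:
            if p.marker_ids != first.marker_ids:
                raise ValueError("marker sets differ; cannot stack")
        return GenotypeMatrix(
            individual_ids=[i for p in parts for i in p.individual_ids],
            marker_ids=first.marker_ids,
            chrom=first.chrom,
            pos_cm=first.pos_cm,
            dosage=np.vstack([p.dosage for p in parts]),
        )


@dataclass
class TraitArchitecture:
    """Per-marker additive and dominance effects plus an intercept.

    Additive coding is heterozygote-centered (dosage - 1 in {-1, 0, 1});
    the dominance effect applies to heterozygotes only, so the degree of
    dominance at a locus is k = d/a (defined where a != 0).
    """

    intercept: float
    additive: np.ndarray
    dominance: np.ndarray

    def __post_init__(self) -> None:
        self.additive = np.asarray(self.additive, dtype=float)
        self.dominance = np.asarray(self.dominance, dtype=float)
        if self.additive.shape != self.dominance.shape:
            raise ValueError("additive and dominance effect vectors differ in length")

    @property
    def n_markers(self) -> int:
        return self.additive.size

    def degree_of_dominance(self) -> np.ndarray:
        """k = d/a per marker; NaN where the additive effect is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            k = self.dominance / self.additive
        k[self.additive == 0] = np.nan
        return k


@dataclass
class CrossingPlan:
    """Ordered list of (female_id, male_id) crosses with a kind tag."""

    crosses: list[tuple[str, str]]
    kind: str = "custom"  # round_robin | factorial | custom

    def parents(self) -> list[str]:
        seen: dict[str, None] = {}
        for f, m in self.crosses:
            seen.setdefault(f)
            seen.setdefault(m)
        return list(seen)

    def __len__(self) -> int:
        return len(self.crosses)


@dataclass
class TrialDesign:
    """Multi-environment trial layout and variance regime.

    An environment is a location x year cell. ``stress_locations`` receive
    genotype effects only weakly correlated (``stress_rho``) with the
    genotype effects expressed elsewhere, emulating a drought outgroup.
    Variances are in squared trait units.
    """

    locations: list[str]
    years: list[int] = field(default_factory=lambda: [2019])
    n_blocks: int = 2
    var_location: float = 4.0
    var_block: float = 1.0
    var_gxe: float = 2.0
    var_residual: float = 5.7
    stress_locations: list[str] = field(default_factory=list)
    stress_rho: float = 0.1

    def __post_init__(self) -> None:
        for name in ("var_location", "var_block", "var_gxe", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not set(self.stress_locations) <= set(self.locations):
            raise ValueError("stress_locations must be a subset of locations")

    @property
    def environments(self) -> list[tuple[str, int]]:
        return [(loc, yr) for yr in self.years for loc in self.locations]


@dataclass
class EnvironmentProfile:
    """EVI (and optional plant-available-water) time series for a location.

    ``evi_min`` / ``evi_max`` are the reference-period extremes used to
    rescale EVI to the vegetation condition index; observed EVI may exceed
    them, the VCI output is clamped to [0, 1] instead.
    """

    location_id: str
    dates: np.ndarray  # day-of-season integers or datetime64
    evi: np.ndarray
    evi_min: float
    evi_max: float
    paw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates)
        self.evi = np.asarray(self.evi, dtype=float)
        if self.evi.shape != self.dates.shape:
            raise ValueError("dates and evi series differ in length")
        if np.any(np.diff(self.dates.astype(float)) <= 0):
            raise ValueError("dates must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"location": self.location_id, "date": self.dates, "evi": self.evi}
        )
        out["paw"] = self.paw if self.paw is not None else np.nan
        return out
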
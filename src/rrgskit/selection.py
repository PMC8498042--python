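"""Response-to-selection calculus for the two-step genomic selection scheme.

Covers the standardized selection differential from the truncated standard
normal, the finite-population selection intensity

    i(N, G) = i(alpha) - (G - N) / (2 N (G + 1) i(alpha)),

the generation-specific deflation of the usable GCA standard deviation (a
factor 1/2 on the variance when selecting within an F2 family, and a
further 7/8 = 1/2 + 1/4 + 1/8 when selecting among F5-derived descendants
of one F2 plant), expected response R_exp = sum_steps i * h * sigma_A,
the observed response R_obs = mu_sel - mu_pop, and the minimum favourable
allele frequency required for its fixation under negative overdominance.

i(alpha) is computed from the closed-form truncated-normal mean phi(z)/p
rather than printed tables; values derived from tables may differ by ~0.01
in the second decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SelectionStep",
    "ResponseReport",
    "std_sel_differential",
    "selection_intensity",
    "gca_sd_f2",
    "gca_sd_f56",
    "mean_accuracy",
    "expected_response",
    "observed_response",
    "fixation_threshold",
]


def std_sel_differential(p: float) -> float:
    """Standardized selection differential i(alpha) = phi(z)/p, z = Phi^-1(1-p).

    The expected mean, in phenotypic standard deviations, of the selected
    upper fraction ``p`` of an infinite standard-normal population.
    """
    if not 0 < p < 1:
        raise ValueError("selected proportion must lie in (0, 1)")
    z = norm.ppf(1.0 - p)
    return float(norm.pdf(z) / p)


def selection_intensity(N: int, G: int) -> float:
    """Finite-population selection intensity i(N, G).

    Applies the correction (G - N) / (2 N (G + 1) i(alpha)) to the
    infinite-population differential at p = N/G. i(G, G) is 0 by convention
    (no selection).
    """
    if N <= 0 or G <= 0:
        raise ValueError("N and G must be positive")
    if N > G:
        raise ValueError("cannot select more genotypes than available")
    if N == G:
        return 0.0
    i_alpha = std_sel_differential(N / G)
    return i_alpha - (G - N) / (2.0 * N * (G + 1) * i_alpha)


def gca_sd_f2(var_gca: float) -> float:
    """Usable GCA standard deviation when selecting within F2 families.

    Half of the base-population GCA variance segregates within a biparental
    F2 family, so sigma_GCA,F2 = sqrt(var_gca / 2).
    """
    if var_gca < 0:
        raise ValueError("variance must be >= 0")
    return float(np.sqrt(var_gca / 2.0))


def gca_sd_f56(sd_gca_f2: float) -> float:
    """Usable GCA standard deviation among F5:6 descendants of one F2 plant.

    Selfing from F2 to F5 releases 1/2 + 1/4 + 1/8 = 7/8 of the F2-stage
    variance among descendant lines: sigma_GCA,F5:6 = sqrt(7/8) * sigma_GCA,F2.
    """
    if sd_gca_f2 < 0:
        raise ValueError("standard deviation must be >= 0")
    return float(np.sqrt(7.0 / 8.0 * sd_gca_f2**2))


def mean_accuracy(abilities: list[float]) -> float:
    """Selection accuracy h as the plain mean of prediction abilities."""
    return float(np.mean(abilities))


@dataclass
class SelectionStep:
    """One truncation-selection step: N selected out of G candidates.

    ``h`` is the selection accuracy (square root of heritability, or a
    prediction ability used in its place) and ``sigma_a`` the standard
    deviation of the breeding values exploitable at this step, in trait
    units. ``intensity`` overrides the computed i(N, G) when a tabulated
    value is preferred.
    """

    N: int
    G: int
    h: float
    sigma_a: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.N <= self.G:
            raise ValueError("require 0 < N <= G")
        if self.sigma_a < 0:
            raise ValueError("sigma_a must be >= 0")
        if not 0 <= self.h <= 1:
            raise ValueError("accuracy h must lie in [0, 1]")

    @property
    def i(self) -> float:
        return self.intensity if self.intensity is not None else selection_intensity(self.N, self.G)

    @property
    def response(self) -> float:
        return self.i * self.h * self.sigma_a


@dataclass
class ResponseReport:
    """Per-step intensities and responses plus totals."""

    intensities: list[float]
    step_responses: list[float]
    total_expected: float
    observed: float | None = None

    def to_dict(self) -> dict:
        return {
            "intensities": self.intensities,
            "step_responses": self.step_responses,
            "total_expected": self.total_expected,
            "observed": self.observed,
        }


def expected_response(steps: list[SelectionStep]) -> ResponseReport:
    """Total expected response: sum over steps of i(N, G) * h * sigma_A."""
    if not steps:
        raise ValueError("need at least one selection step")
    intensities = [s.i for s in steps]
    responses = [s.response for s in steps]
    return ResponseReport(
        intensities=intensities,
        step_responses=responses,
        total_expected=float(sum(responses)),
    )


def observed_response(mu_sel: float, mu_pop: float) -> float:
    """Observed response R_obs = mu_sel - mu_pop (the realized differential)."""
    return float(mu_sel) - float(mu_pop)


def fixation_threshold(k: float) -> float:
    """Minimum favourable-allele frequency for fixation under k < -1.

    With negative overdominance (degree of dominance k < -1), selection
    drives the favourable allele to fixation only when its frequency already
    exceeds (k + 1) / (2 k); below that the heterozygote advantage of the
    other allele wins.
    """
    if k >= -1:
        raise ValueError("threshold applies only for negative overdominance (k < -1)")
    return (k + 1.0) / (2.0 * k)
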
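"""Phenotypic analysis of multi-environment hybrid trials.

Best linear unbiased estimates of genotype means across environments
(fixed genotype, random location and block), robust outlier control on the
standardized residuals with a Bonferroni-Holm test (the "M4r" rule),
combining-ability variance decomposition with role-specific genetic terms
(lines vs hybrids vs checks sharing one model through dummy coding),
heritability on an entry-mean basis, and midparent / better-parent
heterosis.

An environment is a location x year combination throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .lmm import MixedModel, MixedModelFit

__all__ = [
    "VarianceComponents",
    "HeterosisResult",
    "environment_labels",
    "compute_blues",
    "detect_outliers_m4r",
    "fit_variance_components",
    "heritability",
    "gxe_ratio",
    "heterosis",
]


def environment_labels(table: pd.DataFrame) -> pd.Series:
    """Location x year cell labels, e.g. ``ADE_2019``."""
    return table["location"].astype(str) + "_" + table["year"].astype(str)


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    cats = pd.Categorical(labels)
    Z = np.zeros((len(labels), len(cats.categories)))
    codes = np.asarray(cats.codes)
    valid = codes >= 0
    Z[np.flatnonzero(valid), codes[valid]] = 1.0
    return Z, list(map(str, cats.categories))


def compute_blues(
    table: pd.DataFrame,
    varcomp: dict[str, float] | str = "reml",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.Series, MixedModelFit]:
    """Per-genotype BLUEs across environments.

    Model: y = genotype (fixed) + environment + block-in-environment
    (random) + residual. On balanced data with homogeneous variance the
    BLUEs equal arithmetic genotype means. ``varcomp`` may fix
    {"environment", "block", "residual"}.

    Returns the BLUE series (indexed by genotype id) and the full fit,
    whose residuals feed the outlier test.
    """
    env = environment_labels(table)
    Xg, genos = _indicator(table["genotype_id"])
    Ze, envs = _indicator(env)
    Zb, blocks = _indicator(env + "_b" + table["block"].astype(str))
    model = MixedModel(
        y=table["value"].to_numpy(dtype=float),
        X=Xg,
        fixed_names=genos,
        random_terms={"environment": (Ze, envs), "block": (Zb, blocks)},
    )
    fit = model.fit(varcomp=varcomp, tol=tol, max_iter=max_iter)
    return pd.Series(fit.beta, index=genos, name="blue"), fit


def detect_outliers_m4r(
    table: pd.DataFrame,
    residuals: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Robust residual outlier flags (median/MAD + Bonferroni-Holm).

    Residuals are re-scaled by their median and the scaled median absolute
    deviation; two-sided standard-normal p-values are corrected with the
    Holm step-down procedure at family-wise level ``alpha``. Returns the
    flagged records with their standardized residuals. Constant residuals
    (MAD = 0) yield no flags.
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) != len(table):
        raise ValueError("residuals do not align with the table")
    med = np.median(r)
    mad = np.median(np.abs(r - med)) * 1.4826
    out = table.copy()
    if mad == 0:
        out["std_resid"] = 0.0
        out["flagged"] = False
        return out[out["flagged"]]
    z = (r - med) / mad
    pvals = 2.0 * norm.sf(np.abs(z))
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    out["std_resid"] = z
    out["p_value"] = pvals
    out["flagged"] = reject
    return out[out["flagged"]]


@dataclass
class VarianceComponents:
    """All variance components of the combining-ability model.

    ``var_lines`` collects the genetic variance among inbred entries
    (parents and, unless excluded, checks); hybrid genetic variance is
    decomposed into female GCA, male GCA and SCA. ``l_lines`` / ``l_hybrids``
    are the average numbers of environments in which the respective entries
    were observed, the divisor of the entry-mean heritability.
    """

    var_lines: float
    var_lines_x_env: float
    var_gca_female: float
    var_gca_female_x_env: float
    var_gca_male: float
    var_gca_male_x_env: float
    var_sca: float
    var_sca_x_env: float
    var_residual: float
    l_lines: float
    l_hybrids: float

    @property
    def var_hybrids(self) -> float:
        return self.var_gca_female + self.var_gca_male + self.var_sca

    @property
    def var_hybrids_x_env(self) -> float:
        return (
            self.var_gca_female_x_env + self.var_gca_male_x_env + self.var_sca_x_env
        )

    def h2_lines(self) -> float:
        return heritability(
            self.var_lines, self.var_lines_x_env, self.var_residual, self.l_lines
        )

    def h2_hybrids(self) -> float:
        return heritability(
            self.var_hybrids, self.var_hybrids_x_env, self.var_residual, self.l_hybrids
        )

    def to_dict(self) -> dict[str, float]:
        return {
            "var_lines": self.var_lines,
            "var_lines_x_env": self.var_lines_x_env,
            "var_gca_female": self.var_gca_female,
            "var_gca_female_x_env": self.var_gca_female_x_env,
            "var_gca_male": self.var_gca_male,
            "var_gca_male_x_env": self.var_gca_male_x_env,
            "var_sca": self.var_sca,
            "var_sca_x_env": self.var_sca_x_env,
            "var_hybrids": self.var_hybrids,
            "var_hybrids_x_env": self.var_hybrids_x_env,
            "var_residual": self.var_residual,
            "h2_lines": self.h2_lines(),
            "h2_hybrids": self.h2_hybrids(),
        }


def _masked_indicator(
    labels: pd.Series, mask: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Indicator columns for ``labels`` with rows outside ``mask`` zeroed."""
    lab = labels.where(mask, other=pd.NA)
    cats = pd.Categorical(lab)
    Z = np.zeros((len(labels), len(cats.categories)))
    codes = np.asarray(cats.codes)
    valid = codes >= 0
    Z[np.flatnonzero(valid), codes[valid]] = 1.0
    return Z, list(map(str, cats.categories))


def fit_variance_components(
    table: pd.DataFrame,
    exclude_checks: bool = False,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[VarianceComponents, MixedModelFit]:
    """GCA/SCA variance decomposition of a lines + hybrids trial.

    Fixed: intercept and role dummies (check / line / hybrid). Random:
    environment, block-in-environment, line effect (inbred entries), female
    GCA, male GCA, SCA, and the environment interactions of line, female GCA
    and male GCA. Estimation by EM-REML; negative estimates are floored at
    zero by construction of EM. The BLUPs of the female-GCA-by-environment
    term feed the G x E diagnostics.
    """
    roles = table["role"]
    if not {"line", "hybrid"} <= set(roles.unique()):
        raise ValueError("table must contain both lines and hybrids")
    env = environment_labels(table)
    is_hybrid = (roles == "hybrid").to_numpy()
    line_roles = {"line"} if exclude_checks else {"line", "check"}
    is_line = roles.isin(line_roles).to_numpy()

    X = np.column_stack(
        [np.ones(len(table))]
        + [
            (roles == r).to_numpy(dtype=float)
            for r in sorted(roles.unique())[1:]  # drop-first dummy coding
        ]
    )
    fixed_names = ["intercept"] + [f"role_{r}" for r in sorted(roles.unique())[1:]]

    terms: dict[str, tuple[np.ndarray, list[str]]] = {}
    terms["environment"] = _indicator(env)
    terms["block"] = _indicator(env + "_b" + table["block"].astype(str))
    terms["line"] = _masked_indicator(table["genotype_id"], is_line)
    terms["gca_female"] = _masked_indicator(table["female_parent"], is_hybrid)
    terms["gca_male"] = _masked_indicator(table["male_parent"], is_hybrid)
    terms["sca"] = _masked_indicator(
        table["female_parent"].astype(str) + "_x_" + table["male_parent"].astype(str),
        is_hybrid,
    )
    terms["line_x_env"] = _masked_indicator(
        table["genotype_id"].astype(str) + "@" + env, is_line
    )
    terms["gca_female_x_env"] = _masked_indicator(
        table["female_parent"].astype(str) + "@" + env, is_hybrid
    )
    terms["gca_male_x_env"] = _masked_indicator(
        table["male_parent"].astype(str) + "@" + env, is_hybrid
    )
    # SCA x environment is separable from the residual only with replicated
    # blocks within environments; with a single block it is confounded.
    terms["sca_x_env"] = _masked_indicator(
        table["female_parent"].astype(str)
        + "_x_"
        + table["male_parent"].astype(str)
        + "@"
        + env,
        is_hybrid,
    )

    model = MixedModel(
        y=table["value"].to_numpy(dtype=float),
        X=X,
        fixed_names=fixed_names,
        random_terms=terms,
    )
    fit = model.fit(varcomp="reml", tol=tol, max_iter=max_iter)
    if not fit.converged:
        raise RuntimeError(f"EM-REML did not converge in {max_iter} iterations")

    n_env_line = (
        table[is_line].groupby("genotype_id").apply(lambda d: environment_labels(d).nunique(), include_groups=False)
        if is_line.any()
        else pd.Series(dtype=float)
    )
    n_env_hyb = (
        table[is_hybrid].groupby("genotype_id").apply(lambda d: environment_labels(d).nunique(), include_groups=False)
        if is_hybrid.any()
        else pd.Series(dtype=float)
    )
    vc = VarianceComponents(
        var_lines=fit.varcomp["line"],
        var_lines_x_env=fit.varcomp["line_x_env"],
        var_gca_female=fit.varcomp["gca_female"],
        var_gca_female_x_env=fit.varcomp["gca_female_x_env"],
        var_gca_male=fit.varcomp["gca_male"],
        var_gca_male_x_env=fit.varcomp["gca_male_x_env"],
        var_sca=fit.varcomp["sca"],
        var_sca_x_env=fit.varcomp["sca_x_env"],
        var_residual=fit.varcomp["residual"],
        l_lines=float(n_env_line.mean()) if len(n_env_line) else float("nan"),
        l_hybrids=float(n_env_hyb.mean()) if len(n_env_hyb) else float("nan"),
    )
    return vc, fit


def heritability(var_g: float, var_gxe: float, var_e: float, l: float) -> float:
    """Entry-mean heritability h2 = var_G / (var_G + (var_GxE + var_e) / l).

    ``l`` is the average number of environments per genotype.
    """
    if min(var_g, var_gxe, var_e) < 0:
        raise ValueError("variance components must be >= 0")
    if l <= 0:
        raise ValueError("l must be positive")
    if var_g == 0:
        return 0.0
    return var_g / (var_g + (var_gxe + var_e) / l)


def gxe_ratio(var_gxe: float, var_g: float) -> float:
    """Plain quotient var_GxE / var_G."""
    if var_g <= 0:
        raise ValueError("genetic variance must be positive")
    return var_gxe / var_g


@dataclass
class HeterosisResult:
    """Midparent and better-parent heterosis of one hybrid, in percent."""

    hybrid_id: str
    mph: float
    bph: float


def heterosis(
    hybrid_mean: float,
    parent1_mean: float,
    parent2_mean: float,
    hybrid_id: str = "",
) -> HeterosisResult:
    """MPH = 100 (F1 - MP) / MP and BPH = 100 (F1 - BP) / BP.

    MP is the midparent, BP the better parent. Undefined (raises) when the
    midparent or better parent is not positive, as for yield data the
    percentages lose meaning there.
    """
    mp = (parent1_mean + parent2_mean) / 2.0
    bp = max(parent1_mean, parent2_mean)
    if mp <= 0 or bp <= 0:
        raise ValueError("midparent and better parent must be positive")
    return HeterosisResult(
        hybrid_id=hybrid_id,
        mph=100.0 * (hybrid_mean - mp) / mp,
        bph=100.0 * (hybrid_mean - bp) / bp,
    )
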
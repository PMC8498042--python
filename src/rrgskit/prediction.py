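"""Genomic prediction of line and hybrid performance.

Implements the VanRaden genomic relationship matrix, ridge-regression BLUP
with separate additive and dominance effect classes (the hybrid-prediction
model), its kernel-space equivalent GBLUP, and GCA prediction of selection
candidates against a tester panel.

Variance components are estimated by EM-REML on the kernel representation

    V = sum_i sigma2_i K_i + sigma2_e I,

with the GCTA-style updates sigma2_i <- sigma2_i + sigma2_i^2 (y'P K_i P y
- tr(P K_i)) / n, which converge monotonically to the REML optimum. Marker
effects are recovered from the kernel solution as a_hat = sigma2_a Z_A' P y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import CrossingPlan, GenotypeMatrix

__all__ = [
    "GRM",
    "PredictionModel",
    "vanraden_grm",
    "hybrid_design_matrices",
    "candidate_design_rows",
    "fit_rrblup_ad",
    "fit_gblup",
    "predict_hybrid",
    "predict_gca",
    "mean_impute",
]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with individual ids."""

    individual_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


@dataclass
class PredictionModel:
    """Fitted additive + dominance ridge-BLUP model.

    Stores the intercept, per-marker effects, the variance components used
    for shrinkage, and the coding convention (additive = dosage - 1,
    dominance = heterozygosity indicator / expected heterozygosity).
    """

    intercept: float
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    var_additive: float
    var_dominance: float
    var_residual: float
    marker_ids: list[str] = field(default_factory=list)
    coding: str = "additive: dosage-1; dominance: heterozygosity"
    converged: bool = True
    n_iter: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "additive_effects": list(map(float, self.additive_effects)),
            "dominance_effects": list(map(float, self.dominance_effects)),
            "var_additive": self.var_additive,
            "var_dominance": self.var_dominance,
            "var_residual": self.var_residual,
            "marker_ids": self.marker_ids,
            "coding": self.coding,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            intercept=d["intercept"],
            additive_effects=np.asarray(d["additive_effects"]),
            dominance_effects=np.asarray(d["dominance_effects"]),
            var_additive=d["var_additive"],
            var_dominance=d["var_dominance"],
            var_residual=d["var_residual"],
            marker_ids=d.get("marker_ids", []),
            coding=d.get("coding", ""),
        )


def mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-marker mean."""
    x = np.array(dosage, dtype=float)
    means = np.nanmean(x, axis=0)
    nan = np.isnan(x)
    x[nan] = np.take(means, np.where(nan)[1])
    return x


def vanraden_grm(genotypes: GenotypeMatrix) -> GRM:
    """G = W W' / (2 sum p_m (1 - p_m)) with W the frequency-centered dosages.

    Allele frequencies are computed from the supplied panel itself.
    Monomorphic markers contribute zero to both numerator and denominator.
    """
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    x = genotypes.dosage
    if np.isnan(x).any():
        raise ValueError("impute missing dosages before building a GRM")
    p = x.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        raise ValueError("all markers are monomorphic")
    w = x - 2.0 * p
    return GRM(list(genotypes.individual_ids), (w @ w.T) / denom)


def _lookup(genotypes: GenotypeMatrix, ids: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(genotypes.individual_ids)}
    try:
        rows = [index[i] for i in ids]
    except KeyError as err:
        raise KeyError(f"id {err.args[0]!r} not present in genotype matrix") from None
    return genotypes.dosage[rows]


def candidate_design_rows(
    candidate_dosage: np.ndarray, tester_dosage: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Expected additive / dominance design rows for one cross.

    For an inbred tester the expected hybrid has centered additive dosage
    (x_c + x_t)/2 - 1 and per-locus heterozygosity probability |x_t - x_c|/2,
    which reduces to the exact F1 rows when the candidate is inbred and to
    the gametic expectation (0, 1/2 or 1) for a heterozygous F2 candidate.
    """
    xc = np.asarray(candidate_dosage, dtype=float)
    xt = np.asarray(tester_dosage, dtype=float)
    if np.any(xt == 1):
        raise ValueError("testers must be fully inbred")
    z_a = (xc + xt) / 2.0 - 1.0
    z_d = np.abs(xt - xc) / 2.0
    return z_a, z_d


def hybrid_design_matrices(
    female_genotypes: GenotypeMatrix,
    male_genotypes: GenotypeMatrix,
    plan: CrossingPlan,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (Z_A, Z_D) rows for every cross in the plan."""
    za_rows, zd_rows = [], []
    for f, m in plan.crosses:
        xf = _lookup(female_genotypes, [f])[0]
        xm = _lookup(male_genotypes, [m])[0]
        za, zd = candidate_design_rows(xf, xm)
        za_rows.append(za)
        zd_rows.append(zd)
    return np.vstack(za_rows), np.vstack(zd_rows)


def _kernel_em_reml(
    y: np.ndarray,
    kernels: list[np.ndarray],
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[list[float], float, np.ndarray, bool, int]:
    """EM-REML for V = sum sigma2_i K_i + sigma2_e I with fixed intercept.

    Returns (variances, residual variance, P matrix, converged, iterations).
    """
    n = len(y)
    X = np.ones((n, 1))
    var_y = y.var(ddof=1)
    if var_y == 0:
        raise ValueError("zero phenotypic variance; REML is undefined")
    k = len(kernels)
    # spread the phenotypic variance over components, scaled by kernel size
    sig = [var_y / (k + 1) / max(np.mean(np.diag(K)), 1e-12) for K in kernels]
    sig_e = var_y / (k + 1)
    floor = 1e-10 * var_y

    def compute_P(sig, sig_e):
        V = sig_e * np.eye(n)
        for s, K in zip(sig, kernels):
            V += s * K
        Vinv = np.linalg.inv(V)
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
        sign, logdet_v = np.linalg.slogdet(V)
        _, logdet_x = np.linalg.slogdet(X.T @ VX)
        ll = -0.5 * (logdet_v + logdet_x + y @ P @ y)
        return P, ll

    P, ll = compute_P(sig, sig_e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Py = P @ y
        new_sig = []
        for s, K in zip(sig, kernels):
            # tr(P K) via the elementwise product; both matrices symmetric
            grad = Py @ K @ Py - float(np.sum(P * K))
            new_sig.append(max(s + s * s * grad / n, floor))
        grad_e = Py @ Py - np.trace(P)
        new_e = max(sig_e + sig_e * sig_e * grad_e / n, floor)
        P, new_ll = compute_P(new_sig, new_e)
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        sig, sig_e, ll = new_sig, new_e, new_ll
        if rel < tol:
            converged = True
            break
    return sig, sig_e, P, converged, it


def _gls_intercept(y: np.ndarray, sig: list[float], sig_e: float, kernels) -> float:
    n = len(y)
    V = sig_e * np.eye(n)
    for s, K in zip(sig, kernels):
        V += s * K
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    return float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))


def fit_rrblup_ad(
    y: np.ndarray,
    z_a: np.ndarray,
    z_d: np.ndarray,
    varcomp: tuple[float, float, float] | str = "reml",
    marker_ids: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PredictionModel:
    """Ridge-BLUP with additive and dominance marker-effect classes.

    ``varcomp`` is (sigma2_a, sigma2_d, sigma2_e) or "reml". The fit is
    performed in kernel space (K_A = Z_A Z_A', K_D = Z_D Z_D') and marker
    effects recovered by back-transformation, which is exactly equivalent to
    solving the marker-level ridge equations with lambda_a = sigma2_e /
    sigma2_a and lambda_d = sigma2_e / sigma2_d.
    """
    y = np.asarray(y, dtype=float)
    z_a = np.asarray(z_a, dtype=float)
    z_d = np.asarray(z_d, dtype=float)
    if y.shape[0] != z_a.shape[0] or z_a.shape != z_d.shape:
        raise ValueError("phenotypes and design matrices are not conformable")
    n = len(y)
    ka = z_a @ z_a.T
    kd = z_d @ z_d.T
    converged, it = True, 0
    if varcomp == "reml":
        if len(np.unique(y)) < 2:
            raise ValueError("need >= 2 distinct phenotype values for REML")
        (sa, sd), se, P, converged, it = _kernel_em_reml(
            y, [ka, kd], tol=tol, max_iter=max_iter
        )
        if not converged:
            raise RuntimeError(f"EM-REML did not converge in {max_iter} iterations")
    else:
        sa, sd, se = map(float, varcomp)
        V = sa * ka + sd * kd + se * np.eye(n)
        Vinv = np.linalg.inv(V)
        X = np.ones((n, 1))
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
    mu = _gls_intercept(y, [sa, sd], se, [ka, kd])
    Py = P @ y
    a_hat = sa * z_a.T @ Py
    d_hat = sd * z_d.T @ Py
    return PredictionModel(
        intercept=mu,
        additive_effects=a_hat,
        dominance_effects=d_hat,
        var_additive=sa,
        var_dominance=sd,
        var_residual=se,
        marker_ids=marker_ids or [],
        converged=converged,
        n_iter=it,
    )


def fit_gblup(
    y: np.ndarray,
    grm: GRM,
    varcomp: tuple[float, float] | str = "reml",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[float, np.ndarray]:
    """GBLUP of genetic values: y = 1 mu + g + e, g ~ N(0, G sigma2_g).

    Returns (mu_hat, g_hat aligned with the GRM ids). ``varcomp`` is
    (sigma2_g, sigma2_e) or "reml". A diagonal jitter of 1e-8 is added if
    the covariance matrix is numerically singular.
    """
    y = np.asarray(y, dtype=float)
    K = grm.values
    n = len(y)
    if n != K.shape[0]:
        raise ValueError("phenotype length does not match GRM")
    try:
        np.linalg.cholesky(K + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError:
        K = K + 1e-8 * np.eye(n)
    if varcomp == "reml":
        (sg,), se, P, converged, _ = _kernel_em_reml(y, [K], tol=tol, max_iter=max_iter)
        if not converged:
            raise RuntimeError(f"EM-REML did not converge in {max_iter} iterations")
    else:
        sg, se = map(float, varcomp)
        V = sg * K + se * np.eye(n)
        Vinv = np.linalg.inv(V)
        X = np.ones((n, 1))
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
    mu = _gls_intercept(y, [sg], se, [K])
    g_hat = sg * K @ (P @ y)
    return mu, g_hat


def predict_hybrid(
    model: PredictionModel,
    female_id: str,
    male_id: str,
    genotypes: GenotypeMatrix,
) -> float:
    """mu_hat + z_A' a_hat + z_D' d_hat for the expected hybrid."""
    if model.marker_ids and model.marker_ids != genotypes.marker_ids:
        raise ValueError("marker set of model and genotype source differ")
    xf = _lookup(genotypes, [female_id])[0]
    xm = _lookup(genotypes, [male_id])[0]
    za, zd = candidate_design_rows(xf, xm)
    return float(
        model.intercept + za @ model.additive_effects + zd @ model.dominance_effects
    )


def expected_hybrid_matrix(
    candidate_dosage: np.ndarray,
    tester_dosage: np.ndarray,
    intercept: float,
    additive: np.ndarray,
    dominance: np.ndarray,
) -> np.ndarray:
    """Expected hybrid values for every candidate x tester pair.

    Vectorized form of :func:`candidate_design_rows` followed by the linear
    predictor; rows are candidates, columns testers. Works both with fitted
    marker effects and with a true simulated architecture.
    """
    Xc = np.atleast_2d(np.asarray(candidate_dosage, dtype=float))
    Xt = np.atleast_2d(np.asarray(tester_dosage, dtype=float))
    if np.any(Xt == 1):
        raise ValueError("testers must be fully inbred")
    out = np.empty((Xc.shape[0], Xt.shape[0]))
    for j, xt in enumerate(Xt):
        za = (Xc + xt) / 2.0 - 1.0
        zd = np.abs(xt - Xc) / 2.0
        out[:, j] = intercept + za @ additive + zd @ dominance
    return out


def predict_gca(
    model: PredictionModel,
    candidate_ids: list[str],
    tester_ids: list[str],
    genotypes: GenotypeMatrix,
) -> dict[str, float]:
    """Predicted GCA per candidate against a tester panel.

    GCA(c) = mean over testers of the predicted hybrid value minus the grand
    mean over all candidate x tester combinations.
    """
    if not tester_ids:
        raise ValueError("empty tester panel")
    preds = np.array(
        [
            [predict_hybrid(model, c, t, genotypes) for t in tester_ids]
            for c in candidate_ids
        ]
    )
    gca = preds.mean(axis=1) - preds.mean()
    return dict(zip(candidate_ids, map(float, gca)))
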
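"""Cross-validation machinery for genomic prediction.

Repeated k-fold cross-validation of line (GBLUP) and hybrid (additive +
dominance ridge-BLUP) models, and the chessboard scheme for hybrids, in
which the female and male parents are partitioned separately so that test
hybrids share both (T2), one (T1) or no (T0) parental lines with their
training set. Prediction ability is the Pearson correlation between
observed and predicted values; genomic repeatability is the mean ability
over all repeats and folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .prediction import fit_rrblup_ad, vanraden_grm
from .types import GenotypeMatrix

__all__ = ["CVResult", "prediction_ability", "kfold_cv", "chessboard_cv"]


@dataclass
class CVResult:
    """Per-repeat, per-fold prediction abilities and their grand mean."""

    scheme: str
    abilities: pd.DataFrame  # columns: repeat, fold, class, ability

    @property
    def mean_ability(self) -> float:
        return float(self.abilities["ability"].mean())

    def by_class(self) -> pd.Series:
        return self.abilities.groupby("class")["ability"].mean()

    def to_csv(self, path) -> None:
        self.abilities.assign(scheme=self.scheme).to_csv(path, index=False)


def prediction_ability(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if obs.std(ddof=1) == 0 or pred.std(ddof=1) == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(obs, pred)[0, 1])


def _safe_ability(obs: np.ndarray, pred: np.ndarray) -> float:
    if len(obs) < 3 or np.std(obs) == 0 or np.std(pred) == 0:
        return np.nan
    return float(np.corrcoef(obs, pred)[0, 1])


def _gblup_predict(
    grm_values: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    varcomp: tuple[float, float] | str,
) -> np.ndarray:
    """Train GBLUP on ``train`` rows, predict ``test`` rows off the same GRM."""
    K_tr = grm_values[np.ix_(train, train)]
    y_tr = y[train]
    from .prediction import _gls_intercept, _kernel_em_reml  # private API

    n = len(train)
    if varcomp == "reml":
        (sg,), se, P, converged, _ = _kernel_em_reml(y_tr, [K_tr])
        if not converged:
            raise RuntimeError("EM-REML did not converge in cross-validation fold")
    else:
        sg, se = map(float, varcomp)
        V = sg * K_tr + se * np.eye(n)
        Vinv = np.linalg.inv(V)
        X = np.ones((n, 1))
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
    mu = _gls_intercept(y_tr, [sg], se, [K_tr])
    return mu + sg * grm_values[np.ix_(test, train)] @ (P @ y_tr)


def kfold_cv(
    phenotypes: pd.Series,
    genotypes: GenotypeMatrix | tuple[np.ndarray, np.ndarray],
    model: str = "gblup",
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    varcomp: tuple | str = "reml",
) -> CVResult:
    """Repeated k-fold cross-validation.

    ``model`` is "gblup" (lines; ``genotypes`` is a GenotypeMatrix aligned
    with the phenotype index) or "rrblup_ad" (hybrids; ``genotypes`` is the
    (Z_A, Z_D) design pair). Each repeat uses a fresh seeded partition with
    fold sizes differing by at most one. A fold whose observed values have
    zero variance yields a missing ability, excluded from the mean with a
    warning. With k equal to the sample size (leave-one-out), abilities are
    computed by pooling the held-out predictions of each repeat.
    """
    y = phenotypes.to_numpy(dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError("need n >= k >= 2")
    if model == "gblup":
        if list(phenotypes.index) != list(genotypes.individual_ids):
            raise ValueError("phenotype index must match genotype ids")
        features = vanraden_grm(genotypes).values
    elif model == "rrblup_ad":
        features = genotypes
        if features[0].shape[0] != n:
            raise ValueError("design rows do not match phenotypes")
    else:
        raise ValueError(f"unknown model {model!r}")

    rows = []
    loo = k == n
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed * 10_000 + rep)
        pooled_obs, pooled_pred = [], []
        for fold, (train, test) in enumerate(kf.split(np.arange(n))):
            if model == "gblup":
                pred = _gblup_predict(features, y, train, test, varcomp)
            else:
                za, zd = features
                m = fit_rrblup_ad(y[train], za[train], zd[train], varcomp=varcomp)
                pred = (
                    m.intercept
                    + za[test] @ m.additive_effects
                    + zd[test] @ m.dominance_effects
                )
            if loo:
                pooled_obs.extend(y[test])
                pooled_pred.extend(pred)
                continue
            ability = _safe_ability(y[test], pred)
            if np.isnan(ability):
                warnings.warn(
                    f"repeat {rep} fold {fold}: ability undefined, recorded missing"
                )
            rows.append({"repeat": rep, "fold": fold, "class": "all", "ability": ability})
        if loo:
            rows.append(
                {
                    "repeat": rep,
                    "fold": -1,
                    "class": "all",
                    "ability": _safe_ability(np.asarray(pooled_obs), np.asarray(pooled_pred)),
                }
            )
    return CVResult(scheme=f"{k}-fold", abilities=pd.DataFrame(rows))


def chessboard_cv(
    hybrids: pd.DataFrame,
    genotypes: GenotypeMatrix,
    n_female_folds: int = 5,
    n_male_folds: int = 3,
    seed: int = 0,
    varcomp: tuple | str = "reml",
) -> dict[str, CVResult]:
    """Chessboard cross-validation of hybrid prediction (T0/T1/T2).

    ``hybrids`` needs columns ``female_parent``, ``male_parent`` and
    ``value`` (one record per hybrid). Females and males are partitioned
    into fold groups; for each held-out (female-group, male-group) cell the
    training set is restricted per scenario: T2 drops only the tested
    hybrids, T1 additionally drops every hybrid with a female parent in the
    tested female group (test hybrids then share male lines only), and T0
    drops both parent groups entirely. Empty cells or training sets are
    reported as missing abilities.
    """
    if n_female_folds < 2 or n_male_folds < 2:
        raise ValueError("need at least 2 folds on each parent axis")
    from .prediction import candidate_design_rows

    females = sorted(hybrids["female_parent"].unique())
    males = sorted(hybrids["male_parent"].unique())
    rng = np.random.default_rng(seed)
    f_fold = dict(zip(rng.permutation(females), np.arange(len(females)) % n_female_folds))
    m_fold = dict(zip(rng.permutation(males), np.arange(len(males)) % n_male_folds))

    y = hybrids["value"].to_numpy(dtype=float)
    za = np.empty((len(hybrids), genotypes.n_markers))
    zd = np.empty_like(za)
    for i, (_, row) in enumerate(hybrids.iterrows()):
        xf = genotypes.row(row["female_parent"])
        xm = genotypes.row(row["male_parent"])
        za[i], zd[i] = candidate_design_rows(xf, xm)

    ff = hybrids["female_parent"].map(f_fold).to_numpy()
    mf = hybrids["male_parent"].map(m_fold).to_numpy()

    rows: dict[str, list[dict]] = {"T0": [], "T1": [], "T2": []}
    for fi in range(n_female_folds):
        for mj in range(n_male_folds):
            test = (ff == fi) & (mf == mj)
            if not test.any():
                warnings.warn(f"empty test cell ({fi}, {mj})")
                continue
            train_sets = {
                "T2": ~test,
                "T1": ff != fi,
                "T0": (ff != fi) & (mf != mj),
            }
            for cls, train in train_sets.items():
                fold_id = fi * n_male_folds + mj
                if not train.any():
                    warnings.warn(f"empty {cls} training set for cell ({fi}, {mj})")
                    rows[cls].append(
                        {"repeat": 0, "fold": fold_id, "class": cls, "ability": np.nan}
                    )
                    continue
                m = fit_rrblup_ad(y[train], za[train], zd[train], varcomp=varcomp)
                pred = (
                    m.intercept
                    + za[test] @ m.additive_effects
                    + zd[test] @ m.dominance_effects
                )
                rows[cls].append(
                    {
                        "repeat": 0,
                        "fold": fold_id,
                        "class": cls,
                        "ability": _safe_ability(y[test], pred),
                    }
                )
    return {
        cls: CVResult(scheme="chessboard", abilities=pd.DataFrame(r))
        for cls, r in rows.items()
    }
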
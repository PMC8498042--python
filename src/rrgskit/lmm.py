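"""Linear mixed models with independent random terms.

A small dense EM-REML solver built on Henderson's mixed-model equations,
for models of the form

    y = X beta + sum_i Z_i u_i + e,   u_i ~ N(0, sigma2_i I),  e ~ N(0, sigma2_e I)

which covers the across-environment BLUE model (fixed genotype, random
location and block) and the combining-ability variance-component model
(random line, GCA, SCA and their environment interactions). EM updates are
the classical ones: for each term sigma2_i <- (u_i'u_i + sigma2_e tr(C^ii)) / q_i
with C the MME coefficient matrix, and sigma2_e from the residual quadratic
form. EM guarantees nonnegative estimates; components collapsing to zero are
floored at a small multiple of the phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MixedModel", "MixedModelFit"]

_FLOOR = 1e-10


@dataclass
class MixedModelFit:
    beta: np.ndarray
    fixed_names: list[str]
    varcomp: dict[str, float]  # includes "residual"
    blups: dict[str, np.ndarray]
    level_names: dict[str, list[str]]
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int
    history: list[dict[str, float]] = field(repr=False, default_factory=list)


class MixedModel:
    """Mixed model with iid random terms, estimated by EM-REML.

    Parameters
    ----------
    y : response vector
    X : fixed-effect design matrix (n x p), full column rank
    random_terms : mapping name -> (Z, level_names) with Z of shape (n, q)
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        fixed_names: list[str],
        random_terms: dict[str, tuple[np.ndarray, list[str]]],
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.fixed_names = fixed_names
        self.terms = {k: (np.asarray(Z, dtype=float), names) for k, (Z, names) in random_terms.items()}
        self.n = len(self.y)
        self.rank_x = np.linalg.matrix_rank(self.X)
        mats = [self.X]
        pos = self.X.shape[1]
        self._offsets: dict[str, tuple[int, int]] = {}
        for nm, (Z, _) in self.terms.items():
            self._offsets[nm] = (pos, pos + Z.shape[1])
            mats.append(Z)
            pos += Z.shape[1]
        T = np.hstack(mats)
        self._TtT = T.T @ T
        self._Tty = T.T @ self.y

    def fit(
        self,
        varcomp: dict[str, float] | str = "reml",
        tol: float = 1e-6,
        max_iter: int = 500,
    ) -> MixedModelFit:
        """Solve the MME; estimate variance components by EM-REML if asked.

        ``varcomp`` may be "reml" or a dict naming every random term plus
        "residual" with fixed values. Non-convergence after ``max_iter``
        iterations is reported on the fit object, never silently ignored.
        """
        names = list(self.terms)
        var_y = self.y.var(ddof=1) if self.n > 1 else 1.0
        if var_y == 0 and varcomp == "reml":
            raise ValueError("zero phenotypic variance; REML is undefined")
        estimate = varcomp == "reml"
        if estimate:
            k = len(names) + 1
            sig = {nm: var_y / k for nm in names}
            sig_e = var_y / k
        else:
            missing = [nm for nm in names + ["residual"] if nm not in varcomp]
            if missing:
                raise ValueError(f"variance components missing for {missing}")
            sig = {nm: float(varcomp[nm]) for nm in names}
            sig_e = float(varcomp["residual"])

        floor = max(_FLOOR * var_y, _FLOOR)
        history: list[dict[str, float]] = []
        converged = not estimate
        n_iter = 0
        if estimate:
            for n_iter in range(1, max_iter + 1):
                sol, Cinv, offsets = self._solve(sig, sig_e)
                new_sig: dict[str, float] = {}
                for nm in names:
                    lo, hi = offsets[nm]
                    u = sol[lo:hi]
                    q = hi - lo
                    tr = np.trace(Cinv[lo:hi, lo:hi])
                    new_sig[nm] = max((u @ u + sig_e * tr) / q, floor)
                # residual from the REML quadratic form
                r = self._rhs()
                sse = self.y @ self.y - sol @ r
                new_e = max(sse / (self.n - self.rank_x), floor)
                history.append({**new_sig, "residual": new_e})
                # absolute change scaled by the phenotypic variance: a
                # relative criterion never settles for components near zero
                delta = max(
                    [abs(new_sig[nm] - sig[nm]) for nm in names]
                    + [abs(new_e - sig_e)]
                ) / var_y
                sig, sig_e = new_sig, new_e
                if delta < tol:
                    converged = True
                    break

        sol, Cinv, offsets = self._solve(sig, sig_e)
        p = self.X.shape[1]
        beta = sol[:p]
        blups = {}
        level_names = {}
        fitted = self.X @ beta
        for nm in names:
            lo, hi = offsets[nm]
            blups[nm] = sol[lo:hi]
            level_names[nm] = self.terms[nm][1]
            fitted = fitted + self.terms[nm][0] @ sol[lo:hi]
        return MixedModelFit(
            beta=beta,
            fixed_names=self.fixed_names,
            varcomp={**sig, "residual": sig_e},
            blups=blups,
            level_names=level_names,
            fitted=fitted,
            residuals=self.y - fitted,
            converged=converged,
            n_iter=n_iter,
            history=history,
        )

    # -- internals ---------------------------------------------------------

    def _rhs(self) -> np.ndarray:
        return self._Tty

    def _solve(
        self, sig: dict[str, float], sig_e: float
    ) -> tuple[np.ndarray, np.ndarray, dict[str, tuple[int, int]]]:
        C = self._TtT.copy()
        for nm, (lo, hi) in self._offsets.items():
            lam = sig_e / max(sig[nm], _FLOOR)
            idx = np.arange(lo, hi)
            C[idx, idx] += lam
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "mixed-model equations are singular; the design may be "
                "disconnected (a genotype group sharing no environments with "
                "the rest) or fixed effects confounded"
            ) from err
        sol = Cinv @ self._Tty
        return sol, Cinv, self._offsets

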
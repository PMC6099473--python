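"""REML linear mixed models via sparse Henderson mixed-model equations.

Fits Gaussian mixed models of the form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, s2_e I)

with an optional *additive-genetic* ("animal") component u_a ~
N(0, s2_a A) whose covariance is the pedigree numerator relationship
matrix.  The inverse of A is assembled directly from the pedigree
(Henderson's rules with the Quaas inbreeding adjustment), so the
equations stay sparse even for pedigrees with thousands of members.

The restricted likelihood is evaluated through the mixed-model
equations:

    -2 l_R = log|R| + log|G| + log|C| + y' P y  (+ const)

with C the MME coefficient matrix, and maximized over log variance ratios
by Powell's method (residual variance profiled out).  Fixed-effect covariances come from the corresponding
block of C^-1; variance-component standard errors from a finite-
difference Hessian of the restricted likelihood.

statsmodels' MixedLM fits the same class of models for iid random
intercepts and serves as an independent cross-check in the test suite;
this engine exists because a correlated pedigree random effect over
10^4 individuals needs the sparse A-inverse formulation.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .pedigree import Pedigree
from .results import MixedModelResults

__all__ = ["LinearMixedModel"]

_VAR_FLOOR = 1e-8
_VAR_CEIL = 1e4


def _indicator(labels) -> tuple[sparse.csc_matrix, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    n, q = len(codes), len(uniques)
    Z = sparse.csc_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q)
    )
    return Z, q


class LinearMixedModel:
    """Gaussian mixed model with iid and pedigree-correlated components.

    Parameters
    ----------
    endog
        Response vector (length n).
    exog
        Fixed-effect design matrix (n x p), including the intercept.
    exog_names
        Column names for ``exog``.
    vc
        Mapping from variance-component name to a length-n vector of
        group labels; each contributes a random intercept per level.
    animal_ids, pedigree
        When both given, adds an additive-genetic component: row i loads
        on individual ``animal_ids[i]``; the component covariance is
        ``s2_a A`` over the ancestor closure of the ids.
    """

    def __init__(
        self,
        endog,
        exog,
        exog_names: Sequence[str],
        vc: Mapping[str, Sequence] | None = None,
        animal_ids: Sequence[str] | None = None,
        pedigree: Pedigree | None = None,
    ):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.exog_names = list(exog_names)
        self.n, self.p = self.X.shape
        if len(self.y) != self.n:
            raise ValueError("endog and exog lengths differ")
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effect design matrix is rank deficient")
        vc = dict(vc or {})
        self.vc_names = list(vc.keys())
        self._Z_blocks: list[sparse.csc_matrix] = []
        self._q: list[int] = []
        for name in self.vc_names:
            Z, q = _indicator(vc[name])
            self._Z_blocks.append(Z)
            self._q.append(q)
        self._animal = animal_ids is not None
        self._A_inv = None
        self._logdet_A = 0.0
        if self._animal:
            if pedigree is None:
                raise ValueError("animal term requires a pedigree")
            closure = sorted(
                pedigree.ancestors(*set(animal_ids)), key=pedigree._pos.get
            )
            A_inv, order, logdet = pedigree.a_inverse(closure)
            pos = {i: k for k, i in enumerate(order)}
            rows = np.arange(self.n)
            cols = np.array([pos[i] for i in animal_ids])
            Za = sparse.csc_matrix(
                (np.ones(self.n), (rows, cols)), shape=(self.n, len(order))
            )
            self._Z_blocks.append(Za)
            self._q.append(len(order))
            self._A_inv = A_inv
            self._logdet_A = logdet
            self.vc_names.append("additive_genetic")
        # precompute W'W and W'y with W = [X | Z_1 | ... | Z_K]
        Xs = sparse.csc_matrix(self.X)
        self._W = sparse.hstack([Xs] + self._Z_blocks, format="csc")
        self._WtW = (self._W.T @ self._W).tocsc()
        self._Wty = self._W.T @ self.y
        self._yty = float(self.y @ self.y)
        self._qtot = int(sum(self._q))
        self._qarr = np.asarray(self._q, dtype=float)

    # ------------------------------------------------------------------ core

    def _ginv_block(self, variances: np.ndarray) -> sparse.csc_matrix:
        """Block-diagonal G^{-1} on the random-effect coordinates."""
        blocks = []
        for k, q in enumerate(self._q):
            is_animal = self._animal and k == len(self._q) - 1
            if is_animal:
                blocks.append(self._A_inv / variances[k])
            else:
                blocks.append(sparse.identity(q, format="csc") / variances[k])
        return sparse.block_diag(blocks, format="csc")

    def _neg2_reml(self, log_var: np.ndarray, want_solution: bool = False):
        """-2 restricted log-likelihood at the given variances (+ const)."""
        var = np.exp(np.clip(log_var, np.log(_VAR_FLOOR * self._scale),
                             np.log(_VAR_CEIL * self._scale)))
        s2e = var[-1]
        vcs = var[:-1]
        G_inv = self._ginv_block(vcs)
        pad = sparse.block_diag(
            [sparse.csc_matrix((self.p, self.p)), G_inv], format="csc"
        )
        C = (self._WtW / s2e + pad).tocsc()
        lu = splu(C, permc_spec="MMD_AT_PLUS_A")
        logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        rhs = self._Wty / s2e
        sol = lu.solve(rhs)
        ypy = self._yty / s2e - float(sol @ rhs)
        logdet_R = self.n * np.log(s2e)
        logdet_G = 0.0
        for k, q in enumerate(self._q):
            logdet_G += q * np.log(vcs[k])
        if self._animal:
            logdet_G += self._logdet_A
        val = logdet_R + logdet_G + logdet_C + ypy
        if want_solution:
            return val, sol, lu, var
        return val

    def _neg2_reml_profiled(self, log_ratio: np.ndarray, want_all: bool = False):
        """-2 l_R profiled over the residual variance.

        Parameterized by log variance ratios gamma_k = s2_k / s2_e; the
        residual variance has the closed form y'Py* / (n - p).
        """
        gam = np.exp(np.clip(log_ratio, np.log(_VAR_FLOOR), np.log(_VAR_CEIL)))
        G_inv = self._ginv_block(gam)
        pad = sparse.block_diag(
            [sparse.csc_matrix((self.p, self.p)), G_inv], format="csc"
        )
        C = (self._WtW + pad).tocsc()
        lu = splu(C, permc_spec="MMD_AT_PLUS_A")
        logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        sol = lu.solve(self._Wty)
        ypy = self._yty - float(sol @ self._Wty)
        dof = self.n - self.p
        s2e = max(ypy / dof, _VAR_FLOOR * self._scale)
        val = dof * np.log(s2e) + logdet_C + float(self._qarr @ np.log(gam))
        if self._animal:
            val += self._logdet_A
        if want_all:
            return val, s2e, gam
        return val

    def fit(self, maxfev: int = 500, compute_vc_se: bool = True) -> MixedModelResults:
        """Maximize the restricted likelihood; Wald SEs from the MME."""
        flags: list[str] = []
        vary = float(np.var(self.y))
        if vary <= 0:
            return self._degenerate_fit("response has zero variance")
        self._scale = vary
        k = len(self._q)
        x0 = np.zeros(k)  # all ratios start at 1
        res = optimize.minimize(
            self._neg2_reml_profiled,
            x0,
            method="Powell",
            options={"maxfev": maxfev, "xtol": 1e-4, "ftol": 1e-7},
        )
        if not res.success:
            flags.append(f"optimizer: {res.message}")
        _, s2e, gam = self._neg2_reml_profiled(res.x, want_all=True)
        var_hat = np.append(gam * s2e, s2e)
        val, sol, lu, var = self._neg2_reml(np.log(var_hat), want_solution=True)
        beta = sol[: self.p]
        # Var(beta) = top-left block of C^{-1}
        E = np.zeros((self.p + self._qtot, self.p))
        E[: self.p, : self.p] = np.eye(self.p)
        Cinv_cols = lu.solve(E)
        cov_beta = Cinv_cols[: self.p, :]
        bse = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
        vcomp = pd.Series(var[:-1], index=self.vc_names)
        vcomp["residual"] = var[-1]
        vcomp_se = None
        if compute_vc_se:
            vcomp_se = self._vc_standard_errors(var, flags)
        extra: dict = {}
        if self._animal:
            tot = float(np.sum(var))
            extra["heritability"] = float(var[self.vc_names.index("additive_genetic")] / tot)
            if vcomp_se is not None:
                extra["heritability_se"] = self._h2_se(var, vcomp_se)
        out = MixedModelResults(
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            vcomp=vcomp,
            vcomp_se=vcomp_se,
            n_obs=self.n,
            method="REML (sparse MME, Powell)",
            converged=bool(res.success),
            flags=flags,
            loglike=-0.5 * val,
            extra=extra,
        )
        out.extra["cov_params"] = pd.DataFrame(
            cov_beta, index=self.exog_names, columns=self.exog_names
        )
        return out

    # ------------------------------------------------------------- details

    def _vc_standard_errors(self, var: np.ndarray, flags: list[str]) -> pd.Series | None:
        names = self.vc_names + ["residual"]
        k = len(var)
        h = np.maximum(1e-3 * var, 1e-10)

        def f(v):
            return self._neg2_reml(np.log(np.maximum(v, 1e-300)))

        H = np.zeros((k, k))
        f0 = f(var)
        fp = np.zeros(k)
        fm = np.zeros(k)
        for i in range(k):
            vp, vm = var.copy(), var.copy()
            vp[i] += h[i]
            vm[i] = max(vm[i] - h[i], _VAR_FLOOR * self._scale)
            fp[i], fm[i] = f(vp), f(vm)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / (h[i] ** 2)
        for i in range(k):
            for j in range(i + 1, k):
                vpp = var.copy()
                vpp[i] += h[i]
                vpp[j] += h[j]
                H[i, j] = H[j, i] = (
                    f(vpp) - fp[i] - fp[j] + f0
                ) / (h[i] * h[j])
        # -2 logL Hessian -> information = H / 2
        try:
            cov = np.linalg.inv(H / 2.0)
        except np.linalg.LinAlgError:
            flags.append("variance-component Hessian singular")
            return None
        d = np.diag(cov)
        if np.any(d < 0):
            flags.append("variance-component Hessian not positive definite")
            d = np.abs(d)
        self._vc_cov = cov
        return pd.Series(np.sqrt(d), index=names)

    def _h2_se(self, var: np.ndarray, vcomp_se: pd.Series) -> float:
        """Delta-method SE of V_A / sum(V) using the numeric vc covariance."""
        cov = getattr(self, "_vc_cov", None)
        if cov is None:
            return float("nan")
        tot = float(np.sum(var))
        ia = self.vc_names.index("additive_genetic")
        grad = np.full(len(var), -var[ia] / tot**2)
        grad[ia] += 1.0 / tot
        v = float(grad @ cov @ grad)
        return float(np.sqrt(max(v, 0.0)))

    def _degenerate_fit(self, reason: str) -> MixedModelResults:
        nan = float("nan")
        return MixedModelResults(
            params=pd.Series(nan, index=self.exog_names),
            bse=pd.Series(nan, index=self.exog_names),
            vcomp=pd.Series(nan, index=self.vc_names + ["residual"]),
            n_obs=self.n,
            method="REML (sparse MME, Powell)",
            converged=False,
            flags=[f"degenerate: {reason}"],
        )
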
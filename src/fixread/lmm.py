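"""Linear mixed model with crossed random intercepts for participant and word.

Model
-----
    y = X beta + Z_p u_p + Z_w u_w + e
    u_p ~ N(0, sigma_p^2 I),  u_w ~ N(0, sigma_w^2 I),  e ~ N(0, sigma^2 I)

with y a viewing-time component (ms), X the fixed-effect design (frequency,
surprisal, the four similarity measures, reading ability, optional
interactions) and two crossed random intercepts. Estimation is restricted
maximum likelihood, profiled over sigma^2 and the fixed effects, leaving a
two-dimensional optimisation over the variance ratios
gamma_k = sigma_k^2 / sigma^2.

All matrix work runs through the q x q system M = Z'Z + G^{-1}
(q = n_participants + n_words), using

    V = I + Z G Z'            (in units of sigma^2)
    V^{-1} = I - Z M^{-1} Z'
    log|V| = log|M| + log|G|

so a fit costs a handful of Cholesky factorisations of a small matrix
regardless of the number of observations. Wald t-statistics use residual
degrees of freedom n - p (recorded in the results metadata).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_GAMMA_FLOOR = 1e-8          # variance ratio at/below this is reported as boundary
_GAMMA_CEIL = 2.9e6          # ratio at/above this (log = 15) likewise


class CrossedLMM:
    """Linear mixed model with crossed participant and word random intercepts.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response (a viewing-time component, ms).
    exog : array-like, shape (n, p)
        Fixed-effect design matrix, including the intercept column.
    participants, words : array-like, shape (n,)
        Grouping labels for the two crossed random intercepts.
    exog_names : list of str, optional
        Column names for reporting.
    """

    def __init__(self, endog, exog, participants, words, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n, p) matching endog")
        self.nobs, self.k_fe = self.exog.shape
        p_labels, self.p_codes = np.unique(np.asarray(participants), return_inverse=True)
        w_labels, self.w_codes = np.unique(np.asarray(words), return_inverse=True)
        self.participant_labels = p_labels
        self.word_labels = w_labels
        self.n_participants = p_labels.size
        self.n_words = w_labels.size
        if self.n_participants < 2 or self.n_words < 2:
            raise ValueError("need at least 2 participants and 2 words")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.k_fe)]
        )
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.k_fe:
            raise ValueError("fixed-effect design is rank deficient")
        self._build_crossprods()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed_effects: list[str],
        participant_col: str = "participant_id",
        word_col: str = "token_id",
        add_intercept: bool = True,
    ) -> "CrossedLMM":
        cols = [c for c in fixed_effects]
        X = data[cols].to_numpy(dtype=float)
        names = list(cols)
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["Intercept"] + names
        return cls(
            data[response].to_numpy(dtype=float),
            X,
            data[participant_col].to_numpy(),
            data[word_col].to_numpy(),
            exog_names=names,
        )

    # -- sufficient statistics ---------------------------------------------
    def _build_crossprods(self):
        n, p = self.nobs, self.k_fe
        a, b = self.n_participants, self.n_words
        q = a + b
        X, y = self.exog, self.endog
        # Z'X, Z'y, Z'Z via bincount-style accumulation
        ZtX = np.zeros((q, p))
        Zty = np.zeros(q)
        for j in range(p):
            ZtX[:a, j] = np.bincount(self.p_codes, weights=X[:, j], minlength=a)
            ZtX[a:, j] = np.bincount(self.w_codes, weights=X[:, j], minlength=b)
        Zty[:a] = np.bincount(self.p_codes, weights=y, minlength=a)
        Zty[a:] = np.bincount(self.w_codes, weights=y, minlength=b)
        ZtZ = np.zeros((q, q))
        np.fill_diagonal(ZtZ[:a, :a], np.bincount(self.p_codes, minlength=a))
        np.fill_diagonal(ZtZ[a:, a:], np.bincount(self.w_codes, minlength=b))
        # participant x word incidence
        flat = self.p_codes * b + self.w_codes
        N = np.bincount(flat, minlength=a * b).reshape(a, b)
        ZtZ[:a, a:] = N
        ZtZ[a:, :a] = N.T
        self._ZtX, self._Zty, self._ZtZ = ZtX, Zty, ZtZ
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)

    # -- profiled REML ------------------------------------------------------
    def _profile(self, gamma_p: float, gamma_w: float):
        a, b = self.n_participants, self.n_words
        n, p = self.nobs, self.k_fe
        M = self._ZtZ.copy()
        idx = np.arange(a + b)
        M[idx[:a], idx[:a]] += 1.0 / gamma_p
        M[idx[a:], idx[a:]] += 1.0 / gamma_w
        cM, low = linalg.cho_factor(M, lower=True, check_finite=False)
        MinvZtX = linalg.cho_solve((cM, low), self._ZtX, check_finite=False)
        MinvZty = linalg.cho_solve((cM, low), self._Zty, check_finite=False)
        XtVinvX = self._XtX - self._ZtX.T @ MinvZtX
        XtVinvy = self._Xty - self._ZtX.T @ MinvZty
        ytVinvy = self._yty - self._Zty @ MinvZty
        cF = linalg.cho_factor(XtVinvX, lower=True, check_finite=False)
        beta = linalg.cho_solve(cF, XtVinvy, check_finite=False)
        rss = ytVinvy - beta @ XtVinvy
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - p)
        logdet_V = 2.0 * np.sum(np.log(np.diag(cM))) + a * np.log(gamma_p) + b * np.log(gamma_w)
        logdet_F = 2.0 * np.sum(np.log(np.diag(cF[0])))
        neg2_reml = (n - p) * np.log(sigma2) + logdet_V + logdet_F
        return {
            "neg2_reml": neg2_reml,
            "beta": beta,
            "sigma2": sigma2,
            "XtVinvX": XtVinvX,
            "cM": (cM, low),
        }

    def _objective(self, log_gamma: np.ndarray) -> float:
        gp, gw = np.exp(np.clip(log_gamma, -20.0, 15.0))
        try:
            return self._profile(gp, gw)["neg2_reml"]
        except linalg.LinAlgError:
            return np.inf

    def fit(self, extra_starts=((1.0, 1.0), (-6.0, -6.0))) -> "CrossedLMMResults":
        """REML fit.

        The 2-d profiled objective is smooth and unimodal in practice; one
        Nelder-Mead start suffices, with fallback restarts if it reports
        failure.
        """
        best = None
        converged = False
        for i, x0 in enumerate(((-1.0, -1.0),) + tuple(extra_starts)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    self._objective, np.asarray(x0, dtype=float), method="Nelder-Mead",
                    options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 1000},
                )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
                converged = bool(res.success)
            if i == 0 and res.success:
                break
        gamma_p, gamma_w = np.exp(np.clip(best.x, -20.0, 15.0))
        prof = self._profile(gamma_p, gamma_w)
        sigma2 = prof["sigma2"]
        cov_params = sigma2 * linalg.inv(prof["XtVinvX"])
        singular = bool(
            gamma_p <= _GAMMA_FLOOR or gamma_w <= _GAMMA_FLOOR
            or gamma_p >= _GAMMA_CEIL or gamma_w >= _GAMMA_CEIL
        )
        if singular:
            warnings.warn("a random-effect variance is at its boundary", stacklevel=2)
        # BLUPs via Henderson's equations: u = M^{-1} Z'(y - X beta)
        resid_cross = self._Zty - self._ZtX @ prof["beta"]
        u = linalg.cho_solve(prof["cM"], resid_cross, check_finite=False)
        a = self.n_participants
        return CrossedLMMResults(
            model=self,
            params=prof["beta"],
            cov_params=cov_params,
            sigma2_resid=sigma2,
            sigma2_participant=gamma_p * sigma2,
            sigma2_word=gamma_w * sigma2,
            neg2_reml=prof["neg2_reml"],
            converged=converged,
            singular=singular,
            ranef_participant=dict(zip(self.participant_labels, u[:a])),
            ranef_word=dict(zip(self.word_labels, u[a:])),
        )


@dataclass
class CrossedLMMResults:
    """REML estimates, Wald inference and variance components."""

    model: CrossedLMM
    params: np.ndarray
    cov_params: np.ndarray
    sigma2_resid: float
    sigma2_participant: float
    sigma2_word: float
    neg2_reml: float
    converged: bool
    singular: bool
    ranef_participant: dict = field(repr=False, default_factory=dict)
    ranef_word: dict = field(repr=False, default_factory=dict)

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_resid(self) -> int:
        return self.model.nobs - self.model.k_fe

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        crit = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        return np.column_stack([self.params - crit * self.bse, self.params + crit * self.bse])

    def predict_random_effects(self) -> np.ndarray:
        """Per-observation sum of the participant and word intercept BLUPs."""
        m = self.model
        up = np.array([self.ranef_participant[k] for k in m.participant_labels])
        uw = np.array([self.ranef_word[k] for k in m.word_labels])
        return up[m.p_codes] + uw[m.w_codes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=pd.Index(self.exog_names, name="term"),
        )

    def to_dict(self) -> dict:
        return {
            "terms": {
                name: {
                    "estimate": float(b),
                    "se": float(s),
                    "t": float(t),
                    "p": float(p),
                }
                for name, b, s, t, p in zip(
                    self.exog_names, self.params, self.bse, self.tvalues, self.pvalues
                )
            },
            "variance_components": {
                "participant": float(self.sigma2_participant),
                "word": float(self.sigma2_word),
                "residual": float(self.sigma2_resid),
            },
            "n_obs": int(self.nobs),
            "df_resid": int(self.df_resid),
            "df_method": "residual",
            "converged": bool(self.converged),
            "singular": bool(self.singular),
        }

    def summary(self) -> str:
        lines = [
            "Crossed random-intercepts linear mixed model (REML)",
            f"  n_obs = {self.nobs}, participants = {self.model.n_participants}, "
            f"words = {self.model.n_words}",
            f"  converged = {self.converged}, boundary = {self.singular}",
            "",
            f"  {'term':<22}{'estimate':>12}{'SE':>10}{'t':>9}{'p':>11}",
        ]
        for name, b, s, t, p in zip(
            self.exog_names, self.params, self.bse, self.tvalues, self.pvalues
        ):
            lines.append(f"  {name:<22}{b:>12.4f}{s:>10.4f}{t:>9.2f}{p:>11.3g}")
        lines += [
            "",
            "  Variance components:",
            f"    participant intercept  {self.sigma2_participant:>12.4f}",
            f"    word intercept         {self.sigma2_word:>12.4f}",
            f"    residual               {self.sigma2_resid:>12.4f}",
        ]
        return "\n".join(lines)
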
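"""Recursive path analysis over the multi-scale similarity measures.

The causal ordering runs coarse to fine and ends at the viewing-time
component:

    para_para -> sent_para -> sent_sent -> word_sent -> DV

Word frequency and surprisal enter every equation as exogenous covariates
(sources with no incoming edges). The model is a recursive system of
per-equation ordinary least-squares regressions on z-standardized variables:
each endogenous variable is regressed on all of its predecessors plus the
exogenous covariates, giving standardized path coefficients.

Effect decomposition uses the structural form x = B x + e with B strictly
lower-triangular in the causal ordering: the matrix of total effects is
(I - B)^{-1} - I, the direct effect of a source on the DV is its coefficient
in the DV equation, and the indirect effect (the sum over all directed
multi-edge paths of products of path coefficients) is their difference, so
total = direct + indirect holds to machine precision by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ORDER = ("para_para", "sent_para", "sent_sent", "word_sent")
DEFAULT_EXOG = ("freq", "surprisal")


class RankDeficientError(ValueError):
    pass


class RecursivePathModel:
    """Recursive (fully ordered) path model estimated equation by equation.

    Parameters
    ----------
    data : DataFrame
        One row per observation; must contain the endogenous chain columns,
        the exogenous covariates and the DV column.
    dv : str
        Name of the dependent viewing-time component column (e.g. "FFD").
    order : sequence of str
        Causal ordering of the endogenous similarity measures, coarse first.
    exog : sequence of str
        Exogenous covariates included in every equation.
    standardize : bool
        z-score all variables before estimation (standardized coefficients).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        order=DEFAULT_ORDER,
        exog=DEFAULT_EXOG,
        standardize: bool = True,
    ):
        self.dv = dv
        self.order = tuple(order)
        self.exog = tuple(exog)
        self.variables = list(self.exog) + list(self.order) + [dv]
        missing = [v for v in self.variables if v not in data.columns]
        if missing:
            raise KeyError(f"columns missing from data: {missing}")
        frame = data[self.variables].dropna()
        if standardize:
            sds = frame.std(ddof=1)
            zero = sds[sds == 0].index.tolist()
            if zero:
                raise RankDeficientError(f"constant columns cannot be standardized: {zero}")
            frame = (frame - frame.mean()) / sds
        self.frame = frame
        self.standardized = standardize
        self.nobs = len(frame)

    def fit(self) -> "PathResults":
        k = len(self.variables)
        n_exog = len(self.exog)
        B = np.zeros((k, k))
        se = np.full((k, k), np.nan)
        pvals = np.full((k, k), np.nan)
        Xall = self.frame.to_numpy(dtype=float)
        for i in range(n_exog, k):
            y = Xall[:, i]
            pred_idx = list(range(i))
            X = np.column_stack([np.ones(self.nobs), Xall[:, pred_idx]])
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                raise RankDeficientError(
                    f"collinear predictor set for equation {self.variables[i]!r}: "
                    f"{[self.variables[j] for j in pred_idx]}"
                )
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            dof = self.nobs - X.shape[1]
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            B[i, pred_idx] = coef[1:]
            se[i, pred_idx] = np.sqrt(np.diag(cov)[1:])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = coef[1:] / np.sqrt(np.diag(cov)[1:])
            pvals[i, pred_idx] = 2.0 * stats.t.sf(np.abs(t), dof)
        return PathResults(model=self, B=B, se=se, pvalues=pvals)


@dataclass
class PathResults:
    """Standardized path coefficients and the direct/indirect decomposition."""

    model: RecursivePathModel
    B: np.ndarray        # B[i, j]: coefficient of variable j in equation for i
    se: np.ndarray
    pvalues: np.ndarray

    @property
    def variables(self) -> list[str]:
        return self.model.variables

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def coefficient(self, target: str, source: str) -> float:
        v = self.variables
        return float(self.B[v.index(target), v.index(source)])

    def total_effects_matrix(self) -> np.ndarray:
        k = len(self.variables)
        return np.linalg.inv(np.eye(k) - self.B) - np.eye(k)

    def effects(self, target: str | None = None) -> pd.DataFrame:
        """Direct, indirect and total standardized effects of every source on
        ``target`` (default: the DV). total = direct + indirect identically."""
        target = target or self.model.dv
        v = self.variables
        ti = v.index(target)
        T = self.total_effects_matrix()
        rows = []
        for j, src in enumerate(v):
            if j == ti:
                continue
            direct = self.B[ti, j]
            total = T[ti, j]
            rows.append((src, direct, total - direct, total))
        return pd.DataFrame(rows, columns=["source", "direct", "indirect", "total"]).set_index(
            "source"
        )

    def enumerate_paths(self, source: str, target: str | None = None):
        """All directed paths source -> ... -> target with nonzero edges, each
        with its product of path coefficients (indirect = sum over len > 1)."""
        target = target or self.model.dv
        v = self.variables
        si, ti = v.index(source), v.index(target)
        paths = []

        def walk(node, acc, prod):
            if node == ti:
                paths.append(([v[i] for i in acc], prod))
                return
            for nxt in range(node + 1, len(v)):  # edges only run down the ordering
                if self.B[nxt, node] != 0.0:
                    walk(nxt, acc + [nxt], prod * self.B[nxt, node])

        walk(si, [si], 1.0)
        return paths

    def to_dict(self) -> dict:
        v = self.variables
        eff = self.effects()
        return {
            "variables": v,
            "dv": self.model.dv,
            "n_obs": int(self.nobs),
            "coefficients": {
                v[i]: {
                    v[j]: {
                        "estimate": float(self.B[i, j]),
                        "se": float(self.se[i, j]),
                        "p": float(self.pvalues[i, j]),
                    }
                    for j in range(i)
                    if not np.isnan(self.se[i, j])
                }
                for i in range(len(self.model.exog), len(v))
            },
            "effects_on_dv": {
                src: {
                    "direct": float(row["direct"]),
                    "indirect": float(row["indirect"]),
                    "total": float(row["total"]),
                }
                for src, row in eff.iterrows()
            },
        }

    def summary(self) -> str:
        v = self.variables
        lines = [
            f"Recursive path model (standardized), DV = {self.model.dv}, n = {self.nobs}",
            f"  ordering: {' -> '.join(self.model.order)} -> {self.model.dv}",
            f"  exogenous on every equation: {', '.join(self.model.exog)}",
            "",
            f"  {'path':<32}{'estimate':>10}{'SE':>9}{'p':>11}",
        ]
        for i in range(len(self.model.exog), len(v)):
            for j in range(i):
                if np.isnan(self.se[i, j]):
                    continue
                lines.append(
                    f"  {v[j] + ' -> ' + v[i]:<32}{self.B[i, j]:>10.4f}"
                    f"{self.se[i, j]:>9.4f}{self.pvalues[i, j]:>11.3g}"
                )
        lines += ["", f"  Effects on {self.model.dv} (total = direct + indirect):"]
        for src, row in self.effects().iterrows():
            lines.append(
                f"    {src:<14} direct {row['direct']:>8.4f}  indirect {row['indirect']:>8.4f}"
                f"  total {row['total']:>8.4f}"
            )
        return "\n".join(lines)
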
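"""Partial-effect plots of viewing time against a similarity measure.

The plotted response is the dependent variable after removal of
between-participant and between-word variance: DV minus the fitted random
intercept predictions (BLUPs), leaving the fixed-effect structure visible.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .lmm import CrossedLMMResults

_ABILITY_ORDER = ("poor", "average", "good")


def adjusted_dv(rows: pd.DataFrame, result: CrossedLMMResults, dv: str) -> np.ndarray:
    """DV with estimated participant and word random intercepts removed."""
    return rows[dv].to_numpy(dtype=float) - result.predict_random_effects()


def plot_effects(
    rows: pd.DataFrame,
    result: CrossedLMMResults,
    dv: str,
    term: str,
    split: str = "ability",
    out_path=None,
):
    """Scatter + per-group linear trend of the random-effect-adjusted DV
    against a similarity term, split by ability or grade.

    Returns the matplotlib figure; saves it when ``out_path`` is given.
    """
    if term not in rows.columns:
        raise ValueError(
            f"unknown term {term!r}; available: "
            f"{[c for c in rows.columns if c not in ('participant_id', 'token_id')]}"
        )
    if split not in ("ability", "grade"):
        raise ValueError("split must be 'ability' or 'grade'")
    y = adjusted_dv(rows, result, dv)
    x = rows[term].to_numpy(dtype=float)
    levels = (
        [a for a in _ABILITY_ORDER if a in set(rows[split])]
        if split == "ability"
        else sorted(rows[split].unique())
    )
    expected = _ABILITY_ORDER if split == "ability" else ()
    for lvl in expected:
        if lvl not in levels:
            warnings.warn(f"split level {lvl!r} absent from data", stacklevel=2)

    fig, ax = plt.subplots(figsize=(6, 4.2))
    for lvl in levels:
        mask = (rows[split] == lvl).to_numpy()
        ax.scatter(x[mask], y[mask], s=4, alpha=0.15, label=None)
        if mask.sum() >= 3 and np.std(x[mask]) > 0:
            b, a = np.polyfit(x[mask], y[mask], 1)
            xs = np.linspace(x[mask].min(), x[mask].max(), 50)
            ax.plot(xs, a + b * xs, label=f"{split}={lvl}")
    ax.set_xlabel(term)
    ax.set_ylabel(f"{dv} (ms, random effects removed)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(Path(out_path), dpi=120)
    return fig
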
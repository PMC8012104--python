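"""Modelling-dataset assembly and the full analysis grid.

One modelled row is a word-viewing instance: a (participant, token) pair with
a positive viewing-time component as the response and seven fixed covariates
(log word frequency, surprisal, the four similarity measures, reading
ability), plus the two grouping ids for the crossed random intercepts.

``run_analysis_suite`` reproduces the study's analysis grid on any assembled
dataset: per viewing-time component an overall mixed model and per-grade
mixed models; for the first-fixation and re-reading components an overall
path analysis and good/poor-reader splits (the refixation component is left
out of the path analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import CrossedLMM, CrossedLMMResults
from .path import RecursivePathModel
from .simulate import ABILITY_CODE, FIXED_EFFECTS

DVS = ("FFD", "RFD", "RRD")
PATH_DVS = ("FFD", "RRD")  # RFD is excluded from path analysis
SIMILARITY_TERMS = ("word_sent", "sent_sent", "sent_para", "para_para")


class JoinError(KeyError):
    pass


def build_dataset(
    measures: pd.DataFrame,
    covariates: pd.DataFrame,
    participants: pd.DataFrame,
    dv: str = "FFD",
    standardize: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Assemble FeatureRows for one viewing-time component.

    Parameters
    ----------
    measures
        Output of :func:`fixread.gaze.decompose_viewing_times` (one row per
        participant x trial x token; summed over trials here since a token
        belongs to one trial).
    covariates
        Per-token covariate table from :func:`fixread.simulate.token_covariates`
        (freq, surprisal, four similarities), indexed by token_id.
    participants
        Table with participant_id, grade, ability.
    dv
        Which component becomes the response column ("FFD", "RFD" or "RRD").
    standardize
        z-score the covariate columns of the assembled dataset.

    Returns
    -------
    (DataFrame, metadata dict). Rows with DV <= 0 (skips / component absent)
    and rows with any missing similarity (document-initial units) are dropped
    and counted in the metadata.
    """
    if dv not in DVS:
        raise ValueError(f"dv must be one of {DVS}")
    agg = (
        measures.groupby(["participant_id", "token_id"], as_index=False)[list(DVS)]
        .sum()
    )
    n_pairs = len(agg)
    agg = agg[agg[dv] > 0]
    n_zero = n_pairs - len(agg)

    cov = covariates.reset_index()
    orphan_tokens = set(agg["token_id"]) - set(cov["token_id"])
    if orphan_tokens:
        raise JoinError(f"tokens without covariates: {sorted(orphan_tokens)[:10]}")
    df = agg.merge(cov, on="token_id", how="left")

    pt = participants.copy()
    pt["ability_code"] = pt["ability"].map(ABILITY_CODE)
    if pt["ability_code"].isna().any():
        bad = pt.loc[pt["ability_code"].isna(), "ability"].unique().tolist()
        raise JoinError(f"unknown ability levels: {bad}")
    orphan_parts = set(df["participant_id"]) - set(pt["participant_id"])
    if orphan_parts:
        raise JoinError(f"participants missing from table: {sorted(orphan_parts)[:10]}")
    df = df.merge(pt, on="participant_id", how="left")

    covariate_cols = ["freq", "surprisal", *SIMILARITY_TERMS]
    n_before = len(df)
    df = df.dropna(subset=covariate_cols)
    n_missing = n_before - len(df)

    meta = {
        "dv": dv,
        "n_rows": int(len(df)),
        "n_dropped_zero_dv": int(n_zero),
        "n_dropped_missing_similarity": int(n_missing),
        "standardized": bool(standardize),
    }
    out = df[
        ["participant_id", "token_id", "grade", "ability", "ability_code", dv]
        + covariate_cols
    ].copy()
    if standardize:
        for c in covariate_cols + ["ability_code"]:
            sd = out[c].std(ddof=1)
            if sd > 0:
                out[c] = (out[c] - out[c].mean()) / sd
    return out.reset_index(drop=True), meta


def fit_lmm(
    rows: pd.DataFrame,
    dv: str,
    include_interactions: bool = False,
) -> CrossedLMMResults:
    """REML mixed model of the component on the seven fixed effects with
    crossed participant and word random intercepts.

    ``include_interactions`` adds ability x similarity product terms.
    """
    data = rows.copy()
    terms = ["freq", "surprisal", *SIMILARITY_TERMS, "ability_code"]
    if include_interactions:
        for s in SIMILARITY_TERMS:
            data[f"ability_x_{s}"] = data["ability_code"] * data[s]
            terms.append(f"ability_x_{s}")
    model = CrossedLMM.from_dataframe(
        data, response=dv, fixed_effects=terms,
        participant_col="participant_id", word_col="token_id",
    )
    return model.fit()


def fit_path_model(rows: pd.DataFrame, dv: str):
    """Recursive path analysis of the similarity chain on one component."""
    return RecursivePathModel(rows, dv=dv).fit()


def run_analysis_suite(
    measures: pd.DataFrame,
    covariates: pd.DataFrame,
    participants: pd.DataFrame,
    include_interactions: bool = False,
    dvs=DVS,
) -> dict:
    """The full analysis grid; partial failures are recorded, not raised.

    Returns a JSON-serialisable bundle: per DV the overall and per-grade
    mixed models; for FFD and RRD the overall and good/poor-split path
    models; metadata with row counts.
    """
    bundle: dict = {"lmm": {}, "path": {}, "meta": {"datasets": {}}}
    grades = sorted(participants["grade"].unique())
    for dv in dvs:
        rows, meta = build_dataset(measures, covariates, participants, dv=dv)
        bundle["meta"]["datasets"][dv] = meta
        bundle["lmm"][dv] = {}
        cells = [("overall", rows)] + [
            (f"grade{g}", rows[rows["grade"] == g]) for g in grades
        ]
        for name, sub in cells:
            bundle["lmm"][dv][name] = _try_fit(
                lambda s=sub: fit_lmm(s, dv, include_interactions).to_dict()
            )
        if dv in PATH_DVS:
            bundle["path"][dv] = {}
            path_cells = [("overall", rows)] + [
                (ab, rows[rows["ability"] == ab]) for ab in ("good", "poor")
            ]
            for name, sub in path_cells:
                bundle["path"][dv][name] = _try_fit(
                    lambda s=sub: fit_path_model(s, dv).to_dict()
                )
    return bundle


def _try_fit(thunk) -> dict:
    try:
        return {"ok": True, "result": thunk()}
    except Exception as exc:  # partial results with failure markers
        return {"ok": False, "error": f"{type(exc).__name__}: {exc}"}
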
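"""Sequence- and error-sorted behavioral summaries of a trial table.

A trial table has one row per two-alternative trial (columns ``block``,
``trial``, ``stimulus``, ``response``, ``correct``, ``rt``; optionally
``subject``, ``pass``, ``p_alt``).  This module attaches transition labels
(R = the stimulus repeats the previous one, A = it alternates) and
three-stimulus sequence labels (RR, AR, RA, AA — attributed to the final
trial), flags outlier RTs, and reduces the table to the summary statistics
used for model fitting and comparison:

* per-sequence trial counts, mean RTs (overall / correct / error) and error
  rates;
* mean RTs before, on and after error trials;
* the 19-element condition summary vector (57 for the three-condition
  blocked design);
* the sequential RT tradeoff regression (error-trial mean RT against
  correct-trial mean RT across sequence labels) and R-line / A-line slopes.

Labels are stimulus-based, never response-based; the correctness split
refers only to the labeled (final) trial.  Outlier-flagged trials are
excluded from all RT/ER summaries but still define their successors'
transition labels.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

#: canonical sequence-label order
LABELS = ("RR", "AR", "RA", "AA")

#: canonical element order of the 19-element condition summary vector:
#: overall mean RTs, correct mean RTs, error mean RTs and ERs for the four
#: sequence labels, then the pre-/on-/post-error mean RTs.  Seconds for RTs,
#: decimal fractions for ERs.
SUMMARY_ELEMENTS = (
    tuple(f"rt_all_{lab}" for lab in LABELS)
    + tuple(f"rt_correct_{lab}" for lab in LABELS)
    + tuple(f"rt_error_{lab}" for lab in LABELS)
    + tuple(f"er_{lab}" for lab in LABELS)
    + ("rt_pre_error", "rt_on_error", "rt_post_error")
)

#: default outlier bounds on RT, seconds
OUTLIER_LO = 0.100
OUTLIER_HI = 0.900


def _group_keys(df: pd.DataFrame) -> list[str]:
    return [c for c in ("subject", "pass", "block") if c in df.columns]


def label_transitions_and_sequences(df: pd.DataFrame) -> pd.DataFrame:
    """Attach ``transition`` and ``sequence_label`` columns.

    The transition at trial n is R iff its stimulus equals trial n-1's,
    within the same (subject, pass, block) group; the sequence label
    concatenates the previous and current transitions.  The first trial of a
    block has no transition and the first two no sequence label.  Trial
    indices must be strictly increasing within each group.
    """
    for col in ("trial", "stimulus"):
        if col not in df.columns:
            raise ValueError(f"trial table is missing the {col!r} column")
    out = df.copy()
    keys = _group_keys(out)
    grouped = out.groupby(keys, sort=False) if keys else out.groupby(np.zeros(len(out)))
    diffs = grouped["trial"].diff()
    if (diffs.dropna() <= 0).any():
        bad = out.index[diffs <= 0][0]
        raise ValueError(
            f"trial indices must be strictly increasing within each block "
            f"(violated at row {bad})"
        )
    prev_stim = grouped["stimulus"].shift(1)
    trans = pd.Series(
        np.where(prev_stim.isna(), None,
                 np.where(out["stimulus"].values == prev_stim.values, "R", "A")),
        index=out.index, dtype=object,
    )
    out["transition"] = trans
    grouped = out.groupby(keys, sort=False) if keys else out.groupby(np.zeros(len(out)))
    prev_trans = grouped["transition"].shift(1)
    seq = [
        p + c if isinstance(p, str) and isinstance(c, str) else None
        for p, c in zip(prev_trans.to_numpy(object), trans.to_numpy(object))
    ]
    out["sequence_label"] = pd.Series(seq, index=out.index, dtype=object)
    return out


def flag_outliers(df: pd.DataFrame, lo: float = OUTLIER_LO,
                  hi: float = OUTLIER_HI) -> pd.DataFrame:
    """Attach a boolean ``outlier`` column: rt < lo or rt > hi (seconds).

    Flagged trials are excluded from RT/ER summaries but still contribute to
    their successors' transition and sequence labels (labeling happens on the
    full table).
    """
    if "rt" not in df.columns:
        raise ValueError("trial table is missing the 'rt' column")
    out = df.copy()
    out["outlier"] = (out["rt"] < lo) | (out["rt"] > hi)
    return out


def _require(df, cols, hint):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing {missing}; run {hint} first")


def summarize_by_sequence(df: pd.DataFrame,
                          by_condition: bool = False) -> pd.DataFrame:
    """Per-sequence-label counts, mean RTs and error rates.

    Uses non-outlier, labeled trials only.  With ``by_condition=True`` the
    summary is computed separately per block alternation probability
    (``p_alt`` column), giving a row per (p_alt, label).  Empty cells yield
    NaN means and zero counts.
    """
    _require(df, ("sequence_label", "outlier", "correct", "rt"),
             "label_transitions_and_sequences / flag_outliers")
    sel = df[df["sequence_label"].notna() & ~df["outlier"]]
    keys = (["p_alt"] if by_condition else []) + ["sequence_label"]

    def _one(g):
        corr = g["correct"].astype(bool)
        n = len(g)
        n_err = int((~corr).sum())
        return pd.Series({
            "n_total": n,
            "n_correct": n - n_err,
            "n_error": n_err,
            "rt_mean": g["rt"].mean() if n else np.nan,
            "rt_correct": g.loc[corr, "rt"].mean() if (n - n_err) else np.nan,
            "rt_error": g.loc[~corr, "rt"].mean() if n_err else np.nan,
            "er": n_err / n if n else np.nan,
        })

    if len(sel):
        summary = sel.groupby(keys, sort=True).apply(_one, include_groups=False)
    else:
        summary = pd.DataFrame(columns=["n_total", "n_correct", "n_error",
                                        "rt_mean", "rt_correct", "rt_error",
                                        "er"])
    if by_condition:
        conds = sorted(df["p_alt"].dropna().unique())
        idx = pd.MultiIndex.from_product([conds, LABELS],
                                         names=["p_alt", "sequence_label"])
    else:
        idx = pd.Index(LABELS, name="sequence_label")
    summary = summary.reindex(idx)
    for c in ("n_total", "n_correct", "n_error"):
        summary[c] = summary[c].fillna(0).astype(int)
    return summary


def summarize_error_triplets(df: pd.DataFrame,
                             by_condition: bool = False) -> pd.DataFrame:
    """Mean RTs before, on and after errors, with the triplet count.

    Every error trial whose immediate neighbors lie in the same block anchors
    one triplet (regardless of the neighbors' correctness); each of the three
    means is taken over the non-outlier entries among its contributions.
    Errors at block edges are excluded.
    """
    _require(df, ("outlier", "correct", "rt"), "flag_outliers")
    keys = _group_keys(df)
    cond_col = "p_alt" if (by_condition and "p_alt" in df.columns) else None
    acc: dict[object, dict[str, list]] = {}

    groups = df.groupby(keys, sort=False) if keys else [(None, df)]
    for _, g in groups:
        corr = g["correct"].astype(bool).to_numpy()
        rt = g["rt"].to_numpy(dtype=float)
        outl = g["outlier"].to_numpy(dtype=bool)
        cond = g[cond_col].to_numpy() if cond_col else np.full(len(g), 0.0)
        err_pos = np.flatnonzero(~corr)
        err_pos = err_pos[(err_pos >= 1) & (err_pos <= len(g) - 2)]
        for i in err_pos:
            d = acc.setdefault(cond[i], {"pre": [], "on": [], "post": [],
                                         "n": 0})
            d["n"] += 1
            if not outl[i - 1]:
                d["pre"].append(rt[i - 1])
            if not outl[i]:
                d["on"].append(rt[i])
            if not outl[i + 1]:
                d["post"].append(rt[i + 1])

    if by_condition and "p_alt" in df.columns:
        conds = sorted(df["p_alt"].dropna().unique())
    else:
        conds = [0.0]
    rows = []
    for c in conds:
        d = acc.get(c, {"pre": [], "on": [], "post": [], "n": 0})
        rows.append({
            "rt_pre_error": float(np.mean(d["pre"])) if d["pre"] else np.nan,
            "rt_on_error": float(np.mean(d["on"])) if d["on"] else np.nan,
            "rt_post_error": float(np.mean(d["post"])) if d["post"] else np.nan,
            "n_triplets": d["n"],
        })
    if by_condition and "p_alt" in df.columns:
        return pd.DataFrame(rows, index=pd.Index(conds, name="p_alt"))
    return pd.DataFrame(rows, index=pd.Index([0], name="condition"))


def assemble_summary_vector(seq_summary: pd.DataFrame,
                            triplet_summary: pd.Series | pd.DataFrame,
                            ) -> pd.Series:
    """Assemble one condition's 19-element summary vector.

    ``seq_summary`` must be a single-condition per-label summary (index =
    sequence labels) and ``triplet_summary`` the matching triplet row.
    Undefined cells are carried as NaN (missing), never as zero.
    """
    if isinstance(triplet_summary, pd.DataFrame):
        if len(triplet_summary) != 1:
            raise ValueError("triplet_summary must describe a single condition")
        triplet_summary = triplet_summary.iloc[0]
    vals = {}
    for lab in LABELS:
        row = seq_summary.loc[lab]
        vals[f"rt_all_{lab}"] = row["rt_mean"]
        vals[f"rt_correct_{lab}"] = row["rt_correct"]
        vals[f"rt_error_{lab}"] = row["rt_error"]
        vals[f"er_{lab}"] = row["er"]
    for name in ("rt_pre_error", "rt_on_error", "rt_post_error"):
        vals[name] = triplet_summary[name]
    return pd.Series([vals[e] for e in SUMMARY_ELEMENTS],
                     index=list(SUMMARY_ELEMENTS), dtype=float)


def summary_vector(df: pd.DataFrame, by_condition: bool = False,
                   lo: float = OUTLIER_LO, hi: float = OUTLIER_HI) -> pd.Series:
    """Full condition summary vector straight from a trial table.

    Labels, flags outliers, summarizes and assembles.  Single condition:
    length 19.  With ``by_condition=True``: one 19-element segment per block
    alternation probability, concatenated in increasing p_alt order with
    element names prefixed ``pA{p}:``.
    """
    labeled = df if "sequence_label" in df.columns else \
        label_transitions_and_sequences(df)
    labeled = labeled if "outlier" in labeled.columns else \
        flag_outliers(labeled, lo, hi)
    if not by_condition:
        seq = summarize_by_sequence(labeled, by_condition=False)
        trip = summarize_error_triplets(labeled, by_condition=False)
        return assemble_summary_vector(seq, trip)
    seq = summarize_by_sequence(labeled, by_condition=True)
    trip = summarize_error_triplets(labeled, by_condition=True)
    parts = []
    for p in sorted(labeled["p_alt"].dropna().unique()):
        part = assemble_summary_vector(seq.loc[p], trip.loc[p])
        part.index = [f"pA{p:g}:{e}" for e in part.index]
        parts.append(part)
    return pd.concat(parts)


class TradeoffStats(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def tradeoff_statistics(seq_summary: pd.DataFrame) -> TradeoffStats:
    """Sequential RT tradeoff: OLS of error mean RT on correct mean RT.

    Points are the (rt_correct, rt_error) pairs of the sequence labels (all
    conditions pooled if the summary is multi-condition).  Requires at least
    three points with both means defined.
    """
    pts = seq_summary[["rt_correct", "rt_error"]].dropna()
    if len(pts) < 3:
        raise ValueError(
            f"tradeoff regression needs >= 3 points with defined correct and "
            f"error means, got {len(pts)}"
        )
    res = stats.linregress(pts["rt_correct"].to_numpy(),
                           pts["rt_error"].to_numpy())
    return TradeoffStats(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         p_value=float(res.pvalue), n_points=len(pts))


def line_geometry(seq_summary: pd.DataFrame) -> pd.DataFrame:
    """R-line and A-line slopes for a single-condition sequence summary.

    The R line connects the RR and AR points and the A line the RA and AA
    points; the slopes reported are the signed differences RT(AR) - RT(RR)
    and RT(RA) - RT(AA) in seconds, for the overall, correct-only and
    error-only mean RTs.  Undefined cells yield NaN components.
    """
    cols = {"overall": "rt_mean", "correct": "rt_correct", "error": "rt_error"}
    rows = {}
    for name, col in cols.items():
        rows[name] = {
            "r_line_slope": seq_summary.loc["AR", col] - seq_summary.loc["RR", col],
            "a_line_slope": seq_summary.loc["RA", col] - seq_summary.loc["AA", col],
        }
    return pd.DataFrame.from_dict(rows, orient="index")
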
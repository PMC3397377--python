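"""Reading, writing and validation of trial tables and result files.

The on-disk trial table is a plain CSV with one row per trial and a header.
Required columns: ``subject``, ``block``, ``trial``, ``p_alt``, ``stimulus``,
``response``, ``rt``; optional: ``pass``, ``correct``, ``transition``,
``sequence_label``, ``outlier`` and any model-state diagnostics.  Reaction
times are in seconds everywhere; millisecond-looking inputs (median rt above
10) are rejected unless explicitly converted with ``rt_unit="ms"``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject", "block", "trial", "p_alt", "stimulus",
                    "response", "rt")

#: median rt above this value (seconds) triggers the wrong-unit heuristic
MS_HEURISTIC_THRESHOLD = 10.0


class TrialTableError(ValueError):
    """A trial table failed validation."""


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate dtypes and invariants; returns a typed copy.

    Checks for required columns, numeric non-negative rt (naming the first
    offending row), stimulus/response in {1, 2}, and the correctness
    invariant ``correct == (response == stimulus)`` (deriving the column when
    absent).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"trial table is missing columns {missing}")
    out = df.copy()
    rt = pd.to_numeric(out["rt"], errors="coerce")
    bad = out.index[rt.isna()]
    if len(bad):
        raise TrialTableError(f"non-numeric rt at row {bad[0]}")
    neg = out.index[rt < 0]
    if len(neg):
        raise TrialTableError(f"negative rt at row {neg[0]}")
    out["rt"] = rt.astype(float)
    for col in ("block", "trial", "stimulus", "response"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[vals.isna()]
        if len(bad):
            raise TrialTableError(f"non-numeric {col} at row {bad[0]}")
        out[col] = vals.astype(int)
    for col in ("stimulus", "response"):
        bad = out.index[~out[col].isin((1, 2))]
        if len(bad):
            raise TrialTableError(f"{col} must be 1 or 2 at row {bad[0]}")
    out["p_alt"] = pd.to_numeric(out["p_alt"], errors="coerce")
    derived = out["response"].to_numpy() == out["stimulus"].to_numpy()
    if "correct" in out.columns:
        stored = out["correct"].astype(bool).to_numpy()
        mism = np.flatnonzero(stored != derived)
        if mism.size:
            raise TrialTableError(
                f"correct flag inconsistent with response == stimulus at row "
                f"{out.index[mism[0]]}"
            )
        out["correct"] = stored
    else:
        out["correct"] = derived
    return out


def read_trial_table(path, rt_unit: str = "s") -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    ``rt_unit="ms"`` converts millisecond reaction times to seconds on read;
    otherwise millisecond-looking values raise a :class:`TrialTableError`.
    """
    if rt_unit not in ("s", "ms"):
        raise ValueError(f"rt_unit must be 's' or 'ms', got {rt_unit!r}")
    df = pd.read_csv(path)
    df = validate_trial_table(df)
    if rt_unit == "ms":
        df["rt"] = df["rt"] / 1000.0
    elif df["rt"].median() > MS_HEURISTIC_THRESHOLD:
        raise TrialTableError(
            f"median rt is {df['rt'].median():g} s — this looks like "
            f"milliseconds; re-read with rt_unit='ms' to convert"
        )
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (full float precision, round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_summary_tables(seq_summary: pd.DataFrame,
                         triplet_summary: pd.DataFrame, out_dir) -> dict:
    """Write the per-sequence and error-triplet summary CSVs.

    Column headers carry units (seconds / fraction).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq = seq_summary.rename(columns={
        "rt_mean": "rt_mean_s", "rt_correct": "rt_correct_s",
        "rt_error": "rt_error_s", "er": "er_fraction",
    })
    trip = triplet_summary.rename(columns={
        "rt_pre_error": "rt_pre_error_s", "rt_on_error": "rt_on_error_s",
        "rt_post_error": "rt_post_error_s",
    })
    paths = {
        "sequence_summary": out_dir / "sequence_summary.csv",
        "error_triplets": out_dir / "error_triplets.csv",
    }
    seq.to_csv(paths["sequence_summary"])
    trip.to_csv(paths["error_triplets"])
    return paths


def write_fit_result(fit_result, path) -> None:
    """Serialize a :class:`seqddm.fit.FitResult` as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _clean(v):
        if isinstance(v, float) and not np.isfinite(v):
            return str(v)
        return v

    d = fit_result.to_dict()
    d = {k: ({kk: _clean(vv) for kk, vv in v.items()}
             if isinstance(v, dict) else _clean(v))
         for k, v in d.items()}
    path.write_text(json.dumps(d, indent=2) + "\n")


def read_fit_result(path) -> dict:
    return json.loads(Path(path).read_text())
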
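"""Regeneration time-course expression: normalization, phase calls, 2^-ddCt.

Genes x timepoints FPKM matrices are normalized for heatmaps
(log2(FPKM + 1), per-gene z-score) and each trajectory is classified into a
descriptive regeneration phase by the timing of its first >= 2-fold change
relative to the pre-amputation baseline:

* wound_response   - changes within the early window (<= 6 h);
* proliferative    - changes in the mid window (6 h - 4 d) and stays changed;
* late_arrested    - rises in the mid window but returns to baseline in the
                     late window (> 4 d);
* differentiation  - changes only in the late window;
* flat             - never crosses the threshold.

The phase boundaries are explicit, configurable operationalizations of
narrative heatmap readings; they are validated against synthetic truth only.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PHASES = ("wound_response", "proliferative", "differentiation", "late_arrested", "flat")


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseCall:
    gene: str
    phase: str
    change_scores: tuple[float, float, float]  # max |log2FC| per window


@dataclass(frozen=True)
class DdCtInput:
    """Ct values for the 2^-ddCt relative quantification."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        vals = (
            self.ct_target_treated, self.ct_reference_treated,
            self.ct_target_control, self.ct_reference_control,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ExpressionError("Ct values must be finite")
        if any(not (1.0 <= v <= 45.0) for v in vals):
            warnings.warn("Ct value outside the typical [1, 45] cycle range")


# ---------------------------------------------------------------------------
# matrix I/O ("h<hours>" column headers)

_HOUR_RE = re.compile(r"^h(\d+(?:\.\d+)?)$")


def read_fpkm_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x timepoints FPKM matrix from TSV with 'h<hours>' headers.

    Duplicate timepoint columns (replicates) are averaged.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    hours = []
    for c in header[1:]:  # pandas would mangle duplicate replicate headers
        m = _HOUR_RE.match(c.strip())
        if not m:
            raise ExpressionError(f"{path}: column {c!r} is not an 'h<hours>' header")
        hours.append(float(m.group(1)))
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=1, header=None)
    df.index.name = header[0]
    df.columns = hours
    df = df.T.groupby(level=0).mean().T  # average replicate columns
    df = df[sorted(df.columns)]
    validate_matrix(df)
    return df


def write_fpkm_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.columns = [f"h{g:g}" for g in out.columns]
    out.rename_axis("gene_id").to_csv(path, sep="\t")


def validate_matrix(matrix: pd.DataFrame) -> None:
    if (matrix.values < 0).any():
        raise ExpressionError("FPKM values must be nonnegative")
    cols = list(matrix.columns)
    if cols != sorted(cols) or len(set(cols)) != len(cols):
        raise ExpressionError("timepoints must be strictly increasing")


# ---------------------------------------------------------------------------
# operations


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1) then per-gene z-score; zero-variance genes -> all zeros."""
    validate_matrix(matrix)
    logged = np.log2(matrix.astype(float) + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    z = logged.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def classify_pattern(
    row: Sequence[float] | pd.Series,
    timepoints: Sequence[float] | None = None,
    early_cut: float = 6.0,
    mid_cut: float = 96.0,
    fc_threshold: float = 1.0,
    gene: str = "",
    pseudocount: float = 1.0,
) -> PhaseCall:
    """Assign a regeneration phase from log2 fold changes vs the t=0 baseline.

    Fold changes use a pseudocount: log2((v + 1) / (v0 + 1)). Windows are
    (0, early_cut], (early_cut, mid_cut], (mid_cut, inf); each must contain
    at least one timepoint, and t=0 must be present.
    """
    if isinstance(row, pd.Series):
        timepoints = [float(t) for t in row.index] if timepoints is None else list(timepoints)
        values = row.values.astype(float)
        gene = gene or str(row.name)
    else:
        if timepoints is None:
            raise ExpressionError("timepoints required when row is not a Series")
        values = np.asarray(row, dtype=float)
        timepoints = [float(t) for t in timepoints]
    if len(values) != len(timepoints):
        raise ExpressionError("row and timepoints length mismatch")
    if 0.0 not in timepoints:
        raise ExpressionError("baseline timepoint t=0 missing")
    v0 = values[timepoints.index(0.0)]
    fc = {
        t: float(np.log2((v + pseudocount) / (v0 + pseudocount)))
        for t, v in zip(timepoints, values)
        if t > 0
    }
    win = (
        [abs(fc[t]) for t in fc if 0 < t <= early_cut],
        [abs(fc[t]) for t in fc if early_cut < t <= mid_cut],
        [abs(fc[t]) for t in fc if t > mid_cut],
    )
    if any(not w for w in win):
        raise ExpressionError(
            "row must have at least one timepoint in each of the early/mid/late windows"
        )
    early, mid, late = (max(w) for w in win)
    if early >= fc_threshold:
        phase = "wound_response"
    elif mid >= fc_threshold and late <= fc_threshold / 2:
        phase = "late_arrested"
    elif mid >= fc_threshold:
        phase = "proliferative"
    elif late >= fc_threshold:
        phase = "differentiation"
    else:
        phase = "flat"
    return PhaseCall(gene=gene, phase=phase, change_scores=(early, mid, late))


def classify_matrix(
    matrix: pd.DataFrame,
    early_cut: float = 6.0,
    mid_cut: float = 96.0,
    fc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Phase calls for every gene of an FPKM matrix, as a DataFrame."""
    validate_matrix(matrix)
    calls = [
        classify_pattern(matrix.loc[g], early_cut=early_cut, mid_cut=mid_cut,
                         fc_threshold=fc_threshold, gene=str(g))
        for g in matrix.index
    ]
    return pd.DataFrame(
        {
            "gene_id": [c.gene for c in calls],
            "phase": [c.phase for c in calls],
            "early_change": [c.change_scores[0] for c in calls],
            "mid_change": [c.change_scores[1] for c in calls],
            "late_change": [c.change_scores[2] for c in calls],
        }
    ).set_index("gene_id")


def delta_delta_ct(x: DdCtInput) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).
    """
    ddct = (x.ct_target_treated - x.ct_reference_treated) - (
        x.ct_target_control - x.ct_reference_control
    )
    return float(2.0 ** (-ddct))
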
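"""Replay of the published confusion-matrix cells.

The source study prints, for every analysis cell (rule a-e and bands x/y, by
tool and gene scope), the full TP/FN/FP/TN confusion matrix alongside the
positive likelihood ratio and its 95% CI.  Those integers are shipped here as
a plain-text fixture, making the headline numbers reproducible from the LR
engine alone: correct each matrix, recompute pLR and CI, and compare with the
printed values at 1-decimal precision.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .evaluate import ConfusionMatrix, haldane_anscombe, positive_lr

FIXTURE = "published_confusion_cells.tsv"


def load_published_cells() -> pd.DataFrame:
    """The published per-cell confusion matrices with their printed pLR / CI."""
    text = resources.files("pm5calib.data").joinpath(FIXTURE).read_text()
    return pd.read_csv(StringIO(text), sep="\t")


def published_cell(analysis: str, rule: str, tool: str, scope: str) -> ConfusionMatrix:
    """The uncorrected confusion matrix of one published analysis cell."""
    cells = load_published_cells()
    match = cells[
        (cells["analysis"] == analysis)
        & (cells["rule"] == rule)
        & (cells["tool"] == tool)
        & (cells["scope"] == scope)
    ]
    if len(match) != 1:
        raise KeyError(f"no unique cell for {analysis}/{rule}/{tool}/{scope}")
    row = match.iloc[0]
    return ConfusionMatrix(int(row.tp), int(row.fn), int(row.fp), int(row.tn))


def replay_goldens() -> pd.DataFrame:
    """Recompute pLR and CI for every published cell and compare with print.

    Returns the fixture frame with recomputed columns and a boolean ``match``
    that is True when estimate and both CI bounds agree to 1 decimal.
    """
    cells = load_published_cells().copy()
    recomputed = []
    for row in cells.itertuples():
        cm = haldane_anscombe(ConfusionMatrix(row.tp, row.fn, row.fp, row.tn))
        recomputed.append(positive_lr(cm).rounded())
    cells[["plr_recomputed", "ci_low_recomputed", "ci_high_recomputed"]] = recomputed
    cells["match"] = (
        (cells["plr"] == cells["plr_recomputed"])
        & (cells["ci_low"] == cells["ci_low_recomputed"])
        & (cells["ci_high"] == cells["ci_high_recomputed"])
    )
    return cells
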
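"""Confusion matrices and likelihood ratios per scope, rule and tool.

Produces the synthetic analogue of the study's binary and banded result
tables, per gene and combined.  Run 03 first.
"""

from pathlib import Path

import pandas as pd

from pm5calib.evaluate import evaluate_all
from pm5calib.model import write_results_table

OUT = Path(__file__).resolve().parent.parent / "results"

predictions = pd.read_csv(OUT / "predictions.tsv", sep="\t")
results = evaluate_all(predictions)
binary = results[~results["analysis"].str.startswith("band_")]
banded = results[results["analysis"].str.startswith("band_")]
write_results_table(binary.to_dict("records"), OUT / "results_binary.tsv")
write_results_table(banded.to_dict("records"), OUT / "results_banded.tsv")

show = ["analysis", "tool", "tp", "fn", "fp", "tn", "plr", "strength"]
combined = results[results["scope"] == "combined"]
print("combined-scope likelihood ratios:")
print(combined[show].round({"plr": 1}).to_string(index=False))
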
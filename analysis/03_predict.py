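"""PM5 predictions for rules a-e and band assignments on the eligible cohort.

Clinical labels serve as the lookup source and the functional classes as the
reference truthset (the primary approach).  The comparison tools are the
generated meta-predictor scores plus the internally computed BLOSUM62 and
Grantham distances.  Run 02 first.
"""

from pathlib import Path

from pm5calib.engine import run_predictions
from pm5calib.insilico import annotate_physiochemical
from pm5calib.model import read_variant_table
from pm5calib.pipeline import RunConfig, _expand_definitions

OUT = Path(__file__).resolve().parent.parent / "results"
TOOLS = ("BLOSUM62", "Grantham", "REVEL", "Meta-SNP", "CADD")

cohort = annotate_physiochemical(read_variant_table(OUT / "eligible_cohort.tsv"))
config = RunConfig(variants=str(OUT / "eligible_cohort.tsv"), tools=TOOLS)
predictions = run_predictions(
    cohort, "CLINVAR", "MAVE", _expand_definitions(config), band_tools=TOOLS
)
predictions.to_csv(OUT / "predictions.tsv", sep="\t", index=False)

binary = predictions[predictions["kind"] == "definition"]
n_del = binary[binary["prediction"] == "DEL"].groupby("definition").size()
print(f"wrote {len(predictions)} prediction rows")
print("DEL calls by rule (any tool):")
print(n_del.to_string())
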
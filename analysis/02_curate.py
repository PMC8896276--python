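"""Apply the eligibility filters to the synthetic cohort.

Keeps missense, non-initiator, non-para-splice-site substitutions with a
dichotomous functional class, and reports how many records each filter
removed.  Run 01 first.
"""

from pathlib import Path

from pm5calib.curation import curate_cohort
from pm5calib.model import read_variant_table, write_run_summary, write_variant_table

OUT = Path(__file__).resolve().parent.parent / "results"

cohort = read_variant_table(OUT / "synthetic_cohort.tsv")
eligible, report = curate_cohort(cohort)
write_variant_table(eligible, OUT / "eligible_cohort.tsv")
write_run_summary(report.as_dict(), OUT / "curation_report.json")

print(f"{report.n_eligible}/{report.n_input} records eligible")
for reason, count in report.exclusions.items():
    print(f"  excluded {count:4d}  {reason}")
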
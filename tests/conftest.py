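from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from pm5calib.model import (  # noqa: E402
    ClinicalRaw,
    Cohort,
    FunctionalClass,
    SpliceogenicRna,
    VariantRecord,
)


def make_record(
    gene="G1",
    codon=10,
    ref="A",
    alt="V",
    functional="TOL",
    clinical="MISSING",
    stars=0,
    tools=None,
    **kwargs,
):
    """Terse VariantRecord factory for hand-built fixtures."""
    return VariantRecord(
        gene_id=gene,
        codon_index=codon,
        ref_aa=ref,
        alt_aa=alt,
        functional_class=FunctionalClass(functional),
        clinical_raw=ClinicalRaw(clinical),
        clinvar_stars=stars,
        tool_scores=dict(tools or {}),
        **kwargs,
    )


@pytest.fixture
def toy_cohort():
    """Three codons: one mixed, one DEL-only, one TOL-only."""
    return Cohort(
        [
            make_record(codon=10, ref="A", alt="V", functional="DEL", clinical="P", stars=2),
            make_record(codon=10, ref="A", alt="D", functional="TOL"),
            make_record(codon=10, ref="A", alt="G", functional="DEL", clinical="LP", stars=1),
            make_record(codon=20, ref="R", alt="W", functional="DEL", clinical="P", stars=1),
            make_record(codon=20, ref="R", alt="Q", functional="DEL"),
            make_record(codon=30, ref="L", alt="F", functional="TOL", clinical="B", stars=1),
        ]
    )


__all__ = ["make_record", "ClinicalRaw", "FunctionalClass", "SpliceogenicRna"]
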
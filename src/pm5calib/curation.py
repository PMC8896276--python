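"""Eligibility filters and dichotomization of functional / clinical classes.

A record enters the dichotomous analysis only if it is a missense change away
from the initiator codon, not at a para-splice-site position (the 2 exonic
bases flanking an intron-exon boundary), and carries a dichotomous functional
class (DEL or TOL; intermediate or absent assay output is excluded).  Clinical
classes dichotomize to DEL for P/LP and TOL for B/LB, both gated on a >= 1-star
review status; uncertain, conflicting or unrated entries count as missing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ValidationError
from .model import (
    AMINO_ACIDS,
    STOP,
    ClinicalRaw,
    Cohort,
    ExonModel,
    FunctionalClass,
    SpliceogenicRna,
)


class Consequence(str, enum.Enum):
    MISSENSE = "MISSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    NONSENSE = "NONSENSE"
    INITIATION = "INITIATION"


class Dichotomous(str, enum.Enum):
    DEL = "DEL"
    TOL = "TOL"
    EXCLUDE = "EXCLUDE"
    MISSING = "MISSING"


#: exclusion reasons in precedence order (first matching reason is reported)
EXCLUSION_REASONS = (
    "non_missense",
    "initiation_codon",
    "para_splice_site",
    "intermediate_assay",
    "spliceogenic_sensitivity",
)


@dataclass
class CurationReport:
    n_input: int = 0
    n_eligible: int = 0
    exclusions: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "exclusions": dict(self.exclusions),
            "warnings": list(self.warnings),
        }


def classify_consequence(ref_aa: str, alt_aa: str, codon_index: int) -> Consequence:
    """Consequence class of a single-residue change.

    The initiator codon takes precedence: any change at codon 1 is an
    initiation-codon variant regardless of the residues involved.
    """
    for aa in (ref_aa, alt_aa):
        if aa not in AMINO_ACIDS and aa != STOP:
            raise ValidationError(f"unknown amino-acid code {aa!r}")
    if codon_index == 1:
        return Consequence.INITIATION
    if alt_aa == STOP:
        return Consequence.NONSENSE
    if ref_aa == alt_aa:
        return Consequence.SYNONYMOUS
    return Consequence.MISSENSE


def flag_para_splice_site(
    cds_pos: int, exons: ExonModel, flag_terminal: bool = False
) -> bool:
    """True if ``cds_pos`` lies in the 2 bases at an exon edge facing an intron.

    By default the outermost edges of the first and last exon are NOT flagged:
    they abut untranslated sequence, not an intron.  ``flag_terminal=True``
    flags every exon edge.
    """
    i = exons.exon_index(cds_pos)
    start, end = exons.exons[i]
    near_start = cds_pos - start < 2
    near_end = end - cds_pos < 2
    if not flag_terminal:
        if i == 0:
            near_start = False
        if i == len(exons.exons) - 1:
            near_end = False
    return near_start or near_end


def dichotomize_functional(functional_class: FunctionalClass) -> Dichotomous:
    if functional_class is FunctionalClass.DEL:
        return Dichotomous.DEL
    if functional_class is FunctionalClass.TOL:
        return Dichotomous.TOL
    return Dichotomous.EXCLUDE


def dichotomize_clinical(clinical_raw: ClinicalRaw, stars: int) -> Dichotomous:
    if stars >= 1:
        if clinical_raw in (ClinicalRaw.P, ClinicalRaw.LP):
            return Dichotomous.DEL
        if clinical_raw in (ClinicalRaw.B, ClinicalRaw.LB):
            return Dichotomous.TOL
    return Dichotomous.MISSING


def _exclusion_reason(record, exons, drop_spliceogenic, flag_terminal):
    """First matching exclusion reason for a record, or None if eligible."""
    consequence = classify_consequence(
        record.ref_aa, record.alt_aa, record.codon_index
    )
    if consequence in (Consequence.SYNONYMOUS, Consequence.NONSENSE):
        return "non_missense"
    if consequence is Consequence.INITIATION:
        return "initiation_codon"
    para = record.para_splice_site
    if exons is not None and record.cds_pos is not None:
        para = para or flag_para_splice_site(record.cds_pos, exons, flag_terminal)
    if para:
        return "para_splice_site"
    if dichotomize_functional(record.functional_class) is Dichotomous.EXCLUDE:
        return "intermediate_assay"
    if drop_spliceogenic and record.spliceogenic_rna in (
        SpliceogenicRna.INTERMEDIATE,
        SpliceogenicRna.DEPLETED,
    ):
        return "spliceogenic_sensitivity"
    return None


def curate_cohort(
    cohort: Cohort,
    exons: ExonModel | None = None,
    drop_spliceogenic: bool = False,
    flag_terminal: bool = False,
) -> tuple:
    """Apply the eligibility filters; return (eligible cohort, report).

    Nucleotide-level duplicates of one substitution are collapsed first, so the
    eligible cohort contains one record per amino-acid substitution.  The
    filters are independent predicates; the precedence order of
    :data:`EXCLUSION_REASONS` affects only which reason a multiply-excluded
    record is attributed to.
    """
    collapsed, warnings = cohort.collapse_substitutions()
    report = CurationReport(n_input=len(collapsed), warnings=warnings)
    eligible = []
    for record in collapsed:
        reason = _exclusion_reason(record, exons, drop_spliceogenic, flag_terminal)
        if reason is None:
            eligible.append(record)
        else:
            report.exclusions[reason] = report.exclusions.get(reason, 0) + 1
    report.n_eligible = len(eligible)
    assert report.n_input == report.n_eligible + sum(report.exclusions.values())
    return Cohort(eligible), report
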
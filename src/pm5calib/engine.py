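"""Graded PM5 predictions over codon-colocated deleterious variants.

The within-codon concordance (PM5) rule predicts a missense variant to be
deleterious when other substitutions at the same codon are already established
as deleterious.  Five rule stringencies are assessed:

====  =======================  =============================================
rule  colocated DEL required   in-silico comparison required
====  =======================  =============================================
a     >= 1                     none
b     >= 2                     none
c     >= 1                     equal-or-more damaging than >= 1 colocated
d     >= 2                     equal-or-more damaging than >= 1 colocated
e     >= 2                     equal-or-more damaging than >= 2 colocated
====  =======================  =============================================

The banded (mutually exclusive) strata are: band x = exactly one colocated
DEL and the comparison met against it; band y = two or more colocated DEL and
the comparison met against at least one; baseline = everything else.

Colocated references are counted per distinct amino-acid substitution, always
excluding the substitution under examination (leave-one-out), so a variant can
never be its own evidence when lookup and truth share a source.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .curation import Dichotomous, dichotomize_clinical, dichotomize_functional
from .errors import ConfigurationError
from .insilico import DEFAULT_TOOL_REGISTRY, is_equally_or_more_damaging
from .model import Cohort, VariantRecord


class Source(str, enum.Enum):
    CLINVAR = "CLINVAR"
    MAVE = "MAVE"


#: (lookup, truth) combinations with an analysis interpretation
SUPPORTED_APPROACHES = {
    (Source.CLINVAR, Source.MAVE): "primary",
    (Source.MAVE, Source.MAVE): "additional_approach_1",
    (Source.CLINVAR, Source.CLINVAR): "additional_approach_2",
}


class DefinitionId(str, enum.Enum):
    A = "a"
    B = "b"
    C = "c"
    D = "d"
    E = "e"


class Comparison(str, enum.Enum):
    NONE = "NONE"
    GE_ONE = "GE_ONE"
    GE_TWO = "GE_TWO"


_DEFINITION_SHAPES = {
    DefinitionId.A: (1, Comparison.NONE),
    DefinitionId.B: (2, Comparison.NONE),
    DefinitionId.C: (1, Comparison.GE_ONE),
    DefinitionId.D: (2, Comparison.GE_ONE),
    DefinitionId.E: (2, Comparison.GE_TWO),
}


@dataclass(frozen=True)
class Pm5Definition:
    id: DefinitionId
    min_colocated_del: int
    comparison: Comparison
    tool: Optional[str] = None

    def __post_init__(self):
        if self.comparison is not Comparison.NONE and self.tool is None:
            raise ConfigurationError(
                f"definition {self.id.value} needs a comparison tool"
            )


def definition(id: str | DefinitionId, tool: Optional[str] = None) -> Pm5Definition:
    """Build one of the five standard rule stringencies."""
    did = DefinitionId(id)
    min_del, comparison = _DEFINITION_SHAPES[did]
    if comparison is Comparison.NONE:
        tool = None
    return Pm5Definition(did, min_del, comparison, tool)


class Band(str, enum.Enum):
    X = "x"
    Y = "y"
    BASELINE = "baseline"


@dataclass
class BandAssignment:
    band: Band
    n_colocated_del: int
    n_comparisons_met: int


@dataclass
class LookupSet:
    """Reference DEL substitutions per (gene, codon) from one label source."""

    source: Source
    del_substitutions: dict = field(default_factory=dict)

    @classmethod
    def build(cls, cohort: Cohort, source: Source) -> "LookupSet":
        table: dict = {}
        for record in cohort:
            if truth_label(record, source) is Dichotomous.DEL:
                table.setdefault((record.gene_id, record.codon_index), []).append(record)
        return cls(source=source, del_substitutions=table)


def truth_label(record: VariantRecord, source: Source) -> Dichotomous:
    """Dichotomous label of a record under the given source, or MISSING/EXCLUDE."""
    if source is Source.MAVE:
        return dichotomize_functional(record.functional_class)
    return dichotomize_clinical(record.clinical_raw, record.clinvar_stars)


def colocated_del(variant: VariantRecord, lookup: LookupSet) -> list:
    """Reference DEL substitutions at the variant's codon, leave-one-out.

    An entry with the same (ref_aa, alt_aa) as the variant under examination is
    removed: a recurrence of the identical substitution is same-residue
    evidence, not within-codon concordance.
    """
    at_codon = lookup.del_substitutions.get((variant.gene_id, variant.codon_index), [])
    return [
        ref
        for ref in at_codon
        if (ref.ref_aa, ref.alt_aa) != (variant.ref_aa, variant.alt_aa)
    ]


def _n_comparisons_met(variant, references, tool, registry) -> int:
    n = 0
    for ref in references:
        met = is_equally_or_more_damaging(
            tool,
            variant.tool_scores.get(tool),
            ref.tool_scores.get(tool),
            registry,
        )
        if met:  # None (missing) counts as not met
            n += 1
    return n


def predict(
    variant: VariantRecord,
    lookup: LookupSet,
    defn: Pm5Definition,
    registry: Optional[dict] = None,
) -> Dichotomous:
    """DEL if the variant meets the rule's conditions against the lookup, else TOL."""
    registry = registry if registry is not None else DEFAULT_TOOL_REGISTRY
    references = colocated_del(variant, lookup)
    if len(references) < defn.min_colocated_del:
        return Dichotomous.TOL
    if defn.comparison is Comparison.NONE:
        return Dichotomous.DEL
    met = _n_comparisons_met(variant, references, defn.tool, registry)
    needed = 1 if defn.comparison is Comparison.GE_ONE else 2
    return Dichotomous.DEL if met >= needed else Dichotomous.TOL


def assign_band(
    variant: VariantRecord,
    lookup: LookupSet,
    tool: str,
    registry: Optional[dict] = None,
) -> BandAssignment:
    """Mutually exclusive, exhaustive stratum of the variant for one tool."""
    registry = registry if registry is not None else DEFAULT_TOOL_REGISTRY
    references = colocated_del(variant, lookup)
    met = _n_comparisons_met(variant, references, tool, registry)
    if len(references) == 1 and met == 1:
        band = Band.X
    elif len(references) >= 2 and met >= 1:
        band = Band.Y
    else:
        band = Band.BASELINE
    return BandAssignment(band=band, n_colocated_del=len(references), n_comparisons_met=met)


def run_predictions(
    cohort: Cohort,
    lookup_source: Source | str,
    truth_source: Source | str,
    definitions: Iterable[Pm5Definition],
    band_tools: Sequence[str] = (),
    registry: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-variant predictions for every rule, plus band assignments per tool.

    Returns one row per eligible variant x (definition or band tool) with
    columns gene, codon, substitution, kind ("definition"/"band"), definition,
    tool, n_colocated_del, n_met, prediction, band, truth.  Variants without a
    dichotomous truth label are excluded.
    """
    lookup_source = Source(lookup_source)
    truth_source = Source(truth_source)
    if (lookup_source, truth_source) not in SUPPORTED_APPROACHES:
        raise ConfigurationError(
            f"unsupported lookup/truth combination "
            f"{lookup_source.value}/{truth_source.value}"
        )
    registry = registry if registry is not None else DEFAULT_TOOL_REGISTRY
    lookup = LookupSet.build(cohort, lookup_source)
    rows = []
    for variant in cohort:
        truth = truth_label(variant, truth_source)
        if truth not in (Dichotomous.DEL, Dichotomous.TOL):
            continue
        base = {
            "gene": variant.gene_id,
            "codon": variant.codon_index,
            "substitution": variant.label,
            "truth": truth.value,
        }
        for defn in definitions:
            references = colocated_del(variant, lookup)
            rows.append(
                {
                    **base,
                    "kind": "definition",
                    "definition": defn.id.value,
                    "tool": defn.tool or "-",
                    "n_colocated_del": len(references),
                    "n_met": (
                        _n_comparisons_met(variant, references, defn.tool, registry)
                        if defn.tool
                        else None
                    ),
                    "prediction": predict(variant, lookup, defn, registry).value,
                    "band": None,
                }
            )
        for tool in band_tools:
            assignment = assign_band(variant, lookup, tool, registry)
            rows.append(
                {
                    **base,
                    "kind": "band",
                    "definition": None,
                    "tool": tool,
                    "n_colocated_del": assignment.n_colocated_del,
                    "n_met": assignment.n_comparisons_met,
                    "prediction": None,
                    "band": assignment.band.value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "codon",
            "substitution",
            "kind",
            "definition",
            "tool",
            "n_colocated_del",
            "n_met",
            "prediction",
            "band",
            "truth",
        ],
    )
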
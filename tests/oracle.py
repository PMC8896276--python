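"""Brute-force reference implementations, independent of the package engine.

These scan the raw record list directly (no LookupSet, no shared helpers) so
engine regressions cannot hide in shared code.
"""

from __future__ import annotations

from pm5calib.curation import dichotomize_clinical, dichotomize_functional


def _is_del(record, source):
    if source == "MAVE":
        return dichotomize_functional(record.functional_class).value == "DEL"
    return dichotomize_clinical(record.clinical_raw, record.clinvar_stars).value == "DEL"


def _more_damaging(tool, exam, ref):
    if exam is None or ref is None:
        return False
    if tool.startswith("BLOSUM"):
        return exam <= ref
    if tool == "aGVGD":
        order = ["C0", "C15", "C25", "C35", "C45", "C55", "C65"]
        return order.index(exam) >= order.index(ref)
    return exam >= ref


def brute_force_predict(variant, records, lookup_source, min_del, n_met_required, tool):
    """DEL/TOL by direct enumeration over all records."""
    colocated = [
        r
        for r in records
        if r.gene_id == variant.gene_id
        and r.codon_index == variant.codon_index
        and (r.ref_aa, r.alt_aa) != (variant.ref_aa, variant.alt_aa)
        and _is_del(r, lookup_source)
    ]
    if len(colocated) < min_del:
        return "TOL"
    if n_met_required == 0:
        return "DEL"
    met = sum(
        _more_damaging(tool, variant.tool_scores.get(tool), r.tool_scores.get(tool))
        for r in colocated
    )
    return "DEL" if met >= n_met_required else "TOL"


def brute_force_band(variant, records, lookup_source, tool):
    colocated = [
        r
        for r in records
        if r.gene_id == variant.gene_id
        and r.codon_index == variant.codon_index
        and (r.ref_aa, r.alt_aa) != (variant.ref_aa, variant.alt_aa)
        and _is_del(r, lookup_source)
    ]
    met = sum(
        _more_damaging(tool, variant.tool_scores.get(tool), r.tool_scores.get(tool))
        for r in colocated
    )
    if len(colocated) == 1 and met == 1:
        return "x"
    if len(colocated) >= 2 and met >= 1:
        return "y"
    return "baseline"
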
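"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a saturation-assay variant table: codons drawn as
deleterious-only, mixed, or tolerated-only; several distinct substitutions per
codon; a dichotomous functional class per variant; sparse, deleterious-biased
clinical labels with a small error rate; and per-tool scores equal to a latent
damage signal plus Gaussian noise, so in-silico comparisons are informative to
a degree set by the noise standard deviation.

Defaults mirror the scale of the study cohort the pipeline was built around:
~1229 codons carrying ~7.5k substitutions, ~1.9% DEL-only / 27.9% mixed /
70.2% TOL-only codons, clinical labels on ~19% of deleterious and ~0.7% of
tolerated variants.  What the generator deliberately does not emulate: real
score distributions of any tool, linkage between para-splice-site position
and assay readout, and gene-specific codon architecture.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError
from .model import (
    AMINO_ACIDS,
    ClinicalRaw,
    Cohort,
    ExonModel,
    FunctionalClass,
    SpliceogenicRna,
    VariantRecord,
)

_AAS = sorted(AMINO_ACIDS)
_NT = "ACGT"


class CohortConfig(BaseModel):
    """Generator parameters; probabilities in [0, 1]."""

    n_codons: int = Field(default=1229, ge=1)
    codon_class_mix: Tuple[float, float, float] = (0.019, 0.279, 0.702)
    variants_per_codon: Tuple[int, int] = (3, 9)
    p_del_within_mixed: float = Field(default=0.3, ge=0, le=1)
    p_clinical_label_given_del: float = Field(default=0.19, ge=0, le=1)
    p_clinical_label_given_tol: float = Field(default=0.0074, ge=0, le=1)
    clinical_error_rate: float = Field(default=0.02, ge=0, le=1)
    tool_noise_sd: float = Field(default=0.5, ge=0)
    p_para_splice: float = Field(default=0.05, ge=0, le=1)
    p_spliceogenic: float = Field(default=0.017, ge=0, le=1)
    p_intermediate_assay: float = Field(default=0.0, ge=0, le=1)
    gene_id: str = "SYN1"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if abs(sum(self.codon_class_mix) - 1.0) > 1e-9:
            raise ValueError("codon_class_mix must sum to 1")
        if any(p < 0 for p in self.codon_class_mix):
            raise ValueError("codon_class_mix probabilities must be >= 0")
        lo, hi = self.variants_per_codon
        if not (1 <= lo <= hi <= 9):
            raise ValueError("variants_per_codon must lie within 1..9")
        return self


#: tools whose scores the generator draws from the latent damage signal
GENERATED_TOOLS = ("REVEL", "Meta-SNP", "CADD")


def _clinical(rng, truth_del: bool, config) -> tuple:
    p_label = (
        config.p_clinical_label_given_del
        if truth_del
        else config.p_clinical_label_given_tol
    )
    if rng.random() >= p_label:
        return ClinicalRaw.MISSING, 0
    correct = rng.random() >= config.clinical_error_rate
    as_del = truth_del if correct else not truth_del
    if as_del:
        label = ClinicalRaw.P if rng.random() < 0.5 else ClinicalRaw.LP
    else:
        label = ClinicalRaw.B if rng.random() < 0.5 else ClinicalRaw.LB
    return label, int(rng.integers(1, 4))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Deterministic synthetic cohort for a fixed config (one RNG stream)."""
    rng = np.random.default_rng(config.seed)
    records = []
    lo, hi = config.variants_per_codon
    # codon 1 is skipped: the initiator codon is never an eligible missense site
    for codon in range(2, config.n_codons + 2):
        codon_class = rng.choice(3, p=config.codon_class_mix)  # 0 del, 1 mixed, 2 tol
        n_var = int(rng.integers(lo, hi + 1))
        ref_aa = _AAS[rng.integers(len(_AAS))]
        alts = rng.choice(
            [a for a in _AAS if a != ref_aa], size=n_var, replace=False
        )
        if codon_class == 0:
            truth_del = np.ones(n_var, bool)
        elif codon_class == 2:
            truth_del = np.zeros(n_var, bool)
        elif n_var == 1:
            truth_del = rng.random(1) < config.p_del_within_mixed
        else:  # mixed codons with >= 2 variants carry both classes
            while True:
                truth_del = rng.random(n_var) < config.p_del_within_mixed
                if 0 < truth_del.sum() < n_var:
                    break
        for alt_aa, is_del in zip(alts, truth_del):
            damage = 1.0 if is_del else 0.0
            tool_scores = {
                tool: float(damage + rng.normal(0.0, config.tool_noise_sd))
                for tool in GENERATED_TOOLS
            }
            functional = FunctionalClass.DEL if is_del else FunctionalClass.TOL
            if rng.random() < config.p_intermediate_assay:
                functional = FunctionalClass.INTERMEDIATE
            clinical, stars = _clinical(rng, bool(is_del), config)
            offset = int(rng.integers(3))
            ref_nt, alt_nt = rng.choice(list(_NT), size=2, replace=False)
            splice = SpliceogenicRna.NONE
            if rng.random() < config.p_spliceogenic:
                splice = (
                    SpliceogenicRna.INTERMEDIATE
                    if rng.random() < 0.5
                    else SpliceogenicRna.DEPLETED
                )
            records.append(
                VariantRecord(
                    gene_id=config.gene_id,
                    transcript_id=f"{config.gene_id}-tx",
                    cds_pos=3 * (codon - 1) + 1 + offset,
                    codon_index=codon,
                    ref_aa=ref_aa,
                    alt_aa=str(alt_aa),
                    nt_change=f"{ref_nt}>{alt_nt}",
                    functional_class=functional,
                    functional_score=float(damage + rng.normal(0.0, config.tool_noise_sd)),
                    clinical_raw=clinical,
                    clinvar_stars=stars,
                    tool_scores=tool_scores,
                    para_splice_site=bool(rng.random() < config.p_para_splice),
                    spliceogenic_rna=splice,
                )
            )
    return Cohort(records)


def count_codon_types(cohort: Cohort) -> tuple:
    """(del_only, mixed, tol_only) over codons with >= 1 dichotomous variant."""
    del_only = mixed = tol_only = 0
    for members in cohort.index.values():
        classes = {
            m.functional_class
            for m in members
            if m.functional_class in (FunctionalClass.DEL, FunctionalClass.TOL)
        }
        if not classes:
            continue
        if classes == {FunctionalClass.DEL}:
            del_only += 1
        elif classes == {FunctionalClass.TOL}:
            tol_only += 1
        else:
            mixed += 1
    return del_only, mixed, tol_only


def shuffle_null(cohort: Cohort, seed: int) -> Cohort:
    """Permute functional labels across variants, destroying codon clustering.

    Marginal DEL/TOL counts are preserved; every other field stays with its
    record, so any association between codon structure (or clinical labels)
    and the permuted truth is broken — the null under which PM5 lookup carries
    no information.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort.records))
    shuffled = [
        replace(
            rec,
            functional_class=cohort.records[j].functional_class,
            functional_score=cohort.records[j].functional_score,
        )
        for rec, j in zip(cohort.records, order)
    ]
    return Cohort(shuffled)


def synthetic_exon_model(
    n_codons: int, n_exons: int = 10, transcript_id: str = "SYN1-tx"
) -> ExonModel:
    """Contiguous exon intervals covering the CDS of a generated cohort."""
    length = 3 * (n_codons + 1)
    if n_exons < 1 or n_exons > length:
        raise ValidationError("n_exons must be between 1 and the CDS length")
    bounds = np.linspace(0, length, n_exons + 1, dtype=int)
    exons = tuple(
        (int(bounds[i]) + 1, int(bounds[i + 1])) for i in range(n_exons)
    )
    return ExonModel(transcript_id=transcript_id, exons=exons)
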
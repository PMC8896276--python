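"""Physiochemical comparators and the "equally-or-more-damaging" predicate.

BLOSUM45/62/80 scores come from the published matrices shipped with
Biopython; the Grantham distance is computed here from the 1974 amino-acid
properties (composition, polarity, molecular volume) as

    D(a, b) = rho * [alpha*(c_a-c_b)^2 + beta*(p_a-p_b)^2 + gamma*(v_a-v_b)^2]^(1/2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho chosen so the mean
distance over the 190 unordered residue pairs is 100.  Distances are reported
rounded half-up to integers; a frozen copy of the full rounded matrix is
shipped as package data and cross-checked against the formula in the test
suite.  A few cells of historically typeset renditions of the matrix differ by
one unit from direct evaluation of the formula; this package uses the formula
as the single source of truth.

External predictors (REVEL, Meta-SNP, CADD, Align-GVGD) are consumed as input
annotations, never recomputed.  Each tool registers an orientation saying which
direction means "more damaging"; Align-GVGD compares ordered class labels
C0 < C15 < ... < C65.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional

from Bio.Align import substitution_matrices

from .errors import ConfigurationError, ValidationError
from .model import AMINO_ACIDS, Cohort

# --------------------------------------------------------------------------
# Grantham distance
# --------------------------------------------------------------------------

#: 1974 properties: composition, polarity, molecular volume
GRANTHAM_PROPERTIES = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.00, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.00, 8.1, 31.0),
    "V": (0.00, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.00, 5.2, 111.0),
    "F": (0.00, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.00, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

_ALPHA, _BETA, _GAMMA = 1.833, 0.1018, 0.000399


def _check_residue(aa: str) -> None:
    if aa not in AMINO_ACIDS:
        raise ValidationError(f"non-canonical residue {aa!r}")


def _grantham_unscaled(a: str, b: str) -> float:
    ca, pa, va = GRANTHAM_PROPERTIES[a]
    cb, pb, vb = GRANTHAM_PROPERTIES[b]
    return math.sqrt(
        _ALPHA * (ca - cb) ** 2 + _BETA * (pa - pb) ** 2 + _GAMMA * (va - vb) ** 2
    )


@lru_cache(maxsize=1)
def _grantham_rho() -> float:
    """Normalization making the mean pairwise distance exactly 100."""
    aas = sorted(GRANTHAM_PROPERTIES)
    total, n = 0.0, 0
    for i, a in enumerate(aas):
        for b in aas[i + 1 :]:
            total += _grantham_unscaled(a, b)
            n += 1
    return 100.0 * n / total


def grantham_distance(a: str, b: str) -> int:
    """Grantham physiochemical distance, rounded half-up to an integer."""
    _check_residue(a)
    _check_residue(b)
    if a == b:
        return 0
    return int(math.floor(_grantham_unscaled(a, b) * _grantham_rho() + 0.5))


@lru_cache(maxsize=1)
def grantham_matrix() -> dict:
    """The frozen integer matrix shipped as package data (symmetric, d(a,a)=0)."""
    text = resources.files("pm5calib.data").joinpath("grantham.tsv").read_text()
    lines = [ln.split("\t") for ln in text.splitlines() if ln]
    header = lines[0][1:]
    entries = {}
    for row in lines[1:]:
        a = row[0]
        for b, value in zip(header, row[1:]):
            entries[(a, b)] = int(value)
    return entries


# --------------------------------------------------------------------------
# BLOSUM matrices
# --------------------------------------------------------------------------

BLOSUM_NAMES = ("BLOSUM45", "BLOSUM62", "BLOSUM80")


@dataclass(frozen=True)
class SubstitutionMatrix:
    name: str
    entries: dict  # (aa, aa) -> int

    def score(self, a: str, b: str) -> int:
        return self.entries[(a, b)]


@lru_cache(maxsize=None)
def load_blosum(name: str) -> SubstitutionMatrix:
    if name not in BLOSUM_NAMES:
        raise ConfigurationError(f"unknown BLOSUM matrix {name!r}")
    published = substitution_matrices.load(name)
    entries = {
        (a, b): int(published[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
    }
    return SubstitutionMatrix(name=name, entries=entries)


def blosum_score(matrix_name: str, a: str, b: str) -> int:
    _check_residue(a)
    _check_residue(b)
    return load_blosum(matrix_name).score(a, b)


# --------------------------------------------------------------------------
# Tool orientations and the comparator
# --------------------------------------------------------------------------


class Direction(str, enum.Enum):
    HIGHER_IS_DAMAGING = "HIGHER_IS_DAMAGING"
    LOWER_IS_DAMAGING = "LOWER_IS_DAMAGING"
    ORDERED_CLASSES = "ORDERED_CLASSES"


@dataclass(frozen=True)
class ToolOrientation:
    tool: str
    direction: Direction
    class_order: tuple = ()

    def rank(self, label) -> int:
        try:
            return self.class_order.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown class label {label!r} for tool {self.tool}"
            ) from None


ALIGN_GVGD_CLASSES = ("C0", "C15", "C25", "C35", "C45", "C55", "C65")

DEFAULT_TOOL_REGISTRY = {
    "BLOSUM45": ToolOrientation("BLOSUM45", Direction.LOWER_IS_DAMAGING),
    "BLOSUM62": ToolOrientation("BLOSUM62", Direction.LOWER_IS_DAMAGING),
    "BLOSUM80": ToolOrientation("BLOSUM80", Direction.LOWER_IS_DAMAGING),
    "Grantham": ToolOrientation("Grantham", Direction.HIGHER_IS_DAMAGING),
    "REVEL": ToolOrientation("REVEL", Direction.HIGHER_IS_DAMAGING),
    "Meta-SNP": ToolOrientation("Meta-SNP", Direction.HIGHER_IS_DAMAGING),
    "CADD": ToolOrientation("CADD", Direction.HIGHER_IS_DAMAGING),
    "aGVGD": ToolOrientation(
        "aGVGD", Direction.ORDERED_CLASSES, ALIGN_GVGD_CLASSES
    ),
}

#: tools whose scores the package derives from the substitution itself
INTERNAL_TOOLS = ("BLOSUM45", "BLOSUM62", "BLOSUM80", "Grantham")


def is_equally_or_more_damaging(
    tool: str,
    score_exam,
    score_ref,
    registry: Optional[dict] = None,
) -> Optional[bool]:
    """Whether the examined score is at least as damaging as the reference.

    Ties count as met ("equal or more damaging").  Returns ``None`` when either
    score is missing; the prediction engine treats that as condition-not-met,
    which is conservative toward a TOL prediction.
    """
    registry = registry if registry is not None else DEFAULT_TOOL_REGISTRY
    try:
        orientation = registry[tool]
    except KeyError:
        raise ConfigurationError(f"no orientation registered for tool {tool!r}") from None
    if score_exam is None or score_ref is None:
        return None
    if orientation.direction is Direction.LOWER_IS_DAMAGING:
        return score_exam <= score_ref
    if orientation.direction is Direction.HIGHER_IS_DAMAGING:
        return score_exam >= score_ref
    return orientation.rank(score_exam) >= orientation.rank(score_ref)


def annotate_physiochemical(cohort: Cohort) -> Cohort:
    """Fill in the internally computed scores for every missense record.

    BLOSUM and Grantham need only the reference and alternate residues, so the
    pipeline derives them here rather than expecting them as input columns.
    Existing values are left untouched.
    """
    for record in cohort:
        if record.ref_aa in AMINO_ACIDS and record.alt_aa in AMINO_ACIDS:
            for name in BLOSUM_NAMES:
                record.tool_scores.setdefault(
                    name, blosum_score(name, record.ref_aa, record.alt_aa)
                )
            record.tool_scores.setdefault(
                "Grantham", grantham_distance(record.ref_aa, record.alt_aa)
            )
    return cohort
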
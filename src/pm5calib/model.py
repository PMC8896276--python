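"""Domain types and tabular I/O.

Coordinates follow the HGVS c. convention: 1-based inclusive positions on the
coding sequence of a named transcript, with codon 1 the initiator.  A variant
is identified, for lookup purposes, by its amino-acid substitution
``(gene, codon, ref_aa, alt_aa)``; distinct nucleotide changes encoding the
same substitution collapse to a single record (see :meth:`Cohort.collapse_substitutions`).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"


class FunctionalClass(str, enum.Enum):
    DEL = "DEL"
    TOL = "TOL"
    INTERMEDIATE = "INTERMEDIATE"
    MISSING = "MISSING"


class ClinicalRaw(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    CONFLICTING = "CONFLICTING"
    MISSING = "MISSING"


class SpliceogenicRna(str, enum.Enum):
    NONE = "NONE"
    INTERMEDIATE = "INTERMEDIATE"
    DEPLETED = "DEPLETED"
    MISSING = "MISSING"


def codon_of(cds_pos: int) -> int:
    """Protein position of a 1-based CDS coordinate (codon 1 = initiator)."""
    if cds_pos < 1:
        raise ValidationError(f"cds_pos must be >= 1, got {cds_pos}")
    return (cds_pos - 1) // 3 + 1


@dataclass
class VariantRecord:
    """One candidate single-residue substitution with its annotations."""

    gene_id: str
    transcript_id: str = ""
    cds_pos: Optional[int] = None
    codon_index: Optional[int] = None
    ref_aa: str = ""
    alt_aa: str = ""
    nt_change: str = ""
    functional_class: FunctionalClass = FunctionalClass.MISSING
    functional_score: Optional[float] = None
    clinical_raw: ClinicalRaw = ClinicalRaw.MISSING
    clinvar_stars: int = 0
    tool_scores: dict = field(default_factory=dict)
    para_splice_site: bool = False
    spliceogenic_rna: SpliceogenicRna = SpliceogenicRna.MISSING
    row: Optional[int] = None  # source row for error reporting

    def __post_init__(self) -> None:
        if self.codon_index is None and self.cds_pos is not None:
            self.codon_index = codon_of(self.cds_pos)
        if self.cds_pos is not None and self.codon_index is not None:
            expected = codon_of(self.cds_pos)
            if expected != self.codon_index:
                where = f" (row {self.row})" if self.row is not None else ""
                raise ValidationError(
                    f"codon_index {self.codon_index} inconsistent with cds_pos "
                    f"{self.cds_pos} (expected {expected}){where}"
                )
        if self.codon_index is None:
            raise ValidationError("record needs codon_index or cds_pos")
        for aa, label in ((self.ref_aa, "ref_aa"), (self.alt_aa, "alt_aa")):
            if aa and aa not in AMINO_ACIDS and aa != STOP:
                raise ValidationError(f"unknown {label} {aa!r}")
        if self.clinical_raw in (ClinicalRaw.P, ClinicalRaw.LP, ClinicalRaw.B, ClinicalRaw.LB):
            if self.clinvar_stars < 0:
                raise ValidationError("clinvar_stars must be >= 0")

    @property
    def substitution(self) -> tuple:
        return (self.gene_id, self.codon_index, self.ref_aa, self.alt_aa)

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass(frozen=True)
class ExonModel:
    """Ordered, disjoint exon intervals in 1-based inclusive CDS coordinates."""

    transcript_id: str
    exons: tuple

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValidationError(f"exon ({start}, {end}) has start > end")
            if start <= prev_end:
                raise ValidationError("exons must be strictly ascending and disjoint")
            prev_end = end

    def exon_index(self, cds_pos: int) -> int:
        """Index of the exon containing ``cds_pos``; error if outside all exons."""
        for i, (start, end) in enumerate(self.exons):
            if start <= cds_pos <= end:
                return i
        raise ValidationError(
            f"cds_pos {cds_pos} outside all exons of {self.transcript_id}"
        )

    @classmethod
    def from_tsv(cls, path, transcript_id: str = "") -> "ExonModel":
        """Read a two-column (start, end) TSV, 1-based inclusive, optional header."""
        frame = pd.read_csv(path, sep="\t")
        cols = [c.lower() for c in frame.columns]
        if "start" in cols and "end" in cols:
            starts = frame[frame.columns[cols.index("start")]]
            ends = frame[frame.columns[cols.index("end")]]
        else:  # headerless two-column file
            frame = pd.read_csv(path, sep="\t", header=None)
            starts, ends = frame[0], frame[1]
        exons = tuple((int(s), int(e)) for s, e in zip(starts, ends))
        return cls(transcript_id=transcript_id or str(path), exons=exons)


class Cohort:
    """A set of variant records indexed by (gene, codon)."""

    def __init__(self, records: Sequence[VariantRecord]):
        self.records = list(records)
        self.index: dict = {}
        for rec in self.records:
            self.index.setdefault((rec.gene_id, rec.codon_index), []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def at_codon(self, gene_id: str, codon_index: int) -> list:
        return self.index.get((gene_id, codon_index), [])

    def collapse_substitutions(self) -> tuple:
        """Collapse records encoding the same amino-acid substitution.

        Multiple nucleotide changes yielding one substitution become one record.
        If the collapsed records disagree on the dichotomous functional class the
        merged record is set INTERMEDIATE and a warning string is emitted, so the
        disagreement is excluded from dichotomous analyses rather than silently
        resolved.
        """
        merged: dict = {}
        warnings: list = []
        for rec in self.records:
            key = rec.substitution
            if key not in merged:
                merged[key] = rec
                continue
            kept = merged[key]
            if kept.functional_class != rec.functional_class:
                warnings.append(
                    f"{rec.gene_id} {rec.label}: conflicting functional classes "
                    f"{kept.functional_class.value}/{rec.functional_class.value} "
                    "across nucleotide changes; set INTERMEDIATE"
                )
                merged[key] = replace(kept, functional_class=FunctionalClass.INTERMEDIATE)
        return Cohort(list(merged.values())), warnings


#: default input column names; a run config may remap any of them
DEFAULT_DIALECT = {
    "gene": "gene",
    "transcript": "transcript",
    "cds_pos": "cds_pos",
    "codon": "codon",
    "ref_aa": "ref_aa",
    "alt_aa": "alt_aa",
    "nt_change": "nt_change",
    "functional_class": "functional_class",
    "functional_score": "functional_score",
    "clinical": "clinical",
    "stars": "stars",
    "spliceogenic_rna": "spliceogenic_rna",
    "para_splice_site": "para_splice_site",
}

_MANDATORY = ("gene", "ref_aa", "alt_aa")

#: columns that are part of the core schema; anything else is a tool score
_CORE_FIELDS = set(DEFAULT_DIALECT)


def read_variant_table(path, dialect: Optional[Mapping[str, str]] = None) -> Cohort:
    """Read a tab-separated variant table into a :class:`Cohort`.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`) to
    the column names actually present in the file.  Columns not claimed by the
    dialect are preserved as per-tool scores in ``tool_scores``.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in _MANDATORY:
        if names[key] not in frame.columns:
            raise FormatError(f"missing mandatory column {names[key]!r} in {path}")
    if names["cds_pos"] not in frame.columns and names["codon"] not in frame.columns:
        raise FormatError(
            f"need a {names['cds_pos']!r} or {names['codon']!r} column in {path}"
        )
    claimed = {names[k] for k in names if names[k] in frame.columns}
    tool_columns = [c for c in frame.columns if c not in claimed]

    def cell(row, key):
        col = names[key]
        if col not in frame.columns:
            return ""
        return str(row[col]).strip()

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1 = header line
        row = dict(zip(frame.columns, row))
        tool_scores = {}
        for col in tool_columns:
            raw = str(row[col]).strip()
            if raw == "" or raw.upper() in ("NA", "NAN", "."):
                tool_scores[col] = None
            else:
                try:
                    tool_scores[col] = float(raw)
                except ValueError:
                    tool_scores[col] = raw  # ordered class labels (e.g. C0..C65)
        func_raw = cell(row, "functional_class") or "MISSING"
        clin_raw = cell(row, "clinical") or "MISSING"
        splice_raw = cell(row, "spliceogenic_rna") or "MISSING"
        try:
            records.append(
                VariantRecord(
                    gene_id=cell(row, "gene"),
                    transcript_id=cell(row, "transcript"),
                    cds_pos=int(cell(row, "cds_pos")) if cell(row, "cds_pos") else None,
                    codon_index=int(cell(row, "codon")) if cell(row, "codon") else None,
                    ref_aa=cell(row, "ref_aa"),
                    alt_aa=cell(row, "alt_aa"),
                    nt_change=cell(row, "nt_change"),
                    functional_class=FunctionalClass(func_raw.upper()),
                    functional_score=(
                        float(cell(row, "functional_score"))
                        if cell(row, "functional_score")
                        else None
                    ),
                    clinical_raw=ClinicalRaw(clin_raw.upper()),
                    clinvar_stars=int(cell(row, "stars") or 0),
                    tool_scores=tool_scores,
                    para_splice_site=cell(row, "para_splice_site").lower()
                    in ("1", "true", "yes"),
                    spliceogenic_rna=SpliceogenicRna(splice_raw.upper()),
                    row=i,
                )
            )
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(f"row {i} of {path}: {exc}") from exc
    return Cohort(records)


def write_variant_table(cohort: Cohort, path) -> None:
    """Write a cohort back to the TSV layout :func:`read_variant_table` reads."""
    tool_names = sorted({name for rec in cohort for name in rec.tool_scores})
    rows = []
    for rec in cohort:
        row = {
            "gene": rec.gene_id,
            "transcript": rec.transcript_id,
            "cds_pos": "" if rec.cds_pos is None else rec.cds_pos,
            "codon": rec.codon_index,
            "ref_aa": rec.ref_aa,
            "alt_aa": rec.alt_aa,
            "nt_change": rec.nt_change,
            "functional_class": rec.functional_class.value,
            "functional_score": (
                "" if rec.functional_score is None else repr(rec.functional_score)
            ),
            "clinical": rec.clinical_raw.value,
            "stars": rec.clinvar_stars,
            "spliceogenic_rna": rec.spliceogenic_rna.value,
            "para_splice_site": int(rec.para_splice_site),
        }
        for name in tool_names:
            value = rec.tool_scores.get(name)
            row[name] = "" if value is None else (
                repr(value) if isinstance(value, float) else value
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_LR_COLUMNS = {"plr", "plr_ci_low", "plr_ci_high", "nlr", "nlr_ci_low", "nlr_ci_high"}


def write_results_table(rows: Iterable[Mapping], path) -> None:
    """Write result records as TSV with a deterministic column order.

    Likelihood-ratio columns are formatted to 1 decimal, matching how the
    study tables print them; other floats keep full precision so the file
    round-trips through :func:`pandas.read_csv` without loss.
    """
    rows = list(rows)
    frame = pd.DataFrame(rows)
    if rows:
        # preserve first-row key order, then any stragglers alphabetically
        lead = list(rows[0].keys())
        rest = sorted(c for c in frame.columns if c not in lead)
        frame = frame[lead + rest]
    out = frame.copy()
    from .evaluate import round1  # local import to avoid a cycle

    for col in out.columns:
        if col in _LR_COLUMNS:
            out[col] = [("" if v is None or pd.isna(v) else f"{round1(v):.1f}") for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


def write_run_summary(summary: Mapping, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
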
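"""End-to-end orchestration: curate -> annotate -> predict -> evaluate -> report.

A run is described by one declarative YAML config; the three lookup/truth
approaches (clinical lookup vs functional truth, functional/functional,
clinical/clinical) are config changes, not code paths.  Re-running an
identical config over identical inputs yields byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import yaml
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from . import __version__
from .curation import curate_cohort
from .engine import (
    SUPPORTED_APPROACHES,
    Comparison,
    Source,
    _DEFINITION_SHAPES,
    DefinitionId,
    definition,
    run_predictions,
)
from .errors import ConfigurationError
from .evaluate import evaluate_all
from .insilico import DEFAULT_TOOL_REGISTRY, annotate_physiochemical
from .model import (
    ExonModel,
    read_variant_table,
    write_results_table,
    write_run_summary,
    write_variant_table,
)
from .simulate import CohortConfig, generate_cohort


class RunConfig(BaseModel):
    variants: Optional[str] = None  # input variant TSV; omit when simulating
    exons: Optional[str] = None  # optional exon-interval TSV
    dialect: dict = Field(default_factory=dict)
    simulate: Optional[CohortConfig] = None
    lookup_source: str = "CLINVAR"
    truth_source: str = "MAVE"
    definitions: Tuple[str, ...] = ("a", "b", "c", "d", "e")
    tools: Tuple[str, ...] = (
        "BLOSUM45",
        "BLOSUM62",
        "BLOSUM80",
        "Grantham",
        "REVEL",
        "Meta-SNP",
        "CADD",
        "aGVGD",
    )
    banded: bool = True
    drop_spliceogenic: bool = False
    flag_terminal_exon_edges: bool = False
    outdir: str = "results"
    seed: int = 0


def _violations(config: RunConfig) -> list:
    """Complete list of semantic problems with a structurally valid config."""
    problems = []
    if config.variants is None and config.simulate is None:
        problems.append("config needs either 'variants' or a 'simulate' section")
    for label, path in (("variants", config.variants), ("exons", config.exons)):
        if path is not None and not Path(path).exists():
            problems.append(f"{label} path does not exist: {path}")
    try:
        combo = (Source(config.lookup_source), Source(config.truth_source))
        if combo not in SUPPORTED_APPROACHES:
            problems.append(
                f"unsupported lookup/truth combination "
                f"{config.lookup_source}/{config.truth_source}"
            )
    except ValueError:
        problems.append(
            f"unknown source in {config.lookup_source}/{config.truth_source}"
        )
    for defn in config.definitions:
        if defn not in DefinitionId._value2member_map_:
            problems.append(f"unknown PM5 definition {defn!r}")
    for tool in config.tools:
        if tool not in DEFAULT_TOOL_REGISTRY:
            problems.append(f"unknown tool {tool!r}")
    return problems


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; raise with ALL violations at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        config = RunConfig(**raw)
    except PydanticValidationError as exc:
        problems = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        error = ConfigurationError("; ".join(problems))
        error.violations = problems
        raise error from None
    problems = _violations(config)
    if problems:
        error = ConfigurationError("; ".join(problems))
        error.violations = problems
        raise error
    return config


def _expand_definitions(config: RunConfig) -> list:
    expanded = []
    for letter in config.definitions:
        _, comparison = _DEFINITION_SHAPES[DefinitionId(letter)]
        if comparison is Comparison.NONE:
            expanded.append(definition(letter))
        else:
            expanded.extend(definition(letter, tool) for tool in config.tools)
    return expanded


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a mapping of artifact names to paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    problems = _violations(config)
    if problems:
        error = ConfigurationError("; ".join(problems))
        error.violations = problems
        raise error

    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
    else:
        cohort = read_variant_table(config.variants, config.dialect)
    exons = (
        ExonModel.from_tsv(config.exons) if config.exons is not None else None
    )

    eligible, report = curate_cohort(
        cohort,
        exons=exons,
        drop_spliceogenic=config.drop_spliceogenic,
        flag_terminal=config.flag_terminal_exon_edges,
    )
    annotate_physiochemical(eligible)

    predictions = run_predictions(
        eligible,
        config.lookup_source,
        config.truth_source,
        _expand_definitions(config),
        band_tools=config.tools if config.banded else (),
    )
    results = evaluate_all(predictions)

    artifacts = {
        "eligible": outdir / "eligible_variants.tsv",
        "predictions": outdir / "predictions.tsv",
        "results_binary": outdir / "results_binary.tsv",
        "results_banded": outdir / "results_banded.tsv",
        "summary": outdir / "run_summary.json",
    }
    write_variant_table(eligible, artifacts["eligible"])
    predictions.to_csv(artifacts["predictions"], sep="\t", index=False)
    binary = results[~results["analysis"].str.startswith("band_")]
    banded = results[results["analysis"].str.startswith("band_")]
    write_results_table(binary.to_dict("records"), artifacts["results_binary"])
    write_results_table(banded.to_dict("records"), artifacts["results_banded"])
    write_run_summary(
        {
            "version": __version__,
            "approach": SUPPORTED_APPROACHES[
                (Source(config.lookup_source), Source(config.truth_source))
            ],
            "config": config.model_dump(),
            "curation": report.as_dict(),
            "n_prediction_rows": int(len(predictions)),
        },
        artifacts["summary"],
    )
    return {name: str(path) for name, path in artifacts.items()}
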
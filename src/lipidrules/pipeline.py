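"""End-to-end annotation runs over a directory of feature tables and MS2
files, with parameter provenance and per-step count logging.

One run processes every job the discovery step finds (a feature table plus
its same-folder MS2 files of matching polarity), writes the annotated
table and per-class fragment details into an ``output`` folder next to
each feature table, and serializes the resolved configuration into the
output folder so the run is reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data_io import discover_inputs, read_feature_table, read_ms2, write_outputs
from .engine import EngineParams, IdentificationRule, annotate_table, default_rules
from .library import LibraryEntry, build_default_library, read_library

logger = logging.getLogger("lipidrules")

__all__ = ["RunConfig", "RunSummary", "run_annotate"]


@dataclass
class RunConfig:
    root_dir: Path
    params: EngineParams = field(default_factory=EngineParams)
    library_path: Path | None = None  # None -> build the default library
    classes: list[str] | None = None  # restrict library to these classes
    rules_path: Path | None = None
    out_dir_name: str = "output"

    def to_dict(self) -> dict:
        return {
            "root_dir": str(self.root_dir),
            "params": dataclasses.asdict(self.params),
            "library_path": str(self.library_path) if self.library_path else None,
            "classes": self.classes,
            "rules_path": str(self.rules_path) if self.rules_path else None,
            "out_dir_name": self.out_dir_name,
        }


@dataclass
class RunSummary:
    features_read: int = 0
    pairs_formed: int = 0
    ids_by_confidence: dict[int, int] = field(default_factory=dict)
    jobs: int = 0
    warnings: list[str] = field(default_factory=list)


def _load_library(config: RunConfig) -> list[LibraryEntry]:
    if config.library_path is not None:
        entries = read_library(config.library_path)
        if config.classes is not None:
            wanted = {c.lower() for c in config.classes}
            entries = [e for e in entries if e.class_name.lower() in wanted]
        return entries
    return build_default_library(classes=config.classes)


def run_annotate(config: RunConfig) -> RunSummary:
    """Discover inputs under the run's root directory, annotate every job
    and write outputs.  Raises on any malformed input (file and line
    context propagate from the readers)."""
    from .engine import match_precursors, read_rules

    plan = discover_inputs(config.root_dir)  # fail fast before library build
    library = _load_library(config)
    rules: list[IdentificationRule] = (
        read_rules(config.rules_path) if config.rules_path else default_rules()
    )
    summary = RunSummary()
    for f in plan.unrecognized:
        summary.warnings.append(f"unrecognized input file: {f}")
        logger.warning("unrecognized input file: %s", f)

    for job in plan.jobs:
        table = read_feature_table(job.feature_table)
        spectra = []
        for ms2 in job.ms2_files:
            spectra.extend(read_ms2(ms2))
        for w in job.warnings:
            summary.warnings.append(f"{job.feature_table.name}: {w}")
            logger.warning("%s: %s", job.feature_table.name, w)
        params = config.params
        if not job.ms2_files:
            # precursor-only annotation (confidence 4) is all that is possible
            params = dataclasses.replace(params, keep_unconfirmed=True)
        features = table.features
        pairs = match_precursors(
            features, library, params.ms1_tol_da, job.polarity
        )
        results = annotate_table(
            features, spectra, library, rules, params, polarity=job.polarity
        )
        out_dir = job.folder / config.out_dir_name
        write_outputs(table, results, out_dir, stem=job.feature_table.stem)
        with (out_dir / "run_config.yaml").open("w", encoding="utf-8") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

        summary.jobs += 1
        summary.features_read += len(features)
        summary.pairs_formed += len(pairs)
        for idents in results.values():
            for ident in idents:
                summary.ids_by_confidence[ident.confidence] = (
                    summary.ids_by_confidence.get(ident.confidence, 0) + 1
                )
        logger.info(
            "%s: %d features, %d pairs, ids by confidence %s",
            job.feature_table.name,
            len(features),
            len(pairs),
            dict(sorted(summary.ids_by_confidence.items())),
        )
    return summary
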
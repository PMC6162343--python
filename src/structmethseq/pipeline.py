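"""End-to-end orchestration: simulate -> filter -> fold -> annotate ->
enrich -> profile, with a serializable configuration and provenance.

Every run writes the resolved configuration next to its outputs, and a
manifest records the configuration hash together with a checksum of
every output file, so outputs produced under different configurations
are detectable.  Stages communicate through plain text files
(FASTA/Vienna/TSV/JSON), so any stage can be re-run standalone or
replaced by an external tool.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import profiles as prof
from .features import annotations_to_frame, classify_positions
from .fold import FoldParams, fold_many, write_vienna
from .reads import FilterSpec, filter_reads, read_sequences, to_rna
from .simulate import (
    ErrorRates,
    LibraryDesign,
    SelectionModel,
    generate_oligo_library,
    simulate_ip_experiment,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("structmethseq")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    When ``input_reads`` maps library names to read files the simulation
    stage is skipped; otherwise ``n_oligos`` oligos are generated and the
    IP experiment is simulated.
    """

    out_dir: str = "run"
    seed: int = 0
    n_oligos: int = 2000
    input_reads: dict[str, str] = field(default_factory=dict)
    design: LibraryDesign = field(default_factory=LibraryDesign)
    selection: SelectionModel = field(default_factory=SelectionModel)
    filter: FilterSpec = field(default_factory=FilterSpec)
    fold: FoldParams = field(default_factory=FoldParams)
    alpha: float = 0.1
    pseudocount: float = 0.5
    min_total: int = 10
    floor: float = 0.005
    read_format: str = "fasta"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["fold"]["pair_weights"] = [list(p) for p in d["fold"]["pair_weights"]]
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if "design" in data and isinstance(data["design"], dict):
            data["design"] = LibraryDesign(**data["design"])
        if "selection" in data and isinstance(data["selection"], dict):
            sel = dict(data["selection"])
            if isinstance(sel.get("error_rates"), dict):
                sel["error_rates"] = ErrorRates(**sel["error_rates"])
            data["selection"] = SelectionModel(**sel)
        if "filter" in data and isinstance(data["filter"], dict):
            data["filter"] = FilterSpec(**data["filter"])
        if "fold" in data and isinstance(data["fold"], dict):
            fp = dict(data["fold"])
            if "pair_weights" in fp:
                fp["pair_weights"] = tuple(
                    (str(p), float(w)) for p, w in fp["pair_weights"]
                )
            data["fold"] = FoldParams(**fp)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is not
        part of a run's scientific identity)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as handle:
        handle.write(f"# config_hash: {config_hash}\n")
        df.to_csv(handle, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the summary dictionary.

    Outputs under ``config.out_dir``: the resolved config, per-library
    read FASTAs, filter reports, folded structures (Vienna text),
    per-position annotations, the structure count table, enrichment
    results, positional profiles, target-position proportions per class,
    a summary JSON and a manifest with per-file checksums.
    """
    cfg_hash = config.config_hash()
    out = Path(config.out_dir)
    # configuration errors surface before any stage runs
    for lib, path in config.input_reads.items():
        if not Path(path).exists():
            raise PipelineError(f"config: input file for library {lib!r} not found: {path}")
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict[str, Any] = {"config_hash": cfg_hash, "stages": {}}
    t0 = time.time()

    def stage_done(name: str) -> None:
        dt = time.time() - t0
        summary["stages"][name] = round(dt, 3)
        log.info("stage %s done (%.2fs elapsed)", name, dt)

    # --- simulate or load ---------------------------------------------------
    truth = None
    if config.input_reads:
        raw = {
            lib: [seq for _, seq in read_sequences(path)]
            for lib, path in config.input_reads.items()
        }
    else:
        try:
            oligos = generate_oligo_library(config.design, config.n_oligos, config.seed)
            sim = simulate_ip_experiment(
                oligos, config.fold, config.selection, config.design
            )
        except ValueError as exc:
            raise PipelineError(f"simulate: {exc}") from exc
        sim.write(out / "libraries", fmt=config.read_format)
        raw = {lib: [seq for _, seq in recs] for lib, recs in sim.reads.items()}
        truth = sim.truth
    stage_done("simulate")

    # --- filter -------------------------------------------------------------
    kept: dict[str, list[str]] = {}
    reports = {}
    try:
        for lib, seqs in raw.items():
            kept[lib], report = filter_reads(seqs, config.filter)
            reports[lib] = report.as_dict()
    except ValueError as exc:
        raise PipelineError(f"filter: library {lib!r}: {exc}") from exc
    (out / "filter_report.json").write_text(json.dumps(reports, indent=2) + "\n")
    summary["reads"] = {
        lib: {"total": reports[lib]["total"], "kept": reports[lib]["kept"]}
        for lib in reports
    }
    stage_done("filter")

    # --- fold ---------------------------------------------------------------
    unique_seqs = sorted({s for seqs in kept.values() for s in seqs})
    try:
        structures = fold_many(unique_seqs, config.fold)
    except ValueError as exc:
        raise PipelineError(f"fold: {exc}") from exc
    write_vienna(
        out / "structures.vienna",
        ((to_rna(s), structures[to_rna(s)]) for s in unique_seqs),
    )
    stage_done("fold")

    # --- annotate -----------------------------------------------------------
    unique_dbs = sorted({st.dot_bracket for st in structures.values()})
    annotations = {db: classify_positions(db) for db in unique_dbs}
    _write_tsv(annotations_to_frame(annotations), out / "annotations.tsv", cfg_hash)
    summary["structures"] = {"unique_sequences": len(unique_seqs), "unique_dot_brackets": len(unique_dbs)}
    stage_done("annotate")

    # --- enrich -------------------------------------------------------------
    try:
        counts = enr.aggregate_structures(
            kept, {s: structures[to_rna(s)].dot_bracket for s in unique_seqs}
        )
        results = enr.differential_representation(
            counts,
            alpha=config.alpha,
            pseudocount=config.pseudocount,
            min_total=config.min_total,
        )
    except ValueError as exc:
        raise PipelineError(f"enrich: {exc}") from exc
    _write_tsv(counts, out / "counts.tsv", cfg_hash, index=True)
    _write_tsv(results, out / "enrichment.tsv", cfg_hash)
    class_counts = results["class"].value_counts().to_dict()
    summary["enrichment"] = {
        "tested": int(results["tested"].sum()),
        "enriched": int(class_counts.get("enriched", 0)),
        "depleted": int(class_counts.get("depleted", 0)),
        "nondiff": int(class_counts.get("nondiff", 0)),
    }
    stage_done("enrich")

    # --- profile ------------------------------------------------------------
    target = config.design.target_pos
    rule = prof.FloorRule(config.floor)
    profile_rows = []
    summary["target_proportions"] = {}
    class_profiles: dict[str, dict[str, np.ndarray]] = {}
    tested_results = results[results["tested"]]  # untested rows belong to no class
    for klass in ("enriched", "depleted", "nondiff"):
        dbs = tested_results.loc[tested_results["class"] == klass, "structure"].tolist()
        dbs = [db for db in dbs if len(db) == config.design.length]
        if not dbs:
            continue
        anns = [annotations[db] for db in dbs]
        class_profiles[klass] = {}
        for feature in prof.FEATURES:
            freqs = prof.feature_frequency_profile(anns, feature)
            class_profiles[klass][feature] = freqs
            for p, f in enumerate(freqs, 1):
                profile_rows.append(
                    {"class": klass, "feature": feature, "position": p, "frequency": f}
                )
        summary["target_proportions"][klass] = prof.target_feature_proportions(
            anns, target
        )
    ratio_rows = []
    if "nondiff" in class_profiles:
        for klass in ("enriched", "depleted"):
            if klass not in class_profiles:
                continue
            for feature in prof.FEATURES:
                ratios = prof.log2_frequency_ratio(
                    class_profiles[klass][feature],
                    class_profiles["nondiff"][feature],
                    rule,
                )
                for p, r in enumerate(ratios, 1):
                    ratio_rows.append(
                        {
                            "class": klass,
                            "feature": feature,
                            "position": p,
                            "log2_ratio_vs_nondiff": r,
                        }
                    )
    _write_tsv(pd.DataFrame(profile_rows), out / "profiles.tsv", cfg_hash)
    _write_tsv(pd.DataFrame(ratio_rows), out / "profile_ratios.tsv", cfg_hash)
    if truth is not None:
        _write_tsv(truth, out / "ground_truth.tsv", cfg_hash)
    stage_done("profile")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")

    manifest = {
        "config_hash": cfg_hash,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return summary
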
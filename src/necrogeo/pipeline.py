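"""Config-driven orchestration of the classification experiments.

A run executes qc -> sketch -> compare -> classify on a directory of
FASTQ files plus a metadata table, writing plain tabular artifacts
between stages so each stage is independently re-runnable:

    out/
      config.yaml          effective configuration + seed
      qc_report.json       per-sample QC counts
      matrix.csv           angular-similarity matrix
      jackknife.tsv        per-sample leave-one-out predictions
      accuracy_curve.tsv   confidence-aware accuracy curve
      model.json           full-data fitted model
      permutation.tsv      (optional) mock-label control
      targets.tsv          (optional) per-target class probabilities

Two runs with the same config and seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .embed import embed
from .fastq import read_fastq
from .qc import QCParams, run_qc, subsample_reads
from .sketch import AbundanceSketch, SimilarityMatrix, SketchParams, compare_all, sketch_reads
from .taxa import extract_taxon_reads, genus_sample_gate, read_assignments

logger = logging.getLogger("necrogeo")

__all__ = ["RunConfig", "run_experiment"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    input_dir: str = "."
    metadata: str = "metadata.tsv"
    out_dir: str = "necrogeo_run"
    label_col: str = "location"
    seed: int = 0
    # qc
    run_qc_stage: bool = True
    min_len: int = 30
    max_len: int = 80
    trim_each_end: int = 4
    complexity_threshold: float = 0.7
    # sketch
    k: int = 21
    scaled: int = 1000
    hash_seed: int = 42
    # classify
    embed_method: str = "pca_rows"
    cv_folds: int | None = None
    min_reads: int | None = None
    permute: bool = False
    targets: list[str] = field(default_factory=list)
    # genus-restricted workflow
    genus_restricted: bool = False
    assignments: str | None = None
    genus_taxon_id: int | None = None
    genus_min_reads: int = 100_000
    subsample_to: int | None = None

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _find_fastq(input_dir: Path, sample_id: str) -> Path:
    for suffix in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
        candidate = input_dir / f"{sample_id}{suffix}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"no FASTQ found for sample {sample_id!r} in {input_dir}")


def records_to_frame(records: Sequence[_classify.JackknifeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "true_label": [r.true_label for r in records],
            "predicted_label": [r.predicted_label for r in records],
            "p_true": [r.p_true for r in records],
            "p_positive": [r.p_positive for r in records],
            "flagged": [r.flagged for r in records],
        }
    )


def run_experiment(config: RunConfig) -> dict:
    """Execute a full experiment; returns the in-memory results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    meta = pd.read_csv(Path(config.metadata), sep="\t", dtype={"sample_id": str})
    if config.label_col not in meta.columns:
        raise ValueError(f"metadata lacks label column {config.label_col!r}")
    input_dir = Path(config.input_dir)

    qc_params = QCParams(
        min_len=config.min_len,
        max_len=config.max_len,
        trim_each_end=config.trim_each_end,
        complexity_threshold=config.complexity_threshold,
    )
    sketch_params = SketchParams(k=config.k, scaled=config.scaled, hash_seed=config.hash_seed)

    assignments = read_assignments(config.assignments) if config.assignments else None
    if config.genus_restricted and (assignments is None or config.genus_taxon_id is None):
        raise ValueError("genus-restricted mode needs --assignments and --genus-taxon-id")

    sketches: list[AbundanceSketch] = []
    qc_reports: dict[str, dict] = {}
    read_counts: dict[str, int] = {}
    genus_counts: dict[str, int] = {}
    for i, sample_id in enumerate(meta["sample_id"]):
        try:
            reads = list(read_fastq(_find_fastq(input_dir, sample_id)))
            if config.run_qc_stage:
                reads, report = run_qc(reads, qc_params)
                qc_reports[sample_id] = json.loads(report.to_json())
            read_counts[sample_id] = len(reads)
            if config.genus_restricted:
                reads = extract_taxon_reads(reads, assignments, config.genus_taxon_id)
                genus_counts[sample_id] = len(reads)
            if config.subsample_to is not None:
                reads = subsample_reads(reads, config.subsample_to, config.seed + i)
            sketches.append(sketch_reads(reads, sketch_params, sample_id))
            logger.info("sketched %s: %d hashes", sample_id, len(sketches[-1]))
        except Exception as exc:
            raise RuntimeError(f"stage failure at sample {sample_id!r}: {exc}") from exc

    if qc_reports:
        (out / "qc_report.json").write_text(json.dumps(qc_reports, indent=2))

    excluded: list[str] = []
    if config.genus_restricted:
        _, excluded = genus_sample_gate(genus_counts, config.genus_min_reads)
    elif config.min_reads is not None:
        _, excluded = _classify.depth_gate(read_counts, config.min_reads)
    if excluded:
        logger.info("excluded %d samples below read gate: %s", len(excluded), excluded)

    target_ids = set(config.targets)
    ref_sketches = [
        s for s in sketches if s.sample_id not in excluded and s.sample_id not in target_ids
    ]
    S = compare_all(ref_sketches)
    S.to_csv(out / "matrix.csv")

    labels = dict(zip(meta["sample_id"], meta[config.label_col].astype(str)))
    records = _classify.jackknife(
        S, labels, embed_method=config.embed_method, cv_folds=config.cv_folds, seed=config.seed
    )
    records_to_frame(records).to_csv(out / "jackknife.tsv", sep="\t", index=False)

    curve = _classify.accuracy_curve(records)
    pd.DataFrame({"threshold": curve.thresholds, "accuracy": curve.values}).to_csv(
        out / "accuracy_curve.tsv", sep="\t", index=False
    )

    emb = embed(S, method=config.embed_method)
    model = _classify.fit_lasso_logit(
        emb.X, [labels[s] for s in S.sample_ids], cv_folds=config.cv_folds, seed=config.seed
    )
    (out / "model.json").write_text(json.dumps(model.to_dict(), indent=2))

    results: dict = {
        "similarity": S,
        "records": records,
        "curve": curve,
        "model": model,
        "excluded": excluded,
    }

    if config.permute:
        control = _classify.permutation_control(
            S, labels, seed=config.seed, embed_method=config.embed_method, cv_folds=config.cv_folds
        )
        perm_df = records_to_frame(control.records)
        perm_df["permuted_label"] = control.permuted_labels
        perm_df.to_csv(out / "permutation.tsv", sep="\t", index=False)
        results["permutation"] = control

    if config.targets:
        rows = []
        for tid in config.targets:
            target = next(s for s in sketches if s.sample_id == tid)
            probs = _classify.classify_target(
                ref_sketches,
                {s.sample_id: labels[s.sample_id] for s in ref_sketches},
                target,
                embed_method=config.embed_method,
                cv_folds=config.cv_folds,
                seed=config.seed,
            )
            for cls, p in sorted(probs.items()):
                rows.append({"target": tid, "class": cls, "probability": p})
        pd.DataFrame(rows).to_csv(out / "targets.tsv", sep="\t", index=False)
        results["targets"] = rows

    return results
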
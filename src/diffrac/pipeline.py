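"""End-to-end pipeline: align → score → significance → classify → complexes.

Every stage writes its TSV into the output directory and the run closes
with a ``manifest.json`` echoing the configuration, package version, seed
and per-stage row counts, so any stage can be re-run from its on-disk
inputs.  A stage failure aborts the run with the stage name; the failing
stage's partial output is kept under a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotations import load_annotations, neg_ln_p, precision_curve
from .complexes import call_complexes, merge_complex_sets, read_complexes, write_complex_calls
from .io import align_pair, read_elution_matrix
from .score import score_experiment, write_scores
from .shifts import classify_signals, shift_records, write_shifts
from .significance import assign_significance, write_significance

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All paths and tunables of one pipeline run."""

    control_path: str = ""
    treated_path: str = ""
    corum_path: str | None = None
    humap_path: str | None = None
    lt_annotation_files: list = field(default_factory=list)
    ht_annotation_files: list = field(default_factory=list)
    out_dir: str = "diffrac_out"
    s: int = 100
    t_weight: float = 0.7
    alpha: float = 0.05
    r_min: float = 0.75
    p_relaxed: float = 0.5
    min_mean_abundance: float = 10.0
    seed: int = 0
    n_restarts: int = 3
    classify_all: bool = False

    def validate(self) -> None:
        for name, p in (("control", self.control_path), ("treated", self.treated_path)):
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} matrix not found: {p!r}")
        if not 0 < self.t_weight < 1:
            raise ValueError("t_weight must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.s < 1:
            raise ValueError("window half-width s must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_stage(frame_writer, frame, final_path: Path) -> None:
    partial = final_path.with_suffix(final_path.suffix + ".partial")
    frame_writer(frame, partial)
    partial.rename(final_path)


def run_diffrac(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "rows": {},
    }
    stage = "load"
    try:
        control = read_elution_matrix(config.control_path, "control")
        treated = read_elution_matrix(config.treated_path, "treated")
        pair = align_pair(control, treated)
        manifest["rows"]["proteins"] = len(pair.protein_ids)
        manifest["rows"]["fractions"] = pair.n_fractions

        stage = "score"
        scores = score_experiment(pair)
        _write_stage(write_scores, scores, out / "scores.tsv")
        manifest["rows"]["score"] = len(scores)

        stage = "annotations"
        ann = load_annotations(config.lt_annotation_files, config.ht_annotation_files)

        stage = "significance"
        sig = assign_significance(
            scores,
            annotated=ann.union,
            s=config.s,
            t_weight=config.t_weight,
            alpha=config.alpha,
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
        _write_stage(write_significance, sig, out / "significance.tsv")
        manifest["rows"]["significance"] = len(sig)
        manifest["rows"]["significant"] = int(sig["significant"].sum())

        stage = "classify"
        subset = None if config.classify_all else sig.index[sig["significant"]]
        shifts = shift_records(pair, subset=subset)
        labelled, summary = classify_signals(shifts)
        _write_stage(write_shifts, labelled, out / "shifts.tsv")
        _write_stage(
            lambda df, p: df.to_csv(p, sep="\t", index=False),
            summary,
            out / "shift_summary.tsv",
        )
        manifest["rows"]["classified"] = len(labelled)

        stage = "complexes"
        if config.corum_path or config.humap_path:
            corum = (
                read_complexes(config.corum_path, "CORUM")
                if config.corum_path
                else None
            )
            humap = (
                read_complexes(config.humap_path, "huMAP")
                if config.humap_path
                else None
            )
            if corum is None:
                merged = humap
            elif humap is None:
                merged = corum
            else:
                merged = merge_complex_sets(corum, humap)
            calls = call_complexes(
                merged,
                pair.control,
                sig,
                ht_annotated=ann.ht,
                lt_annotated=ann.lt,
                r_min=config.r_min,
                p_relaxed=config.p_relaxed,
            )
            _write_stage(write_complex_calls, calls, out / "complex_calls.tsv")
            manifest["rows"]["complexes"] = len(calls)
            manifest["rows"]["rnp"] = int(calls["is_rnp"].sum())
            manifest["rows"]["rnp_select"] = int(calls["is_rnp_select"].sum())
        else:
            logger.info("no complex files given; complex stage skipped")

        stage = "evaluate"
        if ann.union:
            ranked = sig["p"].dropna().map(neg_ln_p)
            curve = precision_curve(ranked, ann.union)
            _write_stage(
                lambda df, p: df.to_csv(p, sep="\t", index=False),
                curve,
                out / "precision_curve.tsv",
            )
            manifest["rows"]["precision_curve"] = len(curve)
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
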
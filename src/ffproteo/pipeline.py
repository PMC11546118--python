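"""End-to-end orchestration: simulate/load -> score -> select -> effects ->
correlate -> report, with a JSON run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .cohort import AbundanceDataset, CohortConfig, simulate_cohort
from .correlation import wincor_matrix
from .effects import aggregate_repeats, estimate_all
from .errors import ConfigError, PipelineError, ReproducibilityError
from .forest import (ForestParams, ProteinScoreTable, accumulate_scores,
                     select_outlier_proteins)
from .io import read_dataset, write_dataset

FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialisable to/from YAML."""

    matrix: str | None = None
    metadata: str | None = None
    simulate: CohortConfig | None = None
    forest: ForestParams = field(default_factory=ForestParams)
    n_folds: int = 20
    n_cycles: int = 30
    step: float | int | str = 1
    fine_from: int = 0
    n_boot: int = 10_000
    ci_level: float = 0.95
    gamma: float = 0.2
    outlier_k: float = 1.5
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> None:
        if self.simulate is None:
            if self.matrix is None or self.metadata is None:
                raise ConfigError("matrix",
                                  "matrix+metadata required unless simulating")
            for name in ("matrix", "metadata"):
                if not Path(getattr(self, name)).exists():
                    raise ConfigError(name, f"{getattr(self, name)} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw.pop("simulate"))
            for key in ("fluids_per_patient_range", "repeat_sd_range",
                        "baseline_log_mean_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if "effects" in sim and sim["effects"] is not None:
                sim["effects"] = tuple((int(i), float(f)) for i, f in sim["effects"])
            if "block_proteins" in sim and sim["block_proteins"] is not None:
                sim["block_proteins"] = tuple(int(i) for i in sim["block_proteins"])
            known = {f.name for f in dataclasses.fields(CohortConfig)}
            bad = set(sim) - known
            if bad:
                raise ConfigError("simulate", f"unknown key(s) {sorted(bad)}")
            kwargs["simulate"] = CohortConfig(**sim)
        if "forest" in raw and raw["forest"] is not None:
            forest = dict(raw.pop("forest"))
            known = {f.name for f in dataclasses.fields(ForestParams)}
            bad = set(forest) - known
            if bad:
                raise ConfigError("forest", f"unknown key(s) {sorted(bad)}")
            kwargs["forest"] = ForestParams(**forest)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError("run", f"unknown key(s) {sorted(bad)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class ReportRow:
    protein_id: str
    score: float
    log2_fc: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class ReportTable:
    rows: list[ReportRow]


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, quiet: bool = True) -> ReportTable:
    """Run every stage and write scores/effects/corr/report TSVs plus a
    manifest into ``config.out_dir``; identical config+seed reproduces the
    TSVs byte for byte."""
    t_start = time.time()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_score, seed_effects = (int(s.generate_state(1)[0]) for s in ss.spawn(2))

    def log(msg: str) -> None:
        if not quiet:
            print(f"[ffproteo] {msg}", flush=True)

    artifacts: list[Path] = []

    # -- stage: input ---------------------------------------------------------
    try:
        if config.simulate is not None:
            log("simulating cohort")
            dataset = simulate_cohort(config.simulate)
            write_dataset(dataset, out / "matrix.tsv", out / "metadata.tsv")
            artifacts += [out / "matrix.tsv", out / "metadata.tsv"]
        else:
            log("loading dataset")
            dataset = read_dataset(config.matrix, config.metadata)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # -- stage: score ---------------------------------------------------------
    try:
        log(f"scoring ({config.n_cycles} cycles, {config.n_folds} folds)")
        table = accumulate_scores(
            dataset.intensities, dataset.labels, dataset.rows, config.forest,
            n_folds=config.n_folds, n_cycles=config.n_cycles, step=config.step,
            fine_from=config.fine_from,
            feature_ids=dataset.protein_ids, seed=seed_score)
        selected = select_outlier_proteins(table, k=config.outlier_k)
        scores_path = out / "scores.tsv"
        _write_tsv(scores_path, ["protein_id", "score", "selected"],
                   [[pid, _fmt(table.score[pid]),
                     str(int(table.selected[pid]))]
                    for pid in dataset.protein_ids])
        artifacts.append(scores_path)
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    selected_ordered = [pid for pid in dataset.protein_ids if pid in selected]
    if not selected_ordered:
        raise PipelineError("score", "no proteins selected; nothing to report")

    # -- stage: effects -------------------------------------------------------
    try:
        log(f"bootstrap effects for {len(selected_ordered)} proteins")
        estimates = estimate_all(dataset, selected_ordered,
                                 n_boot=config.n_boot, level=config.ci_level,
                                 seed=seed_effects)
        est_by_id = {e.protein_id: e for e in estimates}
        effects_path = out / "effects.tsv"
        effect_lines = {
            pid: [pid, _fmt(est_by_id[pid].log2_fc), _fmt(est_by_id[pid].ci_low),
                  _fmt(est_by_id[pid].ci_high),
                  str(int(est_by_id[pid].significant))]
            for pid in selected_ordered}
        _write_tsv(effects_path,
                   ["protein_id", "log2_fc", "ci_low", "ci_high", "significant"],
                   [effect_lines[pid] for pid in selected_ordered])
        artifacts.append(effects_path)
    except Exception as exc:
        raise PipelineError("effects", str(exc)) from exc

    # -- stage: correlate -----------------------------------------------------
    try:
        log("robust correlation of selected proteins")
        fl = aggregate_repeats(dataset)
        cm = wincor_matrix(fl.values[selected_ordered].to_numpy(),
                           gamma=config.gamma, proteins=selected_ordered)
        corr_path = out / "corr.tsv"
        _write_tsv(corr_path, ["protein_id"] + selected_ordered,
                   [[pid] + [_fmt(v) for v in cm.r[i]]
                    for i, pid in enumerate(selected_ordered)])
        artifacts.append(corr_path)
    except Exception as exc:
        raise PipelineError("correlate", str(exc)) from exc

    # -- stage: report --------------------------------------------------------
    try:
        rows = [ReportRow(pid, table.score[pid], est_by_id[pid].log2_fc,
                          est_by_id[pid].ci_low, est_by_id[pid].ci_high,
                          est_by_id[pid].significant)
                for pid in selected_ordered]
        rows.sort(key=lambda r: (-r.score, -abs(r.log2_fc), r.protein_id))
        report_path = out / "report.tsv"
        _write_tsv(report_path,
                   ["protein_id", "score", "log2_fc", "ci_low", "ci_high",
                    "significant"],
                   [[r.protein_id, _fmt(r.score), _fmt(r.log2_fc),
                     _fmt(r.ci_low), _fmt(r.ci_high), str(int(r.significant))]
                    for r in rows])
        artifacts.append(report_path)
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc

    make_manifest(config, {"score": seed_score, "effects": seed_effects},
                  artifacts, out / "manifest.json",
                  wall_seconds=time.time() - t_start)
    log("done")
    return ReportTable(rows=rows)


def make_manifest(config: RunConfig, stage_seeds: Mapping[str, int],
                  artifacts: list, path, wall_seconds: float | None = None) -> dict:
    """Write a JSON manifest with config, seeds, versions and checksums."""
    if not artifacts:
        raise ValueError("artifact list must be nonempty")
    import sklearn

    manifest = {
        "config": config.to_dict(),
        "master_seed": config.seed,
        "stage_seeds": dict(stage_seeds),
        "versions": {
            "ffproteo": __version__,
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "wall_seconds": wall_seconds,
        "artifacts": {Path(a).name: sha256_file(a) for a in artifacts},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def verify_manifest(manifest_path) -> None:
    """Check that the artifacts beside the manifest still match its checksums."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    mismatches = []
    for name, digest in manifest["artifacts"].items():
        target = manifest_path.parent / name
        if not target.exists() or sha256_file(target) != digest:
            mismatches.append(name)
    if mismatches:
        raise ReproducibilityError(
            f"checksum mismatch for artifact(s): {sorted(mismatches)}")


def replay_manifest(manifest_path, out_dir) -> ReportTable:
    """Re-run the pipeline from a manifest and verify identical checksums."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    cfg_dict["out_dir"] = str(out_dir)
    config = RunConfig.from_dict(cfg_dict)
    report = run_pipeline(config)
    with open(Path(out_dir) / "manifest.json") as fh:
        new_manifest = json.load(fh)
    if new_manifest["artifacts"] != manifest["artifacts"]:
        raise ReproducibilityError("replay produced different artifact checksums")
    return report
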
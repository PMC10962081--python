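"""End-to-end orchestration: simulate → cluster → exclusivity → profiles → association.

A single YAML-able config selects stages and carries every stage parameter;
all randomness derives from one global seed through per-stage sub-seeding
(SHA-256 of ``"<seed>:<stage>"``, truncated below 2^31), so adding a stage
never perturbs another's stream.  A JSON manifest recording the config
snapshot, per-stage status and output paths is written even when a stage
fails; stages depending on a failed one are skipped, independent branches
still run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .association import compare_association, knn_by_roi
from .clustering import ClusteringParams, mean_shift_cluster, width_distribution
from .exceptions import ValidationError
from .exclusivity import exclusivity_verdict, mark_connection, overlap_fraction
from .io_formats import (
    read_localisations,
    read_profiles,
    write_localisations,
    write_profiles,
    write_results,
)
from .profile_analysis import cross_correlate, find_peaks, spacing_stats
from .synthetic_data import (
    FibreSimConfig,
    ProfileSimConfig,
    simulate_fibre,
    simulate_paired_profiles,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate_fibre", "simulate_profiles", "cluster", "exclusivity", "profile", "assoc")

#: stage -> stages that must also be scheduled (or replaced by an input path)
_NEEDS = {
    "cluster": [("simulate_fibre", "locs_path")],
    "exclusivity": [("cluster", None), ("simulate_fibre", "locs_path")],
    "profile": [("simulate_profiles", "profiles_path")],
    "assoc": [("simulate_fibre", "locs_path")],
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Pipeline configuration; see the README for the YAML layout."""

    stages: list[str]
    seed: int = 0
    output_dir: str = "loopstate_out"
    locs_path: Optional[str] = None
    profiles_path: Optional[str] = None
    simulate_fibre: dict = field(default_factory=dict)
    simulate_profiles: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    exclusivity: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    assoc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" not in raw:
            raise ValidationError("config must list 'stages'")
        return cls(**raw)

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValidationError(f"unknown stage {s!r}; choose from {STAGES}")
        for stage, needs in _NEEDS.items():
            if stage not in self.stages:
                continue
            for dep, path_attr in needs:
                if dep in self.stages:
                    continue
                if path_attr and getattr(self, path_attr):
                    continue
                hint = f" or set {path_attr}" if path_attr else ""
                raise ValidationError(f"stage {stage!r} requires stage {dep!r}{hint}")
        if self.locs_path and not Path(self.locs_path).exists():
            raise ValidationError(f"locs_path does not exist: {self.locs_path}")
        if self.profiles_path and not Path(self.profiles_path).exists():
            raise ValidationError(f"profiles_path does not exist: {self.profiles_path}")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict]
    log_path: str

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the configured stages in dependency order; returns the manifest.

    The manifest (``manifest.json`` in the output directory) is written even
    if stages fail.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("loopstate")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        stages={},
        log_path=str(log_path),
    )
    state: dict[str, Any] = {}
    failed: set[str] = set()
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            blocked = {
                dep
                for dep, path_attr in _NEEDS.get(stage, [])
                if dep in failed and not (path_attr and getattr(config, path_attr))
            }
            if blocked:
                manifest.stages[stage] = {"status": "skipped", "blocked_by": sorted(blocked)}
                logger.warning("stage %s skipped (failed dependency %s)", stage, blocked)
                continue
            try:
                outputs = _run_stage(stage, config, state, out)
                manifest.stages[stage] = {"status": "ok", "outputs": outputs}
                logger.info("stage %s ok", stage)
            except Exception as exc:  # noqa: BLE001 - manifest must record any failure
                failed.add(stage)
                manifest.stages[stage] = {"status": "failed", "error": repr(exc)}
                logger.error("stage %s failed: %s\n%s", stage, exc, traceback.format_exc())
    finally:
        manifest.write(out / "manifest.json")
        root.removeHandler(handler)
        handler.close()
    return manifest


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> dict[str, str]:
    seed = stage_seed(config.seed, stage)
    outputs: dict[str, str] = {}

    if stage == "simulate_fibre":
        sim = FibreSimConfig(**{**config.simulate_fibre, "seed": seed})
        table, truth = simulate_fibre(sim)
        state["locs"] = table
        state["fibre_truth"] = truth
        path = out / "locs.csv"
        write_localisations(table, path)
        truth_path = out / "fibre_truth.json"
        with open(truth_path, "w") as fh:
            json.dump(_truth_dict(truth), fh, indent=2)
        outputs = {"locs": str(path), "truth": str(truth_path)}

    elif stage == "simulate_profiles":
        sim = ProfileSimConfig(**{**config.simulate_profiles, "seed": seed})
        profiles, truth = simulate_paired_profiles(sim)
        state["profiles"] = profiles
        state["profile_truth"] = truth
        path = out / "profiles.csv"
        write_profiles(profiles, path)
        outputs = {"profiles": str(path)}

    elif stage == "cluster":
        table = state.get("locs") or read_localisations(config.locs_path)
        state["locs"] = table
        opts = dict(config.cluster)
        marks = opts.pop("marks", table.marks)
        bins = np.asarray(opts.pop("width_bins", np.arange(0.0, 205.0, 5.0)), dtype=float)
        params = ClusteringParams(**opts)
        state["clusters"] = {}
        for mark in marks:
            cs = mean_shift_cluster(table, mark, params)
            state["clusters"][mark] = cs
            path = out / f"clusters_{mark}.csv"
            write_results(cs, path)
            outputs[f"clusters_{mark}"] = str(path)
            if len(cs):
                wd = width_distribution(cs, bins)
                wpath = out / f"widths_{mark}.csv"
                write_results(wd, wpath)
                outputs[f"widths_{mark}"] = str(wpath)

    elif stage == "exclusivity":
        table = state["locs"]
        opts = dict(config.exclusivity)
        mark_a, mark_b = opts.pop("marks", table.marks[:2])
        radius = opts.pop("radius", 50.0)
        scale_limit = opts.pop("scale_limit", 200.0)
        for clustered, other in ((mark_a, mark_b), (mark_b, mark_a)):
            ov = overlap_fraction(state["clusters"][clustered], table, other, radius=radius)
            path = out / f"overlap_{clustered}_vs_{other}.csv"
            write_results(ov, path)
            outputs[f"overlap_{clustered}"] = str(path)
        mcf = mark_connection(table, mark_a, mark_b, seed=seed, **opts)
        path = out / "mcf.csv"
        write_results(mcf, path)
        outputs["mcf"] = str(path)
        verdict = exclusivity_verdict(mcf, scale_limit=scale_limit)
        vpath = out / "mcf_verdict.csv"
        write_results(verdict, vpath)
        outputs["verdict"] = str(vpath)

    elif stage == "profile":
        profiles = state.get("profiles") or read_profiles(config.profiles_path)
        opts = dict(config.profile)
        factors = opts.pop("tolerance_factors", [0.17, 1.0])
        max_lag = opts.pop("max_lag", 1000.0)
        channel = opts.pop("channel", "b")
        for tol in factors:
            peaksets = [find_peaks(p, channel=channel, tolerance_factor=tol) for p in profiles]
            stats = spacing_stats(peaksets)
            path = out / f"spacings_tol{tol}.csv"
            write_results(stats, path)
            outputs[f"spacings_tol{tol}"] = str(path)
        xcorr = [cross_correlate(p, max_lag) for p in profiles]
        state["xcorr"] = xcorr
        rows = [r.to_document().meta for r in xcorr]
        path = out / "xcorr.json"
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
        outputs["xcorr"] = str(path)

    elif stage == "assoc":
        table = state.get("locs") or read_localisations(config.locs_path)
        opts = dict(config.assoc)
        mark_a = opts.get("mark_a", table.marks[0])
        mark_b = opts.get("mark_b", table.marks[1])
        reference = opts.get("reference", table.marks[-1])
        ks = opts.get("ks", [5, 9, 21])
        quantile = opts.get("quantile", 0.9)
        for k in ks:
            res_a = knn_by_roi(table, mark_a, reference, k)
            res_b = knn_by_roi(table, mark_b, reference, k)
            cmp = compare_association(res_a, res_b, quantile=quantile)
            path = out / f"assoc_k{k}.csv"
            write_results(cmp, path)
            outputs[f"assoc_k{k}"] = str(path)

    return outputs


def _truth_dict(truth) -> dict:
    out = {}
    for key, value in dataclasses.asdict(truth).items():
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, dict):
            value = {k: np.asarray(v).tolist() for k, v in value.items()}
        out[key] = value
    return out
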
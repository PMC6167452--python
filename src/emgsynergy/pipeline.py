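"""Pipeline orchestration: validated config, staged execution, artifacts.

A run is described by a single YAML-loadable config (validated before any
compute) and executes read/synthesize → preprocess → extract → cluster →
characterize, writing every intermediate result as tab-delimited text plus
a JSON manifest capturing config, seed and package versions. Reruns with
the same config and seed reproduce all outputs byte-identically. Each
stage can also be run from a prior stage's files alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .characterization import (
    centroid_dot_matrix,
    collect_temporal_components,
    match_within_grasp,
    temporal_correlation_matrix,
)
from .clustering import (
    ClusterSolution,
    build_population,
    ned_curve,
    select_cluster_order,
)
from .extraction import SynergySet, extract_dataset
from .io import read_matrix, read_ninapro_recording, write_matrix, write_table
from .preprocessing import preprocess_recording
from .synthetic import synthesize_dataset

logger = logging.getLogger("emgsynergy")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessingConfig(_StrictModel):
    hp_cutoff_hz: float = Field(50.0, gt=0)
    hp_order: int = Field(7, gt=0)
    lp_cutoff_hz: float = Field(10.0, gt=0)
    lp_order: int = Field(7, gt=0)
    envelope_out_fs: float = Field(100.0, gt=0)
    n_phase: int = Field(1000, ge=2)
    pad_ms: float = Field(0.0, ge=0)
    noisy_channel_rms_multiple: float = Field(3.0, gt=0)
    exclude_channels: list[int] = Field(default_factory=list)


class ExtractionConfig(_StrictModel):
    r_max: int = Field(12, ge=1)
    vaf_threshold: float = Field(0.90, gt=0, lt=1)
    vaf_increment: float = Field(0.05, gt=0, lt=1)
    nmf_reps: int = Field(1000, ge=1)
    nmf_max_iter: int = Field(500, ge=1)
    nmf_tol: float = Field(1e-6, gt=0)


class ClusteringConfig(_StrictModel):
    k_max: int = Field(50, ge=1)
    kmeans_repeats: int = Field(200, ge=1)
    ned_threshold: float = Field(0.05, gt=0, lt=1)


class SynthesisConfig(_StrictModel):
    n_subjects: int = Field(28, ge=1)
    n_grasps: int = Field(20, ge=1)
    n_channels: int = Field(12, ge=2)
    n_prototypes: int = Field(10, ge=1)
    n_reps: int = Field(6, ge=1)
    n_phase: int = Field(100, ge=10)
    subject_variability: float = Field(0.01, ge=0)
    noise_sd: float = Field(0.02, ge=0)


class RunConfig(_StrictModel):
    """Validated configuration for a full pipeline run."""

    synthesis: Optional[SynthesisConfig] = None
    input_dir: Optional[str] = None
    grasp_ids: Optional[list[int]] = None
    preprocessing: PreprocessingConfig = Field(default_factory=PreprocessingConfig)
    extraction: ExtractionConfig = Field(default_factory=ExtractionConfig)
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)
    master_seed: int = 0

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.synthesis is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of `synthesis` or `input_dir` must be given"
            )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.model_validate(yaml.safe_load(f) or {})

    @classmethod
    def test_profile(cls, **overrides) -> "RunConfig":
        """Reduced repetition counts for fast exploratory runs.

        Full-fidelity defaults (1000 NMF restarts, 200 k-means repeats,
        k_max 50) remain the library defaults.
        """
        cfg = cls.model_validate(overrides)
        cfg.extraction.nmf_reps = 20
        cfg.clustering.kmeans_repeats = 20
        cfg.clustering.k_max = 15
        return cfg


# ---------------------------------------------------------------------------
# stage I/O: synergy sets and cluster solutions as self-describing files


def save_synergy_sets(out_dir: str | Path, sets: list[SynergySet]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ss in sets:
        stem = f"{ss.subject_id}_{ss.grasp_id}"
        write_matrix(
            out_dir / f"{stem}_W.tsv",
            ss.W,
            row_names=[f"ch{i + 1}" for i in range(ss.W.shape[0])],
            col_names=[f"syn{j + 1}" for j in range(ss.N)],
        )
        write_matrix(
            out_dir / f"{stem}_C.tsv",
            ss.C,
            row_names=[f"syn{j + 1}" for j in range(ss.N)],
            col_names=[f"t{t + 1}" for t in range(ss.C.shape[1])],
        )
        write_matrix(
            out_dir / f"{stem}_vaf_curve.tsv",
            ss.vaf_curve[None, :],
            row_names=["vaf"],
            col_names=[f"r{r + 1}" for r in range(len(ss.vaf_curve))],
        )
        manifest.append(
            {
                "subject_id": ss.subject_id,
                "grasp_id": ss.grasp_id,
                "N": ss.N,
                "n_phase": ss.n_phase,
                "n_reps": ss.n_reps,
                "seed": ss.seed,
                "threshold_reached": ss.threshold_reached,
            }
        )
    with open(out_dir / "extraction_manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)


def load_synergy_sets(in_dir: str | Path) -> list[SynergySet]:
    in_dir = Path(in_dir)
    with open(in_dir / "extraction_manifest.json") as f:
        manifest = json.load(f)
    sets = []
    for entry in manifest:
        stem = f"{entry['subject_id']}_{entry['grasp_id']}"
        W, _, _ = read_matrix(in_dir / f"{stem}_W.tsv")
        C, _, _ = read_matrix(in_dir / f"{stem}_C.tsv")
        curve, _, _ = read_matrix(in_dir / f"{stem}_vaf_curve.tsv")
        sets.append(
            SynergySet(
                W=W,
                C=C,
                N=entry["N"],
                vaf_curve=curve.ravel(),
                subject_id=entry["subject_id"],
                grasp_id=entry["grasp_id"],
                seed=entry["seed"],
                n_phase=entry["n_phase"],
                n_reps=entry["n_reps"],
                threshold_reached=entry["threshold_reached"],
            )
        )
    return sets


def _write_cluster_outputs(out_dir: Path, curve, solution, pop) -> None:
    write_table(out_dir / "ned_curve.tsv", curve.table)
    write_matrix(
        out_dir / "centroids.tsv",
        solution.centroids,
        row_names=[f"centroid{c + 1}" for c in range(solution.k)],
        col_names=[f"ch{i + 1}" for i in range(solution.centroids.shape[1])],
    )
    prov = pop.provenance or [("", 0, 0)] * pop.size
    write_table(
        out_dir / "assignments.tsv",
        pd.DataFrame(
            {
                "subject_id": [p[0] for p in prov],
                "grasp_id": [p[1] for p in prov],
                "synergy_index": [p[2] for p in prov],
                "centroid": solution.assignments + 1,
            }
        ),
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis and write all artifacts under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed

    # --- input stage -------------------------------------------------------
    if config.synthesis is not None:
        logger.info("synthesizing dataset: %s", config.synthesis)
        syn = config.synthesis
        trials, _gt = synthesize_dataset(
            n_subjects=syn.n_subjects,
            n_grasps=syn.n_grasps,
            n_channels=syn.n_channels,
            n_prototypes=syn.n_prototypes,
            n_reps=syn.n_reps,
            n_phase=syn.n_phase,
            subject_variability=syn.subject_variability,
            noise_sd=syn.noise_sd,
            seed=seed,
        )
    else:
        trials = []
        pp = config.preprocessing
        paths = sorted(Path(config.input_dir).glob("*.mat"))
        if not paths:
            raise FileNotFoundError(f"no .mat files in {config.input_dir}")
        for path in paths:
            rec = read_ninapro_recording(path)
            if not rec.subject_id:
                rec.subject_id = path.stem
            logger.info("preprocessing %s (%d samples)", path.name, rec.n_samples)
            trials.extend(
                preprocess_recording(
                    rec,
                    hp_cutoff_hz=pp.hp_cutoff_hz,
                    hp_order=pp.hp_order,
                    lp_cutoff_hz=pp.lp_cutoff_hz,
                    lp_order=pp.lp_order,
                    envelope_out_fs=pp.envelope_out_fs,
                    n_phase=pp.n_phase,
                    pad_ms=pp.pad_ms,
                    grasp_ids=set(config.grasp_ids) if config.grasp_ids else None,
                    exclude_channels=pp.exclude_channels,
                )
            )

    # --- extraction --------------------------------------------------------
    ex = config.extraction
    log: list[str] = []
    sets = extract_dataset(
        trials,
        r_max=ex.r_max,
        vaf_threshold=ex.vaf_threshold,
        increment=ex.vaf_increment,
        n_reps=ex.nmf_reps,
        max_iter=ex.nmf_max_iter,
        tol=ex.nmf_tol,
        master_seed=seed,
        log=log,
    )
    for line in log:
        logger.warning(line)
    logger.info(
        "extracted %d synergy sets, %d modules total",
        len(sets),
        sum(ss.N for ss in sets),
    )
    save_synergy_sets(out_dir / "synergies", sets)

    # --- clustering --------------------------------------------------------
    cl = config.clustering
    pop = build_population(sets)
    k_max = min(cl.k_max, pop.size)
    curve = ned_curve(pop, k_max=k_max, n_repeats=cl.kmeans_repeats, seed=seed)
    selected_k = select_cluster_order(curve, threshold=cl.ned_threshold)
    solution = curve.solutions[selected_k]
    logger.info("selected clustering order %d (NED %.4f)", selected_k, solution.ned)
    _write_cluster_outputs(out_dir, curve, solution, pop)

    # --- characterization --------------------------------------------------
    profiles = collect_temporal_components(solution, pop, sets)
    dot = centroid_dot_matrix(solution.centroids)
    corr = temporal_correlation_matrix(profiles)
    names = [f"centroid{c + 1}" for c in range(solution.k)]
    write_matrix(out_dir / "centroid_dot.tsv", dot, names, names)
    write_matrix(out_dir / "temporal_corr.tsv", corr, names, names)
    prof_tbl = pd.DataFrame(
        [
            {
                "centroid": c + 1,
                "share_pct": p.share,
                **{
                    f"ch{i + 1}": p.centroid[i]
                    for i in range(p.centroid.shape[0])
                },
                **{
                    f"phase{t}": p.mean_temporal[t]
                    for t in range(p.mean_temporal.shape[0])
                },
            }
            for c, p in enumerate(profiles)
        ]
    )
    write_table(out_dir / "centroid_profiles.tsv", prof_tbl)

    grasp_dir = out_dir / "grasp_summary"
    grasp_dir.mkdir(exist_ok=True)
    for grasp in sorted({ss.grasp_id for ss in sets}):
        members = [ss for ss in sets if ss.grasp_id == grasp]
        if len([m for m in members if m.N > 0]) < 2:
            logger.warning("grasp %s: fewer than 2 subjects, no matching", grasp)
            continue
        matched = match_within_grasp(members)
        n_show = min(3, matched.slot_spatial.shape[0])
        rows = []
        for s in range(n_show):
            rows.append(
                {
                    "slot": s + 1,
                    **{
                        f"ch{i + 1}": matched.slot_spatial[s, i]
                        for i in range(matched.slot_spatial.shape[1])
                    },
                    **{
                        f"phase{t}": matched.slot_temporal[s, t]
                        for t in range(matched.slot_temporal.shape[1])
                    },
                }
            )
        write_table(grasp_dir / f"grasp_{grasp}.tsv", pd.DataFrame(rows))

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": seed,
        "version": __version__,
        "numpy_version": np.__version__,
        "n_synergy_sets": len(sets),
        "n_modules": int(pop.size),
        "selected_k": int(selected_k),
        "ned_at_selected_k": float(solution.ned),
    }
    with open(out_dir / "run_manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return out_dir


def load_cluster_solution(run_dir: str | Path) -> tuple[ClusterSolution, pd.DataFrame]:
    """Rebuild the selected ClusterSolution from a run directory's files."""
    run_dir = Path(run_dir)
    centroids, _, _ = read_matrix(run_dir / "centroids.tsv")
    assign = pd.read_csv(run_dir / "assignments.tsv", sep="\t")
    curve = pd.read_csv(run_dir / "ned_curve.tsv", sep="\t")
    k = centroids.shape[0]
    assignments = assign["centroid"].to_numpy() - 1
    X_row = curve.loc[curve["k"] == k]
    sol = ClusterSolution(
        k=k,
        centroids=centroids,
        assignments=assignments,
        med=float(X_row["MED"].iloc[0]) if len(X_row) else np.nan,
        ned=float(X_row["NED"].iloc[0]) if len(X_row) else np.nan,
    )
    return sol, assign
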
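"""Pipeline orchestration: configuration, seeding, manifests and fixtures.

A :class:`PipelineConfig` (TOML or YAML on disk) plus a master seed fully
determine every output.  The master seed spawns per-stage child seeds by
stable hashing of the stage name, so adding a stage does not perturb the
random streams of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from .analysis import AnalysisOptions, run_full_analysis
from .phantom import CohortSpec, simulate_cohort, write_dataset, read_dataset
from .schemes import generate_multishell_set, read_directions

__all__ = ["PipelineConfig", "stage_seed", "run", "make_fixtures", "load_config"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: crc32(stage) xor master, < 2³¹."""
    return (zlib.crc32(stage.encode()) ^ master_seed) & 0x7FFFFFFF


class SchemeConfig(BaseModel):
    """Either paths to bvec/bval files or generator parameters."""

    bvec_path: str | None = None
    bval_path: str | None = None
    n_low: int = 22
    n_high: int = 43
    b_low: float = 1000.0
    b_high: float = 2700.0


class CohortConfig(BaseModel):
    n_control: int = 15
    n_eae: int = 16
    between_animal_cv: float = 0.05
    eae_attenuation: float = 0.033
    snr_b0: float = 79.5
    shape: tuple[int, int, int] = (48, 48, 6)
    voxel_size: tuple[float, float, float] = (0.08, 0.08, 0.2)


class AnalysisConfig(BaseModel):
    features: tuple[str, ...] = ("FA", "MD", "RD")
    standardize: bool = False
    alpha: float = 0.05
    fit_dki: bool = False


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "hippodti_out"
    scheme: SchemeConfig = Field(default_factory=SchemeConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    write_datasets: bool = False


def load_config(path: str | Path) -> PipelineConfig:
    """Load TOML (preferred) or YAML configuration with schema validation."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text) or {}
    else:
        import tomllib

        data = tomllib.loads(text)
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as e:
        keys = sorted({".".join(str(p) for p in err["loc"]) for err in e.errors()})
        raise ValueError(f"invalid config {path}: offending keys {keys}") from e


def _build_schemes(cfg: PipelineConfig):
    sc = cfg.scheme
    if sc.bvec_path and sc.bval_path:
        shells, _ = read_directions(sc.bvec_path, sc.bval_path)
        if not shells:
            raise ValueError(f"no nonzero-b shells in {sc.bvec_path}")
        return shells
    low, high = generate_multishell_set(
        sc.n_low, sc.n_high, seed=stage_seed(cfg.seed, "schemes"),
        bvalues=(sc.b_low, sc.b_high),
    )
    return [low, high]


def run(config: PipelineConfig | str | Path) -> Path:
    """simulate → reconstruct/subsample → fit → qc → analyze; returns out dir.

    Writes CSV tables (voi_table, qc_table, layer_tests, clustering,
    eae_tests), a JSON summary and a manifest (config hash, seed, version).
    Re-running with an identical config is bit-identical.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    shells = _build_schemes(cfg)
    spec = CohortSpec(
        n_control=cfg.cohort.n_control,
        n_eae=cfg.cohort.n_eae,
        between_animal_cv=cfg.cohort.between_animal_cv,
        eae_attenuation=cfg.cohort.eae_attenuation,
        snr_b0=cfg.cohort.snr_b0,
        seed=stage_seed(cfg.seed, "cohort"),
        shape=tuple(cfg.cohort.shape),
        voxel_size=tuple(cfg.cohort.voxel_size),
    )
    cohort, truth = simulate_cohort(spec, shells)
    truth.to_csv(out / "ground_truth.csv", index=False)
    if cfg.write_datasets:
        for ds in cohort:
            write_dataset(ds, out / "cohort" / ds.animal_id)

    options = AnalysisOptions(
        features=tuple(cfg.analysis.features),
        standardize=cfg.analysis.standardize,
        alpha=cfg.analysis.alpha,
        fit_dki=cfg.analysis.fit_dki,
    )
    bundle = run_full_analysis(cohort, options, seed=stage_seed(cfg.seed, "analysis"))
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False)

    summary = {
        "n_control": spec.n_control,
        "n_eae": spec.n_eae,
        "dataset_labels": sorted(set(bundle["voi_table"]["dataset_label"])),
        "ari": {
            r["dataset_label"]: r["ari"] for _, r in bundle["clustering"].iterrows()
        }
        if len(bundle["clustering"])
        else {},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
    try:
        pkg_version = _pkg_version("hippodti")
    except PackageNotFoundError:
        pkg_version = "unknown"
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "hippodti_version": pkg_version,
        "numpy_version": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def make_fixtures(seed: int, out_dir: str | Path = "fixtures") -> dict:
    """Deterministic tiny golden cohort plus content checksums for tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shells = list(
        generate_multishell_set(8, 12, seed=stage_seed(seed, "fixture-schemes"))
    )
    spec = CohortSpec(
        n_control=2,
        n_eae=0,
        snr_b0=50.0,
        seed=stage_seed(seed, "fixture-cohort"),
        shape=(24, 24, 3),
    )
    cohort, truth = simulate_cohort(spec, shells)
    checksums = {}
    for ds in cohort:
        write_dataset(ds, out / ds.animal_id)
        checksums[ds.animal_id] = hashlib.sha256(
            np.ascontiguousarray(ds.volumes).tobytes()
        ).hexdigest()
    truth.to_csv(out / "ground_truth.csv", index=False)
    (out / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return checksums
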
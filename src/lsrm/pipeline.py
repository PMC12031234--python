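"""Config-driven end-to-end runs: ingest -> preprocess -> denoise ->
postprocess -> metrics -> projections.

A run writes a self-contained directory (denoised stack, per-slice metric
CSV, loss traces, projection images and a JSON manifest capturing the full
configuration, seeds and library versions) so results are exactly
reproducible.  Ablation variants — denoising without the pre/post chain —
are expressed by switching the corresponding config sections off.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dip import DIPConfig, DIPResult, EarlyStopRule, denoise_stack
from .image_io import ImageSlice, ImageStack, read_stack, write_stack
from .metrics import MetricReport, qc_curves
from .phantom import PhantomSpec, PhantomVolume, generate_spheroid_phantom
from .preprocess import (
    PostprocessConfig,
    PreprocessConfig,
    apply_postprocess,
    apply_preprocess,
)
from .volume import render_volume

__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline", "compare_runs"]


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Exactly one of ``phantom`` / ``input_path`` must be set.  ``preprocess``
    or ``postprocess`` set to ``None`` switches that part of the chain off
    (the denoiser then consumes the raw noisy slices), reproducing the
    with/without-processing comparison.
    """

    phantom: PhantomSpec | None = None
    input_path: str | None = None
    reference_path: str | None = None
    preprocess: PreprocessConfig | None = field(default_factory=PreprocessConfig)
    dip: DIPConfig = field(default_factory=DIPConfig)
    postprocess: PostprocessConfig | None = field(default_factory=PostprocessConfig)
    metric_reference: str = "noisy_input"
    slice_indices: list[int] | None = None

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.input_path is None):
            raise ValueError("set exactly one of phantom / input_path")
        if self.metric_reference not in ("noisy_input", "clean_truth"):
            raise ValueError("metric_reference must be 'noisy_input' or 'clean_truth'")
        if self.metric_reference == "clean_truth" and self.phantom is None:
            raise ValueError("clean_truth reference requires a phantom input")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "phantom": conv(self.phantom) if self.phantom else None,
            "input_path": self.input_path,
            "reference_path": self.reference_path,
            "preprocess": conv(self.preprocess) if self.preprocess else None,
            "dip": conv(self.dip),
            "postprocess": conv(self.postprocess) if self.postprocess else None,
            "metric_reference": self.metric_reference,
            "slice_indices": self.slice_indices,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(factory, section):
            if section is None:
                return None
            return factory(**section)

        dip_raw = dict(raw.get("dip") or {})
        if "early_stop" in dip_raw and isinstance(dip_raw["early_stop"], dict):
            dip_raw["early_stop"] = EarlyStopRule(**dip_raw["early_stop"])
        pre_raw = raw.get("preprocess")
        if pre_raw and "clahe_tile_grid" in pre_raw:
            pre_raw = dict(pre_raw)
            pre_raw["clahe_tile_grid"] = tuple(pre_raw["clahe_tile_grid"])
        return cls(
            phantom=build(PhantomSpec, raw.get("phantom")),
            input_path=raw.get("input_path"),
            reference_path=raw.get("reference_path"),
            preprocess=build(PreprocessConfig, pre_raw),
            dip=DIPConfig(**dip_raw),
            postprocess=build(PostprocessConfig, raw.get("postprocess")),
            metric_reference=raw.get("metric_reference", "noisy_input"),
            slice_indices=raw.get("slice_indices"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineRun:
    run_dir: Path
    config: PipelineConfig
    noisy: ImageStack
    denoised: ImageStack
    report: MetricReport
    clean: ImageStack | None = None
    dip_results: list[DIPResult] = field(default_factory=list)


def _subset(stack: ImageStack, indices: list[int] | None) -> ImageStack:
    if indices is None:
        return stack
    return ImageStack([stack[i] for i in indices], stack.z_step_um)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> PipelineRun:
    """Execute the full chain and persist all artifacts under ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "ingest"
    try:
        clean = None
        reference_stack = None
        if config.phantom is not None:
            volume = generate_spheroid_phantom(config.phantom)
            noisy = _subset(volume.noisy, config.slice_indices)
            clean = _subset(volume.clean, config.slice_indices)
            reference_stack = _subset(volume.background, config.slice_indices)
        else:
            noisy = _subset(
                read_stack(config.input_path, normalize=True), config.slice_indices
            )
            if config.reference_path:
                reference_stack = _subset(
                    read_stack(config.reference_path, normalize=True),
                    config.slice_indices,
                )

        stage = "preprocess"
        if config.preprocess is not None:
            pre_slices = []
            for i, s in enumerate(noisy):
                ref = reference_stack[i] if reference_stack is not None else None
                pre_slices.append(apply_preprocess(s, config.preprocess, ref))
            target = ImageStack(pre_slices, noisy.z_step_um)
        else:
            target = noisy

        stage = "denoise"
        denoised, dip_results = denoise_stack(target, config.dip)

        stage = "postprocess"
        if config.postprocess is not None:
            denoised = ImageStack(
                [apply_postprocess(s, config.postprocess) for s in denoised],
                denoised.z_step_um,
            )

        stage = "metrics"
        if config.metric_reference == "clean_truth":
            report = qc_curves(clean, denoised, "clean_truth")
        else:
            report = qc_curves(noisy, denoised, "noisy_input")

        stage = "outputs"
        write_stack(denoised, run_dir / "denoised.tiff")
        write_stack(noisy, run_dir / "noisy.tiff")
        if clean is not None:
            write_stack(clean, run_dir / "clean.tiff")
        report.to_csv(run_dir / "metrics.csv")
        traces = pd.DataFrame(
            {
                f"slice_{i}": pd.Series(r.loss_trace)
                for i, r in enumerate(dip_results)
            }
        )
        traces.to_csv(run_dir / "loss_traces.csv", index=False)
        if denoised.n_slices > 1:
            render_volume(denoised, run_dir, prefix="denoised")

        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "package_version": __version__,
            "numpy_version": np.__version__,
            "n_slices": denoised.n_slices,
            "stop_iterations": [r.stop_iteration for r in dip_results],
            "aggregate_metrics": report.aggregate,
            "reference_convention": report.reference_convention,
            "elapsed_s": round(time.time() - t0, 3),
        }
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return PipelineRun(run_dir, config, noisy, denoised, report, clean, dip_results)


def compare_runs(run_a: str | Path, run_b: str | Path) -> pd.DataFrame:
    """Side-by-side aggregate metric deltas of two runs on the same input.

    Raises when the two manifests disagree on the input definition.
    """
    rows = []
    manifests = []
    for d in (run_a, run_b):
        manifest_path = Path(d) / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(manifest_path)
        manifests.append(json.loads(manifest_path.read_text()))
    key_a = (manifests[0]["config"]["phantom"], manifests[0]["config"]["input_path"])
    key_b = (manifests[1]["config"]["phantom"], manifests[1]["config"]["input_path"])
    if key_a != key_b:
        raise ValueError("runs were produced from different inputs")
    for metric in ("psnr_db", "ssim", "rmse", "frc_mean"):
        a = manifests[0]["aggregate_metrics"][metric]
        b = manifests[1]["aggregate_metrics"][metric]
        rows.append(
            {"metric": metric, "run_a": a, "run_b": b, "delta": b - a}
        )
    return pd.DataFrame(rows)
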
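"""End-to-end orchestration: phantom/input -> tensor fit -> whole-volume
tractography -> TD map -> per-muscle TD-stopped tractography -> fascicle
lengths, with a reproducibility manifest.

The two-pass architecture is explicit: the whole-volume first pass exists
only to build the tract-density map; the per-muscle second pass seeds the
eroded muscle masks and halts where normalized TD exceeds the threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from tdtract import dwi_data, phantom as phantom_mod
from tdtract.dwi_data import DWIStack, GradientTable, LabelVolume, write_scalar
from tdtract.fascicle_length import (
    FascicleLengthResult,
    compare_methods,
    muscle_fascicle_pipeline,
    results_table,
)
from tdtract.tensor_fit import fa_map, fit_wlls, write_tensor
from tdtract.tracking import StoppingConfig, seed_grid, track
from tdtract.tract_density import TractDensityMap, compute_td

log = logging.getLogger("tdtract")


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full run; defaults are the standard protocol.

    Pass 1 (whole volume): FA 0.1-0.7, 20 degrees/step, 1 mm steps, 2 mm
    minimum length, 1 mm seed spacing.  Pass 2 (per muscle): 10 degrees,
    20 mm minimum, step 0.2 of the in-plane voxel, TD threshold 1.5, seeds
    in the mask eroded to 90%.  The FA-only comparison uses 0.15-0.65.
    """

    out_dir: str = "tdtract_out"
    dwi_path: str | None = None
    bvec_path: str | None = None
    bval_path: str | None = None
    labels_path: str | None = None
    noise_path: str | None = None
    phantom: dict | None = None  # PhantomSpec overrides; generate when set

    working_voxel_size: tuple[float, float, float] = (1.5, 1.5, 3.0)

    pass1_fa_range: tuple[float, float] = (0.1, 0.7)
    pass1_max_angle: float = 20.0
    pass1_step_mm: float = 1.0
    pass1_min_length_mm: float = 2.0
    pass1_seed_spacing_mm: float = 1.0

    td_threshold: float = 1.5
    erosion_fraction: float = 0.9
    pass2_fa_range: tuple[float, float] = (0.1, 0.7)
    pass2_max_angle: float = 10.0
    pass2_step_voxel_fraction: float = 0.2
    pass2_min_length_mm: float = 20.0
    pass2_seed_spacing_mm: float = 2.0

    fa_comparison_range: tuple[float, float] = (0.15, 0.65)
    min_fit_sample: int = 50
    seed: int = 0
    compare_muscle: int | None = None  # run the 3-method comparison here

    def __post_init__(self) -> None:
        if self.td_threshold <= 1.0:
            raise ValueError("td_threshold must exceed 1")
        if not (0.0 < self.erosion_fraction < 1.0):
            raise ValueError("erosion_fraction must lie in (0, 1)")
        for rng_ in (self.pass1_fa_range, self.pass2_fa_range, self.fa_comparison_range):
            lo, hi = rng_
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"invalid FA range {rng_}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("working_voxel_size", "pass1_fa_range", "pass2_fa_range",
                    "fa_comparison_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def pass1_config(self) -> StoppingConfig:
        return StoppingConfig(
            fa_range=self.pass1_fa_range,
            max_angle_per_step=self.pass1_max_angle,
            step_length=self.pass1_step_mm,
            min_length=self.pass1_min_length_mm,
        )


def _array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a result bundle (also written to disk).

    The manifest records inputs, parameters, per-stage timing and content
    hashes of every numeric output, so two runs with the same config and
    seed can be compared bit-for-bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "hashes": {}}
    t_all = time.time()

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.time()
                log.info("stage %s ...", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest["stages"][name] = round(time.time() - self_.t0, 3)
                if exc is not None:
                    manifest["failed_stage"] = name
                    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                return False

        return _Timer()

    # --- inputs --------------------------------------------------------------
    truth = None
    with stage("inputs"):
        if config.phantom is not None:
            spec = phantom_mod.PhantomSpec(**{**config.phantom, "seed": config.seed})
            dataset = phantom_mod.generate_phantom(spec)
            phantom_mod.write_phantom(dataset, out / "phantom")
            stack, table = dataset.dwi, dataset.table
            labels = dataset.truth.muscle_labels
            noise = dataset.noise_volume
            truth = dataset.truth
            manifest["phantom"] = spec.to_dict()
        else:
            if not (config.dwi_path and config.bvec_path and config.bval_path
                    and config.labels_path):
                raise ValueError("either phantom or dwi/bvec/bval/labels paths required")
            stack, table = dwi_data.read_dwi(
                config.dwi_path, config.bvec_path, config.bval_path
            )
            labels = dwi_data.read_labels(config.labels_path)
            noise = None
            if config.noise_path:
                import nibabel as nib

                noise = np.asarray(nib.load(config.noise_path).get_fdata())

    with stage("resample"):
        if not np.allclose(stack.voxel_size, config.working_voxel_size):
            stack = dwi_data.resample(stack, config.working_voxel_size)
            if labels.labels.shape != stack.shape:
                raise ValueError(
                    "label grid does not match the working grid; provide labels "
                    "at the working resolution"
                )

    # --- tensor fit ----------------------------------------------------------
    with stage("tensor_fit"):
        tensors = fit_wlls(stack, table)
        fa = fa_map(tensors)
        write_tensor(tensors, out / "tensor.nii.gz")
        write_scalar(fa, out / "fa.nii.gz")
        manifest["hashes"]["tensor"] = _array_hash(tensors.components)
        manifest["hashes"]["fa"] = _array_hash(fa.values)

    with stage("snr"):
        if noise is not None:
            mask = labels.labels > 0
            snr, summary = dwi_data.snr_map(stack, table, noise, mask)
            write_scalar(snr, out / "snr.nii.gz")
            manifest["snr_summary"] = round(summary, 3)

    # --- pass 1: whole-volume tractography and TD ---------------------------
    with stage("pass1_tracking"):
        b0 = stack.b0_volume(table)
        foreground = foreground_mask(b0)
        seeds = seed_grid(foreground, stack.affine, config.pass1_seed_spacing_mm)
        tg1 = track(
            seeds, tensors, fa, config.pass1_config(),
            seeding={"mode": "whole_volume", "spacing_mm": config.pass1_seed_spacing_mm},
        )
        manifest["pass1"] = {"n_seeds": len(seeds), "n_streamlines": len(tg1)}

    with stage("td_map"):
        td = compute_td(tg1, foreground, stack.affine)
        del tg1
        write_scalar(td.normalized, out / "td.nii.gz")
        manifest["hashes"]["td"] = _array_hash(td.values)
        manifest["td_normalization_constant"] = td.normalization_constant

    # --- pass 2: per-muscle fascicle lengths ---------------------------------
    results: list[FascicleLengthResult] = []
    with stage("fascicle_lengths"):
        for muscle_id in labels.present_labels:
            res = muscle_fascicle_pipeline(
                tensors, fa, labels, muscle_id, td=td, mode="td",
                seed_spacing=config.pass2_seed_spacing_mm,
                erosion_fraction=config.erosion_fraction,
                min_sample=config.min_fit_sample,
                config=_pass2_config(config, stack.voxel_size, td),
            )
            results.append(res)
            manifest["hashes"][f"lengths_muscle{muscle_id}"] = _array_hash(res.lengths)
        table_df = results_table(results)
        table_df.to_csv(out / "fascicle_lengths.csv", index=False)

    comparison = None
    with stage("method_comparison"):
        if config.compare_muscle is not None:
            comparison, hist = compare_methods(
                tensors, fa, labels, config.compare_muscle, td,
                seed_spacing=config.pass2_seed_spacing_mm,
                erosion_fraction=config.erosion_fraction,
                min_sample=config.min_fit_sample,
            )
            hist.to_csv(out / "method_histograms.csv", index=False)
            results_table(list(comparison.values())).to_csv(
                out / "method_comparison.csv", index=False
            )
            for mode, r in comparison.items():
                manifest["hashes"][f"compare_{mode}"] = _array_hash(r.lengths)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest["hashes"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "tensors": tensors,
        "fa": fa,
        "td": td,
        "labels": labels,
        "results": results,
        "comparison": comparison,
        "manifest": manifest,
        "truth": truth,
    }


def _pass2_config(config: RunConfig, voxel_size, td: TractDensityMap) -> StoppingConfig:
    return StoppingConfig(
        fa_range=config.pass2_fa_range,
        max_angle_per_step=config.pass2_max_angle,
        step_length=config.pass2_step_voxel_fraction * float(np.min(voxel_size[:2])),
        min_length=config.pass2_min_length_mm,
        td_threshold=config.td_threshold,
        td_map=td.normalized,
    )


def foreground_mask(b0: np.ndarray, rel_threshold: float = 0.25) -> np.ndarray:
    """Tissue foreground from the b=0 volume.

    Voxels above ``rel_threshold`` of the robust (99th percentile) maximum
    are foreground; air in magnitude MR sits far below any tissue class,
    so a fixed relative threshold is stable even when the air fraction is
    small (where histogram-based thresholds misbehave).
    """
    b0 = np.asarray(b0, dtype=float)
    if b0.max() <= 0:
        raise ValueError("b=0 volume is empty")
    return b0 > rel_threshold * np.percentile(b0, 99)
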
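"""End-to-end per-pore image-quality evaluation.

`PoreQualityModel` is built from a reconstructed gray volume plus (optionally)
precomputed segmentations, or directly from a phantom specification; its
``fit()`` runs the full chain

    segmentation -> isolated-pore labeling -> size/sphericity filter
    -> edge-spread resolution -> erosion-based SNR -> aggregation

and returns a `PoreQualityResults` carrying one record per labeled pore,
Table-style aggregates (mean +/- STD and count for SNR and resolution), an
exclusion ledger and a ``summary()`` table. The procedure needs no user
input beyond the configuration, so comparisons between scans are unbiased;
given the same configuration (and seed, for phantom inputs) the output is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import edge_profile as ep
from . import segmentation as seg
from . import snr as snr_mod
from .phantom import PhantomGroundTruth, PhantomSpec, generate_phantom
from .snr import QualitySummary, aggregate_quality
from .volume_io import (
    BinaryMask,
    GrayVolume,
    PoreLabelVolume,
    read_volume,
    write_pore_table,
)

__all__ = ["RunConfig", "PoreQualityRecord", "PoreQualityModel", "PoreQualityResults"]


@dataclass
class RunConfig:
    """All tunable parameters of an evaluation run.

    Every field is echoed verbatim into the output summary for provenance.
    Defaults follow the published analysis protocol: pores kept with more
    than 1000 voxels and sphericity < 1.3, erosion with a radius-5 ball,
    more than 100 voxels required after erosion, distance shells in steps of
    one voxel.
    """

    threshold: float | str = "otsu"  # gray threshold or "otsu"
    segmentation_smooth_sigma: float = 1.0  # voxels; segmentation only
    connectivity: int = 26
    min_voxels: int = 1000
    max_sphericity: float = 1.3
    erosion_radius: int = 5
    snr_min_voxels: int = 100
    local_shell: float = 15.0  # voxels; scaffold neighborhood radius
    scaffold_mode: str = "local"  # or "global"
    max_range: int = 10  # outside shell range, voxels
    level_constant: float = ep.LEVEL_CONSTANT
    contrast_floor: float = 1e-9
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class PoreQualityRecord:
    """Everything measured (or flagged) for one labeled pore."""

    label: int
    voxel_count: int
    volume_um3: float
    surface_area_um2: float
    sphericity: float
    passed_size_filter: bool
    passed_shape_filter: bool
    touches_boundary: bool = False
    # SNR block
    snr: float | None = None
    snr_valid: bool = False
    mu_pore: float | None = None
    mu_scaffold: float | None = None
    sigma_pore: float | None = None
    sigma_scaffold: float | None = None
    n_pore_voxels_eroded: int | None = None
    passed_erosion_filter: bool = False
    # resolution block
    resolution_nm: float | None = None
    fwhm_model_nm: float | None = None
    fit_A1: float | None = None
    fit_A2: float | None = None
    fit_x0: float | None = None
    fit_sigma: float | None = None
    fit_rmse: float | None = None
    crossing_x1: float | None = None
    crossing_x2: float | None = None
    fit_ok: bool = False
    failure_reason: str = ""


class PoreQualityModel:
    """Per-pore resolution and SNR evaluation of one reconstructed volume.

    Parameters
    ----------
    volume : GrayVolume
        The raw floating-point reconstruction; all gray statistics are
        computed on it, never on a rescaled or smoothed copy.
    pore_mask : BinaryMask, optional
        Precomputed binary segmentation of the whole pore space (isolated
        and connected). Derived by thresholding when absent.
    labels : PoreLabelVolume, optional
        Precomputed labeling of the isolated pores. Derived from
        ``pore_mask`` by dropping boundary-connected components when absent.
    bone_mask : BinaryMask, optional
        Mineralized-tissue mask; pores in contact with it are not isolated.
    config : RunConfig, optional
    ground_truth : PhantomGroundTruth, optional
        Attached automatically by :meth:`from_phantom`.
    """

    def __init__(
        self,
        volume: GrayVolume,
        pore_mask: BinaryMask | None = None,
        labels: PoreLabelVolume | None = None,
        bone_mask: BinaryMask | None = None,
        config: RunConfig | None = None,
        ground_truth: PhantomGroundTruth | None = None,
    ) -> None:
        self.volume = volume
        self.pore_mask = pore_mask
        self.labels = labels
        self.bone_mask = bone_mask
        self.config = config or RunConfig()
        self.ground_truth = ground_truth
        for other in (pore_mask, labels, bone_mask):
            if other is not None and other.shape != volume.shape:
                raise ValueError("mask/label shape differs from volume shape")

    # ------------------------------------------------------------------
    @classmethod
    def from_phantom(
        cls,
        spec: PhantomSpec,
        config: RunConfig | None = None,
        use_true_labels: bool = False,
    ) -> "PoreQualityModel":
        """Build the model from a synthetic phantom with known ground truth.

        The segmentation threshold defaults to the mid-gray between the
        scaffold and pore levels. With ``use_true_labels`` the generator's
        label volume bypasses segmentation entirely.
        """
        volume, gt = generate_phantom(spec)
        if config is None:
            config = RunConfig(seed=spec.seed)
        if config.threshold == "otsu":
            config = dataclasses.replace(
                config, threshold=0.5 * (spec.gray_scaffold + spec.gray_pore)
            )
        labels = gt.true_label_volume if use_true_labels else None
        return cls(volume, labels=labels, config=config, ground_truth=gt)

    @classmethod
    def from_files(
        cls,
        volume_path: str | Path,
        mask_path: str | Path | None = None,
        labels_path: str | Path | None = None,
        bone_path: str | Path | None = None,
        config: RunConfig | None = None,
        voxel_size: float | None = None,
    ) -> "PoreQualityModel":
        vol = read_volume(volume_path, voxel_size)
        mask = None
        if mask_path is not None:
            mv = read_volume(mask_path, voxel_size)
            mask = BinaryMask(mv.values > 0, vol.voxel_size)
        labels = None
        if labels_path is not None:
            lv = read_volume(labels_path, voxel_size)
            labels = PoreLabelVolume(lv.values.astype(np.int32), vol.voxel_size)
        bone = None
        if bone_path is not None:
            bv = read_volume(bone_path, voxel_size)
            bone = BinaryMask(bv.values > 0, vol.voxel_size)
        return cls(vol, mask, labels, bone, config)

    # ------------------------------------------------------------------
    def _segment(self) -> tuple[BinaryMask, PoreLabelVolume]:
        cfg = self.config
        mask = self.pore_mask
        if mask is None:
            if self.labels is not None:
                mask = BinaryMask(self.labels.values > 0, self.volume.voxel_size)
            else:
                thr = cfg.threshold
                if thr == "otsu":
                    from skimage.filters import threshold_otsu

                    thr = float(threshold_otsu(self.volume.values))
                mask = seg.binarize(self.volume, float(thr),
                                    smooth_sigma=cfg.segmentation_smooth_sigma)
        labels = self.labels
        if labels is None:
            labels = seg.find_isolated_pores(mask, self.bone_mask,
                                             connectivity=cfg.connectivity)
        return mask, labels

    def fit(self) -> "PoreQualityResults":
        """Run the evaluation; deterministic given the configuration."""
        cfg = self.config
        mask, labels = self._segment()
        vox = self.volume.voxel_size
        scaffold_all = ~mask.values
        if self.bone_mask is not None:
            scaffold_all &= ~self.bone_mask.values

        from scipy import ndimage

        lab_arr = labels.values
        n_labels = int(lab_arr.max())
        objects = ndimage.find_objects(lab_arr, max_label=n_labels)

        pad = int(np.ceil(max(cfg.max_range,
                              cfg.local_shell + cfg.erosion_radius))) + 2
        shape = np.array(self.volume.shape)

        global_scaffold_eroded = None
        if cfg.scaffold_mode == "global":
            global_scaffold_eroded = snr_mod.erode_ball(
                scaffold_all, cfg.erosion_radius
            )

        records: list[PoreQualityRecord] = []
        for label in range(1, n_labels + 1):
            sl = objects[label - 1]
            if sl is None:
                continue
            lo = np.array([max(s.start - pad, 0) for s in sl])
            hi = np.array([min(s.stop + pad, n) for s, n in zip(sl, shape)])
            crop = tuple(slice(a, b) for a, b in zip(lo, hi))

            pore_this = lab_arr[crop] == label
            shape_info = seg.pore_shape(labels, label)
            rec = PoreQualityRecord(
                label=label,
                voxel_count=shape_info.voxel_count,
                volume_um3=shape_info.volume_um3,
                surface_area_um2=shape_info.surface_area_um2,
                sphericity=shape_info.sphericity,
                passed_size_filter=shape_info.voxel_count > cfg.min_voxels,
                passed_shape_filter=shape_info.sphericity < cfg.max_sphericity,
                touches_boundary=any(
                    s.start == 0 or s.stop == n for s, n in zip(sl, shape)
                ),
            )
            records.append(rec)
            if rec.touches_boundary:
                rec.failure_reason = "touches volume boundary"
                continue
            if not (rec.passed_size_filter and rec.passed_shape_filter):
                continue

            vol_crop = GrayVolume(self.volume.values[crop], vox)
            scaffold_crop = scaffold_all[crop]

            # --- SNR ---------------------------------------------------
            pore_eroded = snr_mod.erode_ball(pore_this, cfg.erosion_radius)
            if cfg.scaffold_mode == "global":
                scaffold_eroded = global_scaffold_eroded[crop]
                scaffold_region = scaffold_eroded
            else:
                scaffold_eroded = snr_mod.erode_ball(scaffold_crop,
                                                     cfg.erosion_radius)
                scaffold_region = snr_mod.local_scaffold_shell(
                    scaffold_eroded, pore_this, cfg.local_shell
                )
            snr_res = snr_mod.pore_snr(
                vol_crop, pore_eroded, scaffold_region,
                min_voxels=cfg.snr_min_voxels, label=label,
            )
            rec.snr = None if np.isnan(snr_res.snr) else float(snr_res.snr)
            rec.snr_valid = snr_res.valid
            rec.mu_pore = _nan_none(snr_res.mu_pore)
            rec.mu_scaffold = _nan_none(snr_res.mu_scaffold)
            rec.sigma_pore = _nan_none(snr_res.sigma_pore)
            rec.sigma_scaffold = _nan_none(snr_res.sigma_scaffold)
            rec.n_pore_voxels_eroded = snr_res.n_pore_voxels
            rec.passed_erosion_filter = (
                snr_res.n_pore_voxels > cfg.snr_min_voxels
            )

            # --- resolution -------------------------------------------
            try:
                sd = ep.signed_distance(pore_this)
                inner_range = int(min(cfg.max_range, np.floor(sd.max() + 0.5)))
                profile = ep.step_curve(
                    vol_crop, pore_this, scaffold_crop,
                    max_range=cfg.max_range,
                    max_range_in=max(inner_range, 3),
                )
                fit = ep.fit_erf(profile, contrast_floor=cfg.contrast_floor)
                res = ep.resolution_fwhm(profile, fit, vox,
                                         level_constant=cfg.level_constant)
            except ep.EdgeProfileError as exc:
                rec.failure_reason = str(exc)
                continue
            rec.resolution_nm = float(res)
            rec.fwhm_model_nm = fit.fwhm_model_nm
            rec.fit_A1, rec.fit_A2 = fit.A1, fit.A2
            rec.fit_x0, rec.fit_sigma = fit.x0, fit.sigma_fit
            rec.fit_rmse = fit.rmse
            rec.crossing_x1, rec.crossing_x2 = fit.x1, fit.x2
            rec.fit_ok = True

        return PoreQualityResults(self, records, mask, labels)


def _nan_none(x: float) -> float | None:
    return None if x is None or np.isnan(x) else float(x)


class PoreQualityResults:
    """Fitted per-pore quality metrics and their aggregates."""

    def __init__(
        self,
        model: PoreQualityModel,
        records: list[PoreQualityRecord],
        mask: BinaryMask,
        labels: PoreLabelVolume,
    ) -> None:
        self.model = model
        self.records = records
        self.mask = mask
        self.labels = labels
        self.aggregate: QualitySummary = aggregate_quality(records)
        self.exclusions = self._count_exclusions()

    # ------------------------------------------------------------------
    def _count_exclusions(self) -> dict[str, int]:
        counts = {
            "labeled": len(self.records),
            "kept": 0,
            "touches_boundary": 0,
            "failed_size": 0,
            "failed_sphericity": 0,
            "failed_erosion": 0,
            "failed_fit": 0,
        }
        for r in self.records:
            if r.touches_boundary:
                counts["touches_boundary"] += 1
            elif not r.passed_size_filter:
                counts["failed_size"] += 1
            elif not r.passed_shape_filter:
                counts["failed_sphericity"] += 1
            elif not r.passed_erosion_filter:
                counts["failed_erosion"] += 1
            elif not r.fit_ok:
                counts["failed_fit"] += 1
            else:
                counts["kept"] += 1
        return counts

    @property
    def table(self) -> pd.DataFrame:
        """One row per labeled pore; undefined metrics are NaN, never 0."""
        return pd.DataFrame([dataclasses.asdict(r) for r in self.records])

    # ------------------------------------------------------------------
    @property
    def snr_mean(self) -> float | None:
        return self.aggregate.snr_mean

    @property
    def snr_std(self) -> float | None:
        return self.aggregate.snr_std

    @property
    def resolution_mean_nm(self) -> float | None:
        return self.aggregate.resolution_mean_nm

    @property
    def resolution_std_nm(self) -> float | None:
        return self.aggregate.resolution_std_nm

    @property
    def n_pores(self) -> int:
        return self.exclusions["kept"]

    def summary_dict(self) -> dict[str, Any]:
        agg = self.aggregate
        return {
            "snr_mean": agg.snr_mean,
            "snr_std": agg.snr_std,
            "n_snr": agg.n_snr,
            "resolution_mean_nm": agg.resolution_mean_nm,
            "resolution_std_nm": agg.resolution_std_nm,
            "n_resolution": agg.n_resolution,
            "n_pores_kept": self.exclusions["kept"],
            "exclusions": self.exclusions,
            "config": self.model.config.as_dict(),
        }

    def summary(self) -> str:
        """Human-readable summary table."""

        def fmt(m, s, n):
            if m is None:
                return "n/a"
            return f"{m:.3g} +/- {s:.2g}  (n={n})"

        e = self.exclusions
        agg = self.aggregate
        lines = [
            "Per-pore image quality evaluation",
            "=" * 49,
            f"{'SNR (mean +/- STD)':32s}{fmt(agg.snr_mean, agg.snr_std, agg.n_snr)}",
            f"{'Resolution nm (mean +/- STD)':32s}"
            f"{fmt(agg.resolution_mean_nm, agg.resolution_std_nm, agg.n_resolution)}",
            f"{'Number of porosities':32s}{e['kept']}",
            "-" * 49,
            f"labeled {e['labeled']} | boundary {e['touches_boundary']} | "
            f"size {e['failed_size']} | sphericity {e['failed_sphericity']} | "
            f"erosion {e['failed_erosion']} | fit {e['failed_fit']}",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Write pores.csv (per-pore table) and summary.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pore_table(self.records, out / "pores.csv")
        (out / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, default=_json_default)
        )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
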
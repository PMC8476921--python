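"""End-to-end pipeline: generate -> reconstruct -> decompose -> correlate ->
test -> visualize, as a configured, logged, reproducible run.

A single global seed fans out into per-stage child seeds by stable
derivation (``numpy.random.SeedSequence``), so stages are independently
reproducible.  Every run writes a JSON manifest recording the seed, a config
hash, per-stage row counts, and all artifact paths; :func:`validate_manifest`
re-checks the artifacts afterwards.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .cohort_statistics import (
    SpecimenRecord,
    build_group_samples,
    cohort_results_table,
    ks_shape_check,
)
from .flim_reconstruction import (
    calibrate_phase,
    reconstruct,
    write_frame,
    write_map,
)
from .lifetime_rsc_model import (
    PairedObservation,
    confidence_band,
    fit_polynomial,
    plot_fit,
    prediction_band,
)
from .spectral_decomposition import compute_rsc, fit_baseline, preprocess_spectrum
from .synthetic_data import (
    CohortGroup,
    CohortSpec,
    NoiseModel,
    reference_frame,
    synth_cohort,
)
from .visualization import (
    BlendConfig,
    blend_lifetime_on_intensity,
    colorize_lifetime,
    compute_ssim,
    intensity_grayscale,
)

__all__ = ["RunConfig", "run_pipeline", "validate_manifest", "DEFAULT_GROUPS"]

log = logging.getLogger("flimspec")

# Demo cohort: one group per tissue class, medians echoing the study's
# group structure at desk scale.
DEFAULT_GROUPS = (
    CohortGroup("CTL", "none", "not_visible", 3, 1.6, 0.10),
    CohortGroup("LGG", "INF", "not_visible", 3, 4.1, 0.20),
    CohortGroup("HGG", "TUM", "visible", 3, 13.0, 0.10),
    CohortGroup("MNG", "TUM", "visible", 3, 12.2, 0.10),
)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; loadable from a YAML file."""

    seed: int = 0
    out_dir: str = "flimspec_run"
    groups: tuple = DEFAULT_GROUPS
    frame_shape: tuple[int, int] = (64, 64)
    instrument_phase_offset: float = 0.1
    reference_lifetime_ns: float = 2.0
    smoothing_sigma_nm: float = 2.0
    roi_window_px: int = 1
    poly_degree: int = 5
    n_subsample: int | None = None
    regime_thresholds: tuple[float, float] = (0.25, 0.85)
    colormap_lo_ns: float = 1.0
    colormap_hi_ns: float = 16.0
    noise: NoiseModel = field(
        default_factory=lambda: NoiseModel(
            phase_jitter_scale=0.05, amplitude_noise_sd=0.5, spectrum_poisson=True
        )
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" in raw:
            raw["groups"] = tuple(CohortGroup(**g) for g in raw["groups"])
        if "noise" in raw:
            raw["noise"] = NoiseModel(**raw["noise"])
        if "frame_shape" in raw:
            raw["frame_shape"] = tuple(raw["frame_shape"])
        if "regime_thresholds" in raw:
            raw["regime_thresholds"] = tuple(raw["regime_thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            groups=self.groups,
            frame_shape=self.frame_shape,
            noise=self.noise,
            instrument_phase_offset=self.instrument_phase_offset,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31 - 1)) for s in np.random.SeedSequence(seed).generate_state(n)]


def _roi_lifetime(tau: np.ndarray, row: int, col: int, half: int) -> float:
    window = tau[
        max(row - half, 0) : row + half + 1, max(col - half, 0) : col + half + 1
    ]
    if np.isfinite(window).any():
        return float(np.nanmean(window))
    return float("nan")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}
    seeds = _stage_seeds(config.seed, 4)

    def record(name: str, path: Path) -> Path:
        artifacts[name] = str(path.relative_to(out))
        return path

    # -- generate -------------------------------------------------------------
    try:
        cohort_spec = config.cohort_spec()
        cohort = synth_cohort(cohort_spec, seed=seeds[0])
        data_dir = out / "data"
        record("manifest_csv", cohort.write(data_dir))
        ref = reference_frame(
            cohort_spec, config.reference_lifetime_ns, seed=seeds[1]
        )
        record("reference_frame", write_frame(ref, data_dir / "reference_frame.tif"))
        counts["generate_specimens"] = len(cohort.specimens)
        log.info("generate: %d specimens", len(cohort.specimens))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"generate: {exc}") from exc

    # -- reconstruct ----------------------------------------------------------
    try:
        cal = calibrate_phase(ref, config.reference_lifetime_ns)
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        lifetime_maps = {}
        intensity_maps = {}
        for spec in cohort.specimens:
            tau_map, int_map = reconstruct(spec.frame, cal)
            lifetime_maps[spec.specimen_id] = tau_map
            intensity_maps[spec.specimen_id] = int_map
            record(
                f"lifetime_map/{spec.specimen_id}",
                write_map(
                    tau_map.tau,
                    maps_dir / f"{spec.specimen_id}_tau.tif",
                    pixel_pitch_um=tau_map.pixel_pitch_um,
                    units="ns",
                ),
            )
        counts["reconstruct_frames"] = len(lifetime_maps)
        log.info("reconstruct: offset %.4f rad, %d frames", cal.phase_offset, len(lifetime_maps))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"reconstruct: {exc}") from exc

    # -- decompose ------------------------------------------------------------
    try:
        rows = []
        for spec in cohort.specimens:
            tau = lifetime_maps[spec.specimen_id].tau
            for k, (spectrum, (r, c)) in enumerate(zip(spec.spectra, spec.roi_coords)):
                clean = preprocess_spectrum(
                    spectrum, smoothing_sigma_nm=config.smoothing_sigma_nm
                )
                decomp = compute_rsc(clean, fit_baseline(clean))
                rows.append(
                    {
                        "specimen_id": spec.specimen_id,
                        "roi_id": k,
                        "rsc": decomp.rsc,
                        "s_ppix": decomp.s_ppix,
                        "s_autofl": decomp.s_autofl,
                        "lifetime_ns": _roi_lifetime(tau, r, c, config.roi_window_px),
                        "fluorescence_status": spec.fluorescence_status,
                    }
                )
        roi_table = pd.DataFrame(rows)
        roi_path = out / "roi_decomposition.csv"
        roi_table.to_csv(roi_path, index=False)
        record("roi_decomposition", roi_path)
        counts["decompose_rois"] = len(roi_table)
        log.info("decompose: %d ROI spectra", len(roi_table))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"decompose: {exc}") from exc

    # -- correlate ------------------------------------------------------------
    try:
        paired = roi_table.dropna(subset=["lifetime_ns"])
        points = [
            PairedObservation(
                rsc=row.rsc,
                lifetime_ns=row.lifetime_ns,
                fluorescence_status=row.fluorescence_status,
                specimen_id=row.specimen_id,
            )
            for row in paired.itertuples()
        ]
        fit = fit_polynomial(points, degree=config.poly_degree)
        fit.to_json(out / "poly_fit.json")
        record("poly_fit", out / "poly_fit.json")
        grid = np.linspace(0, 1, 101)
        bands = pd.DataFrame(
            {
                "x0": grid,
                "y_model": fit.predict(grid),
                "ci": confidence_band(fit, grid),
                "pi": prediction_band(fit, grid),
            }
        )
        bands_path = out / "bands.csv"
        bands.to_csv(bands_path, index=False)
        record("bands", bands_path)
        record("correlation_plot", out / "correlation.png")
        plot_fit(points, fit, out / "correlation.png", config.regime_thresholds)
        counts["correlate_points"] = len(points)
        log.info("correlate: n=%d, sigma_hat=%.3f ns", fit.n, fit.sigma_hat)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"correlate: {exc}") from exc

    # -- stats ----------------------------------------------------------------
    try:
        records = [
            SpecimenRecord(
                specimen_id=spec.specimen_id,
                entity=spec.entity,
                subgroup=spec.subgroup,
                fluorescence_status=spec.fluorescence_status,
                lifetime_map=lifetime_maps[spec.specimen_id],
            )
            for spec in cohort.specimens
        ]
        groups = build_group_samples(
            records, n_subsample=config.n_subsample, seed=seeds[2]
        )
        results = cohort_results_table(groups)
        results_path = out / "group_statistics.csv"
        results.to_csv(results_path, index=False)
        record("group_statistics", results_path)
        ks = ks_shape_check(list(groups.values()))
        ks_path = out / "ks_shape_check.csv"
        ks.to_csv(ks_path, index=False)
        record("ks_shape_check", ks_path)
        record("violin_plot", _violin_plot(groups, out / "violins.png"))
        counts["stats_groups"] = len(groups)
        log.info("stats: %d groups", len(groups))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stats: {exc}") from exc

    # -- blend ----------------------------------------------------------------
    try:
        blend_cfg = BlendConfig(lo_ns=config.colormap_lo_ns, hi_ns=config.colormap_hi_ns)
        first = cohort.specimens[0].specimen_id
        lifetime_rgb = colorize_lifetime(lifetime_maps[first], blend_cfg)
        structure_rgb = intensity_grayscale(intensity_maps[first])
        blended = blend_lifetime_on_intensity(lifetime_rgb, structure_rgb, blend_cfg)
        blend_dir = out / "blend"
        blend_dir.mkdir(exist_ok=True)
        for name, image in (
            ("lifetime_rgb", lifetime_rgb),
            ("structure_rgb", structure_rgb),
            ("blended_rgb", blended),
        ):
            path = blend_dir / f"{first}_{name}.png"
            _write_png(image, path)
            record(f"blend/{name}", path)
        counts["blend_images"] = 3
        ssim_self = compute_ssim(blended, blended)
        log.info("blend: self-SSIM %.3f", ssim_self)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"blend: {exc}") from exc

    manifest = {
        "flimspec_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_counts": counts,
        "artifacts": artifacts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_png(image: np.ndarray, path: Path) -> Path:
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))
    return path


def _violin_plot(groups, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = sorted(groups, key=lambda k: np.median(groups[k].lifetimes_ns))
    fig, ax = plt.subplots(figsize=(1.5 * len(keys) + 2, 4))
    parts = ax.violinplot(
        [groups[k].lifetimes_ns for k in keys],
        showmedians=True,
        quantiles=[[0.25, 0.75]] * len(keys),
    )
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    ax.set_xticks(range(1, len(keys) + 1))
    ax.set_xticklabels(["/".join(k[:2]) for k in keys], rotation=30, ha="right")
    ax.set_ylabel("fluorescence lifetime (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def validate_manifest(manifest_path) -> pd.DataFrame:
    """Check every artifact referenced by a run manifest.

    Returns a table ``artifact, path, status, detail`` where status is
    ``ok`` or ``fail``; missing or unreadable files are enumerated, never
    raised.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    rows = []
    for name, rel in manifest.get("artifacts", {}).items():
        path = base / rel
        status, detail = "ok", ""
        if not path.exists():
            status, detail = "fail", "missing"
        else:
            try:
                if path.suffix == ".tif":
                    tifffile.imread(path)
                elif path.suffix == ".csv":
                    pd.read_csv(path)
                elif path.suffix == ".json":
                    json.loads(path.read_text())
            except Exception as exc:  # noqa: BLE001
                status, detail = "fail", f"format error: {exc}"
        rows.append({"artifact": name, "path": str(path), "status": status, "detail": detail})
    return pd.DataFrame(rows)
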
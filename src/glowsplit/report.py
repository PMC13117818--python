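"""Paired before/after comparison reports and run configuration.

The central use case is a paired comparison: the same hands photographed
before and after washing under identical illumination, camera settings and
geometry.  Both images are decomposed with the *same* basis, camera matrix
and thresholds (enforced — the validity of the comparison rests on identical
imaging and analysis conditions), and the integrated fluorescence
coefficients are reported together with their after/before ratio.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .colorspace import (
    DEFAULT_CAMERA_MATRIX,
    DEFAULT_CLIP_THRESHOLD,
    TristimulusImage,
    save_display_png,
    save_float_map,
)
from .spectra import DEFAULT_BASIS, ProjectionBasis
from .unmix import (
    CoefficientMaps,
    integrate_fluorescence,
    matched_filter,
    nnls_decompose,
    rms_contrast,
)

__all__ = ["RunConfig", "ComparisonReport", "compare_measures", "compare_pair", "write_maps"]

log = logging.getLogger("glowsplit")


@dataclass
class RunConfig:
    """Configuration shared by every stage of a run."""

    camera_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_CAMERA_MATRIX.copy())
    basis: ProjectionBasis = DEFAULT_BASIS
    clip_threshold: float = DEFAULT_CLIP_THRESHOLD
    include_saturated: bool = False
    seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        self.camera_matrix = np.asarray(self.camera_matrix, dtype=float)
        if self.camera_matrix.shape != (3, 3) or abs(np.linalg.det(self.camera_matrix)) < 1e-12:
            raise ValueError("camera matrix must be a nonsingular 3x3 matrix")
        if not (0.0 < self.clip_threshold <= 1.0):
            raise ValueError("clip threshold must lie in (0, 1]")

    def provenance(self) -> dict:
        return {
            "package_version": __version__,
            "camera_matrix": self.camera_matrix.tolist(),
            "basis": self.basis.matrix.tolist(),
            "clip_threshold": self.clip_threshold,
            "include_saturated": self.include_saturated,
            "seed": self.seed,
        }


@dataclass
class ComparisonReport:
    """Scalar summary of a paired before/after comparison."""

    integrated_fluorescence_before: float
    integrated_fluorescence_after: float
    ratio_after_over_before: float | None
    ratio_undefined: bool
    pixel_counts: dict
    saturated_counts: dict
    rms_contrast: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "integrated_fluorescence_before": self.integrated_fluorescence_before,
            "integrated_fluorescence_after": self.integrated_fluorescence_after,
            "ratio_after_over_before": self.ratio_after_over_before,
            "ratio_undefined": self.ratio_undefined,
            "pixel_counts": self.pixel_counts,
            "saturated_counts": self.saturated_counts,
            "rms_contrast": self.rms_contrast,
            "provenance": self.provenance,
        }


def compare_measures(
    img: TristimulusImage, basis: ProjectionBasis = DEFAULT_BASIS
) -> tuple[np.ndarray, np.ndarray]:
    """Both fluorescence maps from a single pass over an XYZ image.

    Returns ``(beta_f, g)``: the NNLS fluorescence coefficient map and the
    raw (un-normalized) matched-filter response map.
    """
    maps = nnls_decompose(img, basis)
    return maps.beta_f, matched_filter(img, basis)


def _log_validity(tag: str, img: TristimulusImage) -> None:
    n = img.mask.sum()
    if n:
        sat_pct = 100.0 * (img.saturated & img.mask).sum() / n
        neg_pct = 100.0 * np.any(img.pixels < 0, axis=-1)[img.mask].mean()
        log.info("%s: %.2f%% saturated pixels, %.2f%% pixels with negative XYZ", tag, sat_pct, neg_pct)


def _file_sha256(path) -> str | None:
    try:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()
    except (OSError, TypeError):
        return None


def write_maps(maps: CoefficientMaps, mf_map: np.ndarray, outdir: Path, prefix: str = "") -> None:
    """Write float TIFF (quantitative) and 16-bit PNG (display) map pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    named = {
        "beta_w": maps.beta_w,
        "beta_s": maps.beta_s,
        "beta_f": maps.beta_f,
        "residual_norm": maps.residual_norm,
        "matched_filter": mf_map,
    }
    for name, arr in named.items():
        save_float_map(outdir / f"{prefix}{name}.tif", arr)
        save_display_png(outdir / f"{prefix}{name}.png", arr)


def compare_pair(
    before: TristimulusImage,
    after: TristimulusImage,
    cfg: RunConfig | None = None,
    before_path=None,
    after_path=None,
) -> ComparisonReport:
    """Decompose a before/after pair and report the fluorescence change.

    Both images are processed with the identical basis and thresholds from
    ``cfg``.  If ``cfg.output_dir`` is set, all coefficient maps are written
    there.  A zero before-integral flags the ratio undefined rather than
    producing an infinity.
    """
    cfg = cfg or RunConfig()
    if not before.mask.any() or not after.mask.any():
        raise ValueError("empty analysis mask")
    results = {}
    for tag, img in (("before", before), ("after", after)):
        _log_validity(tag, img)
        maps = nnls_decompose(img, cfg.basis)
        mf = matched_filter(img, cfg.basis)
        total = integrate_fluorescence(maps, include_saturated=cfg.include_saturated)
        results[tag] = (maps, mf, total)
        if cfg.output_dir is not None:
            write_maps(maps, mf, cfg.output_dir, prefix=f"{tag}_")
    b, a = results["before"][2], results["after"][2]
    undefined = b <= 0
    contrast = {}
    for tag, (maps, mf, _) in results.items():
        sel = maps.mask & (~maps.saturated | cfg.include_saturated)
        try:
            contrast[f"{tag}_beta_f"] = rms_contrast(maps.beta_f, sel)
            contrast[f"{tag}_matched_filter"] = rms_contrast(mf, sel)
        except ValueError:
            contrast[f"{tag}_beta_f"] = None
            contrast[f"{tag}_matched_filter"] = None
    provenance = cfg.provenance()
    provenance["inputs"] = {
        "before": {"path": str(before_path) if before_path else None, "sha256": _file_sha256(before_path) if before_path else None},
        "after": {"path": str(after_path) if after_path else None, "sha256": _file_sha256(after_path) if after_path else None},
    }
    return ComparisonReport(
        integrated_fluorescence_before=b,
        integrated_fluorescence_after=a,
        ratio_after_over_before=None if undefined else a / b,
        ratio_undefined=bool(undefined),
        pixel_counts={tag: int(img.mask.sum()) for tag, img in (("before", before), ("after", after))},
        saturated_counts={tag: int((img.saturated & img.mask).sum()) for tag, img in (("before", before), ("after", after))},
        rms_contrast=contrast,
        provenance=provenance,
    )
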
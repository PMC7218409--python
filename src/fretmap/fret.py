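"""Acceptor-photobleaching FRET quantification.

Per-cell (or per-patch) efficiency from donor frames bracketing the acceptor
bleach: background subtraction, phase-frame averaging, an intensity threshold
at the cell's cytoplasmic level, per-pixel de-quenching, and subtraction of
the matched donor-only baseline.

Two per-pixel conventions are computed and reported side by side:

``increase_over_pre``
    e = 100 * (post - pre) / pre — the percentage increase in donor
    fluorescence after acceptor photobleaching (the default).
``dequench_over_post``
    e = 100 * (post - pre) / post — the classical transfer efficiency
    (fraction of donor emission that was quenched).

On noise-free data with a complete bleach the two are related exactly by
``e_pre = e_post / (1 - e_post/100)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageSeries, Roi, RoiSet

CONVENTIONS = ("increase_over_pre", "dequench_over_post")

#: measured acceptor-bleach fractions below this are QC-flagged (not dropped)
BETA_QC_FLOOR = 0.5


@dataclass
class FretMeasurement:
    """One cell's (or one patch's) FRET efficiency in percent."""

    entity_id: str
    E_raw_pct: float                      # uncorrected, default convention
    E_pct: float | None = None            # after donor-only correction
    E_raw_pct_alt: float | None = None    # the other convention, uncorrected
    convention: str = "increase_over_pre"
    n_pixels_used: int = 0
    threshold_used: float = 0.0
    acceptor_bleach_fraction: float | None = None
    baseline_id: str | None = None
    qc_flags: list[str] = field(default_factory=list)
    valid: bool = True


@dataclass
class DonorOnlyBaseline:
    """Mean apparent FRET of donor-only cells, acquired in parallel.

    Slightly negative under ``increase_over_pre`` because of structural
    donor photobleaching during acquisition.
    """

    batch_id: str
    b_pct: float
    n_cells: int
    ci95_pct: float


def _resolve_mask(region, shape) -> np.ndarray:
    if isinstance(region, np.ndarray) and region.dtype == bool:
        return region
    if isinstance(region, Roi):
        return region.rasterize(shape)
    if isinstance(region, RoiSet):
        m = np.zeros(shape, dtype=bool)
        for r in region:
            m |= r.rasterize(shape)
        return m
    raise TypeError(f"cannot interpret region of type {type(region)!r}")


def subtract_background(series: ImageSeries, bg_region,
                        cell_rois: RoiSet | None = None) -> ImageSeries:
    """Subtract the general background from every frame, clipping at zero.

    ``bg_region`` is a constant, a boolean mask, an ROI, or an ROI set; for
    regions the per-frame median inside the region is subtracted (robust to
    stray bright pixels). If ``cell_rois`` is given, a background region
    overlapping any of them raises.
    """
    if np.isscalar(bg_region):
        if bg_region < 0:
            raise ValueError("constant background must be >= 0")
        sub = np.full(series.n_frames, float(bg_region))
    else:
        mask = _resolve_mask(bg_region, series.shape)
        if cell_rois is not None:
            for roi in cell_rois:
                if (mask & roi.rasterize(series.shape)).any():
                    raise ValueError(
                        f"background region overlaps cell ROI {roi.name!r}")
        sub = np.array([np.median(f[mask]) for f in series.frames])
    frames = np.clip(series.frames.astype(float) - sub[:, None, None], 0, None)
    return series.with_frames(frames)


def average_phase_frames(series: ImageSeries, phase: str) -> np.ndarray:
    """Pixel-wise mean of all frames tagged with ``phase``."""
    frames = series.frames_in_phase(phase)
    if len(frames) == 0:
        raise ValueError(f"no frames in phase {phase!r}")
    return frames.astype(float).mean(axis=0)


@dataclass
class CytoplasmThreshold:
    value: float
    qc_flags: list[str] = field(default_factory=list)


def estimate_cytoplasm_threshold(donor_pre_image: np.ndarray,
                                 cyto_roi,
                                 patch_rois: RoiSet | None = None
                                 ) -> CytoplasmThreshold:
    """Intensity threshold at the cytoplasmic fluorescence of the cell.

    Mean donor intensity inside the cytoplasm ROI on the averaged pre-bleach
    image. The ROI is the caller's responsibility to keep patch-free; if a
    supplied patch ROI intersects it, or the ROI contains pixels far above
    its robust spread (a patch caught by accident), a QC flag is raised and
    the value still returned.
    """
    mask = _resolve_mask(cyto_roi, donor_pre_image.shape)
    if not mask.any():
        raise ValueError("empty cytoplasm ROI")
    flags: list[str] = []
    if patch_rois is not None:
        for roi in patch_rois.by_role("patches"):
            if (mask & roi.rasterize(donor_pre_image.shape)).any():
                flags.append("cytoplasm_roi_intersects_patch")
                break
    vals = donor_pre_image[mask]
    med = np.median(vals)
    mad_sd = 1.4826 * np.median(np.abs(vals - med))
    if mad_sd > 0 and np.any(vals > med + 10 * mad_sd):
        flags.append("cytoplasm_roi_contains_bright_pixels")
    return CytoplasmThreshold(value=float(vals.mean()), qc_flags=flags)


def pixel_efficiencies(donor_pre: np.ndarray, donor_post: np.ndarray,
                       mask: np.ndarray, threshold: float,
                       convention: str = "increase_over_pre",
                       threshold_on: str = "both") -> np.ndarray:
    """Per-pixel FRET efficiencies (%) over qualifying pixels.

    Qualifying pixels lie in the mask with donor intensity above the
    threshold on both the averaged pre and post images (``threshold_on=
    "both"``, the default) or on the pre image only (``"pre"``).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if threshold_on not in ("both", "pre"):
        raise ValueError("threshold_on must be 'both' or 'pre'")
    qual = mask & (donor_pre > threshold)
    if threshold_on == "both":
        qual &= donor_post > threshold
    pre = donor_pre[qual].astype(float)
    post = donor_post[qual].astype(float)
    denom = pre if convention == "increase_over_pre" else post
    return 100.0 * (post - pre) / denom


def convert_convention(e_pct: float | np.ndarray, source: str, target: str):
    """Convert an efficiency between the two per-pixel conventions.

    ``increase_over_pre`` and ``dequench_over_post`` values are related by
    ``e_pre = e_post / (1 - e_post/100)`` (exact on ratio level).
    """
    if source == target:
        return e_pct
    if source == "dequench_over_post" and target == "increase_over_pre":
        return e_pct / (1.0 - e_pct / 100.0)
    if source == "increase_over_pre" and target == "dequench_over_post":
        return e_pct / (1.0 + e_pct / 100.0)
    raise ValueError(f"unknown conversion {source!r} -> {target!r}")


def compute_fret_efficiency(donor_pre: np.ndarray, donor_post: np.ndarray,
                            roi, threshold: float,
                            convention: str = "increase_over_pre",
                            threshold_on: str = "both",
                            entity_id: str = "cell",
                            min_pixels: int = 1) -> FretMeasurement:
    """Mean per-pixel de-quenching efficiency over an ROI.

    Both conventions are evaluated; ``E_raw_pct`` carries the requested one
    and ``E_raw_pct_alt`` the other. Zero qualifying pixels marks the
    measurement invalid (excluded from aggregation) instead of raising.
    """
    mask = _resolve_mask(roi, donor_pre.shape)
    e_main = pixel_efficiencies(donor_pre, donor_post, mask, threshold,
                                convention, threshold_on)
    alt = CONVENTIONS[1 - CONVENTIONS.index(convention)]
    e_alt = pixel_efficiencies(donor_pre, donor_post, mask, threshold,
                               alt, threshold_on)
    n = e_main.size
    if n < max(min_pixels, 1):
        return FretMeasurement(entity_id=entity_id, E_raw_pct=np.nan,
                               convention=convention, n_pixels_used=n,
                               threshold_used=float(threshold),
                               qc_flags=["no_qualifying_pixels"], valid=False)
    return FretMeasurement(entity_id=entity_id,
                           E_raw_pct=float(e_main.mean()),
                           E_raw_pct_alt=float(e_alt.mean()),
                           convention=convention, n_pixels_used=int(n),
                           threshold_used=float(threshold))


def measure_acceptor_bleach(acceptor_pre: np.ndarray, acceptor_post: np.ndarray,
                            roi) -> float:
    """Measured bleached fraction, ``1 - mean_post/mean_pre``, clipped to [0, 1]."""
    mask = _resolve_mask(roi, acceptor_pre.shape)
    mpre = float(acceptor_pre[mask].mean())
    if mpre <= 0:
        raise ValueError("non-positive pre-bleach acceptor mean")
    mpost = float(acceptor_post[mask].mean())
    return float(np.clip(1.0 - mpost / mpre, 0.0, 1.0))


def apply_donor_only_correction(measurements: list[FretMeasurement],
                                baseline: DonorOnlyBaseline
                                ) -> list[FretMeasurement]:
    """Subtract the donor-only batch baseline: ``E = E_raw - b``."""
    out = []
    for m in measurements:
        if not m.valid:
            out.append(m)
            continue
        out.append(FretMeasurement(
            entity_id=m.entity_id,
            E_raw_pct=m.E_raw_pct,
            E_pct=m.E_raw_pct - baseline.b_pct,
            E_raw_pct_alt=m.E_raw_pct_alt,
            convention=m.convention,
            n_pixels_used=m.n_pixels_used,
            threshold_used=m.threshold_used,
            acceptor_bleach_fraction=m.acceptor_bleach_fraction,
            baseline_id=baseline.batch_id,
            qc_flags=list(m.qc_flags),
            valid=m.valid))
    return out


def quantify_apb(donor: ImageSeries, acceptor: ImageSeries | None,
                 rois: RoiSet, bg_region=None,
                 convention: str = "increase_over_pre",
                 threshold_on: str = "both",
                 entity_id: str = "cell",
                 target_role: str = "patches") -> FretMeasurement:
    """Whole pipeline for one cell: background, averaging, threshold, E.

    ``bg_region`` defaults to the ROI set's ``background`` role. The target
    region (default the pooled patch ROIs) is measured against the
    cytoplasm-level threshold; the acceptor bleach fraction is recorded and
    QC-flagged when below :data:`BETA_QC_FLOOR`.
    """
    if bg_region is None:
        bg_region = rois.mask("background", donor.shape)
    donor_b = subtract_background(donor, bg_region)
    pre = average_phase_frames(donor_b, "pre")
    post = average_phase_frames(donor_b, "post")
    thr = estimate_cytoplasm_threshold(pre, rois.mask("cytoplasm", donor.shape),
                                       patch_rois=rois)
    target = rois.mask(target_role, donor.shape)
    m = compute_fret_efficiency(pre, post, target, thr.value, convention,
                                threshold_on, entity_id=entity_id)
    m.qc_flags.extend(thr.qc_flags)
    if acceptor is not None:
        acc_b = subtract_background(acceptor, bg_region)
        beta = measure_acceptor_bleach(average_phase_frames(acc_b, "pre"),
                                       average_phase_frames(acc_b, "post"),
                                       target)
        m.acceptor_bleach_fraction = beta
        if beta < BETA_QC_FLOOR:
            m.qc_flags.append("incomplete_acceptor_bleach")
    return m


def donor_only_baseline(measurements: list[FretMeasurement],
                        batch_id: str) -> DonorOnlyBaseline:
    """Aggregate donor-only cells into a batch baseline (mean, 95% CI)."""
    from .stats import mean_ci

    vals = [m.E_raw_pct for m in measurements if m.valid]
    if len(vals) < 2:
        raise ValueError("need >= 2 valid donor-only cells for a baseline")
    mean, hw = mean_ci(vals)
    return DonorOnlyBaseline(batch_id=batch_id, b_pct=mean,
                             n_cells=len(vals), ci95_pct=hw)
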
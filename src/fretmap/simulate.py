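"""Synthetic two-channel wide-field microscopy of yeast endocytic patches.

Forward model for acceptor-photobleaching FRET acquisitions and FRAP series
with known ground truth, so the whole quantification pipeline is testable
without real microscope data.

The scene is a cell (ellipse) containing diffraction-limited endocytic
patches (sub-pixel centers, Gaussian PSF) over cytoplasmic signal, with
extracellular/camera background everywhere. Donor emission is quenched by a
ground-truth FRET efficiency ``E_true`` while the acceptor is intact, and
de-quenched after the acceptor bleach pulse; repeated donor acquisitions
cause mild structural photobleaching. Noise follows an EMCCD model: shot
noise inflated by the EM excess-noise factor plus additive Gaussian read
noise.

Conventions
-----------
``E_true`` is the fraction of donor emission quenched pre-bleach, i.e. at a
complete acceptor bleach ``E_true = 1 - D_pre / D_post``. With a partial
bleach of fraction ``beta_bleach`` the residual acceptor keeps quenching:
post-bleach donor signal carries the factor ``1 - E_true*(1 - beta_bleach)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from scipy.special import erf

from .io import ImageSeries, Roi, RoiSet

Channel = Literal["donor", "acceptor"]
Phase = Literal["pre", "post"]

EM_EXCESS_FACTOR = float(np.sqrt(2.0))  # high-gain EMCCD excess-noise limit


@dataclass
class CellScene:
    """Geometry and photon budget of one simulated cell.

    All *_level/*_amplitude values are expected photons per frame; the
    patch amplitude is the total (PSF-integrated) expected photon count of
    one patch, the levels are per pixel.
    """

    shape: tuple[int, int] = (64, 64)
    cell_center: tuple[float, float] = (31.5, 31.5)
    cell_radii: tuple[float, float] = (26.0, 22.0)
    patch_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    patch_amplitude_donor: float = 1200.0
    patch_amplitude_acceptor: float = 900.0
    cytoplasm_level: float = 100.0
    background_level: float = 20.0
    psf_sigma_px: float = 1.1
    pixel_size_nm: float = 178.0

    def __post_init__(self) -> None:
        self.patch_centers = np.asarray(self.patch_centers, dtype=float).reshape(-1, 2)
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        for v in (self.patch_amplitude_donor, self.patch_amplitude_acceptor,
                  self.cytoplasm_level, self.background_level):
            if v < 0:
                raise ValueError("expected-photon levels must be >= 0")
        mask = self.cell_mask()
        for r, c in self.patch_centers:
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < self.shape[0] and 0 <= ci < self.shape[1]
                    and mask[ri, ci]):
                raise ValueError(f"patch center ({r}, {c}) outside the cell mask")

    def cell_mask(self) -> np.ndarray:
        """Boolean mask of the cell interior (inclusive ellipse at centers).

        Cached: scenes are treated as immutable after construction.
        """
        if getattr(self, "_mask", None) is None:
            cr, cc = self.cell_center
            rr, rc = self.cell_radii
            r = np.arange(self.shape[0])[:, None]
            c = np.arange(self.shape[1])[None, :]
            self._mask = ((r - cr) / rr) ** 2 + ((c - cc) / rc) ** 2 <= 1.0
        return self._mask

    def patch_kernels(self) -> np.ndarray:
        """Unit-mass pixel-integrated Gaussian PSF per patch, (n, H, W); cached."""
        if getattr(self, "_kernels", None) is None:
            self._kernels = _gaussian_kernels(self.patch_centers, self.shape,
                                              self.psf_sigma_px)
        return self._kernels


def _gaussian_kernels(centers: np.ndarray, shape: tuple[int, int],
                      sigma: float) -> np.ndarray:
    """Pixel-integrated symmetric 2-D Gaussians (exact erf integrals)."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    s = sigma * np.sqrt(2.0)
    r = np.arange(shape[0])
    c = np.arange(shape[1])
    # (n, H) and (n, W) 1-D integrals over [k-0.5, k+0.5]
    gr = 0.5 * (erf((r[None, :] + 0.5 - centers[:, 0:1]) / s)
                - erf((r[None, :] - 0.5 - centers[:, 0:1]) / s))
    gc = 0.5 * (erf((c[None, :] + 0.5 - centers[:, 1:2]) / s)
                - erf((c[None, :] - 0.5 - centers[:, 1:2]) / s))
    return gr[:, :, None] * gc[:, None, :]


@dataclass
class AcquisitionConfig:
    """Acceptor-photobleaching acquisition protocol and ground truth.

    Frame counts follow the protocol: two acceptor-channel and three to five
    donor-channel acquisitions before the bleach pulse, then three to five
    donor and two acceptor frames after it.
    """

    n_pre_donor: int = 4
    n_post_donor: int = 4
    n_pre_acceptor: int = 2
    n_post_acceptor: int = 2
    frame_exposure_s: float = 0.5
    bleach_pulse_s: float = 4.0
    #: scalar, or one ground-truth efficiency per patch (stage experiments)
    E_true: float | np.ndarray = 0.10
    E_true_cytoplasm: float | None = None  # None -> E_true (0 if per-patch)
    beta_bleach: float = 1.0
    delta_struct: float = 0.001
    read_noise_sd: float = 2.0
    em_gain_factor: float = EM_EXCESS_FACTOR
    rng_seed: int = 0

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.E_true, dtype=float))
        if np.any(e < 0) or np.any(e >= 1):
            raise ValueError("E_true must lie in [0, 1)")
        if not 0 <= self.beta_bleach <= 1:
            raise ValueError("beta_bleach must lie in [0, 1]")
        if not 0 <= self.delta_struct < 1:
            raise ValueError("delta_struct must lie in [0, 1)")
        for n in (self.n_pre_donor, self.n_post_donor,
                  self.n_pre_acceptor, self.n_post_acceptor):
            if n < 1:
                raise ValueError("frame counts must be >= 1")

    @property
    def e_patch(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.E_true, dtype=float))

    @property
    def e_cyto(self) -> float:
        if self.E_true_cytoplasm is not None:
            return self.E_true_cytoplasm
        return float(self.E_true) if np.isscalar(self.E_true) else 0.0


@dataclass
class GroundTruthManifest:
    """Everything needed to recompute the expected noise-free images exactly."""

    scene: CellScene
    config: AcquisitionConfig | "FrapConfig"
    kind: str = "apb"  # "apb" | "frap"

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, np.generic):
                return v.item()
            return v

        d = {"kind": self.kind,
             "scene": clean(dataclasses.asdict(self.scene)),
             "config": clean(dataclasses.asdict(self.config))}
        d["scene"].pop("_mask", None)
        d["scene"].pop("_kernels", None)
        return d

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruthManifest":
        d = yaml.safe_load(Path(path).read_text())
        sc = d["scene"]
        sc["shape"] = tuple(sc["shape"])
        sc["cell_center"] = tuple(sc["cell_center"])
        sc["cell_radii"] = tuple(sc["cell_radii"])
        scene = CellScene(**sc)
        cfg_cls = AcquisitionConfig if d["kind"] == "apb" else FrapConfig
        cfg = cfg_cls(**d["config"])
        return cls(scene=scene, config=cfg, kind=d["kind"])


def _donor_quench(e, phase: Phase, beta: float):
    if phase == "pre":
        return 1.0 - np.asarray(e)
    return 1.0 - np.asarray(e) * (1.0 - beta)


def render_expected_image(scene: CellScene, channel: Channel, phase: Phase,
                          cfg: AcquisitionConfig, frame_index: int) -> np.ndarray:
    """Noise-free expected-photon image for one frame.

    ``frame_index`` counts within the phase. Donor frames accumulate
    structural photobleaching: the k-th donor acquisition overall (pre frames
    first) is scaled by ``(1 - delta_struct)**k``.
    """
    if channel not in ("donor", "acceptor") or phase not in ("pre", "post"):
        raise ValueError(f"invalid channel/phase ({channel}, {phase})")
    n_in_phase = {("donor", "pre"): cfg.n_pre_donor,
                  ("donor", "post"): cfg.n_post_donor,
                  ("acceptor", "pre"): cfg.n_pre_acceptor,
                  ("acceptor", "post"): cfg.n_post_acceptor}[(channel, phase)]
    if not 0 <= frame_index < n_in_phase:
        raise ValueError(f"frame_index {frame_index} invalid for {channel}/{phase}")

    mask = scene.cell_mask()
    img = np.full(scene.shape, scene.background_level, dtype=float)
    kernels = scene.patch_kernels()
    if channel == "donor":
        k_prior = frame_index if phase == "pre" else cfg.n_pre_donor + frame_index
        decay = (1.0 - cfg.delta_struct) ** k_prior
        img += (mask * scene.cytoplasm_level
                * _donor_quench(cfg.e_cyto, phase, cfg.beta_bleach) * decay)
        if len(kernels):
            e = cfg.e_patch
            if e.size == 1:
                e = np.full(len(kernels), e[0])
            elif e.size != len(kernels):
                raise ValueError("per-patch E_true length must match patch count")
            amp = (scene.patch_amplitude_donor
                   * _donor_quench(e, phase, cfg.beta_bleach) * decay)
            img += np.tensordot(amp, kernels, axes=(0, 0))
    else:
        surv = 1.0 if phase == "pre" else 1.0 - cfg.beta_bleach
        img += mask * scene.cytoplasm_level * surv
        if len(kernels):
            img += scene.patch_amplitude_acceptor * surv * kernels.sum(axis=0)
    return img


def apply_noise(expected: np.ndarray, cfg, rng: np.random.Generator | None = None
                ) -> np.ndarray:
    """EMCCD noise: per-pixel variance ``em_gain_factor**2 * mean +
    read_noise_sd**2``, clipped at zero, integer counts.

    Implemented as a mean-preserving EM-scaled Poisson deviation plus
    Gaussian read noise (adequate at the simulated photon counts compared
    with a full gain-register cascade).
    """
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected image must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    g = cfg.em_gain_factor
    shot = g * (rng.poisson(expected) - expected)
    read = rng.normal(0.0, cfg.read_noise_sd, size=expected.shape)
    return np.clip(np.rint(expected + shot + read), 0, None).astype(np.int64)


def simulate_apb_experiment(scene: CellScene, cfg: AcquisitionConfig
                            ) -> tuple[ImageSeries, ImageSeries, GroundTruthManifest]:
    """Full acceptor-photobleaching acquisition: acceptor pre frames, donor
    pre frames, bleach pulse, donor post frames, acceptor post frames."""
    rng = np.random.default_rng(cfg.rng_seed)
    dt = cfg.frame_exposure_s

    t = 0.0
    acc_frames, acc_phases, acc_times = [], [], []
    don_frames, don_phases, don_times = [], [], []

    for i in range(cfg.n_pre_acceptor):
        acc_frames.append(apply_noise(
            render_expected_image(scene, "acceptor", "pre", cfg, i), cfg, rng))
        acc_phases.append("pre"); acc_times.append(t); t += dt
    for i in range(cfg.n_pre_donor):
        don_frames.append(apply_noise(
            render_expected_image(scene, "donor", "pre", cfg, i), cfg, rng))
        don_phases.append("pre"); don_times.append(t); t += dt
    t += cfg.bleach_pulse_s
    for i in range(cfg.n_post_donor):
        don_frames.append(apply_noise(
            render_expected_image(scene, "donor", "post", cfg, i), cfg, rng))
        don_phases.append("post"); don_times.append(t); t += dt
    for i in range(cfg.n_post_acceptor):
        acc_frames.append(apply_noise(
            render_expected_image(scene, "acceptor", "post", cfg, i), cfg, rng))
        acc_phases.append("post"); acc_times.append(t); t += dt

    donor = ImageSeries(np.stack(don_frames), "donor", tuple(don_phases),
                        np.array(don_times), scene.pixel_size_nm)
    acceptor = ImageSeries(np.stack(acc_frames), "acceptor", tuple(acc_phases),
                           np.array(acc_times), scene.pixel_size_nm)
    return donor, acceptor, GroundTruthManifest(scene, cfg, "apb")


def render_marker_image(scene: CellScene, marker_present: np.ndarray,
                        marker_amplitude: float = 800.0,
                        marker_cytoplasm_level: float = 60.0) -> np.ndarray:
    """Expected stage-marker (Abp1) channel image.

    ``marker_present`` is a boolean flag per patch; flagged patches carry
    the marker amplitude on top of the cytoplasmic marker level.
    """
    marker_present = np.asarray(marker_present, dtype=bool)
    if marker_present.size != len(scene.patch_centers):
        raise ValueError("marker_present length must match patch count")
    img = np.full(scene.shape, scene.background_level, dtype=float)
    img += scene.cell_mask() * marker_cytoplasm_level
    kernels = scene.patch_kernels()
    if marker_present.any():
        img += marker_amplitude * kernels[marker_present].sum(axis=0)
    return img


# ---------------------------------------------------------------------------
# FRAP

@dataclass
class FrapConfig:
    """Single-channel FRAP time series: bleach one spot, follow recovery.

    The bleached spot's expected intensity follows
    ``F(t) = F_post0 + M*(F_pre - F_post0)*(1 - exp(-t/tau))`` on top of
    per-frame acquisition photobleaching that affects the whole cell.
    """

    n_pre: int = 5
    frame_interval_s: float = 0.5
    duration_s: float = 60.0
    bleach_depth: float = 0.9        # fraction of spot signal destroyed
    mobile_fraction: float = 0.7
    tau_s: float = 5.0
    bleach_spot_index: int = 0       # which patch gets bleached
    delta_struct: float = 0.002      # per-frame acquisition photobleaching
    read_noise_sd: float = 2.0
    em_gain_factor: float = EM_EXCESS_FACTOR
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must lie in (0, 1]")
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")


def frap_expected_amplitudes(cfg: FrapConfig, n_patches: int
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame relative amplitude of every patch and of the cytoplasm.

    Returns ``(times_s, patch_scale (T, n_patches), cyto_scale (T,))`` with
    scales relative to the unbleached pre-bleach level; acquisition
    photobleaching ``(1 - delta)**k`` is included.
    """
    n_post = int(round(cfg.duration_s / cfg.frame_interval_s))
    if cfg.bleach_spot_index >= n_patches:
        raise ValueError("bleach_spot_index outside the patch list")
    n_total = cfg.n_pre + n_post
    times = np.arange(n_total) * cfg.frame_interval_s
    k = np.arange(n_total)
    decay = (1.0 - cfg.delta_struct) ** k
    scale = np.tile(decay[:, None], (1, max(n_patches, 1)))
    f0 = 1.0 - cfg.bleach_depth
    t_post = (np.arange(n_post)) * cfg.frame_interval_s
    recovery = f0 + cfg.mobile_fraction * (1.0 - f0) * (1.0 - np.exp(-t_post / cfg.tau_s))
    if n_patches:
        scale[cfg.n_pre:, cfg.bleach_spot_index] = recovery * decay[cfg.n_pre:]
    return times, scale, decay


def frap_expected_stack(scene: CellScene, cfg: FrapConfig
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected FRAP stack and its time base."""
    n_patches = len(scene.patch_centers)
    times, patch_scale, cyto_scale = frap_expected_amplitudes(cfg, n_patches)
    mask = scene.cell_mask().astype(float)
    base = scene.background_level + 0.0 * mask
    expected = (base[None]
                + mask[None] * scene.cytoplasm_level * cyto_scale[:, None, None])
    if n_patches:
        expected = expected + np.tensordot(
            patch_scale * scene.patch_amplitude_donor, scene.patch_kernels(),
            axes=(1, 0))
    return expected, times


def simulate_frap_experiment(scene: CellScene, cfg: FrapConfig
                             ) -> tuple[ImageSeries, GroundTruthManifest]:
    """Simulate a FRAP acquisition of the scene's donor channel."""
    rng = np.random.default_rng(cfg.rng_seed)
    expected, times = frap_expected_stack(scene, cfg)
    frames = apply_noise(expected, cfg, rng)
    phases = tuple(["pre"] * cfg.n_pre + ["post"] * (len(times) - cfg.n_pre))
    series = ImageSeries(frames, "donor", phases, times, scene.pixel_size_nm)
    return series, GroundTruthManifest(scene, cfg, "frap")


# ---------------------------------------------------------------------------
# scene factories

def make_scene(rng: np.random.Generator | int | None = None,
               n_patches: int | None = None,
               shape: tuple[int, int] = (64, 64),
               min_separation_px: float = 0.0,
               **overrides) -> CellScene:
    """Random default scene: 5-15 endocytic patches near the cell cortex.

    Patches sit in an annulus near the plasma membrane (where endocytic
    sites live); with ``min_separation_px`` left at 0 they may overlap,
    mimicking the apparent clustering of stalled sites on diffraction-limited
    images.
    """
    rng = np.random.default_rng(rng)
    if n_patches is None:
        n_patches = int(rng.integers(5, 16))
    proto = CellScene(shape=shape, **overrides)
    cr, cc = proto.cell_center
    rr, rc = proto.cell_radii
    centers: list[tuple[float, float]] = []
    guard = 0
    while len(centers) < n_patches and guard < 10000:
        guard += 1
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.55, 0.88)        # cortical annulus, inside the mask
        cand = (cr + rho * rr * np.sin(theta), cc + rho * rc * np.cos(theta))
        if min_separation_px > 0 and any(
                np.hypot(cand[0] - a, cand[1] - b) < min_separation_px
                for a, b in centers):
            continue
        centers.append(cand)
    return dataclasses.replace(proto, patch_centers=np.asarray(centers))


def _background_strip(scene: CellScene) -> Roi:
    """Full-width extracellular strip along the top rows (clear of the cell
    and of cortical-patch PSF tails); large enough for a stable median."""
    w = scene.shape[1]
    return Roi("background", "background", "polygon",
               vertices=np.array([(-0.5, -0.5), (-0.5, w - 0.5),
                                  (2.5, w - 0.5), (2.5, -0.5)]))


def make_frap_scene(rng: np.random.Generator | int | None = None,
                    n_patches: int = 6, **overrides) -> CellScene:
    """Scene for FRAP acquisitions: well-separated bright patches.

    The FRAP channel images a bright tag with no FRET losses, so its spot
    photon budget is an order of magnitude above the FRET-donor default
    (20 000 expected photons/frame, per-frame spot SNR ~50).
    """
    overrides.setdefault("patch_amplitude_donor", 20000.0)
    overrides.setdefault("min_separation_px", 8.0)
    return make_scene(rng, n_patches=n_patches, **overrides)


def frap_roi_set(scene: CellScene, spot_index: int = 0,
                 spot_radius_px: float = 2.0) -> RoiSet:
    """FRAP analysis ROIs: bleached spot, large cytoplasmic reference
    (tracks acquisition photobleaching at low noise), and background."""
    cr, cc = scene.cell_center
    rr, rc = scene.cell_radii
    return RoiSet([
        Roi("spot", "frap_spot", "oval",
            center=tuple(scene.patch_centers[spot_index]),
            radii=(spot_radius_px, spot_radius_px)),
        Roi("reference", "reference", "oval", center=(cr, cc),
            radii=(0.45 * rr, 0.45 * rc)),
        _background_strip(scene),
    ])


def default_roi_set(scene: CellScene, patch_radius_px: float = 2.0) -> RoiSet:
    """Standard analysis ROIs for a simulated scene.

    One oval per patch (role ``patches``), an extracellular background
    rectangle, and a central cytoplasm oval clear of the cortical patches.
    """
    h, w = scene.shape
    rois = [Roi(f"patch_{i}", "patches", "oval", center=tuple(c),
                radii=(patch_radius_px, patch_radius_px))
            for i, c in enumerate(scene.patch_centers)]
    cr, cc = scene.cell_center
    rr, rc = scene.cell_radii
    rois.append(Roi("cytoplasm", "cytoplasm", "oval", center=(cr, cc),
                    radii=(0.4 * rr, 0.4 * rc)))
    rois.append(_background_strip(scene))
    return RoiSet(rois)
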
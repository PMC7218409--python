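"""End-to-end simulation pipelines: scene -> acquisition -> quantification.

These drive whole-screen experiments on synthetic data: per-cell FRET with a
parallel donor-only batch, classified pair records, and stage-sorted
per-patch panels. They are thin compositions of the simulator and the
quantification modules.
"""

from __future__ import annotations

import numpy as np

from .fret import (FretMeasurement, apply_donor_only_correction,
                   donor_only_baseline, quantify_apb)
from .simulate import (AcquisitionConfig, FrapConfig,
                       default_roi_set, frap_roi_set, make_frap_scene,
                       make_scene, simulate_apb_experiment,
                       simulate_frap_experiment)
from .stats import ScreenRecord, aggregate_screen


def simulate_cell_measurement(E_true: float, rng: np.random.Generator,
                              convention: str = "increase_over_pre",
                              scene_kwargs: dict | None = None,
                              cfg_kwargs: dict | None = None
                              ) -> FretMeasurement:
    """One simulated cell through the full quantification pipeline."""
    scene = make_scene(rng, **(scene_kwargs or {}))
    cfg = AcquisitionConfig(E_true=E_true,
                            rng_seed=int(rng.integers(2 ** 31)),
                            **(cfg_kwargs or {}))
    donor, acceptor, _ = simulate_apb_experiment(scene, cfg)
    return quantify_apb(donor, acceptor, default_roi_set(scene),
                        convention=convention)


def simulate_donor_only_batch(n_cells: int, rng: np.random.Generator,
                              batch_id: str = "batch",
                              convention: str = "increase_over_pre",
                              scene_kwargs: dict | None = None,
                              cfg_kwargs: dict | None = None):
    """Donor-only cells (E = 0) acquired 'in parallel': same settings."""
    ms = [simulate_cell_measurement(0.0, rng, convention, scene_kwargs,
                                    cfg_kwargs)
          for _ in range(n_cells)]
    return donor_only_baseline([m for m in ms if m.valid], batch_id)


def simulate_screen_pair(E_true: float, n_cells: int,
                         rng: np.random.Generator,
                         baseline=None,
                         pair_id: str = "pair",
                         convention: str = "increase_over_pre",
                         n_donor_only: int | None = None,
                         scene_kwargs: dict | None = None,
                         cfg_kwargs: dict | None = None) -> ScreenRecord:
    """Simulate one protein pair: n cells plus donor-only correction.

    If no baseline is passed, a parallel donor-only batch of
    ``n_donor_only`` (default ``n_cells``) cells is simulated with the same
    settings.
    """
    if baseline is None:
        baseline = simulate_donor_only_batch(
            n_donor_only if n_donor_only is not None else n_cells,
            rng, f"{pair_id}-donor-only", convention, scene_kwargs, cfg_kwargs)
    ms = [simulate_cell_measurement(E_true, rng, convention, scene_kwargs,
                                    cfg_kwargs)
          for _ in range(n_cells)]
    ms = apply_donor_only_correction(ms, baseline)
    rows = [{"pair_id": pair_id, "compartment": "endocytic_sites",
             "E_pct": m.E_pct, "valid": m.valid,
             "baseline_id": m.baseline_id} for m in ms]
    (record,) = aggregate_screen(rows)
    return record


def simulate_stage_panel(E_absent: float, E_present: float,
                         n_per_group: int, rng: np.random.Generator,
                         patches_per_cell: int = 10,
                         convention: str = "increase_over_pre",
                         cfg_kwargs: dict | None = None
                         ) -> tuple[list[float], list[float]]:
    """Per-patch FRET panel sorted by a simulated stage marker.

    Each cell carries ``patches_per_cell`` well-separated patches, half with
    the marker (ground-truth efficiency ``E_present``) and half without
    (``E_absent``). Cells are simulated until both groups hold
    ``n_per_group`` valid patches; the full per-patch pipeline (background,
    averaging, cytoplasm threshold, marker k-sigma rule) is exercised.
    """
    from .fret import (average_phase_frames, estimate_cytoplasm_threshold,
                       subtract_background)
    from .simulate import apply_noise, render_marker_image
    from .stages import stage_resolved_fret

    absent: list[float] = []
    present: list[float] = []
    guard = 0
    while (len(absent) < n_per_group or len(present) < n_per_group) \
            and guard < 10 * n_per_group:
        guard += 1
        scene = make_scene(rng, n_patches=patches_per_cell,
                           min_separation_px=6.0)
        n_p = len(scene.patch_centers)
        marker_flags = np.zeros(n_p, dtype=bool)
        marker_flags[rng.permutation(n_p)[:n_p // 2]] = True
        e_patch = np.where(marker_flags, E_present, E_absent)
        cfg = AcquisitionConfig(E_true=e_patch,
                                rng_seed=int(rng.integers(2 ** 31)),
                                **(cfg_kwargs or {}))
        donor, _, _ = simulate_apb_experiment(scene, cfg)
        marker_noisy = apply_noise(render_marker_image(scene, marker_flags),
                                   cfg, np.random.default_rng(
                                       int(rng.integers(2 ** 31))))
        rois = default_roi_set(scene)
        bg = rois.mask("background", donor.shape)
        donor_b = subtract_background(donor, bg)
        pre = average_phase_frames(donor_b, "pre")
        post = average_phase_frames(donor_b, "post")
        thr = estimate_cytoplasm_threshold(pre, rois.mask("cytoplasm",
                                                          donor.shape))
        cmask = rois.mask("cytoplasm", donor.shape)
        marker_img = marker_noisy.astype(float) - np.median(marker_noisy[bg])
        c_level = float(marker_img[cmask].mean())
        c_sd = float(marker_img[cmask].std())
        cmp = stage_resolved_fret(scene.patch_centers, pre, post, marker_img,
                                  thr.value, c_level, c_sd,
                                  convention=convention)
        absent.extend(cmp.values_absent)
        present.extend(cmp.values_present)
    return absent[:n_per_group], present[:n_per_group]


def simulate_frap_roundtrip(mobile_fraction: float, tau_s: float,
                            rng: np.random.Generator,
                            scene_kwargs: dict | None = None,
                            cfg_kwargs: dict | None = None):
    """Simulate -> extract -> normalize -> fit one FRAP experiment.

    Returns the :class:`~fretmap.frap.RecoveryFit` for a default FRAP scene
    with the first patch bleached.
    """
    from .frap import extract_trace, fit_recovery

    scene = make_frap_scene(rng, **(scene_kwargs or {}))
    cfg = FrapConfig(mobile_fraction=mobile_fraction, tau_s=tau_s,
                     rng_seed=int(rng.integers(2 ** 31)),
                     **(cfg_kwargs or {}))
    series, _ = simulate_frap_experiment(scene, cfg)
    rois = frap_roi_set(scene)
    trace = extract_trace(series, rois.mask("frap_spot", series.shape),
                          rois.mask("reference", series.shape),
                          rois.mask("background", series.shape))
    return fit_recovery(trace)
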
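"""End-to-end validation experiments on fully synthetic data.

Each function here regenerates its inputs from a seed, runs the relevant
pipeline stage, and returns summary numbers. They back both the validation
test suite and the standalone reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .fret import (apply_donor_only_correction, donor_only_baseline,
                   pixel_efficiencies)
from .mapping import (MapConfig, assign_layers, brute_force_embedding,
                      build_graph, planted_geometry_instance)
from .pipelines import (simulate_cell_measurement, simulate_frap_roundtrip,
                        simulate_stage_panel)
from .simulate import AcquisitionConfig, make_scene, render_expected_image
from .simulate import default_roi_set
from .stats import classify_fret_positive, mean_ci, welch_t_test


def estimator_bias(seed: int, n_cells: int = 200,
                   e_true_pct=(0.0, 2.0, 5.0, 10.0, 15.0)) -> dict:
    """Mean corrected efficiency vs truth across ground-truth conditions.

    Simulates ``n_cells`` per condition plus one parallel donor-only batch,
    quantifies with the ``dequench_over_post`` convention (whose noise-free
    fixed point is E_true itself) and reports per-condition bias in
    percentage points.
    """
    rng = np.random.default_rng(seed)
    donor_only = [simulate_cell_measurement(0.0, rng, "dequench_over_post")
                  for _ in range(n_cells)]
    baseline = donor_only_baseline([m for m in donor_only if m.valid], "acc")
    out = {}
    for e in e_true_pct:
        ms = [simulate_cell_measurement(e / 100.0, rng, "dequench_over_post")
              for _ in range(n_cells)]
        ms = apply_donor_only_correction(ms, baseline)
        vals = [m.E_pct for m in ms if m.valid]
        out[e] = {"mean_E_pct": float(np.mean(vals)),
                  "bias_pct": float(np.mean(vals) - e),
                  "n": len(vals)}
    return out


def convention_identity_error(seed: int) -> float:
    """Max deviation of e_pre = e_post/(1 - e_post/100) on noise-free images."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for e in (0.02, 0.10, 0.15):
        scene = make_scene(rng, n_patches=8)
        cfg = AcquisitionConfig(E_true=e, delta_struct=0.0, read_noise_sd=0.0)
        pre = render_expected_image(scene, "donor", "pre", cfg, 0) \
            - scene.background_level
        post = render_expected_image(scene, "donor", "post", cfg, 0) \
            - scene.background_level
        mask = default_roi_set(scene).mask("patches", pre.shape)
        e_pre = pixel_efficiencies(pre, post, mask, 10.0, "increase_over_pre")
        e_post = pixel_efficiencies(pre, post, mask, 10.0, "dequench_over_post")
        worst = max(worst, float(np.max(np.abs(
            e_pre - e_post / (1 - e_post / 100)))))
    return worst


def classification_calibration(seed: int, n_replicates: int = 400,
                               n_cells: int = 20,
                               n_donor_only: int = 60,
                               e_alt_pct: float = 2.0) -> dict:
    """False-positive rate of null pairs and detection rate of weak pairs.

    Per replicate: one session-level donor-only batch, one E = 0 pair and
    one E = ``e_alt_pct`` pair of ``n_cells`` cells each, all acquired with
    the same settings; pairs classified by the mean/CI positivity rule.

    The donor-only pool is larger than a single pair (one batch serves a
    whole acquisition session): subtracting a noisy baseline correlates the
    corrected values, and the pair-level CI does not see that shared error,
    so a small baseline would inflate the false-positive rate above the
    rule's nominal level.
    """
    rng = np.random.default_rng(seed)
    null_pos = alt_pos = 0
    for _ in range(n_replicates):
        donor_only = [simulate_cell_measurement(0.0, rng)
                      for _ in range(n_donor_only)]
        base = donor_only_baseline([m for m in donor_only if m.valid], "b")
        for e_pct, counter in ((0.0, "null"), (e_alt_pct, "alt")):
            ms = [simulate_cell_measurement(e_pct / 100.0, rng)
                  for _ in range(n_cells)]
            ms = apply_donor_only_correction(ms, base)
            vals = [m.E_pct for m in ms if m.valid]
            mean, hw = mean_ci(vals)
            verdict = classify_fret_positive(mean, hw)
            if counter == "null":
                null_pos += verdict == "positive"
            else:
                alt_pos += verdict == "positive"
    return {"false_positive_rate_pct": 100.0 * null_pos / n_replicates,
            "detection_rate_pct": 100.0 * alt_pos / n_replicates,
            "n_replicates": n_replicates}


def welch_validation(seed: int, n_replicates: int = 10_000) -> dict:
    """Worked example plus the type-I error rate under the null."""
    t, df, p = welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_replicates, 20))
    b = rng.normal(size=(n_replicates, 20))
    res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    # the vectorized scipy call must agree with our scalar Welch
    t0, _, p0 = welch_t_test(a[0], b[0])
    assert abs(t0 - res.statistic[0]) < 1e-12 and abs(p0 - res.pvalue[0]) < 1e-12
    return {"example_t": t, "example_df": df, "example_p": p,
            "type1_rate_pct": float(100 * (res.pvalue < 0.05).mean())}


def stage_sorting_power(seed: int, n_replicates: int = 100,
                        n_per_group: int = 70,
                        delta_e_pct: float = 6.0) -> float:
    """Fraction of two-group panels (ground-truth gap ``delta_e_pct``)
    significant at p < 0.001."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        a, p = simulate_stage_panel(0.0, delta_e_pct / 100.0, n_per_group, rng)
        _, _, pv = welch_t_test(a, p)
        hits += pv < 1e-3
    return 100.0 * hits / n_replicates


def stage_sorting_null_uniformity(seed: int, n_replicates: int = 150,
                                  n_per_group: int = 70) -> dict:
    """KS test of Welch p-values against Uniform(0,1) when both groups share
    the same ground truth."""
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_replicates):
        a, p = simulate_stage_panel(0.05, 0.05, n_per_group, rng)
        pvals.append(welch_t_test(a, p)[2])
    ks = sps.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_replicates": n_replicates}


FRAP_GRID = tuple((m, t) for m in (0.0, 0.3, 0.7, 1.0) for t in (2.0, 5.0, 15.0))


def frap_grid_recovery(seed: int, n_replicates: int = 100) -> dict:
    """Round-trip success over the (M, tau) grid.

    Success: fitted M within 10% of truth and fitted tau within 10% of
    truth; for immobile truth (M = 0) tau is unidentifiable, so success is
    fitted M <= 0.05.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for m_true, tau_true in FRAP_GRID:
        ok = 0
        for _ in range(n_replicates):
            fit = simulate_frap_roundtrip(m_true, tau_true, rng)
            if not fit.success:
                continue
            if m_true == 0.0:
                ok += fit.mobile_fraction <= 0.05
            else:
                ok += (abs(fit.mobile_fraction - m_true) <= 0.1 * m_true
                       and abs(fit.tau_s - tau_true) <= 0.1 * tau_true)
        out[(m_true, tau_true)] = 100.0 * ok / n_replicates
    return out


def layer_optimizer_oracle(seed: int, n_instances: int = 3) -> float:
    """Worst optimizer/bruteforce objective ratio on 5-node instances."""
    worst = 0.0
    for k in range(n_instances):
        rows, anchors, _ = planted_geometry_instance(5, seed + k, x_span=35.0)
        g = build_graph(rows)
        cfg = MapConfig(seed=seed + k, x_max_nm=40.0)
        asg = assign_layers(g, anchors, cfg)
        _, brute_val = brute_force_embedding(g, anchors, cfg)
        ratio = asg.objective / brute_val if brute_val > 1e-12 else \
            (1.0 if asg.objective <= 1e-9 else np.inf)
        worst = max(worst, ratio)
    return worst


def planted_geometry_tau(seed: int, n_seeds: int = 20,
                         n_nodes: int = 12) -> dict:
    """Kendall rank correlation of recovered vs planted coordinates."""
    from scipy.stats import kendalltau

    taus = []
    for k in range(n_seeds):
        rows, anchors, truth = planted_geometry_instance(n_nodes, seed + k)
        asg = assign_layers(build_graph(rows), anchors,
                            MapConfig(seed=seed + k))
        nodes = list(truth)
        taus.append(kendalltau([truth[n] for n in nodes],
                               [asg.coordinates_nm[n] for n in nodes]).statistic)
    return {"min_tau": float(min(taus)), "mean_tau": float(np.mean(taus))}


def pixel_loop_oracle(seed: int, n_images: int = 50) -> bool:
    """Vectorized per-pixel efficiency vs an explicit loop, bit for bit."""
    rng = np.random.default_rng(seed)
    for _ in range(n_images):
        pre = rng.uniform(1, 2000, size=(16, 16))
        post = rng.uniform(1, 2000, size=(16, 16))
        mask = rng.random((16, 16)) > 0.25
        thr = rng.uniform(0, 800)
        conv = rng.choice(["increase_over_pre", "dequench_over_post"])
        got = pixel_efficiencies(pre, post, mask, thr, conv)
        manual = []
        for i in range(16):
            for j in range(16):
                if mask[i, j] and pre[i, j] > thr and post[i, j] > thr:
                    denom = pre[i, j] if conv == "increase_over_pre" else post[i, j]
                    manual.append(100.0 * (post[i, j] - pre[i, j]) / denom)
        if got.tolist() != manual:
            return False
    return True
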
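"""Screen-level statistics: mean/95% CI, FRET-positivity, Welch's t, box plots.

A protein pair is called FRET-positive when its mean FRET efficiency and
both ends of the 95% confidence interval are positive. No multiple-testing
correction is applied by default, matching the per-pair CI rule; a
Benjamini-Hochberg helper is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps


def mean_ci(values: Sequence[float], level: float = 0.95,
            method: str = "t") -> tuple[float, float]:
    """Sample mean and CI halfwidth.

    ``method="t"`` (default): mean +/- t_{1-a/2, n-1} * s / sqrt(n).
    ``method="bootstrap"``: percentile bootstrap halfwidth (seeded),
    half the central-interval width.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need n >= 2 for a confidence interval")
    m = float(v.mean())
    if method == "t":
        s = float(v.std(ddof=1))
        t = sps.t.ppf(0.5 + level / 2, df=n - 1)
        return m, float(t * s / np.sqrt(n))
    if method == "bootstrap":
        rng = np.random.default_rng(0)
        boots = rng.choice(v, size=(2000, n), replace=True).mean(axis=1)
        lo, hi = np.quantile(boots, [(1 - level) / 2, 0.5 + level / 2])
        return m, float((hi - lo) / 2)
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class ScreenRecord:
    """Aggregated FRET of one protein pair in one compartment."""

    pair_id: str
    donor_label: str
    acceptor_label: str
    compartment: str                     # "endocytic_sites" | "cytoplasm"
    values_pct: list[float]
    n_cells: int
    mean_E_pct: float
    ci95_halfwidth_pct: float
    verdict: str = "negative"
    provenance: dict = field(default_factory=dict)


def classify_fret_positive(mean_E_pct: float, ci95_halfwidth_pct: float) -> str:
    """Positive iff the mean and both 95% CI bounds are positive."""
    lo = mean_E_pct - ci95_halfwidth_pct
    hi = mean_E_pct + ci95_halfwidth_pct
    return "positive" if (mean_E_pct > 0 and lo > 0 and hi > 0) else "negative"


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]
                 ) -> tuple[float, float, float]:
    """Two-tailed Welch's t-test for unpaired samples of uneven variances.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite df. Two zero-variance
    samples with equal means give ``(0, n_a+n_b-2, 1)`` by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), \
            float(a.size + b.size - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (se2a ** 2 / (a.size - 1) + se2b ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass
class BoxplotSummary:
    """Quartiles, 1.5*IQR whiskers and notch (1.58*IQR/sqrt(n))."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    notch_halfwidth: float
    n: int


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Box-plot statistics with linear (inclusive) quartile interpolation.

    Whiskers reach the most extreme data points within 1.5*IQR of the
    quartiles; the notch halfwidth is the conventional 1.58*IQR/sqrt(n)
    approximation to the median's 95% CI.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need n >= 5 for box-plot statistics")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(median=float(med), q25=float(q25), q75=float(q75),
                          whisker_low=float(inside.min()),
                          whisker_high=float(inside.max()),
                          notch_halfwidth=float(1.58 * iqr / np.sqrt(v.size)),
                          n=int(v.size))


def aggregate_screen(measurements: Iterable[dict],
                     ci_method: str = "t") -> list[ScreenRecord]:
    """Fold per-cell measurements into one record per (pair, compartment).

    Each measurement dict needs ``pair_id``, ``compartment``, ``E_pct`` and
    ``valid``; invalid cells are dropped. Pairs with < 2 valid cells are
    absent from the output; use :func:`aggregate_screen_full` to also get the
    skipped pairs with reasons.
    """
    records, _ = aggregate_screen_full(measurements, ci_method)
    return records


def aggregate_screen_full(measurements: Iterable[dict],
                          ci_method: str = "t"
                          ) -> tuple[list[ScreenRecord], list[dict]]:
    """As :func:`aggregate_screen`, also returning skipped pairs with reasons."""
    groups: dict[tuple[str, str], list[dict]] = {}
    for m in measurements:
        for key in ("pair_id", "compartment", "E_pct"):
            if key not in m:
                raise ValueError(f"measurement missing {key!r}: {m}")
        groups.setdefault((m["pair_id"], m["compartment"]), []).append(m)

    records, skipped = [], []
    for (pair_id, compartment), ms in sorted(groups.items()):
        vals = [float(m["E_pct"]) for m in ms if m.get("valid", True)
                and np.isfinite(m["E_pct"])]
        if len(vals) < 2:
            skipped.append({"pair_id": pair_id, "compartment": compartment,
                            "reason": f"only {len(vals)} valid cells"})
            continue
        mean, hw = mean_ci(vals, method=ci_method)
        records.append(ScreenRecord(
            pair_id=pair_id,
            donor_label=ms[0].get("donor_label", ""),
            acceptor_label=ms[0].get("acceptor_label", ""),
            compartment=compartment,
            values_pct=vals, n_cells=len(vals),
            mean_E_pct=mean, ci95_halfwidth_pct=hw,
            verdict=classify_fret_positive(mean, hw),
            provenance={"batch_ids": sorted({m.get("batch_id", "") for m in ms}),
                        "baseline_ids": sorted({str(m.get("baseline_id", "")) for m in ms})},
        ))
    return records, skipped


def benjamini_hochberg(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """BH-adjusted q-values (optional; the positivity rule does not use it)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.clip(q, 0, 1)
    return out
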
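"""Paired baseline-vs-end comparisons and report assembly.

Each outcome is compared with a classic paired Student t-test on the
per-participant deltas (two-sided); deltas are screened for normality with
Shapiro-Wilk and the result is carried as a flag only.  P-values are
reported uncorrected across the many subgroup/threshold combinations, which
mirrors the analysed program's reporting; an optional Benjamini-Hochberg
switch is provided for sensitivity checks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class PairedComparison:
    metric: str
    n: int
    mean_baseline: float
    mean_end: float
    mean_delta: float
    t_stat: float
    p_value: float
    normal_deltas: bool
    degenerate: bool = False  # zero-variance deltas: t undefined

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < ALPHA


def paired_t(
    baseline: Sequence[float],
    end: Sequence[float],
    metric: str = "",
) -> PairedComparison:
    """Paired t-test of end vs baseline (positive t = increase)."""
    b = np.asarray(baseline, dtype=float)
    e = np.asarray(end, dtype=float)
    if b.shape != e.shape:
        raise ValueError("baseline and end must be paired (equal length)")
    keep = np.isfinite(b) & np.isfinite(e)
    b, e = b[keep], e[keep]
    if b.size < 2:
        raise ValueError("paired t-test needs n >= 2 complete pairs")
    deltas = e - b
    if np.allclose(deltas.std(ddof=1), 0.0):
        return PairedComparison(
            metric=metric, n=b.size,
            mean_baseline=float(b.mean()), mean_end=float(e.mean()),
            mean_delta=float(deltas.mean()),
            t_stat=float("nan"), p_value=float("nan"),
            normal_deltas=True, degenerate=True,
        )
    t, p = sps.ttest_rel(e, b)
    # Shapiro-Wilk needs 3+ points and chokes on huge n; subsample like a
    # screening check would.
    if deltas.size >= 3:
        sub = deltas if deltas.size <= 5000 else deltas[:5000]
        normal = bool(sps.shapiro(sub).pvalue >= ALPHA)
    else:
        normal = True
    return PairedComparison(
        metric=metric, n=b.size,
        mean_baseline=float(b.mean()), mean_end=float(e.mean()),
        mean_delta=float(deltas.mean()),
        t_stat=float(t), p_value=float(p),
        normal_deltas=normal,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def cohort_report(
    glycemic_deltas,
    nutrient_pairs: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    behavior_pairs: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    adjust: bool = False,
) -> dict:
    """Assemble paired comparisons for glycemic metrics (per subgroup and
    category), nutrient ratios, and behavior measures.

    ``glycemic_deltas`` is the output of glycemic.participant_deltas;
    the *_pairs arguments map metric name -> (baseline values, end values)
    aligned by participant.  Empty subgroups are absent, never zeros.
    """
    from .glycemic import DELTA_METRICS, _metric_value, subgroup_membership

    report: dict = {"glycemic": {}, "nutrients": {}, "behavior": {}}

    groups: dict[tuple[str, str], list] = {}
    for d in glycemic_deltas:
        for g in subgroup_membership(d.baseline):
            groups.setdefault((g, "all"), []).append(d)
            groups.setdefault((g, d.category), []).append(d)
    for key, members in sorted(groups.items()):
        if len(members) < 2:
            continue
        entry = {}
        for metric in DELTA_METRICS:
            b = [_metric_value(m.baseline, metric) for m in members]
            e = [_metric_value(m.end, metric) for m in members]
            entry[metric] = paired_t(b, e, metric=metric)
        report["glycemic"][key] = entry

    for name, (b, e) in (nutrient_pairs or {}).items():
        if np.isfinite(np.asarray(b, float)).sum() >= 2:
            report["nutrients"][name] = paired_t(b, e, metric=name)
    for name, (b, e) in (behavior_pairs or {}).items():
        if np.isfinite(np.asarray(b, float)).sum() >= 2:
            report["behavior"][name] = paired_t(b, e, metric=name)

    if adjust:
        comps = [
            c
            for section in ("glycemic", "nutrients", "behavior")
            for v in report[section].values()
            for c in (v.values() if isinstance(v, dict) else [v])
            if not c.degenerate
        ]
        adj = benjamini_hochberg([c.p_value for c in comps])
        report["bh_adjusted"] = {
            (c.metric, i): float(a) for i, (c, a) in enumerate(zip(comps, adj))
        }
    return report
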
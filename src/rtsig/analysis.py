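"""Signature statistics: distributions per modification type, condition
comparisons, jump-rate deltas, prevalence fractions and mismatch composition.

Conventions adopted here (the source pipelines for this kind of data rarely
name their tests): matched per-position condition contrasts use a two-sided
Wilcoxon signed-rank test; unmatched pools use a two-sided Mann-Whitney U;
significance threshold alpha = 0.05 with no multiple-testing correction
(per-panel flags only). Confidence intervals for both median and mean are
bootstrap percentile intervals (10,000 resamples, seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySelectionError, ValidationError
from .types import ModificationAnnotation, PositionProfile, annotation_index

#: Feature names accepted throughout this module. ``jump_total`` is the sum
#: of the three deletion classes and is the default "jump rate" of aggregate
#: reports.
FEATURES = ("arrest", "mismatch", "jump_direct", "jump_delayed", "jump_double", "jump_total")

ALPHA = 0.05


def feature_value(row: PositionProfile, feature: str) -> float:
    if feature == "arrest":
        return row.arrest_rate
    if feature == "mismatch":
        return row.mism_rate
    if feature == "jump_direct":
        return row.single_jump_rate_direct
    if feature == "jump_delayed":
        return row.single_jump_rate_delayed
    if feature == "jump_double":
        return row.double_jump_rate
    if feature == "jump_total":
        return (row.single_jump_rate_direct + row.single_jump_rate_delayed
                + row.double_jump_rate)
    raise ValidationError(f"unknown feature {feature!r}; expected one of {FEATURES}")


def select_profiles(
    profiles: Iterable[PositionProfile],
    annotations: list[ModificationAnnotation],
    mod_filter: str | None,
) -> list[PositionProfile]:
    """Select rows by modification status.

    ``mod_filter``: a modification code keeps annotated positions bearing
    that code; ``"modified"`` keeps every annotated position regardless of
    code; ``"unmodified"`` keeps positions absent from the annotation;
    ``None`` keeps everything.
    """
    if mod_filter is None:
        return list(profiles)
    idx = annotation_index(annotations)
    if mod_filter == "unmodified":
        return [p for p in profiles if (p.ref_seg, p.pos) not in idx]
    if mod_filter == "modified":
        return [p for p in profiles if (p.ref_seg, p.pos) in idx]
    return [p for p in profiles if idx.get((p.ref_seg, p.pos)) == mod_filter]


@dataclass
class SignatureSummary:
    """Distribution statistics of one feature over one position selection."""

    mod: str
    feature: str
    condition: str
    n_positions: int
    median: float
    mean: float
    ci95_median: tuple[float, float]
    ci95_mean: tuple[float, float]
    p_vs_reference: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_vs_reference is not None and self.p_vs_reference < ALPHA


@dataclass
class PositionDelta:
    """Per-position difference of one feature between two conditions."""

    ref_seg: str
    pos: int
    mod: str
    feature: str
    value_reference: float
    value_treated: float

    @property
    def delta(self) -> float:
        return self.value_treated - self.value_reference


@dataclass
class ConditionComparison:
    reference: SignatureSummary
    treated: SignatureSummary
    p_value: float | None
    deltas: list[PositionDelta]

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < ALPHA

    @property
    def mean_delta(self) -> float:
        return float(np.mean([d.delta for d in self.deltas]))


def _bootstrap_ci(
    values: np.ndarray, statistic, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    replicates = statistic(values[idx], axis=1)
    lo, hi = np.percentile(replicates, [2.5, 97.5])
    return float(lo), float(hi)


def summarize(
    profiles: Iterable[PositionProfile],
    annotations: list[ModificationAnnotation],
    mod_filter: str | None,
    feature: str,
    condition: str = "",
    n_boot: int = 10_000,
    seed: int = 0,
) -> SignatureSummary:
    """Median/mean of one feature over a selection, with bootstrap 95% CIs."""
    selected = select_profiles(profiles, annotations, mod_filter)
    if not selected:
        raise EmptySelectionError(f"no positions match mod_filter={mod_filter!r}")
    values = np.array([feature_value(p, feature) for p in selected], dtype=float)
    rng = np.random.default_rng([seed, len(values)])
    return SignatureSummary(
        mod=mod_filter or "all",
        feature=feature,
        condition=condition,
        n_positions=len(values),
        median=float(np.median(values)),
        mean=float(np.mean(values)),
        ci95_median=_bootstrap_ci(values, np.median, n_boot, rng),
        ci95_mean=_bootstrap_ci(values, np.mean, n_boot, rng),
    )


def compare_conditions(
    reference: Iterable[PositionProfile],
    treated: Iterable[PositionProfile],
    annotations: list[ModificationAnnotation],
    mod_filter: str | None,
    feature: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ConditionComparison:
    """Matched per-position contrast of one feature between two conditions.

    Positions must pass the coverage filter in *both* profile sets to be
    matched; deltas are treated - reference. The p-value is a two-sided
    Wilcoxon signed-rank test over the matched deltas (None, flagged
    non-significant, with fewer than 2 matched positions; 1.0 when every
    delta is exactly zero). Summaries are computed over the matched subsets.
    """
    ref_sel = select_profiles(reference, annotations, mod_filter)
    trt_sel = select_profiles(treated, annotations, mod_filter)
    ref_by_key = {(p.ref_seg, p.pos): p for p in ref_sel}
    trt_by_key = {(p.ref_seg, p.pos): p for p in trt_sel}
    matched = sorted(set(ref_by_key) & set(trt_by_key))
    if not matched:
        raise EmptySelectionError(
            f"no positions matched in both conditions for mod_filter={mod_filter!r}"
        )
    ann_idx = annotation_index(annotations)
    deltas = [
        PositionDelta(
            ref_seg=r, pos=p, mod=ann_idx.get((r, p), ""), feature=feature,
            value_reference=feature_value(ref_by_key[(r, p)], feature),
            value_treated=feature_value(trt_by_key[(r, p)], feature),
        )
        for r, p in matched
    ]
    diff = np.array([d.delta for d in deltas])
    if len(diff) < 2:
        p_value = None
    elif np.all(diff == 0):
        p_value = 1.0
    else:
        p_value = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
    ref_matched = [ref_by_key[k] for k in matched]
    trt_matched = [trt_by_key[k] for k in matched]
    ref_summary = summarize(ref_matched, annotations, mod_filter, feature,
                            condition="reference", n_boot=n_boot, seed=seed)
    trt_summary = summarize(trt_matched, annotations, mod_filter, feature,
                            condition="treated", n_boot=n_boot, seed=seed + 1)
    trt_summary.p_vs_reference = p_value
    return ConditionComparison(
        reference=ref_summary, treated=trt_summary, p_value=p_value, deltas=deltas,
    )


def compare_pools(
    reference: Iterable[PositionProfile],
    treated: Iterable[PositionProfile],
    annotations: list[ModificationAnnotation],
    mod_filter: str | None,
    feature: str,
) -> float:
    """Two-sided Mann-Whitney U over unmatched position pools."""
    ref_vals = [feature_value(p, feature)
                for p in select_profiles(reference, annotations, mod_filter)]
    trt_vals = [feature_value(p, feature)
                for p in select_profiles(treated, annotations, mod_filter)]
    if not ref_vals or not trt_vals:
        raise EmptySelectionError("empty pool in unmatched comparison")
    return float(stats.mannwhitneyu(ref_vals, trt_vals, alternative="two-sided").pvalue)


def prevalence(
    profiles: Iterable[PositionProfile],
    annotations: list[ModificationAnnotation],
    feature: str,
    threshold: float = 0.0,
    mod_filter: str | None = None,
) -> float:
    """Percentage of selected positions with feature value > ``threshold``.

    The default threshold 0 asks which fraction of positions bear the feature
    at all (e.g. "positions bearing a jump").
    """
    selected = select_profiles(profiles, annotations, mod_filter)
    if not selected:
        raise EmptySelectionError(f"no positions match mod_filter={mod_filter!r}")
    hits = sum(1 for p in selected if feature_value(p, feature) > threshold)
    return 100.0 * hits / len(selected)


def mismatch_composition(
    profiles: Iterable[PositionProfile],
    annotations: list[ModificationAnnotation],
    mod_filter: str | None = None,
    group_by_prebase: bool = False,
) -> pd.DataFrame:
    """Composition of misincorporated bases over a position selection.

    Forward and reverse counters are merged; each position contributes its
    non-reference base counts (``N`` included as an unresolved
    misincorporation). Fractions are normalized to sum to 1 per stratum.
    With ``group_by_prebase`` the selection is stratified by the 3'-preceding
    base; otherwise a single ``all`` stratum is returned. Columns:
    ``A/C/G/T/N`` fractions plus ``n_mismatch_bases``.
    """
    selected = select_profiles(profiles, annotations, mod_filter)
    if not selected:
        raise EmptySelectionError(f"no positions match mod_filter={mod_filter!r}")
    strata: dict[str, dict[str, int]] = {}
    for row in selected:
        key = (row.pre_base or "3'-terminal") if group_by_prebase else "all"
        bucket = strata.setdefault(key, dict.fromkeys("ACGTN", 0))
        counts = row.base_counts()
        for base in "ACGTN":
            if base == row.ref_base:
                continue
            bucket[base] += counts[base] + counts[base.lower()]
    records = []
    for key in sorted(strata):
        bucket = strata[key]
        total = sum(bucket.values())
        if total == 0:
            continue
        rec = {"stratum": key, "n_mismatch_bases": total}
        rec.update({base: bucket[base] / total for base in "ACGTN"})
        records.append(rec)
    if not records:
        raise EmptySelectionError("no mismatching bases in selection")
    frame = pd.DataFrame(records).set_index("stratum")
    return frame[["A", "C", "G", "T", "N", "n_mismatch_bases"]]


def summaries_frame(summaries: Sequence[SignatureSummary]) -> pd.DataFrame:
    """Tabular export of summaries (one row each)."""
    return pd.DataFrame([
        {
            "mod": s.mod, "feature": s.feature, "condition": s.condition,
            "n_positions": s.n_positions, "median": s.median, "mean": s.mean,
            "ci95_median_lo": s.ci95_median[0], "ci95_median_hi": s.ci95_median[1],
            "ci95_mean_lo": s.ci95_mean[0], "ci95_mean_hi": s.ci95_mean[1],
            "p_vs_reference": s.p_vs_reference,
            "significant": s.significant,
        }
        for s in summaries
    ])


def deltas_frame(deltas: Sequence[PositionDelta]) -> pd.DataFrame:
    """Tabular export of per-position deltas."""
    return pd.DataFrame([
        {
            "ref_seg": d.ref_seg, "pos": d.pos, "mod": d.mod, "feature": d.feature,
            "value_reference": d.value_reference, "value_treated": d.value_treated,
            "delta": d.delta,
        }
        for d in deltas
    ])
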
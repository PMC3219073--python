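"""Transcriptome-instability profiles from FIRMA score matrices.

A (probe set, sample) score beyond the global lower/upper 1st-percentile
thresholds counts as deviating exon usage: below the lower threshold as
skipping, above the upper as inclusion.  Per-sample counts are expressed
on the log2 scale relative to the cohort average,

    rel_x = log2(count_x / mean_over_samples(count_x)),

and two subtypes are called with fixed cut-offs: skewed TIN (sTIN) when
|rel_skip - rel_incl| > 0.7, overall TIN (oTIN) when |rel_total| > 1.0.
Both comparisons are strict, and a sample may carry both subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("tinstab")

__all__ = [
    "Thresholds", "compute_thresholds", "count_deviations", "relative_amounts",
    "call_subtypes", "TinModel", "TinResults", "paired_tumor_normal",
    "PairedComparison",
]


@dataclass(frozen=True)
class Thresholds:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValidationError(f"lower threshold {self.lower} > upper {self.upper}")


def compute_thresholds(scores: pd.DataFrame, lower_pct: float = 1.0,
                       upper_pct: float = 99.0) -> Thresholds:
    """Percentile thresholds over the flattened score matrix.

    Linear interpolation between order statistics (the common statistical
    default); the thresholds used are always reported so any percentile
    dialect difference is visible downstream.
    """
    values = np.asarray(scores, dtype=float).ravel()
    if values.size == 0:
        raise ValidationError("empty score matrix")
    lower, upper = np.percentile(values, [lower_pct, upper_pct])
    logger.info("thresholds: lower %.4f (pct %g), upper %.4f (pct %g)",
                lower, lower_pct, upper, upper_pct)
    return Thresholds(float(lower), float(upper))


def count_deviations(scores: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Per-sample counts of scores strictly beyond the thresholds.

    Returns a DataFrame indexed by sample with columns n_skip (score <
    lower), n_incl (score > upper) and n_total.
    """
    vals = scores.to_numpy(dtype=float)
    n_skip = (vals < thresholds.lower).sum(axis=0)
    n_incl = (vals > thresholds.upper).sum(axis=0)
    out = pd.DataFrame({"n_skip": n_skip, "n_incl": n_incl},
                       index=scores.columns)
    out["n_total"] = out["n_skip"] + out["n_incl"]
    logger.info("deviations: %d flagged of %d scores (%.3f%%)",
                out["n_total"].sum(), vals.size,
                100 * out["n_total"].sum() / vals.size)
    return out


def relative_amounts(counts: pd.DataFrame, pseudocount: float = 0.0,
                     geometric_mean: bool = False) -> pd.DataFrame:
    """log2 amounts of deviating exon usage relative to the cohort average.

    The reference is the arithmetic mean of the per-sample counts (a
    geometric-mean alternative is available).  A zero count for any sample
    makes the log-ratio undefined; use a pseudocount (e.g. 0.5) in that
    case.
    """
    out = counts.copy()
    rel = {}
    for col, name in (("n_skip", "rel_skip"), ("n_incl", "rel_incl"),
                      ("n_total", "rel_total")):
        c = counts[col].to_numpy(dtype=float) + pseudocount
        if (c <= 0).any():
            bad = counts.index[np.flatnonzero(c <= 0)[0]]
            raise ValidationError(
                f"zero {col} for sample {bad!r}; rerun with a pseudocount "
                f"(e.g. --pseudocount 0.5)"
            )
        ref = stats.gmean(c) if geometric_mean else c.mean()
        rel[name] = np.log2(c / ref)
    for name, v in rel.items():
        out[name] = v
    out["skew"] = out["rel_skip"] - out["rel_incl"]
    return out


def call_subtypes(profiles: pd.DataFrame, skew_threshold: float = 0.7,
                  overall_threshold: float = 1.0) -> pd.DataFrame:
    """Flag sTIN (|skew| strictly > 0.7) and oTIN (|rel_total| strictly > 1.0).

    The flags are independent; a sample may carry both subtypes.
    """
    out = profiles.copy()
    out["is_sTIN"] = out["skew"].abs() > skew_threshold
    out["is_oTIN"] = out["rel_total"].abs() > overall_threshold
    logger.info("subtype calls: %d sTIN, %d oTIN, %d both of %d samples",
                int(out["is_sTIN"].sum()), int(out["is_oTIN"].sum()),
                int((out["is_sTIN"] & out["is_oTIN"]).sum()), len(out))
    return out


class TinModel:
    """Per-sample transcriptome-instability profiling of a FIRMA score matrix."""

    def __init__(self, scores: pd.DataFrame):
        if scores.size == 0:
            raise ValidationError("empty score matrix")
        self.scores = scores

    def fit(self, lower_pct: float = 1.0, upper_pct: float = 99.0,
            skew_threshold: float = 0.7, overall_threshold: float = 1.0,
            pseudocount: float = 0.0, geometric_mean: bool = False,
            thresholds: Thresholds | None = None) -> "TinResults":
        """Threshold, count, normalize and call subtypes.

        Pass precomputed ``thresholds`` to score one series against
        another's cut-offs (the cross-use is logged).
        """
        if thresholds is None:
            thresholds = compute_thresholds(self.scores, lower_pct, upper_pct)
        else:
            logger.info("using externally supplied thresholds %s", thresholds)
        counts = count_deviations(self.scores, thresholds)
        profiles = relative_amounts(counts, pseudocount, geometric_mean)
        profiles = call_subtypes(profiles, skew_threshold, overall_threshold)
        return TinResults(profiles=profiles, thresholds=thresholds,
                          skew_threshold=skew_threshold,
                          overall_threshold=overall_threshold)


@dataclass
class TinResults:
    """Deviation counts, relative amounts and subtype calls per sample."""

    profiles: pd.DataFrame
    thresholds: Thresholds
    skew_threshold: float = 0.7
    overall_threshold: float = 1.0

    @property
    def rel_total(self) -> pd.Series:
        return self.profiles["rel_total"]

    @property
    def stin_samples(self) -> pd.Index:
        return self.profiles.index[self.profiles["is_sTIN"]]

    @property
    def otin_samples(self) -> pd.Index:
        return self.profiles.index[self.profiles["is_oTIN"]]

    def summary(self) -> str:
        p = self.profiles
        return "\n".join([
            "TIN profiles",
            f"  samples          : {len(p)}",
            f"  score thresholds : lower {self.thresholds.lower:.4f}, "
            f"upper {self.thresholds.upper:.4f}",
            f"  mean deviating exons/sample: {p['n_total'].mean():.1f} "
            f"(range {p['n_total'].min()} to {p['n_total'].max()})",
            f"  sTIN (|skew| > {self.skew_threshold}) : {int(p['is_sTIN'].sum())}",
            f"  oTIN (|rel_total| > {self.overall_threshold}): {int(p['is_oTIN'].sum())}",
            f"  both subtypes    : {int((p['is_sTIN'] & p['is_oTIN']).sum())}",
        ])

    def plot(self, ax=None):
        """Scatter of relative deviating skipping vs inclusion per sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.profiles
        colors = np.where(p["is_sTIN"] & p["is_oTIN"], "purple",
                          np.where(p["is_sTIN"], "red",
                                   np.where(p["is_oTIN"], "blue", "grey")))
        ax.scatter(p["rel_skip"], p["rel_incl"], c=colors, s=18)
        ax.axline((0, -self.skew_threshold), slope=1, ls="--", lw=0.7, color="red")
        ax.axline((0, self.skew_threshold), slope=1, ls="--", lw=0.7, color="red")
        ax.set_xlabel("relative deviating exon skipping (log2)")
        ax.set_ylabel("relative deviating exon inclusion (log2)")
        return ax


@dataclass
class PairedComparison:
    """Tumor-minus-normal differences in relative deviating exon usage."""

    differences: pd.Series      # indexed by tumor sample
    mean_difference: float
    t_statistic: float
    p_value: float
    note: str = ""

    def summary(self) -> str:
        return "\n".join([
            f"paired tumor-normal comparison ({len(self.differences)} pairs)",
            f"  mean difference (log2): {self.mean_difference:.4f}",
            f"  paired t = {self.t_statistic:.4f}, two-sided p = {self.p_value:.4g}"
            + (f"  [{self.note}]" if self.note else ""),
        ])


def paired_tumor_normal(scores: pd.DataFrame, pairing: Mapping[str, str],
                        lower_pct: float = 1.0, upper_pct: float = 99.0,
                        pseudocount: float = 0.0) -> PairedComparison:
    """Compare deviating exon usage in tumors against their paired normals.

    Scores must have been computed jointly on tumors and normals; relative
    amounts are taken over the joint cohort so each tumor's burden is
    normalized against the background deviation level in normal mucosa.
    """
    tumors = list(pairing.keys())
    normals = list(pairing.values())
    if len(set(normals)) != len(normals):
        raise ValidationError("a normal sample is paired with more than one tumor")
    expected = set(tumors) | set(normals)
    present = set(scores.columns)
    if expected - present:
        raise ValidationError(f"paired sample(s) missing from scores: "
                              f"{sorted(expected - present)[:5]}")
    if present - expected:
        raise ValidationError(f"unpaired sample(s) in score matrix: "
                              f"{sorted(present - expected)[:5]}")
    thresholds = compute_thresholds(scores, lower_pct, upper_pct)
    counts = count_deviations(scores, thresholds)
    rel = relative_amounts(counts, pseudocount)["rel_total"]
    diffs = pd.Series({t: rel[t] - rel[n] for t, n in pairing.items()}, name="diff")
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        note = "no variation between pairs; t statistic undefined"
        logger.warning(note)
        return PairedComparison(diffs, float(diffs.mean()), np.nan, np.nan, note)
    t, p = stats.ttest_rel(rel[tumors].to_numpy(), rel[normals].to_numpy())
    return PairedComparison(diffs, float(diffs.mean()), float(t), float(p))
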
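"""Detection scoring: sensitivity/selectivity at taxon and read level, surveillance score.

Terminology follows the precision/recall family re-expressed for
metabarcoding benchmarks:

* **taxa sensitivity** — of the taxa truly in the community, the percentage
  detected (recall at taxon level);
* **taxa selectivity** — of the taxa a classifier reported, the percentage
  truly present (precision at taxon level);
* **read sensitivity** — of all input reads, the percentage mapped to taxa
  truly present;
* **read selectivity** — of the *mapped* reads, the percentage mapped to
  taxa truly present;
* **surveillance score** — a composite summarizing pathogen-detection
  usefulness: the mean of the two sensitivity x selectivity products
  (taxon-level and read-level), on a 0-100 scale.

A taxon counts as detected when at least one read maps to it.  Names are
canonicalized on both sides before matching, so strain decorations never
break truth/detected comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .community_design import TruthProfile, TIER_ORDER
from .io_profiles import ClassificationProfile, canonicalize_name

__all__ = [
    "DetectionReport",
    "taxa_confusion",
    "detection_report",
    "tier_sensitivity",
    "surveillance_score",
    "relative_change",
    "absolute_error_reduction",
]


@dataclass
class DetectionReport:
    """Confusion-style metrics for one profile scored against truth (percent scale).

    Selectivities are ``None`` (undefined, not zero) when nothing was detected.
    """

    taxa_sensitivity: float
    taxa_selectivity: float | None
    read_sensitivity: float
    read_selectivity: float | None
    surveillance_score: float | None
    tier_sensitivity: dict[str, float]
    false_positivity_rate: float | None

    def as_dict(self) -> dict[str, float | None]:
        d = {
            "taxa_sensitivity": self.taxa_sensitivity,
            "taxa_selectivity": self.taxa_selectivity,
            "read_sensitivity": self.read_sensitivity,
            "read_selectivity": self.read_selectivity,
            "surveillance_score": self.surveillance_score,
            "false_positivity_rate": self.false_positivity_rate,
        }
        for tier, v in self.tier_sensitivity.items():
            d[f"{tier}_taxa_sensitivity"] = v
        return d


def _canonical_counts(profile: ClassificationProfile) -> dict[str, int]:
    out: dict[str, int] = {}
    for t, c in profile.counts.items():
        if c >= 1:
            key = canonicalize_name(t)
            out[key] = out.get(key, 0) + c
    return out


def _canonical_truth(truth: TruthProfile) -> dict[str, str]:
    """canonical name -> tier"""
    return {canonicalize_name(t.taxon_name): t.tier for t in truth.taxa}


def taxa_confusion(
    profile: ClassificationProfile, truth: TruthProfile
) -> tuple[set[str], set[str], set[str]]:
    """(TP, FP, FN) taxon sets on canonicalized names.

    TP = detected and truly present; FP = detected only; FN = present but
    undetected.
    """
    detected = set(_canonical_counts(profile))
    true_names = set(_canonical_truth(truth))
    return detected & true_names, detected - true_names, true_names - detected


def surveillance_score(
    taxa_sens: float, taxa_sel: float, read_sens: float, read_sel: float
) -> float:
    """Mean of the taxon-level and read-level sensitivity x selectivity products.

    All inputs and the result are percentages; a perfect classifier scores
    100, and any deficiency on either axis at either level pulls the score
    down multiplicatively.
    """
    return (taxa_sens * taxa_sel + read_sens * read_sel) / 200.0


def detection_report(profile: ClassificationProfile, truth: TruthProfile) -> DetectionReport:
    """Score one classification profile against the ground-truth community."""
    if not truth.taxa:
        raise ValueError("truth profile is empty")
    counts = _canonical_counts(profile)
    tiers = _canonical_truth(truth)
    tp, fp, fn = taxa_confusion(profile, truth)

    n_truth = len(tiers)
    n_detected = len(counts)
    taxa_sens = 100.0 * len(tp) / n_truth
    taxa_sel = 100.0 * len(tp) / n_detected if n_detected else None
    fp_rate = 100.0 * len(fp) / n_detected if n_detected else None

    reads_on_tp = sum(c for t, c in counts.items() if t in tp)
    mapped = sum(counts.values())
    read_sens = 100.0 * reads_on_tp / profile.total_reads if profile.total_reads else 0.0
    read_sel = 100.0 * reads_on_tp / mapped if mapped else None

    score = (
        surveillance_score(taxa_sens, taxa_sel, read_sens, read_sel)
        if taxa_sel is not None and read_sel is not None
        else None
    )
    return DetectionReport(
        taxa_sensitivity=taxa_sens,
        taxa_selectivity=taxa_sel,
        read_sensitivity=read_sens,
        read_selectivity=read_sel,
        surveillance_score=score,
        tier_sensitivity=tier_sensitivity(profile, truth),
        false_positivity_rate=fp_rate,
    )


def tier_sensitivity(profile: ClassificationProfile, truth: TruthProfile) -> dict[str, float]:
    """Percentage of each abundance tier's taxa that were detected."""
    detected = set(_canonical_counts(profile))
    tiers = _canonical_truth(truth)
    out: dict[str, float] = {}
    for tier in TIER_ORDER:
        members = [n for n, t in tiers.items() if t == tier]
        if members:
            out[tier] = 100.0 * sum(n in detected for n in members) / len(members)
    return out


def relative_change(baseline: float, improved: float) -> float:
    """Percent change relative to the baseline: 100 x (improved - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("relative change is undefined for a zero baseline")
    return 100.0 * (improved - baseline) / baseline


def absolute_error_reduction(baseline_pct_error: float, improved_pct_error: float) -> float:
    """Accuracy gain in percentage points: |baseline error| - |improved error|.

    Positive when the improved pipeline's percent error is smaller in
    magnitude, regardless of the sign (over- vs under-estimation) of either.
    """
    return abs(baseline_pct_error) - abs(improved_pct_error)
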
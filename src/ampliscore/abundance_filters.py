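"""Low-read-taxon filters that trade sensitivity for selectivity.

False-positive taxa tend to attract far fewer reads than taxa truly present,
so there is some reads-per-taxon threshold below which a detected taxon is
more likely spurious than real.  Two filters implement this idea:

* **z-score filter** — threshold at ``mu - |z| * sigma`` over the detected
  taxa's read counts (population sigma), removing taxa whose counts sit a
  fraction of a standard deviation below the mean of the distribution.
  Suited to best-hit classifiers whose read counts are roughly unimodal.
* **fraction filter** — threshold at a fixed fraction of the total input
  reads (default 0.4% for deep simulated read sets, 0.004% for shallower,
  more widely distributed real read sets).  More robust on classifiers with
  irregular read distributions.

Both remove a taxon iff ``count < threshold`` (a count exactly at the
threshold is kept) and leave surviving counts untouched.  Removal can only
lower taxa sensitivity; on inputs with the heavy-tailed false-positive
tendency it raises selectivity and the fraction of reads mapped correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .community_design import TruthProfile
from .detection_metrics import detection_report, taxa_confusion
from .io_profiles import ClassificationProfile, canonicalize_name

__all__ = [
    "FilterSpec",
    "FilterDiagnostics",
    "zscore_filter",
    "fraction_filter",
    "apply_filter",
    "filter_diagnostics_with_truth",
    "threshold_sweep",
]

#: default z cutoff: remove taxa more than 0.25 sigma below the mean read count
DEFAULT_Z_CUTOFF = -0.25
#: default total-read fractions: deep simulated sets / shallow real sets
DEFAULT_FRACTION_SIMULATED = 0.004
DEFAULT_FRACTION_REAL = 0.00004


@dataclass(frozen=True)
class FilterSpec:
    """Which filter to run and with what cutoff."""

    kind: str = "zscore"  # "zscore" | "fraction"
    z_cutoff: float = DEFAULT_Z_CUTOFF
    fraction_cutoff: float = DEFAULT_FRACTION_SIMULATED

    def __post_init__(self) -> None:
        if self.kind not in ("zscore", "fraction"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "fraction" and not (0.0 <= self.fraction_cutoff < 1.0):
            raise ValueError("fraction_cutoff must be in [0, 1)")


@dataclass
class FilterDiagnostics:
    """What a filter did, and (when truth is available) what it did to accuracy."""

    threshold_reads: float
    removed_taxa: set[str] = field(default_factory=set)
    kept_taxa: set[str] = field(default_factory=set)
    fp_rate_below_cutoff: float | None = None
    read_correct_pct_before: float | None = None
    read_correct_pct_after: float | None = None


def zscore_filter(
    profile: ClassificationProfile, z_cutoff: float = DEFAULT_Z_CUTOFF
) -> tuple[ClassificationProfile, FilterDiagnostics]:
    """Remove taxa with fewer reads than ``mu - |z_cutoff| * sigma``.

    Sigma is the population standard deviation of the detected taxa's read
    counts — deterministic even on two-taxon profiles.  Single-pass: the
    threshold is computed once on the unfiltered distribution.  With a single
    detected taxon sigma is undefined and the profile is returned unchanged
    with a warning.
    """
    detected = {t: c for t, c in profile.counts.items() if c >= 1}
    if len(detected) < 2:
        warnings.warn("fewer than 2 detected taxa; z-score filter not applied")
        return profile, FilterDiagnostics(
            threshold_reads=float("nan"), removed_taxa=set(), kept_taxa=set(detected)
        )
    counts = np.array(list(detected.values()), dtype=float)
    threshold = float(counts.mean() - abs(z_cutoff) * counts.std())  # population sigma
    return _apply_threshold(profile, detected, threshold)


def fraction_filter(
    profile: ClassificationProfile, fraction_cutoff: float = DEFAULT_FRACTION_SIMULATED
) -> tuple[ClassificationProfile, FilterDiagnostics]:
    """Remove taxa with fewer reads than ``fraction_cutoff x total_reads``."""
    if profile.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    detected = {t: c for t, c in profile.counts.items() if c >= 1}
    threshold = fraction_cutoff * profile.total_reads
    return _apply_threshold(profile, detected, threshold)


def _apply_threshold(
    profile: ClassificationProfile, detected: dict[str, int], threshold: float
) -> tuple[ClassificationProfile, FilterDiagnostics]:
    kept = {t: c for t, c in detected.items() if c >= threshold}
    removed = set(detected) - set(kept)
    filtered = ClassificationProfile(
        sample_id=profile.sample_id,
        pipeline_label=profile.pipeline_label + "+filtered",
        counts=kept,
        total_reads=profile.total_reads,
    )
    diag = FilterDiagnostics(
        threshold_reads=threshold, removed_taxa=removed, kept_taxa=set(kept)
    )
    return filtered, diag


def apply_filter(
    profile: ClassificationProfile, spec: FilterSpec
) -> tuple[ClassificationProfile, FilterDiagnostics]:
    if spec.kind == "zscore":
        return zscore_filter(profile, spec.z_cutoff)
    return fraction_filter(profile, spec.fraction_cutoff)


def _reads_correct_pct(profile: ClassificationProfile, truth: TruthProfile) -> float | None:
    """Percent of mapped reads on taxa truly present (read selectivity)."""
    return detection_report(profile, truth).read_selectivity


def filter_diagnostics_with_truth(
    profile: ClassificationProfile, truth: TruthProfile, spec: FilterSpec
) -> FilterDiagnostics:
    """Run the filter and grade its removals against the known community.

    Adds the false-positive rate among below-threshold taxa and the percent
    of mapped reads on true taxa before vs. after filtering.
    """
    filtered, diag = apply_filter(profile, spec)
    truth_names = {canonicalize_name(t.taxon_name) for t in truth.taxa}
    removed_canon = {canonicalize_name(t) for t in diag.removed_taxa}
    if removed_canon:
        fp_removed = len(removed_canon - truth_names)
        diag.fp_rate_below_cutoff = 100.0 * fp_removed / len(removed_canon)
    diag.read_correct_pct_before = _reads_correct_pct(profile, truth)
    diag.read_correct_pct_after = _reads_correct_pct(filtered, truth)
    return diag


def threshold_sweep(
    profile: ClassificationProfile,
    truth: TruthProfile,
    thresholds: Sequence[float],
) -> list[dict[str, float | None]]:
    """Detection metrics at each candidate reads-per-taxon threshold.

    One row per threshold with taxa sensitivity and selectivity of the
    filtered profile; sensitivity is non-increasing along increasing
    thresholds, which is the basis for choosing a cutoff that buys
    selectivity without giving up more sensitivity than intended.
    """
    if not len(thresholds):
        raise ValueError("threshold grid is empty")
    detected = {t: c for t, c in profile.counts.items() if c >= 1}
    rows = []
    for thr in thresholds:
        filtered, _ = _apply_threshold(profile, detected, float(thr))
        rep = detection_report(filtered, truth)
        rows.append(
            {
                "threshold": float(thr),
                "taxa_sensitivity": rep.taxa_sensitivity,
                "taxa_selectivity": rep.taxa_selectivity,
                "n_detected": float(len(filtered.detected_taxa)),
            }
        )
    return rows
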
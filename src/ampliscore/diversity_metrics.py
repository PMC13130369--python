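"""Alpha/beta diversity, the composite diversity score and replicate precision.

Alpha diversity: observed richness, the bias-corrected Chao1 estimator of
true richness (uses singleton and doubleton taxa), Shannon entropy
``H = -sum(p ln p)`` in natural-log units, and Pielou's evenness
``J = H / ln(S)``.  Beta diversity: Bray–Curtis dissimilarity
``1 - sum(min(p_i, q_i))`` on renormalized profiles.

The **diversity score** condenses a classifier's diversity accuracy into one
number: 100 minus the mean absolute percent error of its richness, Shannon,
evenness and Bray–Curtis estimates against the known truth.  The
**replicate/site precision ratio** assesses reproducibility on replicated
sequencing of the same sample: mean per-replicate diversity divided by the
mean per-site diversity (for richness, the site value is the union of taxa
across the site's replicates); the closer to 100%, the more consistent the
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_profiles import ClassificationProfile, RelAbundanceProfile

__all__ = [
    "AlphaReport",
    "DiversityScoreInput",
    "shannon",
    "pielou",
    "chao1",
    "alpha_report",
    "bray_curtis",
    "diversity_score",
    "percent_error",
    "replicate_site_ratio",
    "richness_precision",
]


@dataclass
class AlphaReport:
    """Alpha-diversity summary of one profile."""

    richness: int
    chao1: float
    shannon: float
    pielou: float | None  # undefined for a single-taxon community

    def as_dict(self) -> dict[str, float | None]:
        return {
            "richness": self.richness,
            "chao1": self.chao1,
            "shannon": self.shannon,
            "pielou": self.pielou,
        }


@dataclass
class DiversityScoreInput:
    """Signed percent errors of the four diversity estimates vs. truth."""

    pct_error_richness: float
    pct_error_shannon: float
    pct_error_evenness: float
    pct_error_braycurtis: float


def _as_array(abundances: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    if isinstance(abundances, Mapping):
        vals = np.asarray(list(abundances.values()), dtype=float)
    else:
        vals = np.asarray(abundances, dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    return vals


def shannon(abundances: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy, natural log, after internal renormalization."""
    vals = _as_array(abundances)
    if vals.sum() <= 0:
        raise ValueError("cannot compute entropy of an all-zero abundance vector")
    return float(stats.entropy(vals[vals > 0]))  # scipy renormalizes; base e


def pielou(abundances: Mapping[str, float] | Sequence[float]) -> float | None:
    """Evenness ``H / ln(S)``; ``None`` when fewer than two taxa are present."""
    vals = _as_array(abundances)
    s = int(np.count_nonzero(vals))
    if s <= 1:
        return None
    return shannon(abundances) / float(np.log(s))


def chao1(counts: Mapping[str, int] | Sequence[int]) -> float:
    """Bias-corrected Chao1 richness estimate: ``S + F1(F1-1) / (2(F2+1))``.

    ``F1``/``F2`` are the numbers of taxa seen in exactly one / two reads;
    the bias-corrected form stays finite when no doubletons exist.
    """
    vals = _as_array(counts).astype(int)
    vals = vals[vals > 0]
    s_obs = len(vals)
    f1 = int(np.sum(vals == 1))
    f2 = int(np.sum(vals == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_report(profile: ClassificationProfile) -> AlphaReport:
    counts = {t: c for t, c in profile.counts.items() if c >= 1}
    if not counts:
        raise ValueError("profile has no detected taxa")
    return AlphaReport(
        richness=len(counts),
        chao1=chao1(counts),
        shannon=shannon(counts),
        pielou=pielou(counts),
    )


def bray_curtis(a: RelAbundanceProfile, b: RelAbundanceProfile) -> float:
    """Bray–Curtis dissimilarity ``1 - sum(min(p, q))`` over the taxon union.

    Both profiles are renormalized to sum 1, so identical compositions score
    0 and disjoint ones score 1 regardless of unmapped-read mass.
    """
    if not a.abundances or not b.abundances:
        raise ValueError("cannot compare an empty profile")
    taxa = sorted(set(a.abundances) | set(b.abundances))
    p = np.array([a.abundances.get(t, 0.0) for t in taxa])
    q = np.array([b.abundances.get(t, 0.0) for t in taxa])
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("cannot compare an all-zero profile")
    p, q = p / p.sum(), q / q.sum()
    return float(1.0 - np.minimum(p, q).sum())


def percent_error(measured: float, true: float) -> float:
    """Signed percent error ``100 x (measured - true) / true``."""
    if true == 0:
        raise ValueError("percent error undefined for a zero true value")
    return 100.0 * (measured - true) / true


def diversity_score(inp: DiversityScoreInput) -> float:
    """100 minus the mean absolute percent error of the four diversity estimates.

    Sign-insensitive by construction: over- and under-estimation are
    penalized alike.  Can go negative for wildly inaccurate estimates.
    """
    errs = (
        inp.pct_error_richness,
        inp.pct_error_shannon,
        inp.pct_error_evenness,
        inp.pct_error_braycurtis,
    )
    return 100.0 - float(np.mean([abs(e) for e in errs]))


def replicate_site_ratio(
    replicate_values: Sequence[float], site_values: Sequence[float]
) -> float:
    """Precision ratio: 100 x mean(per-replicate values) / mean(per-site values)."""
    if not replicate_values or not site_values:
        raise ValueError("need at least one replicate and one site value")
    site_mean = float(np.mean(site_values))
    if site_mean == 0:
        raise ValueError("site mean is zero; ratio undefined")
    return 100.0 * float(np.mean(replicate_values)) / site_mean


def richness_precision(
    sites: Mapping[str, Sequence[ClassificationProfile]],
) -> tuple[float, float, float]:
    """(mean replicate richness, mean site union richness, precision ratio).

    Each site's replicate values are its profiles' observed richness; the
    site value is the size of the union of detected taxa across replicates.
    """
    rep_vals: list[float] = []
    site_vals: list[float] = []
    for site, profiles in sites.items():
        if not profiles:
            raise ValueError(f"site {site!r} has no replicates")
        rep_vals.extend(len(p.detected_taxa) for p in profiles)
        union: set[str] = set()
        for p in profiles:
            union |= p.detected_taxa
        site_vals.append(len(union))
    ratio = replicate_site_ratio(rep_vals, site_vals)
    return float(np.mean(rep_vals)), float(np.mean(site_vals)), ratio
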
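"""Stochastic classifier-output simulator.

Real taxonomic classifiers mis-assign a fraction of reads, leave some
unmapped, and occasionally miss a community member entirely.  A robust
empirical regularity is that false-positive taxa attract far fewer reads
than taxa actually present: mis-assignments scatter thinly over many
spurious names while true taxa accumulate reads in proportion to their
abundance.  This module generates :class:`ClassificationProfile` objects
from a ground-truth community under a simple confusion channel with exactly
that structure, so detection metrics and low-read-taxon filters can be
exercised end to end without running any external pipeline.

The channel, per read: with probability ``p_unmapped`` the read maps
nowhere; with probability ``p_correct`` it maps to its taxon of origin;
otherwise it is assigned to one of ``fp_pool_size`` false-positive names
drawn from a Zipf-like (power-law) allocation with shape
``fp_concentration`` — the heavy tail concentrates most mis-assigned reads
on a few spurious taxa while the rest receive only a handful each.
Additionally each true taxon drops out entirely with probability
``p_dropout`` (its reads are rerouted through the error channel), modelling
reference-database gaps.  One seeded generator drives every sampling stage,
so output is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community_design import TruthProfile
from .io_profiles import ClassificationProfile

__all__ = ["ConfusionParams", "simulate_classification", "double_reads", "FP_NAME_FORMAT"]

#: false positives live in a reserved namespace disjoint from any real species name
FP_NAME_FORMAT = "fp_{:04d}"


@dataclass(frozen=True)
class ConfusionParams:
    """Parameters of the read-confusion channel.

    Defaults describe a moderately noisy classifier in the regime where
    roughly a fifth of reads are mis-assigned or lost and mis-assignments
    follow a heavy-tailed allocation over spurious taxa.
    """

    p_correct: float = 0.8
    p_dropout: float = 0.0
    fp_pool_size: int = 50
    fp_concentration: float = 1.5
    p_unmapped: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_correct", "p_dropout", "p_unmapped"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_correct + self.p_unmapped > 1.0 + 1e-12:
            raise ValueError("p_correct + p_unmapped must not exceed 1")
        if self.fp_pool_size < 0:
            raise ValueError("fp_pool_size must be >= 0")
        if self.fp_concentration <= 0:
            raise ValueError("fp_concentration must be positive")


def _zipf_probs(pool: int, shape: float) -> np.ndarray:
    ranks = np.arange(1, pool + 1, dtype=float)
    w = ranks**-shape
    return w / w.sum()


def simulate_classification(
    truth: TruthProfile,
    n_reads: int,
    params: ConfusionParams,
    *,
    pipeline_label: str = "simulated",
) -> ClassificationProfile:
    """Push ``n_reads`` through the confusion channel and tally the output profile.

    Reads are first allotted to true taxa at exactly the truth proportions
    (largest-remainder rounding), mirroring how simulated mock-community read
    sets are constructed; each taxon's reads then split stochastically into
    correct / unmapped / mis-assigned portions, with dropout taxa
    contributing their whole allotment to the error channel so they can
    never be detected.
    Mis-assigned reads are spread over the false-positive pool by a
    multinomial on Zipf weights.  Mapped + unmapped reads equal ``n_reads``
    exactly.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not truth.taxa:
        raise ValueError("truth profile is empty")
    rng = np.random.default_rng(params.seed)

    names = [t.taxon_name for t in truth.taxa]
    probs = np.array([t.abundance_pct for t in truth.taxa], dtype=float)
    probs = probs / probs.sum()
    # the read-set composition is fixed by design (reads are *constructed* at
    # the target proportions, like a simulated mock community), so allot reads
    # deterministically by largest remainder; only classification is random
    exact = n_reads * probs
    per_taxon = np.floor(exact).astype(int)
    short = n_reads - per_taxon.sum()
    if short:
        order = np.argsort(-(exact - per_taxon), kind="stable")
        per_taxon[order[:short]] += 1

    dropped = rng.random(len(names)) < params.p_dropout

    counts: dict[str, int] = {}
    fp_reads = 0
    unmapped = 0
    p_err = 1.0 - params.p_correct - params.p_unmapped
    for i, name in enumerate(names):
        n_i = int(per_taxon[i])
        if n_i == 0:
            continue
        if dropped[i]:
            # the correct channel is closed: reads are either unmapped or errors
            n_unm = rng.binomial(n_i, params.p_unmapped) if params.p_unmapped > 0 else 0
            unmapped += n_unm
            fp_reads += n_i - n_unm
        else:
            split = rng.multinomial(n_i, [params.p_correct, params.p_unmapped, max(p_err, 0.0)])
            if split[0]:
                counts[name] = counts.get(name, 0) + int(split[0])
            unmapped += int(split[1])
            fp_reads += int(split[2])

    if fp_reads:
        if params.fp_pool_size == 0:
            # nowhere to put errors: they fall through as unmapped
            unmapped += fp_reads
        else:
            alloc = rng.multinomial(fp_reads, _zipf_probs(params.fp_pool_size, params.fp_concentration))
            for j, c in enumerate(alloc):
                if c:
                    counts[FP_NAME_FORMAT.format(j + 1)] = int(c)

    return ClassificationProfile(
        sample_id=truth.site_id,
        pipeline_label=pipeline_label,
        counts=counts,
        total_reads=n_reads,
    )


def double_reads(profile: ClassificationProfile) -> ClassificationProfile:
    """Profile-level representation of the read-doubling transform.

    Concatenating a read set onto itself doubles every count and the read
    total while leaving all relative abundances unchanged.
    """
    return ClassificationProfile(
        sample_id=profile.sample_id,
        pipeline_label=profile.pipeline_label + "+x2",
        counts={t: 2 * c for t, c in profile.counts.items()},
        total_reads=2 * profile.total_reads,
    )
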
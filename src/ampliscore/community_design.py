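"""Tiered mock-community design and representative-species selection.

The default design mirrors a three-tier mock community used to benchmark
classifiers on complex samples: fifteen species per site, with the five most
abundant as *main* taxa (15% each, drawn from three strain/subspecies
sequence variants at 5% apiece), the next five as *mid* taxa (4.5% each) and
the last five as *rare* taxa (0.5% each), summing to exactly 100%.
Representative species for a site are chosen as the top-k species by mean
relative abundance across pilot sequencing replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io_profiles import ClassificationProfile, RelAbundanceProfile, to_relative

__all__ = [
    "TruthTaxon",
    "TruthProfile",
    "TierSpec",
    "DEFAULT_TIERS",
    "design_default_community",
    "design_community",
    "select_representatives",
    "emit_abundance_config",
    "read_truth_profile",
    "write_truth_profile",
]

TIER_ORDER = ("main", "mid", "rare")


@dataclass(frozen=True)
class TruthTaxon:
    """One ground-truth community member."""

    taxon_name: str
    tier: str
    abundance_pct: float
    n_variants: int = 1

    def __post_init__(self) -> None:
        if self.tier not in TIER_ORDER:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.abundance_pct < 0:
            raise ValueError("abundance_pct must be non-negative")


@dataclass
class TruthProfile:
    """Ground-truth community for one site: unique taxa with tiers and abundances."""

    site_id: str
    taxa: list[TruthTaxon] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.taxon_name for t in self.taxa]
        if len(names) != len(set(names)):
            raise ValueError("duplicate taxon names in truth profile")

    @property
    def taxon_names(self) -> set[str]:
        return {t.taxon_name for t in self.taxa}

    @property
    def abundances(self) -> dict[str, float]:
        return {t.taxon_name: t.abundance_pct for t in self.taxa}

    def tier_of(self, name: str) -> str:
        for t in self.taxa:
            if t.taxon_name == name:
                return t.tier
        raise KeyError(name)

    def to_relative(self) -> RelAbundanceProfile:
        return RelAbundanceProfile(dict(self.abundances))


@dataclass(frozen=True)
class TierSpec:
    """Geometry of one abundance tier: how many species, at what percent, from how many variants."""

    tier: str
    n_species: int
    abundance_pct: float
    n_variants: int


#: five main taxa at 15% (three 5% variants each), five mid at 4.5%, five rare at 0.5%
DEFAULT_TIERS: tuple[TierSpec, ...] = (
    TierSpec("main", 5, 15.0, 3),
    TierSpec("mid", 5, 4.5, 1),
    TierSpec("rare", 5, 0.5, 1),
)


def design_community(
    site_id: str,
    species: Sequence[str],
    tiers: Sequence[TierSpec] = DEFAULT_TIERS,
) -> TruthProfile:
    """Assign ranked species to abundance tiers.

    ``species`` must be ordered by abundance rank (most abundant first) and
    exactly fill the tier geometry; the default geometry takes 15 names.
    """
    species = list(species)
    needed = sum(t.n_species for t in tiers)
    if len(species) != needed:
        raise ValueError(f"expected exactly {needed} species names, got {len(species)}")
    if len(set(species)) != len(species):
        raise ValueError("species names must be unique")
    taxa: list[TruthTaxon] = []
    i = 0
    for spec in tiers:
        for name in species[i : i + spec.n_species]:
            taxa.append(TruthTaxon(name, spec.tier, spec.abundance_pct, spec.n_variants))
        i += spec.n_species
    total = sum(t.abundance_pct for t in taxa)
    if abs(total - 100.0) > 1e-9:
        raise ValueError(f"tier geometry sums to {total}%, not 100%")
    return TruthProfile(site_id, taxa)


def design_default_community(site_id: str, species: Sequence[str]) -> TruthProfile:
    """The default 15-species, three-tier design (5 x 15% / 5 x 4.5% / 5 x 0.5%)."""
    return design_community(site_id, species, DEFAULT_TIERS)


def select_representatives(
    pilot_profiles: Sequence[ClassificationProfile], k: int = 15
) -> list[str]:
    """Rank species by mean relative abundance across pilot replicates; return the top k.

    A species absent from a replicate contributes zero to its mean.  Ties are
    broken lexicographically, so the ranking is independent of input order.
    """
    if not pilot_profiles:
        raise ValueError("at least one pilot profile is required")
    rel = [to_relative(p, "mapped").abundances for p in pilot_profiles]
    species = sorted(set().union(*[set(r) for r in rel]))
    if len(species) < k:
        raise ValueError(
            f"only {len(species)} distinct species across replicates; need {k}"
        )
    means = {s: sum(r.get(s, 0.0) for r in rel) / len(rel) for s in species}
    ranked = sorted(species, key=lambda s: (-means[s], s))
    return ranked[:k]


def emit_abundance_config(profile: TruthProfile, total_reads: int) -> str:
    """Render the per-sequence-variant abundance table used to drive read simulation.

    One row per sequence variant (``<species>|v1`` ... ``|vN``), with the
    species' abundance split evenly across its variants as a fraction of 1;
    the fractions sum to 1 within 1e-9.  The text is compatible with
    community-design inputs of read simulators that take (genome id,
    fraction) pairs.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    lines = []
    for t in profile.taxa:
        frac = t.abundance_pct / 100.0 / t.n_variants
        for v in range(1, t.n_variants + 1):
            lines.append(f"{t.taxon_name}|v{v}\t{frac:.10g}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# truth profile TSV round trip
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "taxon\ttier\tabundance_pct\tn_variants"


def write_truth_profile(profile: TruthProfile, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"#site_id={profile.site_id}\n{_TRUTH_HEADER}\n")
        for t in profile.taxa:
            fh.write(f"{t.taxon_name}\t{t.tier}\t{t.abundance_pct:.10g}\t{t.n_variants}\n")


def read_truth_profile(path: str | Path) -> TruthProfile:
    site_id = Path(path).stem
    taxa: list[TruthTaxon] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#site_id="):
                site_id = line.split("=", 1)[1]
                continue
            if line == _TRUTH_HEADER or line.startswith("#"):
                continue
            name, tier, pct, nv = line.split("\t")
            taxa.append(TruthTaxon(name, tier, float(pct), int(nv)))
    return TruthProfile(site_id, taxa)
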
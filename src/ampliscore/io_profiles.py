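"""Profile I/O: classifier report parsers, writers, subsampling and name canonicalization.

A *classification profile* is the common currency of the toolkit: one
classifier run on one sample, reduced to a mapping from species-level taxon
name to the number of reads assigned to it, plus the total number of reads
that went into the classifier.  Four on-disk formats are supported: the
Kraken 2 six-column report, the Bracken species-level table, BLAST tabular
hit files (outfmt-6 style) and a generic two-column taxon/count TSV.
Unmapped reads are represented implicitly as ``total_reads - sum(counts)``,
never as a pseudo-taxon.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TaxonCount",
    "ClassificationProfile",
    "RelAbundanceProfile",
    "BlastColumns",
    "ProfileParseError",
    "read_kraken_or_bracken_report",
    "read_blast_hits",
    "read_taxon_table",
    "write_taxon_table",
    "write_kraken_report",
    "subsample_reads",
    "to_relative",
    "canonicalize_name",
]


class ProfileParseError(ValueError):
    """Raised when a classifier report cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class TaxonCount:
    """Reads mapped to a single species-level taxon."""

    taxon_name: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative count for {self.taxon_name!r}: {self.count}")
        if not self.taxon_name.strip():
            raise ValueError("empty taxon name")


@dataclass
class ClassificationProfile:
    """One classifier's output for one sample.

    ``counts`` maps taxon name -> mapped reads; ``total_reads`` is the number
    of reads fed to the classifier, so ``total_reads - sum(counts)`` reads are
    unmapped.  Counts stay integral end to end; only relative abundances are
    floating point.
    """

    sample_id: str
    pipeline_label: str
    counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    def __post_init__(self) -> None:
        for name, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {name!r}")
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")
        if self.mapped_reads > self.total_reads:
            raise ValueError(
                f"mapped reads ({self.mapped_reads}) exceed total_reads "
                f"({self.total_reads})"
            )

    @property
    def mapped_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def detected_taxa(self) -> set[str]:
        """Taxa with at least one read mapped."""
        return {t for t, c in self.counts.items() if c >= 1}

    def taxon_counts(self) -> list[TaxonCount]:
        return [TaxonCount(t, c) for t, c in sorted(self.counts.items())]


@dataclass
class RelAbundanceProfile:
    """Taxon -> relative abundance in percent (sums to <= 100 when reads are unmapped)."""

    abundances: dict[str, float]

    def __post_init__(self) -> None:
        for name, a in self.abundances.items():
            if not (0.0 <= a <= 100.0 + 1e-9):
                raise ValueError(f"abundance out of [0, 100] for {name!r}: {a}")
        if sum(self.abundances.values()) > 100.0 + 1e-6:
            raise ValueError("abundances sum to more than 100%")


# ---------------------------------------------------------------------------
# name canonicalization
# ---------------------------------------------------------------------------

# tokens that start strain/subspecies designations appended to a binomial
_STRAIN_MARKERS = {"strain", "str.", "str", "subsp.", "subsp", "var.", "var", "serovar"}
_DESIGNATION_RE = re.compile(r"^(?=.*\d)[\w.\-]+$|^[A-Z0-9\-]{2,}$")


def canonicalize_name(raw: str) -> str:
    """Reduce a taxon string to a canonical lowercase species binomial.

    Whitespace is trimmed and collapsed, the result lowercased, and any
    strain/subspecies tokens following the binomial are stripped: tokens
    beginning ``strain``/``str.``/``subsp.``/``var.``/``serovar`` or a
    designation containing digits or all-capitals (e.g. ``K-12``, ``DSM 1535``).
    A leading ``Candidatus`` is preserved as part of the name.
    """
    words = raw.strip().split()
    if not words:
        raise ValueError("taxon name is empty after stripping")
    prefix: list[str] = []
    if words[0].lower() == "candidatus":
        prefix = [words[0]]
        words = words[1:]
    # binomial = first two words; everything after is inspected for markers
    keep = words[:2]
    for w in words[2:]:
        if w.lower() in _STRAIN_MARKERS or _DESIGNATION_RE.match(w):
            break
        keep.append(w)
    canonical = " ".join(prefix + keep).lower()
    if not canonical:
        raise ValueError("taxon name is empty after stripping")
    return canonical


# ---------------------------------------------------------------------------
# Kraken 2 / Bracken reports
# ---------------------------------------------------------------------------

_BRACKEN_HEADER = (
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_kraken_or_bracken_report(
    path: str | Path,
    level: str = "S",
    *,
    sample_id: str = "",
    pipeline_label: str = "kraken",
) -> ClassificationProfile:
    """Parse a Kraken 2 report or a Bracken species table into a profile.

    Kraken reports are the six-column layout (percent, clade reads, direct
    reads, rank code, taxid, indented name); rows whose rank code equals
    ``level`` are taken, with the clade-read column as the count so that
    strain-level assignments roll up to the species row.  ``total_reads`` is
    the root clade-read count.  Paired reads count as one record (Kraken's
    own convention).  Bracken tables are detected by their header line; the
    ``new_est_reads`` column is the count and ``total_reads`` is its sum.
    """
    sample_id = sample_id or Path(path).stem
    with _open_text(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.rstrip("\n").split("\t")[: len(_BRACKEN_HEADER)] == list(_BRACKEN_HEADER):
            return _parse_bracken(fh, level, sample_id, pipeline_label)
        return _parse_kraken(fh, level, sample_id, pipeline_label)


def _parse_kraken(
    fh: IO[str], level: str, sample_id: str, pipeline_label: str
) -> ClassificationProfile:
    counts: dict[str, int] = {}
    total = 0
    for lineno, line in enumerate(fh, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 6:
            raise ProfileParseError(f"line {lineno}: expected 6 tab-separated columns")
        try:
            clade_reads = int(fields[1])
        except ValueError as exc:
            raise ProfileParseError(f"line {lineno}: bad clade-read count {fields[1]!r}") from exc
        rank = fields[3].strip()
        name = fields[5].strip()
        if rank == "R" and name == "root":
            total = clade_reads
        if rank == level:
            counts[name] = counts.get(name, 0) + clade_reads
    if total == 0:
        total = sum(counts.values())
    return ClassificationProfile(sample_id, pipeline_label, counts, total)


def _parse_bracken(
    fh: IO[str], level: str, sample_id: str, pipeline_label: str
) -> ClassificationProfile:
    next(fh)  # header
    counts: dict[str, int] = {}
    for lineno, line in enumerate(fh, 2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 7:
            raise ProfileParseError(f"line {lineno}: expected 7 tab-separated columns")
        name, rank = fields[0].strip(), fields[2].strip()
        try:
            est = int(fields[5])
        except ValueError as exc:
            raise ProfileParseError(f"line {lineno}: bad read count {fields[5]!r}") from exc
        if rank == level:
            counts[name] = counts.get(name, 0) + est
    return ClassificationProfile(sample_id, pipeline_label, counts, sum(counts.values()))


def write_kraken_report(profile: ClassificationProfile, path: str | Path) -> None:
    """Write a minimal Kraken-2-style report (root row + one species row per taxon)."""
    unmapped = profile.total_reads - profile.mapped_reads
    total = profile.total_reads or 1
    with open(path, "w", newline="\n") as fh:
        if unmapped:
            fh.write(f"{100*unmapped/total:.2f}\t{unmapped}\t{unmapped}\tU\t0\tunclassified\n")
        fh.write(f"{100*profile.mapped_reads/total:.2f}\t{profile.total_reads}\t0\tR\t1\troot\n")
        for t, c in sorted(profile.counts.items()):
            fh.write(f"{100*c/total:.2f}\t{c}\t{c}\tS\t0\t    {t}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlastColumns:
    """Column positions (0-based) in a BLAST tabular file.

    Defaults match ``-outfmt 6`` with the subject id doubling as the taxon
    label; point ``taxon`` at an ``stitle``/``ssciname`` column when present.
    """

    query: int = 0
    taxon: int = 1
    evalue: int = 10
    bitscore: int = 11


def read_blast_hits(
    path: str | Path,
    columns: BlastColumns = BlastColumns(),
    *,
    sample_id: str = "",
    pipeline_label: str = "blast",
) -> ClassificationProfile:
    """Reduce a BLAST tabular hit file to best-hit-per-query taxon counts.

    Each query read contributes exactly one count to the taxon of its best
    hit: highest bitscore, ties broken by lower e-value and then lexicographic
    taxon name — deterministic regardless of database order.  ``total_reads``
    is the number of distinct query ids (queries with no hits still count if
    they appear with an empty hit line, which BLAST does not emit; callers
    may override ``total_reads`` when the query set size is known).
    """
    # per query: (bitscore, -? e-value, name) kept as best so far
    best: dict[str, tuple[float, float, str]] = {}
    needed = max(columns.query, columns.taxon, columns.evalue, columns.bitscore) + 1
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < needed:
                raise ProfileParseError(
                    f"line {lineno}: expected at least {needed} columns, got {len(fields)}"
                )
            try:
                bitscore = float(fields[columns.bitscore])
                evalue = float(fields[columns.evalue])
            except ValueError as exc:
                raise ProfileParseError(f"line {lineno}: unparseable bitscore/e-value") from exc
            q = fields[columns.query]
            name = fields[columns.taxon].strip()
            cand = (bitscore, -evalue, name)
            prev = best.get(q)
            # higher bitscore wins; then lower e-value; then lexicographically
            # smaller name (note: name comparison is inverted vs. the tuple
            # ordering, so compare explicitly)
            if prev is None:
                best[q] = cand
            elif (cand[0], cand[1]) > (prev[0], prev[1]):
                best[q] = cand
            elif (cand[0], cand[1]) == (prev[0], prev[1]) and cand[2] < prev[2]:
                best[q] = cand
    counts: dict[str, int] = {}
    for _, (_, _, name) in best.items():
        counts[name] = counts.get(name, 0) + 1
    return ClassificationProfile(sample_id or Path(path).stem, pipeline_label, counts, len(best))


# ---------------------------------------------------------------------------
# generic taxon/count TSV
# ---------------------------------------------------------------------------

_TOTAL_READS_RE = re.compile(r"^#total_reads=(\d+)\s*$")


def read_taxon_table(
    path: str | Path,
    *,
    sample_id: str = "",
    pipeline_label: str = "tsv",
) -> ClassificationProfile:
    """Read a two-column (taxon, count) TSV; duplicate taxa are summed.

    ``total_reads`` defaults to the count sum unless a ``#total_reads=N``
    header line overrides it.  A non-numeric second field on the first data
    line is treated as a header row and skipped.
    """
    counts: dict[str, int] = {}
    total: int | None = None
    first_data = True
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _TOTAL_READS_RE.match(line)
            if m:
                total = int(m.group(1))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ProfileParseError(f"line {lineno}: expected 2 tab-separated columns")
            try:
                c = int(fields[1])
            except ValueError:
                if first_data:
                    first_data = False
                    continue  # header row
                raise ProfileParseError(f"line {lineno}: bad count {fields[1]!r}") from None
            first_data = False
            if c < 0:
                raise ProfileParseError(f"line {lineno}: negative count {c}")
            name = fields[0].strip()
            counts[name] = counts.get(name, 0) + c
    if total is None:
        total = sum(counts.values())
    return ClassificationProfile(sample_id or Path(path).stem, pipeline_label, counts, total)


def write_taxon_table(profile: ClassificationProfile, path: str | Path) -> None:
    """Write a profile as a taxon/count TSV with a ``#total_reads`` header."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"#total_reads={profile.total_reads}\n")
        for t, c in sorted(profile.counts.items()):
            fh.write(f"{t}\t{c}\n")


# ---------------------------------------------------------------------------
# read subsampling and relative abundance
# ---------------------------------------------------------------------------


def subsample_reads(
    path: str | Path,
    n: int,
    seed: int,
    *,
    fmt: str | None = None,
) -> list[SeqRecord]:
    """Sample ``n`` records uniformly without replacement from FASTQ/FASTA.

    Deterministic for a fixed seed; gzip is handled transparently.  ``fmt``
    is inferred from the filename when not given.
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, fmt))
    if n > len(records):
        raise ValueError(f"requested {n} records but file contains only {len(records)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    return [records[i] for i in sorted(idx)]


def to_relative(
    profile: ClassificationProfile, denominator: str = "mapped"
) -> RelAbundanceProfile:
    """Convert counts to percent relative abundance.

    ``denominator='mapped'`` divides by the mapped-read sum (abundances sum to
    100); ``'total'`` divides by ``total_reads`` (sum < 100 when reads are
    unmapped).  Both conventions appear in classifier outputs, so the choice
    is always explicit.
    """
    if denominator == "mapped":
        denom = profile.mapped_reads
    elif denominator == "total":
        denom = profile.total_reads
    else:
        raise ValueError(f"denominator must be 'mapped' or 'total', got {denominator!r}")
    if denom == 0:
        raise ValueError(f"cannot normalize: {denominator} read count is zero")
    return RelAbundanceProfile({t: 100.0 * c / denom for t, c in profile.counts.items()})
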
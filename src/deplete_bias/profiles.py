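"""Taxonomic profiles, read-count tables and Gram annotations.

The in-memory model mirrors what a shotgun read classifier emits per sample:
either a relative-abundance profile (percent of classified microbial reads,
summing to 100) or a raw count table with dedicated host and unclassified
bins.  Taxon identity is the exact name string — no fuzzy matching, no rank
parsing — so nothing is ever silently merged.

File format: tab-separated ``taxon<TAB>value``, UTF-8, ``#`` comments, no
header required (an optional ``taxon<TAB>abundance`` header line is
tolerated).  The input dialect (percent vs count) is always declared by the
caller, never sniffed: a column of small percentages is indistinguishable
from a column of counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .exceptions import EmptyProfileError, ParseError, ValidationError

#: Literal row name routed to the host bin of a count table.
HOST_TAXON = "Homo sapiens"
#: Literal row name routed to the unclassified bin of a count table.
UNCLASSIFIED = "unclassified"

GRAM_NEGATIVE = "gram_negative"
GRAM_POSITIVE = "gram_positive"
GRAM_UNKNOWN = "unknown"
GRAM_CLASSES = (GRAM_NEGATIVE, GRAM_POSITIVE, GRAM_UNKNOWN)

#: Tolerance on the sum of a normalized profile (percent points).
NORMALIZATION_TOL = 1e-6

_HEADER_ALIASES = {("taxon", "abundance"), ("taxon", "value"), ("taxon", "count")}


@dataclass
class TaxonProfile:
    """A sample's relative-abundance vector over named taxa (percent scale).

    Parameters
    ----------
    sample_id
        Free-text sample label.
    taxa
        Ordered mapping taxon name -> relative abundance in percent (>= 0).
    normalized
        If True, the abundances are asserted to sum to 100 within
        ``NORMALIZATION_TOL``.
    """

    sample_id: str
    taxa: dict[str, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.taxa = dict(self.taxa)
        for name, value in self.taxa.items():
            v = float(value)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"profile {self.sample_id!r}: abundance of {name!r} is {value!r}, "
                    "must be finite and >= 0"
                )
            self.taxa[name] = v
        if self.normalized:
            total = self.total
            if abs(total - 100.0) > NORMALIZATION_TOL:
                raise ValidationError(
                    f"profile {self.sample_id!r} flagged normalized but sums to "
                    f"{total!r} (expected 100 +/- {NORMALIZATION_TOL})"
                )

    @property
    def total(self) -> float:
        return float(sum(self.taxa.values()))

    def abundance(self, taxon: str) -> float:
        """Abundance of ``taxon``; absent taxa report 0."""
        return self.taxa.get(taxon, 0.0)


@dataclass
class CountTable:
    """Raw classified read counts per taxon plus host and unclassified bins."""

    sample_id: str
    taxon_counts: dict[str, int]
    host_reads: int = 0
    unclassified_reads: int = 0

    def __post_init__(self) -> None:
        self.taxon_counts = dict(self.taxon_counts)
        for name, value in self.taxon_counts.items():
            self.taxon_counts[name] = _as_count(value, f"count of {name!r}", self.sample_id)
        self.host_reads = _as_count(self.host_reads, "host_reads", self.sample_id)
        self.unclassified_reads = _as_count(
            self.unclassified_reads, "unclassified_reads", self.sample_id
        )

    @property
    def total(self) -> int:
        """All reads: classified taxa + host + unclassified."""
        return sum(self.taxon_counts.values()) + self.host_reads + self.unclassified_reads


def _as_count(value, what: str, sample_id: str) -> int:
    try:
        i = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"sample {sample_id!r}: {what} is not an integer: {value!r}")
    if i != value or i < 0:
        raise ValidationError(f"sample {sample_id!r}: {what} must be an integer >= 0, got {value!r}")
    return i


class GramAnnotation:
    """Taxon -> Gram class lookup; unannotated taxa resolve to ``unknown``."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for taxon, label in (mapping or {}).items():
            if label not in GRAM_CLASSES:
                raise ValidationError(
                    f"Gram label for {taxon!r} must be one of {GRAM_CLASSES}, got {label!r}"
                )
            self._map[taxon] = label

    def __getitem__(self, taxon: str) -> str:
        return self._map.get(taxon, GRAM_UNKNOWN)

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GramAnnotation":
        """Read a ``taxon<TAB>gram_positive|gram_negative|unknown`` table."""
        mapping: dict[str, str] = {}
        for lineno, fields in _iter_tsv(path):
            if len(fields) != 2:
                raise ParseError(
                    f"expected 2 columns, got {len(fields)}", str(path), lineno
                )
            taxon, label = fields
            if (taxon.lower(), label.lower()) == ("taxon", "gram"):
                continue
            if label not in GRAM_CLASSES:
                raise ParseError(
                    f"Gram label must be one of {GRAM_CLASSES}, got {label!r}",
                    str(path), lineno,
                )
            if taxon in mapping:
                raise ParseError(f"duplicate taxon {taxon!r}", str(path), lineno)
            mapping[taxon] = label
        return cls(mapping)


def _iter_tsv(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_profile(
    path: str | Path,
    dialect: str,
    *,
    sample_id: str | None = None,
    host_name: str = HOST_TAXON,
) -> TaxonProfile | CountTable:
    """Parse a two-column taxon table.

    ``dialect`` is ``"percent"`` (returns an unnormalized :class:`TaxonProfile`)
    or ``"count"`` (returns a :class:`CountTable`; rows named exactly
    ``host_name`` or ``"unclassified"`` are routed to the dedicated bins).
    """
    if dialect not in ("percent", "count"):
        raise ValidationError(f"dialect must be 'percent' or 'count', got {dialect!r}")
    sid = sample_id if sample_id is not None else Path(path).stem
    seen: dict[str, float] = {}
    host = 0
    unclassified = 0
    first = True
    for lineno, fields in _iter_tsv(path):
        if len(fields) < 2:
            raise ParseError(f"expected >= 2 columns, got {len(fields)}", str(path), lineno)
        taxon, raw_value = fields[0], fields[1]
        if first:
            first = False
            if (taxon.strip().lower(), raw_value.strip().lower()) in _HEADER_ALIASES:
                continue
        try:
            value = float(raw_value) if dialect == "percent" else int(raw_value)
        except ValueError:
            raise ParseError(f"non-numeric value {raw_value!r}", str(path), lineno)
        if value < 0:
            raise ParseError(f"negative value {raw_value!r}", str(path), lineno)
        if dialect == "count" and taxon == host_name:
            host += int(value)
            continue
        if dialect == "count" and taxon == UNCLASSIFIED:
            unclassified += int(value)
            continue
        if taxon in seen:
            raise ParseError(f"duplicate taxon {taxon!r}", str(path), lineno)
        seen[taxon] = value
    if dialect == "percent":
        return TaxonProfile(sample_id=sid, taxa=seen, normalized=False)
    return CountTable(
        sample_id=sid,
        taxon_counts={t: int(v) for t, v in seen.items()},
        host_reads=host,
        unclassified_reads=unclassified,
    )


def write_profile(profile: TaxonProfile | CountTable, path: str | Path) -> None:
    """Write a profile or count table as ``taxon<TAB>value`` TSV.

    Percent values are written with full float precision (``repr``) so a
    write/read round trip is lossless; rounding happens only at report time.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# sample: {profile.sample_id}\n")
        if isinstance(profile, CountTable):
            for taxon, count in profile.taxon_counts.items():
                handle.write(f"{taxon}\t{count}\n")
            if profile.host_reads:
                handle.write(f"{HOST_TAXON}\t{profile.host_reads}\n")
            if profile.unclassified_reads:
                handle.write(f"{UNCLASSIFIED}\t{profile.unclassified_reads}\n")
        else:
            for taxon, value in profile.taxa.items():
                handle.write(f"{taxon}\t{value!r}\n")


def to_profile(
    counts: CountTable,
    *,
    exclude_host: bool = True,
    exclude_unclassified: bool = True,
    host_name: str = HOST_TAXON,
) -> TaxonProfile:
    """Convert read counts to a normalized percent profile.

    The denominator is the sum of included reads; by default host and
    unclassified reads are excluded, matching the convention that reported
    microbial relative abundances are percentages of classified microbial
    reads after host-read filtering.
    """
    entries: list[tuple[str, int]] = list(counts.taxon_counts.items())
    if not exclude_host:
        entries.append((host_name, counts.host_reads))
    if not exclude_unclassified:
        entries.append((UNCLASSIFIED, counts.unclassified_reads))
    denom = sum(c for _, c in entries)
    if denom == 0:
        raise EmptyProfileError(
            f"sample {counts.sample_id!r}: no reads left in the denominator"
        )
    taxa = {t: 100.0 * c / denom for t, c in entries}
    return TaxonProfile(sample_id=counts.sample_id, taxa=taxa, normalized=True)


def renormalize(profile: TaxonProfile, drop_taxa: Iterable[str] = ()) -> TaxonProfile:
    """Drop the given taxa and rescale the remainder to sum to 100.

    Order of the surviving taxa is preserved.  Raises
    :class:`EmptyProfileError` if no abundance mass remains.
    """
    drop = set(drop_taxa)
    kept = {t: v for t, v in profile.taxa.items() if t not in drop}
    total = sum(kept.values())
    if total <= 0:
        raise EmptyProfileError(
            f"sample {profile.sample_id!r}: all abundance mass dropped"
        )
    taxa = {t: 100.0 * v / total for t, v in kept.items()}
    return TaxonProfile(sample_id=profile.sample_id, taxa=taxa, normalized=True)
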
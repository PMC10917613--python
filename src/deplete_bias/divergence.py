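"""Profile-comparison statistics.

The central statistic is the taxonomic variation index (TVI): the sum over
the union of taxa of absolute relative-abundance differences between two
normalized percent profiles.  It ranges from 0 (identical profiles) to 200
(disjoint taxon sets), a taxon absent from one profile contributing its full
abundance, and equals 2 x 100 x the Bray-Curtis dissimilarity.

Also here: the lost/gained-taxon comparison report and the read-subsampling
comparability check — draw a fixed number of reads without replacement
(multivariate hypergeometric across taxon/host/unclassified bins) and measure
how far the subsampled profile diverges from the full-depth one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NormalizationError, ValidationError
from .profiles import (
    NORMALIZATION_TOL,
    CountTable,
    TaxonProfile,
    to_profile,
)


def _require_normalized(profile: TaxonProfile) -> None:
    if not profile.normalized or abs(profile.total - 100.0) > NORMALIZATION_TOL:
        raise NormalizationError(
            f"profile {profile.sample_id!r} is not normalized to 100% "
            "(renormalize explicitly before comparing)"
        )


def tvi(a: TaxonProfile, b: TaxonProfile) -> float:
    """Taxonomic variation index between two normalized profiles.

    ``sum_t |p_t(a) - p_t(b)|`` on the percent scale, over the union of taxa
    matched by exact name.  Symmetric; in [0, 200].
    """
    _require_normalized(a)
    _require_normalized(b)
    union = set(a.taxa) | set(b.taxa)
    return float(sum(abs(a.abundance(t) - b.abundance(t)) for t in union))


@dataclass
class ComparisonReport:
    """Treated-vs-untreated profile comparison.

    ``per_taxon_delta`` maps each taxon in the union to
    ``(abundance_untreated, abundance_treated, treated - untreated)``.
    Lost taxa are present above the threshold in the untreated arm and absent
    from the treated arm; gained taxa the reverse.  Both lists are sorted by
    descending abundance, ties broken lexicographically.
    """

    untreated_id: str
    treated_id: str
    tvi: float
    per_taxon_delta: dict[str, tuple[float, float, float]]
    lost_taxa: list[tuple[str, float]]
    gained_taxa: list[tuple[str, float]]
    presence_threshold: float = 0.0

    def to_dict(self) -> dict:
        return {
            "untreated_id": self.untreated_id,
            "treated_id": self.treated_id,
            "tvi": self.tvi,
            "presence_threshold": self.presence_threshold,
            "per_taxon_delta": {
                t: {"untreated": u, "treated": v, "delta": d}
                for t, (u, v, d) in self.per_taxon_delta.items()
            },
            "lost_taxa": [{"taxon": t, "untreated": u} for t, u in self.lost_taxa],
            "gained_taxa": [{"taxon": t, "treated": v} for t, v in self.gained_taxa],
        }


def compare(
    untreated: TaxonProfile,
    treated: TaxonProfile,
    presence_threshold: float = 0.0,
) -> ComparisonReport:
    """Full comparison: TVI, per-taxon deltas, lost and gained taxa."""
    _require_normalized(untreated)
    _require_normalized(treated)
    if presence_threshold < 0:
        raise ValidationError(f"presence_threshold must be >= 0, got {presence_threshold}")
    union = list(dict.fromkeys([*untreated.taxa, *treated.taxa]))
    deltas: dict[str, tuple[float, float, float]] = {}
    lost: list[tuple[str, float]] = []
    gained: list[tuple[str, float]] = []
    for t in union:
        u, v = untreated.abundance(t), treated.abundance(t)
        deltas[t] = (u, v, v - u)
        if v == 0 and u > presence_threshold:
            lost.append((t, u))
        elif u == 0 and v > presence_threshold:
            gained.append((t, v))
    order = lambda item: (-item[1], item[0])
    return ComparisonReport(
        untreated_id=untreated.sample_id,
        treated_id=treated.sample_id,
        tvi=float(sum(abs(d) for _, _, d in deltas.values())),
        per_taxon_delta=deltas,
        lost_taxa=sorted(lost, key=order),
        gained_taxa=sorted(gained, key=order),
        presence_threshold=presence_threshold,
    )


def subsample_counts(
    counts: CountTable,
    depth: int,
    seed: int | np.random.Generator,
) -> CountTable:
    """Draw exactly ``depth`` reads without replacement from a count table.

    The draw is multivariate hypergeometric across all bins (taxa, host,
    unclassified), i.e. a random subset of the existing reads; reproducible
    for a fixed integer seed.
    """
    total = counts.total
    if depth <= 0:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds total reads {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(counts.taxon_counts)
    colors = np.array(
        [counts.taxon_counts[t] for t in names]
        + [counts.host_reads, counts.unclassified_reads],
        dtype=np.int64,
    )
    drawn = rng.multivariate_hypergeometric(colors, depth)
    return CountTable(
        sample_id=f"{counts.sample_id}@{depth}",
        taxon_counts={t: int(c) for t, c in zip(names, drawn[:-2])},
        host_reads=int(drawn[-2]),
        unclassified_reads=int(drawn[-1]),
    )


@dataclass
class SubsampleSummary:
    """Distribution of TVI between the full-depth profile and subsampled replicates."""

    sample_id: str
    depth: int
    n_reps: int
    tvis: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(np.mean(self.tvis))

    @property
    def min(self) -> float:
        return float(np.min(self.tvis))

    @property
    def max(self) -> float:
        return float(np.max(self.tvis))

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "depth": self.depth,
            "n_reps": self.n_reps,
            "mean_tvi": self.mean,
            "min_tvi": self.min,
            "max_tvi": self.max,
        }


def comparability_check(
    counts: CountTable,
    depth: int,
    n_reps: int,
    seed: int | np.random.Generator,
    *,
    exclude_host: bool = True,
    exclude_unclassified: bool = True,
) -> SubsampleSummary:
    """Measure profile stability under fixed-depth read subsampling.

    For each replicate, subsample ``depth`` reads, convert to a percent
    profile and compute the TVI against the full-depth profile.  Reports the
    TVI distribution; no pass/fail verdict is attached — thresholds are the
    caller's business.
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    full = to_profile(
        counts, exclude_host=exclude_host, exclude_unclassified=exclude_unclassified
    )
    values = np.empty(n_reps)
    for i in range(n_reps):
        sub = subsample_counts(counts, depth, rng)
        prof = to_profile(
            sub, exclude_host=exclude_host, exclude_unclassified=exclude_unclassified
        )
        values[i] = tvi(full, prof)
    return SubsampleSummary(
        sample_id=counts.sample_id, depth=depth, n_reps=n_reps, tvis=values
    )
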
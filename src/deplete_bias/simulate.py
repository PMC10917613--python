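"""Synthetic differential-lysis communities and shallow shotgun sequencing.

The generator emulates the wet-lab experiment end to end on an absolute DNA
copy scale (copies/mL): a host cell pool plus a multi-taxon bacterial
community with known Gram labels; saponin treatment at concentration ``c``
(% wt/vol) as class-wise exponential survival ``exp(-k_class * c)`` with
``k_host >> k_gram_neg > k_gram_pos >= 0`` by default (host cells lyse
readily, Gram-negative envelopes are more saponin-susceptible than
Gram-positive ones, and DNase removal of freed host DNA is folded into
``k_host`` since only the net host fraction is observable downstream); and
sequencing as a multinomial draw of ``depth`` labeled reads with
probabilities proportional to surviving copies.

Exponential survival is the minimal monotone one-parameter-per-class model
consistent with a monotone dose-response; nothing deeper is claimed for it.
Sequencing reads are *generated* (multinomial, with replacement), which is
deliberately distinct from :func:`deplete_bias.divergence.subsample_counts`,
which *selects* existing reads (hypergeometric).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .accounting import ReadAccounting, write_accounting_tsv
from .exceptions import ValidationError
from .profiles import (
    GRAM_CLASSES,
    GRAM_NEGATIVE,
    GRAM_POSITIVE,
    CountTable,
    GramAnnotation,
    TaxonProfile,
    to_profile,
    write_profile,
)

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CommunityTaxon:
    name: str
    gram: str
    copies: float

    def __post_init__(self) -> None:
        if self.gram not in GRAM_CLASSES:
            raise ValidationError(f"taxon {self.name!r}: bad Gram label {self.gram!r}")
        if not (self.copies >= 0 and math.isfinite(self.copies)):
            raise ValidationError(f"taxon {self.name!r}: copies must be finite >= 0")


@dataclass
class SyntheticCommunity:
    """Absolute composition of one sample: host DNA copies plus bacterial taxa."""

    host_copies: float
    taxa: list[CommunityTaxon]

    def __post_init__(self) -> None:
        if not (self.host_copies >= 0 and math.isfinite(self.host_copies)):
            raise ValidationError("host_copies must be finite >= 0")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate taxon names in community")

    @property
    def bacterial_copies(self) -> float:
        return float(sum(t.copies for t in self.taxa))

    @property
    def total_copies(self) -> float:
        return self.host_copies + self.bacterial_copies

    def gram_annotation(self) -> GramAnnotation:
        return GramAnnotation({t.name: t.gram for t in self.taxa})

    def expected_profile(self, sample_id: str = "expected") -> TaxonProfile:
        """Noise-free percent profile of the bacterial fraction (the
        composition an infinitely deep, host-excluded sequencing run would
        converge to)."""
        total = self.bacterial_copies
        if total <= 0:
            raise ValidationError("community has no bacterial copies")
        return TaxonProfile(
            sample_id=sample_id,
            taxa={t.name: 100.0 * t.copies / total for t in self.taxa},
            normalized=True,
        )


@dataclass(frozen=True)
class DepletionModel:
    """Class-wise exponential survival rates per % wt/vol saponin.

    ``survival(c) = exp(-k * c)``; survival(0) = 1 and survival is
    non-increasing in c for every class since all rates are >= 0.
    """

    k_host: float
    k_gram_neg: float
    k_gram_pos: float

    def __post_init__(self) -> None:
        for name in ("k_host", "k_gram_neg", "k_gram_pos"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValidationError(f"{name} must be finite >= 0, got {v!r}")

    def rate(self, gram: str) -> float:
        if gram == GRAM_NEGATIVE:
            return self.k_gram_neg
        if gram == GRAM_POSITIVE:
            return self.k_gram_pos
        # taxa of unknown Gram class survive like Gram-positives (conservative)
        return self.k_gram_pos

    def survival(self, gram: str, c: float) -> float:
        return math.exp(-self.rate(gram) * c)


@dataclass(frozen=True)
class SequencingConfig:
    """Shallow shotgun sequencing as a fixed-depth labeled-read draw."""

    depth: int
    misclassification_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.depth, int) and self.depth >= 1):
            raise ValidationError(f"depth must be an integer >= 1, got {self.depth!r}")
        if not 0.0 <= self.misclassification_rate <= 1.0:
            raise ValidationError(
                f"misclassification_rate must be in [0, 1], got {self.misclassification_rate!r}"
            )


def make_community(
    n_taxa: int,
    gram_neg_fraction: float = 0.5,
    host_to_bacteria_ratio: float = 1.13,
    abundance_spread: float = 1.0,
    seed: "SeedLike" = 0,
    mean_copies: float = 1e7,
) -> SyntheticCommunity:
    """Draw a random host + bacterial community.

    Taxon copy numbers are log-normal around ``mean_copies`` with log-scale
    standard deviation ``abundance_spread`` (spread -> 0 gives equal copies);
    Gram labels are independent Bernoulli(``gram_neg_fraction``) draws; host
    copies equal ``host_to_bacteria_ratio`` times the total bacterial copies,
    so the ratio is exact by construction.
    """
    if n_taxa < 1:
        raise ValidationError(f"n_taxa must be >= 1, got {n_taxa}")
    if not 0.0 <= gram_neg_fraction <= 1.0:
        raise ValidationError(f"gram_neg_fraction must be in [0, 1], got {gram_neg_fraction}")
    if not (host_to_bacteria_ratio >= 0 and math.isfinite(host_to_bacteria_ratio)):
        raise ValidationError(f"host_to_bacteria_ratio must be finite >= 0")
    if not (abundance_spread >= 0 and math.isfinite(abundance_spread)):
        raise ValidationError(f"abundance_spread must be finite >= 0")
    rng = _rng(seed)
    # mean of lognormal(mu, sigma) is exp(mu + sigma^2/2); center it on mean_copies
    mu = math.log(mean_copies) - abundance_spread**2 / 2.0
    copies = rng.lognormal(mean=mu, sigma=abundance_spread, size=n_taxa)
    grams = np.where(rng.random(n_taxa) < gram_neg_fraction, GRAM_NEGATIVE, GRAM_POSITIVE)
    width = len(str(n_taxa))
    taxa = [
        CommunityTaxon(name=f"taxon_{i + 1:0{width}d}", gram=str(g), copies=float(x))
        for i, (g, x) in enumerate(zip(grams, copies))
    ]
    host = host_to_bacteria_ratio * float(copies.sum())
    return SyntheticCommunity(host_copies=host, taxa=taxa)


def apply_depletion(
    comm: SyntheticCommunity, c: float, model: DepletionModel
) -> SyntheticCommunity:
    """Scale every class's copies by its survival at concentration ``c``.

    Deterministic: lysis acts on DNA copies before any sequencing noise.
    """
    if c < 0:
        raise ValidationError(f"saponin concentration must be >= 0, got {c}")
    taxa = [
        dataclasses.replace(t, copies=t.copies * model.survival(t.gram, c))
        for t in comm.taxa
    ]
    return SyntheticCommunity(
        host_copies=comm.host_copies * math.exp(-model.k_host * c), taxa=taxa
    )


def sequence(
    comm: SyntheticCommunity,
    cfg: SequencingConfig,
    *,
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, ReadAccounting]:
    """Draw ``depth`` labeled reads multinomially from the community.

    Host DNA is one bin among the taxa; bacterial reads are independently
    relabeled "unclassified" with the configured misclassification rate
    (host reads are identified by alignment downstream and are not subject
    to it).  Counts always sum exactly to ``depth``.  The returned
    accounting sets produced = high-quality = depth and retained = depth
    minus drawn host reads.
    """
    total = comm.total_copies
    if total <= 0:
        raise ValidationError("cannot sequence an empty community (zero total copies)")
    gen = rng if rng is not None else np.random.default_rng(cfg.seed)
    names = [t.name for t in comm.taxa]
    weights = np.array([t.copies for t in comm.taxa] + [comm.host_copies], dtype=float)
    counts = gen.multinomial(cfg.depth, weights / weights.sum())
    taxon_counts = counts[:-1].copy()
    host = int(counts[-1])
    unclassified = 0
    if cfg.misclassification_rate > 0:
        mis = gen.binomial(taxon_counts, cfg.misclassification_rate)
        taxon_counts = taxon_counts - mis
        unclassified = int(mis.sum())
    table = CountTable(
        sample_id=sample_id,
        taxon_counts={n: int(c) for n, c in zip(names, taxon_counts)},
        host_reads=host,
        unclassified_reads=unclassified,
    )
    acc = ReadAccounting(
        sample_id=sample_id,
        reads_produced=cfg.depth,
        high_quality_reads=cfg.depth,
        retained_after_host_filter=cfg.depth - host,
    )
    return table, acc


# --------------------------------------------------------------------------
# scenario configuration and batch runs


#: Concentration grid used by the default scenario: untreated plus the
#: assayed saponin doses, including the 2.5% wt/vol standard protocol dose.
DEFAULT_CONCENTRATIONS = (0.0, 0.0125, 0.05, 0.1, 0.5, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class CommunityConfig:
    n_taxa: int = 40
    gram_neg_fraction: float = 0.5
    host_to_bacteria_ratio: float = 1.13
    abundance_spread: float = 1.0


@dataclass
class ScenarioConfig:
    """Full generative configuration: community, depletion model, grid, depth."""

    community: CommunityConfig = field(default_factory=CommunityConfig)
    model: DepletionModel = field(
        default_factory=lambda: DepletionModel(k_host=2.0, k_gram_neg=0.8, k_gram_pos=0.05)
    )
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    sequencing: SequencingConfig = field(
        default_factory=lambda: SequencingConfig(depth=150_000)
    )
    seeds: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        self.concentrations = tuple(float(c) for c in self.concentrations)
        self.seeds = tuple(int(s) for s in self.seeds)
        if not self.concentrations:
            raise ValidationError("concentrations must be non-empty")
        if any(c < 0 for c in self.concentrations):
            raise ValidationError("concentrations must be >= 0")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValidationError("concentrations must be distinct")
        if not self.seeds:
            raise ValidationError("seeds must be non-empty")

    def to_dict(self) -> dict:
        return {
            "community": dataclasses.asdict(self.community),
            "model": dataclasses.asdict(self.model),
            "concentrations": list(self.concentrations),
            "sequencing": {
                "depth": self.sequencing.depth,
                "misclassification_rate": self.sequencing.misclassification_rate,
            },
            "seeds": list(self.seeds),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        """Build from a JSON-style mapping, reporting every offending key."""
        known = {"community", "model", "concentrations", "sequencing", "seeds"}
        problems = [f"unknown key: {k}" for k in data if k not in known]
        kwargs: dict = {}
        try:
            if "community" in data:
                kwargs["community"] = CommunityConfig(**data["community"])
        except (TypeError, ValidationError) as exc:
            problems.append(f"community: {exc}")
        try:
            if "model" in data:
                kwargs["model"] = DepletionModel(**data["model"])
        except (TypeError, ValidationError) as exc:
            problems.append(f"model: {exc}")
        try:
            if "sequencing" in data:
                kwargs["sequencing"] = SequencingConfig(**data["sequencing"])
        except (TypeError, ValidationError) as exc:
            problems.append(f"sequencing: {exc}")
        if "concentrations" in data:
            kwargs["concentrations"] = tuple(data["concentrations"])
        if "seeds" in data:
            kwargs["seeds"] = tuple(data["seeds"])
        if problems:
            raise ValidationError("invalid scenario config: " + "; ".join(problems))
        try:
            return cls(**kwargs)
        except ValidationError as exc:
            raise ValidationError(f"invalid scenario config: {exc}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


def default_scenario(**overrides) -> ScenarioConfig:
    """The sputum-like default scenario.

    Host DNA at roughly half the sequenced reads before treatment
    (host-to-bacteria copy ratio 1.13 -> host read fraction ~ 0.53), an even
    Gram-negative/Gram-positive split, and rates k_host=2.0, k_neg=0.8,
    k_pos=0.05 per % wt/vol so host depletion is fast, Gram-negative loss
    substantial and Gram-positive loss mild across the assayed grid.
    """
    cfg = ScenarioConfig()
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


@dataclass
class ScenarioDataset:
    """One simulated sequencing run: a (seed, concentration) cell."""

    seed: int
    concentration: float
    counts: CountTable
    accounting: ReadAccounting
    profile: TaxonProfile
    expected_profile: TaxonProfile


@dataclass
class ScenarioRun:
    """All datasets of a scenario plus the ground truth that generated them."""

    config: ScenarioConfig
    communities: dict[int, SyntheticCommunity]
    datasets: list[ScenarioDataset]

    def annotation(self, seed: int | None = None) -> GramAnnotation:
        key = seed if seed is not None else self.config.seeds[0]
        return self.communities[key].gram_annotation()

    def for_seed(self, seed: int) -> list[ScenarioDataset]:
        return [d for d in self.datasets if d.seed == seed]


def simulate_scenario(config: ScenarioConfig) -> ScenarioRun:
    """Run the full generative model over the configured seed x concentration grid.

    Per seed: one community is drawn, then for each concentration the
    depleted community is sequenced with an independent child stream.  The
    seed tree is derived with ``numpy.random.SeedSequence`` so identical
    configs yield identical outputs.
    """
    communities: dict[int, SyntheticCommunity] = {}
    datasets: list[ScenarioDataset] = []
    for seed in config.seeds:
        children = np.random.SeedSequence(seed).spawn(1 + len(config.concentrations))
        comm = make_community(
            n_taxa=config.community.n_taxa,
            gram_neg_fraction=config.community.gram_neg_fraction,
            host_to_bacteria_ratio=config.community.host_to_bacteria_ratio,
            abundance_spread=config.community.abundance_spread,
            seed=np.random.default_rng(children[0]),
        )
        communities[seed] = comm
        for i, c in enumerate(config.concentrations):
            depleted = apply_depletion(comm, c, config.model)
            sample_id = f"sim-s{seed}-c{c:g}"
            counts, acc = sequence(
                depleted,
                config.sequencing,
                sample_id=sample_id,
                rng=np.random.default_rng(children[1 + i]),
            )
            datasets.append(
                ScenarioDataset(
                    seed=seed,
                    concentration=c,
                    counts=counts,
                    accounting=acc,
                    profile=to_profile(counts),
                    expected_profile=depleted.expected_profile(sample_id + "-expected"),
                )
            )
    return ScenarioRun(config=config, communities=communities, datasets=datasets)


def run_scenario(config: ScenarioConfig, out_dir: str | Path) -> ScenarioRun:
    """Simulate and write the scenario to a directory.

    Emits per-dataset count and profile TSVs, a pooled accounting TSV, a
    Gram-annotation TSV per seed, a ``manifest.tsv`` linking each (seed,
    concentration) cell to its files, and ``ground_truth.json`` recording the
    resolved config and per-seed community (the simulator's ground truth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = simulate_scenario(config)
    manifest_rows = ["seed\tconcentration\tcounts\tprofile\tannotation"]
    for ds in run.datasets:
        tag = f"s{ds.seed}_c{ds.concentration:g}"
        counts_path = out / f"counts_{tag}.tsv"
        profile_path = out / f"profile_{tag}.tsv"
        write_profile(ds.counts, counts_path)
        write_profile(ds.profile, profile_path)
        manifest_rows.append(
            f"{ds.seed}\t{ds.concentration:g}\t{counts_path.name}"
            f"\t{profile_path.name}\tannotation_s{ds.seed}.tsv"
        )
    for seed, comm in run.communities.items():
        with open(out / f"annotation_s{seed}.tsv", "w", encoding="utf-8") as handle:
            for taxon, label in comm.gram_annotation().items():
                handle.write(f"{taxon}\t{label}\n")
    write_accounting_tsv([ds.accounting for ds in run.datasets], out / "accounting.tsv")
    (out / "manifest.tsv").write_text("\n".join(manifest_rows) + "\n", encoding="utf-8")
    truth = {
        "config": config.to_dict(),
        "communities": {
            str(seed): {
                "host_copies": comm.host_copies,
                "taxa": [dataclasses.asdict(t) for t in comm.taxa],
            }
            for seed, comm in run.communities.items()
        },
    }
    with open(out / "ground_truth.json", "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
        handle.write("\n")
    return run
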
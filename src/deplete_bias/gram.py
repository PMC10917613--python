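"""Gram-stratified aggregation and saponin dose-response summaries.

Saponin lyses host cells but also attacks bacterial envelopes, and it does so
differentially: Gram-negative cells (thin wall plus outer membrane) lyse more
readily than Gram-positive ones (thick wall).  Aggregating a taxonomic
profile by Gram class therefore exposes the depletion bias directly — as the
saponin concentration rises, the Gram-negative share of the recovered
profile falls.

Two summaries are provided: per-concentration Gram fractions with simple
monotonicity statistics (Spearman rank correlation and a least-squares slope
of Gram-negative percent versus concentration), and a per-taxon log-ratio
regression that estimates survival-rate *contrasts* under an exponential
survival model.  Relative abundances are compositional: only differences of
per-taxon decay rates are identifiable, never absolute rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .profiles import (
    GRAM_NEGATIVE,
    GRAM_POSITIVE,
    GramAnnotation,
    TaxonProfile,
)


@dataclass
class GramSummary:
    """Percent of a profile attributable to each Gram class.

    Unannotated taxa accumulate in ``unknown_pct`` — they are never silently
    dropped or prorated.  ``empty`` flags an all-zero input profile.
    """

    sample_id: str
    gram_negative_pct: float
    gram_positive_pct: float
    unknown_pct: float
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gram_negative_pct": self.gram_negative_pct,
            "gram_positive_pct": self.gram_positive_pct,
            "unknown_pct": self.unknown_pct,
            "empty": self.empty,
        }


def gram_fractions(profile: TaxonProfile, ann: GramAnnotation) -> GramSummary:
    """Sum a profile's abundances by Gram class.

    Conserves total abundance: the three outputs sum to the input profile's
    sum.  An empty profile yields all zeros with ``empty=True`` and a warning.
    """
    neg = pos = unk = 0.0
    for taxon, abundance in profile.taxa.items():
        label = ann[taxon]
        if label == GRAM_NEGATIVE:
            neg += abundance
        elif label == GRAM_POSITIVE:
            pos += abundance
        else:
            unk += abundance
    empty = profile.total == 0
    if empty:
        warnings.warn(f"profile {profile.sample_id!r} is empty; Gram fractions are all zero")
    return GramSummary(
        sample_id=profile.sample_id,
        gram_negative_pct=neg,
        gram_positive_pct=pos,
        unknown_pct=unk,
        empty=empty,
    )


class DoseResponseSeries:
    """Profiles observed along a saponin concentration grid.

    Points are (concentration in % wt/vol, profile), stored sorted by
    concentration; concentration 0 denotes the untreated sample.
    Concentrations must be distinct and >= 0.
    """

    def __init__(self, points: Sequence[tuple[float, TaxonProfile]]):
        pts = sorted(((float(c), p) for c, p in points), key=lambda x: x[0])
        concs = [c for c, _ in pts]
        if any(c < 0 for c in concs):
            raise ValidationError("concentrations must be >= 0")
        if len(set(concs)) != len(concs):
            dupes = sorted({c for c in concs if concs.count(c) > 1})
            raise ValidationError(f"duplicate concentrations: {dupes}")
        self.points: list[tuple[float, TaxonProfile]] = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def concentrations(self) -> list[float]:
        return [c for c, _ in self.points]


@dataclass
class DoseResponseResult:
    """Per-concentration Gram fractions plus monotonicity statistics.

    ``slope`` is the ordinary-least-squares slope of Gram-negative percent
    versus concentration (percent points per % wt/vol, untreated included at
    c=0); ``spearman_rho`` the rank correlation between concentration and the
    Gram-negative percent.  With constant input the correlation is undefined
    and flagged rather than reported as a number.  With few points both are
    descriptive — no p-values are attached.
    """

    table: pd.DataFrame
    slope: float
    spearman_rho: float | None

    @property
    def correlation_defined(self) -> bool:
        return self.spearman_rho is not None

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "slope": self.slope,
            "spearman_rho": self.spearman_rho,
        }


def dose_response(series: DoseResponseSeries, ann: GramAnnotation) -> DoseResponseResult:
    """Summarize Gram fractions along a concentration grid."""
    if len(series) < 2:
        raise ValidationError("dose_response needs at least 2 concentrations")
    rows = []
    for c, profile in series.points:
        summary = gram_fractions(profile, ann)
        rows.append(
            {
                "concentration": c,
                "sample_id": summary.sample_id,
                "gram_negative_pct": summary.gram_negative_pct,
                "gram_positive_pct": summary.gram_positive_pct,
                "unknown_pct": summary.unknown_pct,
            }
        )
    table = pd.DataFrame(rows)
    x = table["concentration"].to_numpy(dtype=float)
    y = table["gram_negative_pct"].to_numpy(dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        rho = None
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    return DoseResponseResult(table=table, slope=slope, spearman_rho=rho)


@dataclass
class SurvivalContrast:
    """Estimated log-survival-rate differences versus a reference taxon.

    Under the exponential survival model (copies of taxon t scaled by
    ``exp(-k_t c)`` at concentration c), the log abundance ratio against the
    reference is linear in c:

        log(p_t(c) / p_ref(c)) = alpha_t + beta_t * c,  beta_t = k_ref - k_t.

    Only such contrasts are identifiable from relative abundances; absolute
    rates are not (compositional closure cancels in the ratio, so the
    estimate is invariant to renormalization of each profile).
    """

    ref_taxon: str
    beta: dict[str, float]
    alpha: dict[str, float] = field(repr=False, default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    note: str = (
        "compositional data: beta_t estimates k_ref - k_t; "
        "only survival-rate contrasts are identifiable, never absolute rates"
    )

    def to_dict(self) -> dict:
        return {
            "ref_taxon": self.ref_taxon,
            "beta": self.beta,
            "dropped": self.dropped,
            "note": self.note,
        }


def survival_contrast(series: DoseResponseSeries, ref_taxon: str) -> SurvivalContrast:
    """Fit per-taxon log-ratio slopes against a reference taxon by OLS.

    Estimation is restricted to taxa with positive abundance at every
    concentration; taxa hitting zero anywhere are dropped with a warning.
    The reference must be present everywhere.
    """
    if len(series) < 2:
        raise ValidationError("survival_contrast needs at least 2 concentrations")
    concs = np.array(series.concentrations, dtype=float)
    profiles = [p for _, p in series.points]
    ref = np.array([p.abundance(ref_taxon) for p in profiles])
    if np.any(ref <= 0):
        missing = [f"{c:g}" for c, r in zip(concs, ref) if r <= 0]
        raise ValidationError(
            f"reference taxon {ref_taxon!r} absent at concentration(s) {', '.join(missing)}"
        )
    candidates = list(dict.fromkeys(t for p in profiles for t in p.taxa if t != ref_taxon))
    beta: dict[str, float] = {}
    alpha: dict[str, float] = {}
    dropped: list[str] = []
    log_ref = np.log(ref)
    for taxon in candidates:
        y = np.array([p.abundance(taxon) for p in profiles])
        if np.any(y <= 0):
            dropped.append(taxon)
            continue
        logratio = np.log(y) - log_ref
        b, a = np.polyfit(concs, logratio, 1)
        beta[taxon] = float(b)
        alpha[taxon] = float(a)
    if dropped:
        warnings.warn(
            f"{len(dropped)} taxa dropped from survival_contrast "
            "(zero abundance at some concentration)"
        )
    return SurvivalContrast(ref_taxon=ref_taxon, beta=beta, alpha=alpha, dropped=dropped)


def gram_rate_contrast(
    series: DoseResponseSeries, ann: GramAnnotation
) -> tuple[float, int]:
    """Estimate the Gram-negative minus Gram-positive survival-rate contrast.

    Picks as reference the Gram-positive taxon with the largest minimum
    abundance across the grid (the most reliably observed one), fits
    :func:`survival_contrast`, and returns ``(median over Gram-negative taxa
    of -beta_t, number of taxa used)`` — an estimate of ``k_neg - k_pos``.
    """
    profiles = [p for _, p in series.points]
    eligible: dict[str, float] = {}
    for taxon in profiles[0].taxa:
        if ann[taxon] != GRAM_POSITIVE:
            continue
        values = [p.abundance(taxon) for p in profiles]
        if min(values) > 0:
            eligible[taxon] = min(values)
    if not eligible:
        raise ValidationError("no Gram-positive taxon present at all concentrations")
    ref = max(eligible, key=lambda t: (eligible[t], t))
    contrast = survival_contrast(series, ref)
    negs = [-b for t, b in contrast.beta.items() if ann[t] == GRAM_NEGATIVE]
    if not negs:
        raise ValidationError("no Gram-negative taxon present at all concentrations")
    return float(np.median(negs)), len(negs)


def gram_shift(untreated: GramSummary, treated: GramSummary) -> dict[str, float]:
    """Treated-minus-untreated change in each Gram class, percent points."""
    return {
        "gram_negative_pct": treated.gram_negative_pct - untreated.gram_negative_pct,
        "gram_positive_pct": treated.gram_positive_pct - untreated.gram_positive_pct,
        "unknown_pct": treated.unknown_pct - untreated.unknown_pct,
    }
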
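"""Gram-stratified aggregation, dose-response and survival contrasts."""

import math

import numpy as np
import pytest

from deplete_bias import (
    DoseResponseSeries,
    GramAnnotation,
    TaxonProfile,
    ValidationError,
    dose_response,
    gram_fractions,
    gram_rate_contrast,
    survival_contrast,
)
from deplete_bias.gram import gram_shift


def prof(sample_id="p", normalized=True, **taxa):
    return TaxonProfile(sample_id, dict(taxa), normalized=normalized)


ANN = GramAnnotation({"A": "gram_negative", "B": "gram_positive"})


class TestGramFractions:
    def test_single_negative_taxon(self):
        out = gram_fractions(prof(A=100.0), ANN)
        assert (out.gram_negative_pct, out.gram_positive_pct, out.unknown_pct) == (100.0, 0.0, 0.0)

    def test_even_split(self):
        out = gram_fractions(prof(A=50.0, B=50.0), ANN)
        assert (out.gram_negative_pct, out.gram_positive_pct) == (50.0, 50.0)

    def test_unannotated_taxa_go_to_unknown_bucket(self):
        out = gram_fractions(prof(A=70.0, B=20.0, C=10.0), ANN)
        assert (out.gram_negative_pct, out.gram_positive_pct, out.unknown_pct) == (
            70.0, 20.0, 10.0,
        )

    def test_conserves_total_abundance(self):
        p = prof(A=12.5, B=37.5, C=25.0, D=25.0)
        out = gram_fractions(p, ANN)
        total = out.gram_negative_pct + out.gram_positive_pct + out.unknown_pct
        assert math.isclose(total, p.total, abs_tol=1e-9)

    def test_empty_profile_flags_and_warns(self):
        empty = TaxonProfile("void", {})
        with pytest.warns(UserWarning):
            out = gram_fractions(empty, ANN)
        assert out.empty and out.gram_negative_pct == 0.0

    def test_gram_shift(self):
        u = gram_fractions(prof(A=80.0, B=20.0), ANN)
        t = gram_fractions(prof(A=30.0, B=70.0), ANN)
        shift = gram_shift(u, t)
        assert shift["gram_negative_pct"] == pytest.approx(-50.0)
        assert shift["gram_positive_pct"] == pytest.approx(50.0)


class TestDoseResponseSeries:
    def test_points_sorted_by_concentration(self):
        series = DoseResponseSeries([(2.0, prof(A=100.0)), (0.0, prof(A=100.0))])
        assert series.concentrations == [0.0, 2.0]

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            DoseResponseSeries([(1.0, prof(A=100.0)), (1.0, prof(A=100.0))])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            DoseResponseSeries([(-0.1, prof(A=100.0))])


class TestDoseResponse:
    def test_equal_profiles_flat_slope_undefined_correlation(self):
        series = DoseResponseSeries(
            [(0.0, prof(A=60.0, B=40.0)), (1.0, prof(A=60.0, B=40.0))]
        )
        result = dose_response(series, ANN)
        assert result.slope == pytest.approx(0.0, abs=1e-12)
        assert not result.correlation_defined

    def test_collinear_points_exact_least_squares(self):
        series = DoseResponseSeries(
            [
                (0.0, prof(A=80.0, B=20.0)),
                (1.0, prof(A=60.0, B=40.0)),
                (2.0, prof(A=40.0, B=60.0)),
            ]
        )
        result = dose_response(series, ANN)
        assert result.slope == pytest.approx(-20.0)
        assert result.spearman_rho == pytest.approx(-1.0)

    def test_needs_two_points(self):
        with pytest.raises(ValidationError):
            dose_response(DoseResponseSeries([(0.0, prof(A=100.0))]), ANN)


def exponential_series(k, base, concentrations, sample="sim"):
    """Noise-free relative abundances under per-taxon exponential survival."""
    points = []
    for c in concentrations:
        masses = {t: base[t] * math.exp(-k[t] * c) for t in base}
        total = sum(masses.values())
        points.append(
            (c, TaxonProfile(f"{sample}-{c:g}", {t: 100 * m / total for t, m in masses.items()},
                             normalized=True))
        )
    return DoseResponseSeries(points)


class TestSurvivalContrast:
    def test_identical_profiles_give_zero_slopes(self):
        series = DoseResponseSeries(
            [(c, prof(f"s{c:g}", A=70.0, B=30.0)) for c in (0.0, 1.0, 2.0)]
        )
        out = survival_contrast(series, "B")
        assert out.beta["A"] == pytest.approx(0.0, abs=1e-12)

    def test_two_taxon_closed_form(self):
        # k_A - k_B = 1.0 per % wt/vol -> beta_A (ref B) = -1.0 exactly
        series = exponential_series(
            {"A": 1.2, "B": 0.2}, {"A": 30.0, "B": 70.0}, (0.0, 1.0, 2.0)
        )
        out = survival_contrast(series, "B")
        assert out.beta["A"] == pytest.approx(-1.0, abs=1e-12)

    def test_invariant_to_profile_rescaling(self):
        k = {"A": 0.9, "B": 0.1, "C": 0.4}
        base = {"A": 10.0, "B": 60.0, "C": 30.0}
        concs = (0.0, 0.5, 1.0, 2.0)
        series = exponential_series(k, base, concs)
        rescaled = DoseResponseSeries(
            [
                (c, TaxonProfile(p.sample_id, {t: v * (7.3 + i) for t, v in p.taxa.items()}))
                for i, (c, p) in enumerate(series.points)
            ]
        )
        a = survival_contrast(series, "B")
        b = survival_contrast(rescaled, "B")
        for taxon in a.beta:
            assert a.beta[taxon] == pytest.approx(b.beta[taxon], abs=1e-9)

    def test_missing_reference_is_an_error(self):
        series = DoseResponseSeries(
            [(0.0, prof(A=100.0)), (1.0, prof(A=50.0, B=50.0))]
        )
        with pytest.raises(ValidationError, match="reference"):
            survival_contrast(series, "B")

    def test_taxon_with_zero_dropped_with_warning(self):
        series = DoseResponseSeries(
            [(0.0, prof(A=50.0, B=25.0, C=25.0)), (1.0, prof(A=60.0, B=40.0))]
        )
        with pytest.warns(UserWarning):
            out = survival_contrast(series, "B")
        assert out.dropped == ["C"]
        assert "C" not in out.beta


class TestGramRateContrast:
    def test_recovers_class_contrast_exactly_on_noise_free_series(self):
        k = {"n1": 0.8, "n2": 0.8, "p1": 0.05, "p2": 0.05}
        base = {"n1": 30.0, "n2": 20.0, "p1": 40.0, "p2": 10.0}
        ann = GramAnnotation(
            {"n1": "gram_negative", "n2": "gram_negative",
             "p1": "gram_positive", "p2": "gram_positive"}
        )
        series = exponential_series(k, base, (0.0, 0.5, 1.0, 1.5, 2.0))
        estimate, n_used = gram_rate_contrast(series, ann)
        assert estimate == pytest.approx(0.75, abs=1e-9)
        assert n_used == 2

    def test_requires_both_classes(self):
        ann = GramAnnotation({"A": "gram_negative", "B": "gram_negative"})
        series = DoseResponseSeries(
            [(0.0, prof(A=50.0, B=50.0)), (1.0, prof(A=50.0, B=50.0))]
        )
        with pytest.raises(ValidationError):
            gram_rate_contrast(series, ann)
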
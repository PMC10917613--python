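"""Synthetic community generator, depletion model and sequencing draw."""

import filecmp
import math

import numpy as np
import pytest

from deplete_bias import (
    DepletionModel,
    ScenarioConfig,
    SequencingConfig,
    SyntheticCommunity,
    ValidationError,
    apply_depletion,
    default_scenario,
    make_community,
    percent_host_filtered,
    run_scenario,
    sequence,
    simulate_scenario,
)
from deplete_bias.simulate import CommunityTaxon


class TestMakeCommunity:
    def test_single_taxon_host_free(self):
        comm = make_community(n_taxa=1, host_to_bacteria_ratio=0.0, seed=0)
        assert len(comm.taxa) == 1
        assert comm.host_copies == 0.0

    def test_host_ratio_exact_by_construction(self):
        comm = make_community(n_taxa=20, host_to_bacteria_ratio=9.0, seed=1)
        assert comm.host_copies == pytest.approx(9.0 * comm.bacterial_copies, rel=1e-12)

    def test_degenerate_spread_gives_equal_copies(self):
        comm = make_community(n_taxa=30, abundance_spread=1e-9, seed=2)
        copies = np.array([t.copies for t in comm.taxa])
        assert np.all(np.abs(copies / copies.mean() - 1) < 0.01)

    def test_gram_neg_fraction_extremes(self):
        all_neg = make_community(10, gram_neg_fraction=1.0, seed=3)
        all_pos = make_community(10, gram_neg_fraction=0.0, seed=3)
        assert {t.gram for t in all_neg.taxa} == {"gram_negative"}
        assert {t.gram for t in all_pos.taxa} == {"gram_positive"}

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_taxa": 0},
            {"n_taxa": 5, "gram_neg_fraction": 1.5},
            {"n_taxa": 5, "host_to_bacteria_ratio": -1.0},
            {"n_taxa": 5, "abundance_spread": -0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_community(seed=0, **kwargs)


class TestApplyDepletion:
    model = DepletionModel(k_host=2.0, k_gram_neg=0.8, k_gram_pos=0.0)

    def comm(self):
        return SyntheticCommunity(
            host_copies=1000.0,
            taxa=[
                CommunityTaxon("neg", "gram_negative", 500.0),
                CommunityTaxon("pos", "gram_positive", 300.0),
            ],
        )

    def test_zero_concentration_is_identity(self):
        out = apply_depletion(self.comm(), 0.0, self.model)
        assert out.host_copies == 1000.0
        assert [t.copies for t in out.taxa] == [500.0, 300.0]

    def test_host_exponential_decay(self):
        out = apply_depletion(self.comm(), 1.0, self.model)
        assert out.host_copies == pytest.approx(1000.0 * math.exp(-2.0), rel=1e-12)

    def test_zero_rate_class_unchanged(self):
        out = apply_depletion(self.comm(), 5.0, self.model)
        assert out.taxa[1].copies == 300.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            apply_depletion(self.comm(), -0.1, self.model)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            DepletionModel(k_host=-1.0, k_gram_neg=0.0, k_gram_pos=0.0)


class TestSequence:
    def test_counts_sum_exactly_to_depth(self):
        comm = make_community(15, seed=4)
        counts, acc = sequence(comm, SequencingConfig(depth=5_000, seed=0))
        assert counts.total == 5_000
        assert acc.high_quality_reads == 5_000
        assert acc.retained_after_host_filter == 5_000 - counts.host_reads

    def test_host_free_community_filters_nothing(self):
        comm = make_community(5, host_to_bacteria_ratio=0.0, seed=5)
        counts, acc = sequence(comm, SequencingConfig(depth=1_000, seed=0))
        assert counts.host_reads == 0
        assert percent_host_filtered(acc) == 0.00

    def test_host_only_community_filters_everything(self):
        comm = SyntheticCommunity(host_copies=1e6, taxa=[])
        counts, acc = sequence(comm, SequencingConfig(depth=1_000, seed=0))
        assert acc.retained_after_host_filter == 0
        assert percent_host_filtered(acc) == 100.00

    def test_host_fraction_within_binomial_error(self):
        # host probability exactly 0.5 -> drawn fraction within 3*sqrt(0.25/n)
        comm = SyntheticCommunity(
            host_copies=1000.0, taxa=[CommunityTaxon("t", "gram_positive", 1000.0)]
        )
        depth = 10**6
        counts, _ = sequence(comm, SequencingConfig(depth=depth, seed=123))
        assert abs(counts.host_reads / depth - 0.5) < 3 * math.sqrt(0.25 / depth)

    def test_misclassification_relabels_bacterial_reads(self):
        comm = make_community(5, host_to_bacteria_ratio=1.0, seed=6)
        counts, _ = sequence(
            comm, SequencingConfig(depth=2_000, misclassification_rate=1.0, seed=0)
        )
        assert sum(counts.taxon_counts.values()) == 0
        assert counts.unclassified_reads == 2_000 - counts.host_reads

    def test_empty_community_rejected(self):
        with pytest.raises(ValidationError):
            sequence(SyntheticCommunity(host_copies=0.0, taxa=[]), SequencingConfig(depth=10))


class TestCompositionLaw:
    def test_empirical_profile_matches_depletion_expectation(self):
        """At depth 1e6 each taxon's sampled share sits within 3 binomial
        standard errors of copies_t e^(-k_t c) / sum_j copies_j e^(-k_j c)."""
        comm = make_community(6, host_to_bacteria_ratio=0.5, abundance_spread=0.5, seed=7)
        model = DepletionModel(k_host=2.0, k_gram_neg=0.8, k_gram_pos=0.05)
        depth = 10**6
        depleted = apply_depletion(comm, 1.0, model)
        counts, _ = sequence(depleted, SequencingConfig(depth=depth, seed=8), sample_id="cl")
        weights = {t.name: t.copies for t in depleted.taxa}
        weights["__host__"] = depleted.host_copies
        total = sum(weights.values())
        observed = dict(counts.taxon_counts)
        observed["__host__"] = counts.host_reads
        for name, w in weights.items():
            p = w / total
            se = math.sqrt(p * (1 - p) / depth)
            assert abs(observed[name] / depth - p) < 3 * se + 1e-12


class TestScenario:
    def test_config_from_dict_lists_offending_keys(self):
        with pytest.raises(ValidationError) as exc:
            ScenarioConfig.from_dict({"communty": {}, "model": {"k_host": -1, "k_gram_neg": 0, "k_gram_pos": 0}})
        message = str(exc.value)
        assert "communty" in message and "model" in message

    def test_config_round_trip(self, tmp_path):
        cfg = default_scenario()
        path = tmp_path / "scenario.json"
        path.write_text(__import__("json").dumps(cfg.to_dict()), encoding="utf-8")
        back = ScenarioConfig.from_json(path)
        assert back == cfg

    def test_duplicate_or_negative_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioConfig(concentrations=(0.0, 1.0, 1.0))
        with pytest.raises(ValidationError):
            ScenarioConfig(concentrations=(-1.0,))

    def test_single_concentration_matches_untreated_expectation(self):
        cfg = default_scenario(
            concentrations=(0.0,), sequencing=SequencingConfig(depth=50_000), seeds=(3,)
        )
        run = simulate_scenario(cfg)
        ds = run.datasets[0]
        comm = run.communities[3]
        assert ds.counts.total == 50_000
        host_p = comm.host_copies / comm.total_copies
        se = math.sqrt(host_p * (1 - host_p) / 50_000)
        assert abs(ds.counts.host_reads / 50_000 - host_p) < 4 * se

    def test_run_scenario_outputs_are_byte_identical_across_reruns(self, tmp_path):
        cfg = default_scenario(
            concentrations=(0.0, 1.0), sequencing=SequencingConfig(depth=2_000), seeds=(1, 2)
        )
        run_scenario(cfg, tmp_path / "a")
        run_scenario(cfg, tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []

    def test_host_filtered_percent_decreases_across_grid(self):
        cfg = default_scenario(sequencing=SequencingConfig(depth=100_000), seeds=(11,))
        run = simulate_scenario(cfg)
        pcts = [
            percent_host_filtered(d.accounting)
            for d in sorted(run.datasets, key=lambda d: d.concentration)
        ]
        assert pcts == sorted(pcts, reverse=True)
        assert all(a > b for a, b in zip(pcts, pcts[1:]))
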
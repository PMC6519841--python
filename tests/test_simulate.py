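import numpy as np
import pytest

from tempopg import (
    GenomeConfig,
    HistoryParams,
    SamplingConfig,
    matched_filter,
    observed_excluded_fraction,
    simulate_snp_table,
    wf_drift_frequencies,
    wf_forward_oracle,
)
from tempopg.demography import ModelSpec, Prior
from tempopg.simulate import (
    SummaryPipeline,
    build_reference_table,
    to_msprime_demography,
)

from conftest import random_snp_table

H_CONST = HistoryParams(Ne_mod=400.0, m_hist=0.02, m_mod=0.02, t_hist_sample=90.0)
S2 = SamplingConfig(modern=(3, 3), historic=(3, 3))
G_SMALL = GenomeConfig(n_loci=10, locus_length=2000.0, mu=1e-7)


def point_prior_spec() -> ModelSpec:
    return ModelSpec(
        model_id="F", n_demes=2, migration_mode="symmetric",
        size_change="none", migration_change=True,
        priors={"Ne_mod": Prior("uniform", 400.0, 400.0),
                "m_hist": Prior("uniform", 0.02, 0.02),
                "m_mod": Prior("uniform", 0.005, 0.005)},
    )


class TestCoalescent:
    def test_zero_mutation_rate_gives_zero_snps(self):
        g = GenomeConfig(n_loci=5, locus_length=1000.0, mu=0.0)
        t = simulate_snp_table(H_CONST, 2, S2, g, seed=1)
        assert t.n_sites == 0

    def test_groups_and_chromosome_totals(self):
        t = simulate_snp_table(H_CONST, 2, S2, G_SMALL, seed=2)
        assert t.groups == ["hist:d0", "hist:d1", "mod:d0", "mod:d1"]
        assert np.all(t.n == 6)

    def test_sites_segregate_in_union(self):
        t = simulate_snp_table(H_CONST, 2, S2, G_SMALL, seed=3)
        tot = t.x.sum(axis=1)
        assert np.all((tot > 0) & (tot < t.n.sum(axis=1)))

    def test_seed_reproducibility(self):
        a = simulate_snp_table(H_CONST, 2, S2, G_SMALL, seed=5)
        b = simulate_snp_table(H_CONST, 2, S2, G_SMALL, seed=5)
        assert np.array_equal(a.x, b.x) and list(a.site_id) == list(b.site_id)

    def test_disconnected_demes_rejected(self):
        h = HistoryParams(Ne_mod=400.0, m_hist=0.0, m_mod=0.0)
        with pytest.raises(ValueError, match="migration"):
            to_msprime_demography(h, 2)

    def test_bottleneck_translation_sizes(self):
        h = HistoryParams(Ne_mod=100.0, r_shrink=0.01, t_shrink=90.0)
        dem = to_msprime_demography(h, 1)
        # backward growth: size at 90 generations ago is Ne_mod * e^{0.9}
        epochs = dem.debug().epochs
        assert epochs[0].populations[0].growth_rate == pytest.approx(-0.01)
        assert epochs[1].populations[0].start_size == pytest.approx(100 * np.exp(0.9))

    def test_expansion_floor_epoch(self):
        h = HistoryParams(Ne_mod=1000.0, r_grow=0.01, t_grow_stop=200.0)
        dem = to_msprime_demography(h, 1)
        last = dem.debug().epochs[-1]
        assert last.populations[0].start_size == pytest.approx(10.0)


class TestMatchedFilter:
    def test_zero_probability_is_identity(self):
        t = random_snp_table(50, ["hist:d0", "mod:d0"], [6, 6], seed=1)
        out, removed = matched_filter(t, excluded_probability=0.0, seed=1)
        assert removed == 0 and out.n_sites == 50

    def test_probability_one_empties_table(self):
        t = random_snp_table(50, ["hist:d0", "mod:d0"], [6, 6], seed=2)
        out, removed = matched_filter(t, excluded_probability=1.0, seed=1)
        assert removed == 50 and out.n_sites == 0

    def test_binomial_expectation_at_half(self):
        t = random_snp_table(10_000, ["hist:d0", "mod:d0"], [6, 6], seed=3)
        out, _ = matched_filter(t, excluded_probability=0.5, seed=4)
        assert abs(out.n_sites - 5000) <= 3 * 50

    def test_invalid_probability_rejected(self):
        t = random_snp_table(5, ["hist:d0", "mod:d0"], [6, 6], seed=4)
        with pytest.raises(ValueError, match="probability"):
            matched_filter(t, excluded_probability=1.5)

    def test_class_assignment_path_filters_deamination_pairs(self):
        t = random_snp_table(4000, ["hist:d0", "mod:d0"], [6, 6], seed=5)
        probs = {("C", "T"): 0.25, ("G", "A"): 0.25, ("A", "C"): 0.5}
        out, removed = matched_filter(t, class_probs=probs, seed=6)
        assert abs(removed - 2000) <= 3 * np.sqrt(4000 * 0.25)
        assert observed_excluded_fraction(out) == 0.0

    def test_observed_excluded_fraction(self):
        t = random_snp_table(2000, ["hist:d0"], [6], seed=7)
        frac = observed_excluded_fraction(t)
        brute = np.mean([frozenset((a, d)) in ({"C", "T"}, {"G", "A"})
                         for a, d in zip(t.anc, t.der)])
        assert frac == pytest.approx(brute)


class TestReferenceTable:
    def test_one_row_per_model(self):
        specs = [point_prior_spec(),
                 ModelSpec(model_id="E", n_demes=2, migration_mode="symmetric",
                           size_change="none", migration_change=False,
                           priors={"Ne_mod": Prior("uniform", 300.0, 300.0),
                                   "m": Prior("uniform", 0.01, 0.01)})]
        pl = SummaryPipeline(sampling=S2, genome=G_SMALL)
        ref = build_reference_table(specs, 1, pl, seed=1)
        assert list(ref.df["model"]) == ["F", "E"]

    def test_master_seed_bit_reproducibility(self, tmp_path):
        pl = SummaryPipeline(sampling=S2, genome=G_SMALL)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        build_reference_table([point_prior_spec()], 3, pl, seed=9, out_path=p1)
        build_reference_table([point_prior_spec()], 3, pl, seed=9, out_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_degenerate_priors_share_params_but_not_summaries(self):
        pl = SummaryPipeline(sampling=S2, genome=G_SMALL)
        ref = build_reference_table([point_prior_spec()], 6, pl, seed=3)
        assert ref.df["Ne_mod"].nunique() == 1
        assert ref.summaries().std(axis=0).sum() > 0

    def test_save_load_round_trip(self, tmp_path):
        pl = SummaryPipeline(sampling=S2, genome=G_SMALL)
        ref = build_reference_table([point_prior_spec()], 2, pl, seed=5,
                                    out_path=tmp_path / "ref.tsv")
        from tempopg.simulate import ReferenceTable
        back = ReferenceTable.load(tmp_path / "ref.tsv")
        assert back.summary_cols == ref.summary_cols
        assert np.allclose(back.summaries(), ref.summaries())
        assert back.meta["pipeline"] == ref.meta["pipeline"]


class TestWrightFisherOracle:
    def test_no_drift_limit(self):
        p = wf_drift_frequencies(0.5, Ne=1e6, t=2, n_rep=500, seed=1)
        assert np.mean(np.abs(p - 0.5)) < 0.01

    def test_drift_variance_formula(self):
        # Var(p_t) = p0(1-p0) (1 - (1 - 1/(2Ne))^t)
        Ne, t = 1000, 90
        p = wf_drift_frequencies(0.5, Ne, t, n_rep=2000, seed=2)
        expect = 0.25 * (1 - (1 - 1 / (2 * Ne)) ** t)
        se = expect * np.sqrt(2 / (len(p) - 1))
        assert abs(p.var() - expect) < 3 * se

    def test_zero_migration_demes_independent(self):
        h = HistoryParams(Ne_mod=200.0, m_hist=0.0, m_mod=0.0, t_hist_sample=90.0)
        t = wf_forward_oracle(h, SamplingConfig(modern=(20, 20), historic=(20, 20)),
                              n_sites=4000, seed=3)
        p0 = t.x[:, t.groups.index("mod:d0")] / 40
        p1 = t.x[:, t.groups.index("mod:d1")] / 40
        r = np.corrcoef(p0, p1)[0, 1]
        assert abs(r) < 3 / np.sqrt(t.n_sites)

    def test_large_population_rejected(self):
        h = HistoryParams(Ne_mod=50_000.0)
        with pytest.raises(ValueError, match="5000"):
            wf_forward_oracle(h, S2, n_sites=10, seed=0)

    def test_exactly_one_source_of_standing_variation(self):
        h = HistoryParams(Ne_mod=200.0)
        with pytest.raises(ValueError, match="exactly one"):
            wf_forward_oracle(h, SamplingConfig(modern=(3,), historic=(3,)),
                              n_sites=10, genome=G_SMALL, seed=0)


class TestConfigs:
    def test_sampling_validation(self):
        with pytest.raises(ValueError):
            SamplingConfig(modern=(0,), historic=(0,))
        with pytest.raises(ValueError):
            SamplingConfig(modern=(1, 2), historic=(1,))

    def test_genome_validation(self):
        with pytest.raises(ValueError):
            GenomeConfig(n_loci=0)

    def test_pipeline_summary_length_matches_simulation(self):
        pl = SummaryPipeline(sampling=S2, genome=G_SMALL, bin_width=1)
        v = pl.simulate_summary(H_CONST, 2, seed=11)
        assert len(v) == pl.summary_length()

    def test_pipeline_rejects_mismatched_table(self):
        pl = SummaryPipeline(sampling=S2, genome=G_SMALL)
        t = random_snp_table(10, ["hist:d0", "mod:d0"], [10, 10], seed=1)
        with pytest.raises(ValueError, match="sampling configuration"):
            pl.summarize_table(t)
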
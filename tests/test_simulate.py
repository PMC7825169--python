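import numpy as np
import pytest

from ampdiv.align import sequence_identity
from ampdiv.profiles import build_profiles, dominance_stats
from ampdiv.simulate import (SimulationConfig, simulate_community,
                             simulate_genotypes, simulate_pileup,
                             simulate_templates)


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="dispersal"):
            SimulationConfig(dispersal=1.5)

    def test_range_validity(self):
        with pytest.raises(ValueError, match="depth_range"):
            SimulationConfig(depth_range=(100, 50))


class TestTemplates:
    def test_single_template_length_bounds(self):
        cfg = SimulationConfig(seed=3, n_lineages=1)
        templates, boundaries = simulate_templates(cfg)
        (seq,) = templates.values()
        assert 1800 <= len(seq) <= 2100
        ssu_end, lsu_start, length = next(iter(boundaries.values()))
        assert 0 < ssu_end < lsu_start < length == len(seq)

    def test_pairwise_16s_divergence_respected(self):
        cfg = SimulationConfig(seed=4, n_lineages=3,
                               inter_lineage_divergence=0.08)
        templates, boundaries = simulate_templates(cfg)
        ssus = {lid: templates[lid][:boundaries[lid][0]] for lid in templates}
        ids = list(ssus)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert sequence_identity(ssus[a], ssus[b]) <= 0.92

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=9, n_lineages=2)
        assert simulate_templates(cfg) == simulate_templates(cfg)

    def test_infeasible_divergence_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_templates(SimulationConfig(inter_lineage_divergence=0.999))


class TestGenotypes:
    @pytest.fixture(scope="class")
    def template(self):
        cfg = SimulationConfig(seed=5, n_lineages=1)
        templates, boundaries = simulate_templates(cfg)
        lid = next(iter(templates))
        return templates[lid], boundaries[lid]

    def test_genotypes_distinct_and_near_template(self, template):
        seq, bounds = template
        cfg = SimulationConfig(seed=5, indel_prob=0.3)
        rng = np.random.default_rng(5)
        gts = simulate_genotypes(seq, bounds, cfg, rng, 12)
        seqs = [g.sequence for g in gts]
        assert len(set(seqs)) == 12
        for g in gts:
            assert sequence_identity(g.sequence, seq) > 0.99
            assert 1 <= len(g.substitutions) <= 6

    def test_its_bias_places_most_snps_in_its(self, template):
        seq, (ssu_end, lsu_start, _length) = template
        cfg = SimulationConfig(seed=6, its_bias=0.8, indel_prob=0)
        rng = np.random.default_rng(6)
        gts = simulate_genotypes(seq, (ssu_end, lsu_start, len(seq)), cfg,
                                 rng, 40)
        in_its = total = 0
        for g in gts:
            for pos, _old, _new in g.substitutions:
                total += 1
                in_its += ssu_end <= pos < lsu_start
        assert in_its / total > 0.6  # 80% expected; allow sampling noise

    def test_single_its_snp_visible_in_anchored_msa(self, template):
        from ampdiv.align import anchored_msa

        seq, (ssu_end, lsu_start, _l) = template
        pos = ssu_end + 50
        other = seq[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]] \
            + seq[pos + 1:]
        msa = anchored_msa(seq, [other], member_ids=["m"])
        variants = [p for p in range(len(seq)) if msa.rows["m"][p] != seq[p]]
        assert variants == [pos]

    def test_indels_confined_to_its(self, template):
        seq, bounds = template
        cfg = SimulationConfig(seed=7, indel_prob=1.0)
        rng = np.random.default_rng(7)
        gts = simulate_genotypes(seq, bounds, cfg, rng, 10)
        ssu_end, lsu_start, _length = bounds
        for g in gts:
            assert g.indel is not None
            _kind, pos, _base = g.indel
            assert ssu_end <= pos < lsu_start


class TestCommunity:
    def test_fixed_depth_column_sums(self):
        cfg = SimulationConfig(seed=8, n_lineages=2,
                               genotypes_per_lineage=(3, 5),
                               lakes_per_region=(1, 1, 1),
                               depth_range=(100, 100))
        table, _truth = simulate_community(cfg)
        assert (table.counts.sum(axis=0) == 100).all()

    def test_same_seed_identical_table(self, small_cfg):
        t1, _ = simulate_community(small_cfg)
        t2, _ = simulate_community(small_cfg)
        assert t1.counts.equals(t2.counts)
        assert t1.sequences == t2.sequences

    def test_truth_traces_every_emitted_count(self, small_community):
        table, truth = small_community
        geno = truth.genotype_of_asv()
        assert set(table.asv_ids) == set(geno)
        for sample, mix in truth.mixtures.items():
            assert sum(mix.values()) == pytest.approx(1.0)

    def test_asv_table_invariants_hold(self, small_community):
        table, _truth = small_community
        table.validate()  # raises on violation
        assert all(len(s) > 1500 for s in table.sequences.values())

    def test_asv_ids_ranked_by_abundance(self, small_community):
        table, _truth = small_community
        totals = table.counts.sum(axis=1)
        ranks = [int(a.split("_")[1]) for a in table.asv_ids]
        assert ranks == sorted(ranks)
        assert totals.iloc[0] == totals.max()

    def test_dispersal_zero_pools_region_private(self):
        cfg = SimulationConfig(seed=12, n_lineages=2,
                               genotypes_per_lineage=(4, 6),
                               lakes_per_region=(2, 1, 1), dispersal=0.0)
        table, truth = simulate_community(cfg)
        geno = truth.genotype_of_asv()
        meta = {s.sample_id: s for s in table.samples}
        for asv in table.asv_ids:
            present = table.counts.columns[table.counts.loc[asv] > 0]
            for s in present:
                assert meta[s].region == geno[asv].home_region

    def test_dominance_rises_as_alpha_drops(self):
        """Smaller Dirichlet concentration -> more skewed communities."""
        means = []
        for alpha in (2.0, 0.05):
            tops = []
            for seed in (21, 22, 23):
                cfg = SimulationConfig(seed=seed, n_lineages=1,
                                       genotypes_per_lineage=(8, 8),
                                       lakes_per_region=(2, 1, 1),
                                       dispersal=1.0, dirichlet_alpha=alpha,
                                       depth_range=(500, 500))
                table, truth = simulate_community(cfg)
                prof = build_profiles(
                    table, {a: "O" for a in table.asv_ids})["O"]
                tops.append(dominance_stats(prof).means["top1"])
            means.append(np.mean(tops))
        assert means[1] > means[0]


class TestPileupSimulation:
    def test_single_genotype_no_error_exact(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        p = simulate_pileup({"g": 1.0}, {"g": seq}, 50, error_rate=0.0, seed=1)
        assert (p.rows["depth"] == 50).all()
        for k, base in enumerate(seq):
            assert p.rows.iloc[k][base] == 50

    def test_minor_frequency_within_binomial_bound(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), 200))
        alt = "C" + base[1:] if base[0] != "C" else "G" + base[1:]
        p = simulate_pileup({"a": 0.6, "b": 0.4}, {"a": base, "b": alt},
                            10_000, error_rate=0.0, seed=2)
        row = p.rows.iloc[0]
        minor = row[alt[0]] / row["depth"]
        assert abs(minor - 0.4) < 0.015  # 3 sigma

    def test_error_rate_expectation_at_invariant_site(self):
        seq = "A" * 1000
        p = simulate_pileup({"g": 1.0}, {"g": seq}, 1000, error_rate=0.005,
                            seed=4)
        non_ref = 1 - p.rows["A"].sum() / p.rows["depth"].sum()
        assert non_ref == pytest.approx(0.005, abs=0.001)

    def test_deletions_pass_through(self):
        ref = "ACGTACGTACGTACGTACGT"
        member = ref[:9] + ref[10:]
        p = simulate_pileup({"a": 0.5, "b": 0.5}, {"a": ref, "b": member},
                            400, error_rate=0.0, seed=6)
        assert p.rows["del"].sum() > 0
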
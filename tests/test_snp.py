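import numpy as np
import pandas as pd
import pytest

from ampdiv.align import RegionPartition, anchored_msa
from ampdiv.io import PileupTable
from ampdiv.snp import (DetectionThresholds, SnpSite, classify_concordance,
                        compare_major_props, detected_variant_sites,
                        expected_variant_sites)


def _pileup(rows):
    df = pd.DataFrame(rows, columns=["pos", "A", "C", "G", "T", "del"])
    df["depth"] = df[["A", "C", "G", "T", "del"]].sum(axis=1)
    return PileupTable("ref", df)


def _partition(n, ssu_end=None, lsu_start=None):
    ssu_end = ssu_end if ssu_end is not None else n
    lsu_start = lsu_start if lsu_start is not None else n
    return RegionPartition("ref", (0, ssu_end), (ssu_end, lsu_start),
                           (lsu_start, n))


class TestExpectedSites:
    def test_single_member_no_sites(self):
        msa = anchored_msa("ACGTACGT", [], reference_id="r")
        assert expected_variant_sites(msa, {"r": 10}, _partition(8)) == []

    def test_abundance_weighted_proportions(self):
        msa = anchored_msa("ACGTACGTAC", ["ACGTACGTGC"], member_ids=["m"],
                           reference_id="r")
        sites = expected_variant_sites(msa, {"r": 60, "m": 40}, _partition(10))
        assert len(sites) == 1
        site = sites[0]
        assert site.position == 9
        assert site.expected_props == {"A": pytest.approx(0.6),
                                       "G": pytest.approx(0.4)}

    def test_gap_is_a_state(self):
        ref = "ACGTACGTACGTACGTACGT"
        member = ref[:9] + ref[10:]
        msa = anchored_msa(ref, [member], member_ids=["m"], reference_id="r")
        sites = expected_variant_sites(msa, {"r": 1, "m": 1}, _partition(len(ref)))
        assert any("gap" in s.expected_props for s in sites)

    def test_region_relative_labels(self):
        msa = anchored_msa("ACGTACGTAC", ["ACCTACGTGC"], member_ids=["m"],
                           reference_id="r")
        sites = expected_variant_sites(msa, {"r": 1, "m": 1},
                                       _partition(10, ssu_end=5, lsu_start=8))
        by_pos = {s.position: s for s in sites}
        assert by_pos[3].region == "SSU" and by_pos[3].region_position == 3
        assert by_pos[9].region == "LSU" and by_pos[9].region_position == 1

    def test_missing_abundance_is_error(self):
        msa = anchored_msa("ACGT", ["ACGA"], member_ids=["m"],
                           reference_id="r")
        with pytest.raises(ValueError, match="abundance missing"):
            expected_variant_sites(msa, {"r": 1}, _partition(4))


class TestDetectedSites:
    def test_monomorphic_not_variable(self):
        variable, covered = detected_variant_sites(_pileup([[1, 100, 0, 0, 0, 0]]))
        assert variable == {} and covered == {1}

    def test_ninety_ten_detected(self):
        variable, _ = detected_variant_sites(_pileup([[5, 90, 0, 10, 0, 0]]))
        assert variable[5] == {"A": pytest.approx(0.9), "G": pytest.approx(0.1)}

    def test_singleton_minor_state_suppressed(self):
        variable, _ = detected_variant_sites(_pileup([[5, 99, 0, 1, 0, 0]]))
        assert variable == {}

    def test_low_depth_uncovered(self):
        variable, covered = detected_variant_sites(_pileup([[5, 4, 4, 0, 0, 0]]))
        assert variable == {} and covered == set()

    def test_deletion_state_counts(self):
        variable, _ = detected_variant_sites(_pileup([[2, 80, 0, 0, 0, 20]]))
        assert variable[2]["gap"] == pytest.approx(0.2)


class TestClassification:
    def _expected_at(self, positions):
        return [SnpSite(position=p, region="SSU", region_position=p,
                        expected_props={"A": 0.7, "G": 0.3})
                for p in positions]

    def test_full_agreement(self):
        detected = {p: {"A": 0.7, "G": 0.3} for p in (2, 4, 6, 8)}
        summary = classify_concordance(self._expected_at([2, 4, 6, 8]), detected)
        assert summary.proportions()["both"] == 1.0
        assert summary.n_sites == 4

    def test_hand_partition_of_four_sites(self):
        expected = self._expected_at([1, 2, 3])
        detected = {3: {"A": 0.8, "G": 0.2}, 9: {"C": 0.5, "T": 0.5}}
        summary = classify_concordance(expected, detected, _partition(20))
        props = summary.proportions()
        assert summary.n_sites == 4
        assert props == {"both": pytest.approx(0.25),
                         "expected_only": pytest.approx(0.5),
                         "detected_only": pytest.approx(0.25)}

    def test_summary_proportions_partition_unity(self):
        expected = self._expected_at([1, 5])
        detected = {5: {"A": 0.9, "G": 0.1}, 7: {"A": 0.6, "T": 0.4}}
        props = classify_concordance(expected, detected, _partition(20)
                                     ).proportions()
        assert sum(props.values()) == pytest.approx(1.0)


class TestCompareMajorProps:
    def _both_site(self, expected, detected):
        from ampdiv.snp import SnpSite
        return SnpSite(position=1, region="SSU", region_position=1,
                       expected_props=expected, detected_freqs=detected,
                       status="both")

    def test_identical_distributions_zero_tv(self):
        site = self._both_site({"A": 0.6, "G": 0.4}, {"A": 0.6, "G": 0.4})
        *_rest, tv = compare_major_props(site)
        assert tv == pytest.approx(0.0)

    def test_stated_tv_example(self):
        site = self._both_site({"A": 0.6, "G": 0.4}, {"A": 0.5, "G": 0.5})
        states, exp, det, tv = compare_major_props(site)
        assert tv == pytest.approx(0.1)
        assert states == ["A", "G"]

    def test_requires_both_status(self):
        from ampdiv.snp import SnpSite
        site = SnpSite(position=1, region="SSU", region_position=1,
                       expected_props={"A": 0.6, "G": 0.4})
        with pytest.raises(ValueError, match="both"):
            compare_major_props(site)


class TestSimulationRoundTrip:
    def test_error_free_deep_pileup_fully_concordant(self):
        """Expected sites from the true mixture are all re-detected; none extra."""
        from ampdiv.simulate import simulate_pileup

        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACGT"), 400))
        genotypes = {"g1": base}
        muts = {"g2": [50], "g3": [50, 200], "g4": [350]}
        for g, positions in muts.items():
            s = list(base)
            for p in positions:
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            genotypes[g] = "".join(s)
        mixture = {"g1": 0.4, "g2": 0.3, "g3": 0.2, "g4": 0.1}
        depth = 10_000
        pileup = simulate_pileup(mixture, genotypes, depth, error_rate=0.0,
                                 seed=5)
        msa = anchored_msa(base, [genotypes[g] for g in ("g2", "g3", "g4")],
                           member_ids=["g2", "g3", "g4"], reference_id="g1")
        expected = expected_variant_sites(msa, mixture, _partition(400))
        assert {s.position for s in expected} == {51, 201, 351}
        detected, _ = detected_variant_sites(pileup)
        summary = classify_concordance(expected, detected, _partition(400))
        props = summary.proportions()
        assert props["detected_only"] == 0.0
        assert props["both"] == 1.0
        for site in summary.sites:
            *_rest, tv = compare_major_props(site)
            assert tv < 3 / np.sqrt(depth)

    def test_error_above_min_freq_creates_detected_only(self):
        """Cranking the error rate past the frequency cutoff adds false sites."""
        from ampdiv.simulate import simulate_pileup

        genotypes = {"g1": "ACGTACGTACGTACGTACGTACGTACGTACGT" * 4}
        counts = []
        for err in (0.0, 0.15):
            pileup = simulate_pileup({"g1": 1.0}, genotypes, 500,
                                     error_rate=err, seed=3)
            detected, _ = detected_variant_sites(pileup)
            counts.append(len(detected))
        assert counts[0] == 0
        assert counts[1] > counts[0]
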
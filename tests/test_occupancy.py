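import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trnareg.occupancy import (
    assign_peaks_to_trnas,
    call_enrichment,
    classify_activity,
    consensus_hits,
    multimap_filter,
    nearest_trna_distance,
    normalized_signal,
)


def _mm(rows):
    return pd.DataFrame(rows, columns=["gene", "library", "unique", "multi"])


class TestMultimapFilter:
    def test_excluded_when_both_conditions_hold_in_all_libraries(self):
        mm = _mm([("g", "L1", 40, 20), ("g", "L2", 40, 20)])  # 33%, total 60
        kept, excluded = multimap_filter(mm)
        assert excluded == ["g"]

    def test_kept_when_total_below_min_reads(self):
        mm = _mm([("g", "L1", 10, 30), ("g", "L2", 10, 30)])  # 75% but total 40
        kept, excluded = multimap_filter(mm)
        assert kept == ["g"]

    def test_kept_when_fraction_low(self):
        mm = _mm([("g", "L1", 90, 10), ("g", "L2", 90, 10)])
        kept, excluded = multimap_filter(mm)
        assert kept == ["g"]

    def test_consensus_requires_every_library(self):
        mm = _mm([("g", "L1", 40, 20), ("g", "L2", 90, 10)])
        kept, excluded = multimap_filter(mm)
        assert kept == ["g"]


class TestCallEnrichment:
    def test_strong_signal_matches_poisson_tail(self):
        genes = [f"g{i}" for i in range(50)]
        rng = np.random.default_rng(0)
        inp = pd.DataFrame({"s_rep1": rng.poisson(10, 50)}, index=genes)
        ip = pd.DataFrame({"s_rep1": inp["s_rep1"].copy()}, index=genes)
        ip.iloc[0, 0] = 500
        calls = call_enrichment(ip, inp).set_index("gene")
        assert calls.loc["g0", "significant"]
        # raw p equals the upper-tail Poisson probability at the reported rate
        lam = calls.loc["g0", "lam"]
        assert calls.loc["g0", "pvalue"] == pytest.approx(
            stats.poisson.sf(499, lam)
        )
        assert not calls.drop("g0")["significant"].any()

    def test_alpha_zero_means_no_calls(self):
        genes = ["a", "b"]
        ip = pd.DataFrame({"s_rep1": [100, 5]}, index=genes)
        inp = pd.DataFrame({"s_rep1": [5, 5]}, index=genes)
        calls = call_enrichment(ip, inp, alpha=0.0)
        assert not calls["significant"].any()

    def test_zero_depth_library_rejected(self):
        ip = pd.DataFrame({"s_rep1": [0, 0]}, index=["a", "b"])
        inp = pd.DataFrame({"s_rep1": [5, 5]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero-depth"):
            call_enrichment(ip, inp)

    def test_background_scaling_corrects_composition_bias(self):
        # 2/3 of genes strongly bound: the library-ratio scale dilutes
        # true enrichment, the background estimate recovers it
        rng = np.random.default_rng(1)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        bound = np.arange(n) < 200
        inp = pd.DataFrame({"s_rep1": rng.poisson(50, n)}, index=genes)
        ip = pd.DataFrame(
            {"s_rep1": rng.poisson(np.where(bound, 400, 50))}, index=genes
        )
        bg = call_enrichment(ip, inp, scale_method="background").set_index("gene")
        assert bg.loc[np.array(genes)[bound], "significant"].all()
        # false discoveries stay at the controlled FDR level
        fp = int(bg.loc[np.array(genes)[~bound], "significant"].sum())
        assert fp / (fp + 200) <= 0.075


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestAssignPeaks:
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [1000], "end": [1073], "name": ["tA"]}
    )

    def _assign(self, summit, window=125):
        peaks = _peaks([("chr1", summit - 10, summit + 10, "p")])
        return assign_peaks_to_trnas(peaks, self.genes, window=window)

    def test_hit_100bp_upstream(self):
        out = self._assign(900)
        assert list(out["gene"]) == ["tA"] and out["distance"].iloc[0] == 100

    def test_no_hit_at_126bp(self):
        assert self._assign(1000 - 126).empty

    def test_hit_at_exactly_125bp(self):
        assert not self._assign(1000 - 125).empty

    def test_summit_inside_gene_distance_zero(self):
        out = self._assign(1030)
        assert out["distance"].iloc[0] == 0

    def test_nearest_gene_wins(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1000, 1200],
             "end": [1073, 1273], "name": ["tA", "tB"]}
        )
        peaks = _peaks([("chr1", 1150, 1160, "p")])  # summit 1155
        out = assign_peaks_to_trnas(peaks, genes, window=125)
        assert list(out["gene"]) == ["tB"]
        out2 = assign_peaks_to_trnas(peaks, genes, window=125, multi_assign=True)
        assert sorted(out2["gene"]) == ["tA", "tB"]

    def test_unknown_chromosome_warns_and_skips(self):
        peaks = _peaks([("chrUn", 10, 20, "p")])
        with pytest.warns(UserWarning, match="chrUn"):
            out = assign_peaks_to_trnas(peaks, self.genes)
        assert out.empty

    def test_narrowpeak_summit_offset_preferred(self):
        peaks = _peaks([("chr1", 500, 1500, "p")])
        peaks["summit"] = [1400]  # midpoint would hit; summit misses
        out = assign_peaks_to_trnas(peaks, self.genes, window=125)
        assert out.empty


class TestConsensusAndClassification:
    def test_consensus_is_strict_intersection(self):
        assert consensus_hits([{"a", "b"}, {"b"}]) == {"b"}
        assert consensus_hits([{"a"}, {"a"}, set()]) == set()
        with pytest.raises(ValueError):
            consensus_hits([{"a"}])

    def test_definitions(self):
        consensus = {
            "iPSC": {"hk", "rep"},
            "CM": {"hk"},
            "NPC": {"hk"},
            "neuron": {"hk"},
        }
        out = classify_activity(consensus, ["hk", "rep", "inact"]).set_index("gene")
        assert out.loc["hk", "class"] == "housekeeping"
        assert out.loc["rep", "class"] == "repressed"
        assert out.loc["inact", "class"] == "inactive"

    def test_partition_is_exhaustive_and_disjoint(self, study600):
        cfg, genes, truth, ip, inp, mm = study600
        kept, _ = multimap_filter(mm)
        calls = call_enrichment(ip.loc[kept], inp.loc[kept], scale_method="background")
        from trnareg.repertoire import sample_metadata

        meta = sample_metadata(ip.columns)
        consensus = {
            ct: consensus_hits(
                [set(calls.query("sample == @s and significant")["gene"]) for s in ss]
            )
            for ct, ss in meta.groupby("cell_type").groups.items()
        }
        labels = classify_activity(consensus, kept)
        assert sorted(labels["gene"]) == sorted(kept)
        assert set(labels["class"]) <= {"housekeeping", "repressed", "inactive"}

    def test_monotonicity_adding_a_hit_never_moves_toward_inactive(self):
        rank = {"inactive": 0, "repressed": 1, "housekeeping": 2}
        consensus = {"iPSC": {"g"}, "CM": set()}
        before = classify_activity(consensus, ["g"]).set_index("gene").loc["g", "class"]
        consensus["CM"] = {"g"}
        after = classify_activity(consensus, ["g"]).set_index("gene").loc["g", "class"]
        assert rank[after] >= rank[before]


class TestNormalizedSignal:
    def test_identical_libraries_rpm_scaling(self):
        t = pd.DataFrame({"a_rep1": [10, 90], "a_rep2": [10, 90]},
                         index=["x", "y"])
        out = normalized_signal(t)
        assert np.allclose(out["a_rep1"], t["a_rep1"] * 1e6 / 100)

    def test_uniform_doubling_leaves_signal_unchanged(self):
        t = pd.DataFrame({"a_rep1": [10, 90], "a_rep2": [20, 180]},
                         index=["x", "y"])
        out = normalized_signal(t)
        assert np.allclose(out["a_rep1"], out["a_rep2"])

    def test_zero_count_stays_zero(self):
        t = pd.DataFrame({"a_rep1": [0, 90], "a_rep2": [5, 80]}, index=["x", "y"])
        assert normalized_signal(t).loc["x", "a_rep1"] == 0


class TestNearestDistance:
    def test_gap_between_neighbours(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 250],
             "end": [200, 350], "name": ["a", "b"]}
        )
        d = nearest_trna_distance(genes)
        assert d["a"] == 50 and d["b"] == 50

    def test_overlap_is_zero(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 150],
             "end": [200, 250], "name": ["a", "b"]}
        )
        assert (nearest_trna_distance(genes) == 0).all()

    def test_lone_gene_on_chromosome_is_missing(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "start": [100, 100],
             "end": [200, 200], "name": ["a", "b"]}
        )
        assert nearest_trna_distance(genes).isna().all()
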
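import itertools

import numpy as np
import pandas as pd
import pytest

from methdecon import call_dmgrs, intersect_strata, map_probes_to_regions
from methdecon.regions import ProbeRegionMapping


class TestMapping:
    def test_two_neighboring_genes_both_kept(self, toy_manifest):
        mapping = map_probes_to_regions(toy_manifest)
        pairs = set(map(tuple, mapping.pairs[mapping.pairs["probe_id"] == "cg02"]
                        [["gene", "region"]].values))
        assert pairs == {("KLHL17", "3'UTR"), ("PLEKHN1", "TSS1500")}

    def test_duplicate_pairs_counted_once(self, toy_manifest):
        mapping = map_probes_to_regions(toy_manifest)
        cg01 = mapping.pairs[mapping.pairs["probe_id"] == "cg01"]
        assert len(cg01) == 2  # (SAMD11, TSS1500) and (SAMD11, Body)

    def test_third_gene_dropped(self, toy_manifest):
        mapping = map_probes_to_regions(toy_manifest)
        cg04 = mapping.pairs[mapping.pairs["probe_id"] == "cg04"]
        assert set(cg04["gene"]) == {"A", "B"}
        assert mapping.n_dropped_genes == 1

    def test_unannotated_probe_unmapped(self, toy_manifest):
        mapping = map_probes_to_regions(toy_manifest)
        assert mapping.unmapped == ["cg03"]

    def test_island_mode_conserves_probes(self, toy_manifest):
        mapping = map_probes_to_regions(toy_manifest, mode="island_context")
        assert len(mapping.pairs) == len(toy_manifest)
        assert mapping.unmapped == []
        assert set(mapping.pairs["gene"]) <= {
            "Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}


def _results(rows):
    return pd.DataFrame(rows, columns=["probe_id", "beta_tumor", "q"])


def _mapping(records):
    return ProbeRegionMapping(
        pairs=pd.DataFrame(records, columns=["probe_id", "gene", "region"]),
        unmapped=[], mode="gene_region",
    )


class TestCalling:
    def test_median_arithmetic(self):
        mapping = _mapping([("p1", "G", "Body"), ("p2", "G", "Body"),
                            ("p3", "G", "Body")])
        results = _results([("p1", 0.1, 0.001), ("p2", 0.1, 0.003),
                            ("p3", 0.1, 0.2)])
        for rule in ("median", "any"):
            calls = call_dmgrs(results, mapping, q_cutoff=0.01, rule=rule)
            row = calls.iloc[0]
            assert row["median_q"] == pytest.approx(0.003)
            assert bool(row["dmgr"])

    def test_mixed_signs_give_bidirectional_code(self):
        mapping = _mapping([("p1", "G", "Body"), ("p2", "G", "Body")])
        results = _results([("p1", 0.2, 0.001), ("p2", -0.2, 0.002)])
        calls = call_dmgrs(results, mapping)
        assert calls.iloc[0]["direction"] == "-+"

    def test_direction_single_signs(self):
        mapping = _mapping([("p1", "G1", "Body"), ("p2", "G2", "Body")])
        results = _results([("p1", 0.2, 0.001), ("p2", -0.2, 0.002)])
        calls = call_dmgrs(results, mapping).set_index("gene")
        assert calls.loc["G1", "direction"] == "+"
        assert calls.loc["G2", "direction"] == "-"

    def test_no_significant_cpgs_no_dmgrs(self):
        mapping = _mapping([("p1", "G", "Body")])
        calls = call_dmgrs(_results([("p1", 0.1, 0.5)]), mapping)
        assert not calls["dmgr"].any()

    def test_rules_differ_on_outlier_region(self):
        # one significant CpG among many null ones: called by "any" only
        mapping = _mapping([(f"p{i}", "G", "Body") for i in range(5)])
        results = _results([("p0", 0.2, 0.001)]
                           + [(f"p{i}", 0.0, 0.8) for i in range(1, 5)])
        by_median = call_dmgrs(results, mapping, rule="median")
        by_any = call_dmgrs(results, mapping, rule="any")
        assert not by_median.iloc[0]["dmgr"]
        assert by_any.iloc[0]["dmgr"]

    @pytest.mark.parametrize("rule", ["median", "any"])
    def test_monotone_in_cutoff(self, rule):
        rng = np.random.default_rng(17)
        mapping = _mapping([(f"p{i}", f"G{i % 7}", "Body") for i in range(40)])
        results = _results([(f"p{i}", rng.normal(), rng.random() * 0.1)
                            for i in range(40)])
        sets = []
        for cutoff in (0.001, 0.01, 0.05):
            calls = call_dmgrs(results, mapping, q_cutoff=cutoff, rule=rule)
            sets.append(set(zip(calls[calls["dmgr"]]["gene"],
                                calls[calls["dmgr"]]["region"])))
        assert sets[0] <= sets[1] <= sets[2]

    def test_collapsing_conservation(self):
        """Each significant CpG contributes to >= 1 unit or is unmapped;
        never twice to the same unit."""
        rng = np.random.default_rng(23)
        manifest = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(12)],
            "chrom": "chr1", "pos": range(1, 13),
            "gene_names": (["GA;GB"] * 4 + ["GA"] * 4 + [""] * 4),
            "gene_groups": (["Body;TSS200"] * 4 + ["Body"] * 4 + [""] * 4),
            "island_relation": "OpenSea",
            "mask_snp": False, "mask_crossreactive": False, "mask_sex": False,
        })
        mapping = map_probes_to_regions(manifest)
        results = _results([(f"p{i}", rng.normal(), 0.001) for i in range(12)])
        calls = call_dmgrs(results, mapping)
        member_lists = [set(p.split(";")) for p in calls["probe_ids"]]
        mapped = set().union(*member_lists)
        assert mapped | set(mapping.unmapped) == {f"p{i}" for i in range(12)}
        for probes, n in zip(member_lists, calls["n_probes"]):
            assert len(probes) == n  # no double contribution within a unit

    def test_empty_mapping_warns(self, caplog):
        empty = ProbeRegionMapping(
            pairs=pd.DataFrame(columns=["probe_id", "gene", "region"]),
            unmapped=[], mode="gene_region")
        with caplog.at_level("WARNING"):
            calls = call_dmgrs(_results([("p1", 0.1, 0.001)]), empty)
        assert calls.empty


class TestIntersection:
    def test_identical_sets(self):
        s = {(f"G{i}", "Body") for i in range(5)}
        res = intersect_strata({c: s for c in "abcd"})
        assert len(res.shared_calls) == 5

    def test_powerset_oracle(self):
        A, B, C, D = ("A", "Body"), ("B", "Body"), ("C", "Body"), ("D", "Body")
        sets = {"s1": {A, B}, "s2": {B, C}, "s3": {B}, "s4": {B, D}}
        res = intersect_strata(sets)
        assert res.shared_calls == {B}
        universe = {A, B, C, D}
        labels = sorted(sets)
        for r in range(1, 5):
            for combo in itertools.combinations(labels, r):
                expected = sum(
                    1 for u in universe
                    if all(u in sets[s] for s in combo)
                    and all(u not in sets[s] for s in labels if s not in combo)
                )
                assert res.overlap_classes[combo] == expected

    def test_shared_is_subset_of_each(self):
        rng = np.random.default_rng(31)
        units = [(f"G{i}", "Body") for i in range(20)]
        sets = {f"s{j}": {u for u in units if rng.random() < 0.6}
                for j in range(4)}
        res = intersect_strata(sets)
        for s in sets.values():
            assert res.shared_calls <= s

    def test_accepts_call_frames(self):
        frame = pd.DataFrame({
            "gene": ["G1", "G2"], "region": ["Body", "Body"],
            "dmgr": [True, False],
        })
        res = intersect_strata({"a": frame, "b": {("G1", "Body")}})
        assert res.shared_calls == {("G1", "Body")}

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError, match="two strata"):
            intersect_strata({"a": set()})
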
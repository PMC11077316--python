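"""Orthogroup clique construction, loss filter, confirm pass, HRA matrix."""

from __future__ import annotations

import pytest

from regenscreen.screen import (
    Orthogroup,
    ScreenConfig,
    ScreenError,
    build_wbr_orthogroups,
    collect_hra_orthologs,
    confirm_absence,
    filter_lost_in_lra,
    run_screen,
)
from regenscreen.similarity import (
    MbhPair,
    Proteome,
    SimilarityHit,
    estimate_evalue,
    local_align_score,
)


def mbh(sa, ga, sb, gb, score=500):
    return MbhPair(sa, ga, sb, gb, score, 1e-30)


WBR3 = ("s1", "s2", "s3")


def config(**kw):
    defaults = dict(wbr=WBR3, hra=("h1",), lra=("l1", "l2"), confirm=("c1",))
    defaults.update(kw)
    return ScreenConfig(**defaults)


class TestBuildWbrOrthogroups:
    def test_complete_clique_emitted(self):
        pairs = {
            ("s1", "s2"): [mbh("s1", "a", "s2", "b")],
            ("s1", "s3"): [mbh("s1", "a", "s3", "c")],
            ("s2", "s3"): [mbh("s2", "b", "s3", "c")],
        }
        groups = build_wbr_orthogroups(pairs, WBR3)
        assert len(groups) == 1
        assert groups[0].members == frozenset({("s1", "a"), ("s2", "b"), ("s3", "c")})
        assert groups[0].anchor == ("s1", "a")

    def test_open_triangle_rejected(self):
        pairs = {
            ("s1", "s2"): [mbh("s1", "a", "s2", "b")],
            ("s2", "s3"): [mbh("s2", "b", "s3", "c")],
            ("s1", "s3"): [],
        }
        assert build_wbr_orthogroups(pairs, WBR3) == []

    def test_missing_pair_list_rejected(self):
        with pytest.raises(ScreenError):
            build_wbr_orthogroups({("s1", "s2"): []}, WBR3)

    def test_component_mode_requires_one_member_per_species(self):
        # transitive MBH edges: clique and component modes agree
        pairs = {
            ("s1", "s2"): [mbh("s1", "a", "s2", "b")],
            ("s1", "s3"): [mbh("s1", "a", "s3", "c")],
            ("s2", "s3"): [mbh("s2", "b", "s3", "c")],
        }
        cl = build_wbr_orthogroups(pairs, WBR3, "clique")
        co = build_wbr_orthogroups(pairs, WBR3, "components")
        assert [g.members for g in cl] == [g.members for g in co]
        # open triangle: the component survives in components mode only
        open_pairs = dict(pairs)
        open_pairs[("s1", "s3")] = []
        assert build_wbr_orthogroups(open_pairs, WBR3, "clique") == []
        co2 = build_wbr_orthogroups(open_pairs, WBR3, "components")
        assert len(co2) == 1

    def test_deterministic_ids_sorted_by_anchor(self):
        pairs = {
            ("s1", "s2"): [mbh("s1", "z", "s2", "zz"), mbh("s1", "a", "s2", "aa")],
            ("s1", "s3"): [mbh("s1", "z", "s3", "zzz"), mbh("s1", "a", "s3", "aaa")],
            ("s2", "s3"): [mbh("s2", "zz", "s3", "zzz"), mbh("s2", "aa", "s3", "aaa")],
        }
        groups = build_wbr_orthogroups(pairs, WBR3)
        assert [g.anchor[1] for g in groups] == ["a", "z"]
        assert [g.group_id for g in groups] == ["OG0001", "OG0002"]


def _group(gid, anchor_gene):
    members = frozenset({("s1", anchor_gene), ("s2", anchor_gene), ("s3", anchor_gene)})
    return Orthogroup(gid, members, ("s1", anchor_gene))


class TestFilterLostInLra:
    def test_hit_below_threshold_removes_group(self):
        g = _group("OG0001", "f1")
        hits = [SimilarityHit("s1", "f1", "l1", "x", 120, 1e-5)]
        assert filter_lost_in_lra([g], hits, config()) == []

    def test_hit_above_threshold_keeps_group(self):
        g = _group("OG0001", "f1")
        hits = [SimilarityHit("s1", "f1", "l1", "x", 80, 2e-4)]
        assert filter_lost_in_lra([g], hits, config()) == [g]

    def test_no_hits_keeps_group(self):
        g = _group("OG0001", "f1")
        assert filter_lost_in_lra([g], [], config()) == [g]

    def test_any_member_any_lra_hit_disqualifies(self):
        g = _group("OG0001", "f1")
        hits = [SimilarityHit("s3", "f1", "l2", "y", 200, 1e-9)]
        assert filter_lost_in_lra([g], hits, config()) == []

    def test_loosening_threshold_never_increases_survivors(self):
        groups = [_group(f"OG{i:04d}", f"f{i}") for i in range(5)]
        hits = [
            SimilarityHit("s1", "f0", "l1", "x", 120, 1e-6),
            SimilarityHit("s1", "f1", "l1", "x", 100, 5e-5),
            SimilarityHit("s1", "f2", "l1", "x", 90, 5e-4),
        ]
        survivors = {}
        for emax in (1e-6, 1e-5, 1e-4, 1e-3):
            cfg = config(evalue_max_loss=emax)
            survivors[emax] = {g.group_id for g in filter_lost_in_lra(groups, hits, cfg)}
        assert survivors[1e-3] <= survivors[1e-4] <= survivors[1e-5] <= survivors[1e-6]


class TestConfirmAbsence:
    def _proteomes(self, member_seq):
        wbr = {f"s{i}": Proteome(f"s{i}", "WBR", {"f1": [("t1", member_seq)]})
               for i in (1, 2, 3)}
        return wbr

    def test_empty_panel_warns_and_passes_through(self):
        g = _group("OG0001", "f1")
        with pytest.warns(UserWarning):
            out, audit = confirm_absence([g], self._proteomes("A" * 10), {}, config())
        assert out == [g] and audit.empty

    def test_boundary_evalue_removes_and_audits(self, scheme):
        # identical 10-residue poly-A: S = 40, E = 0.041*100*e^-10.68 = 9.4e-5
        seq = "A" * 10
        e = estimate_evalue(local_align_score(seq, seq, scheme), 10, 10, scheme)
        assert 9e-5 < e < 1e-4
        g = _group("OG0001", "f1")
        panel = {"c1": Proteome("c1", "CONFIRM", {"x": [("t1", seq)]})}
        out, audit = confirm_absence([g], self._proteomes(seq), panel, config(), scheme)
        assert out == [] and len(audit) == 1
        assert audit.iloc[0]["group_id"] == "OG0001"

    def test_just_above_threshold_retained(self, scheme):
        # 9 residues: E = 2.2e-4 > 1e-4, so the group survives confirmation
        seq = "A" * 9
        e = estimate_evalue(local_align_score(seq, seq, scheme), 9, 9, scheme)
        assert e > 1e-4
        g = _group("OG0001", "f1")
        panel = {"c1": Proteome("c1", "CONFIRM", {"x": [("t1", seq)]})}
        out, audit = confirm_absence([g], self._proteomes(seq), panel, config(), scheme)
        assert out == [g] and audit.empty


class TestCollectHraOrthologs:
    def _setup(self, anchor_seq, hra_seq):
        groups = [Orthogroup("OG0001",
                             frozenset({("s1", "f1"), ("s2", "f1"), ("s3", "f1")}),
                             ("s1", "f1"))]
        proteomes = {
            "s1": Proteome("s1", "WBR", {"f1": [("t1", anchor_seq)]}),
            "h1": Proteome("h1", "HRA", {"g1": [("t1", hra_seq)]}),
        }
        return groups, proteomes

    def test_score_101_present_100_absent(self, scheme):
        # poly-A scores 4/residue: 26 residues -> MBH score 104 > 100
        groups, proteomes = self._setup("A" * 26, "A" * 26)
        assert local_align_score("A" * 26, "A" * 26, scheme) == 104
        m = collect_hra_orthologs(groups, proteomes, config(), scheme)
        assert m.data.loc["OG0001", "h1"] == 1
        # exactly 100 fails the strict inequality
        groups, proteomes = self._setup("A" * 25, "A" * 25)
        assert local_align_score("A" * 25, "A" * 25, scheme) == 100
        m = collect_hra_orthologs(groups, proteomes, config(), scheme)
        assert m.data.loc["OG0001", "h1"] == 0

    def test_no_similarity_absent(self, scheme):
        groups, proteomes = self._setup("A" * 40, "W" * 40)
        m = collect_hra_orthologs(groups, proteomes, config(), scheme)
        assert m.data.loc["OG0001", "h1"] == 0

    def test_wbr_present_lra_absent_columns(self, scheme):
        groups, proteomes = self._setup("A" * 26, "A" * 26)
        m = collect_hra_orthologs(groups, proteomes, config(), scheme)
        for sp in WBR3:
            assert m.data.loc["OG0001", sp] == 1
        for sp in ("l1", "l2", "c1"):
            assert m.data.loc["OG0001", sp] == 0
        m.validate()

    def test_missing_anchor_member_rejected(self, scheme):
        g = Orthogroup("OG0001", frozenset({("s2", "f1")}), ("s2", "f1"))
        proteomes = {
            "s1": Proteome("s1", "WBR", {"f1": [("t1", "A" * 26)]}),
            "h1": Proteome("h1", "HRA", {"g1": [("t1", "A" * 26)]}),
        }
        with pytest.raises(ScreenError):
            collect_hra_orthologs([g], proteomes, config(), scheme)


class TestScreenConfig:
    def test_overlapping_lists_rejected(self):
        with pytest.raises(ScreenError):
            ScreenConfig(wbr=("a", "b"), lra=("b",))

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ScreenError):
            ScreenConfig(wbr=("a",), evalue_max_loss=0.0)
        with pytest.raises(ScreenError):
            ScreenConfig(wbr=("a",), score_min_hra=0)


@pytest.fixture(scope="module")
def result(small_scenario, small_config, scheme):
    proteomes, _ = small_scenario
    return run_screen(proteomes, small_config, scheme)


class TestRunScreenSmallScenario:
    """End-to-end truth recovery on the fast 8-species scenario."""

    def test_initial_groups_are_all_wbr_complete_families(self, result, small_scenario):
        _, truth = small_scenario
        expected = (truth.background_family_ids | truth.cbr_family_ids
                    | truth.paralog_family_ids)
        assert {g.anchor[1] for g in result.initial_groups} == expected

    def test_survivors_equal_planted_cbr(self, result, small_scenario):
        _, truth = small_scenario
        assert result.candidate_families == truth.cbr_family_ids

    def test_paralog_families_removed_by_loss_filter(self, result, small_scenario):
        _, truth = small_scenario
        after = {g.anchor[1] for g in result.after_lra}
        assert not (after & truth.paralog_family_ids)

    def test_hra_presence_equals_planting_pattern(self, result, small_scenario,
                                                  small_config):
        _, truth = small_scenario
        for g in result.confirmed:
            fam = g.anchor[1]
            planted = set(truth.hra_presence_by_family[fam])
            got = {sp for sp in small_config.hra
                   if result.matrix.data.loc[g.group_id, sp] == 1}
            assert got == planted

    def test_matrix_invariant_holds(self, result):
        result.matrix.validate()

    def test_paralog_separation_score_gap(self, small_scenario, scheme, small_config):
        # min over planted families of best within-WBR ortholog score must
        # exceed the max over paralog families of the WBR vs LRA-copy score
        proteomes, truth = small_scenario
        from regenscreen.similarity import select_longest_isoform

        red = {sp: select_longest_isoform(p) for sp, p in proteomes.items()}
        wbr = list(small_config.wbr)
        min_cbr = min(
            max(
                local_align_score(red[a].gene_sequence(fam),
                                  red[b].gene_sequence(fam), scheme)
                for i, a in enumerate(wbr) for b in wbr[i + 1:]
            )
            for fam in truth.cbr_family_ids
        )
        max_par = max(
            local_align_score(
                red[w].gene_sequence(fam),
                red[host].gene_sequence(f"{fam}_par"),
                scheme,
            )
            for fam in truth.paralog_family_ids
            for host in truth.paralog_hosts_by_family[fam]
            for w in wbr
        )
        assert min_cbr > max_par
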
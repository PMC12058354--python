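"""Hit filtering, LCA, rank-threshold refinement and community tabulation."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swabdiv.taxonomy import (
    RANKS,
    CommunityMatrix,
    HitRecord,
    Lineage,
    RankThresholds,
    assign_taxonomy,
    exclude_nontarget,
    filter_hits,
    lca,
    naive_search,
    parse_hits,
    parse_lineage_fasta,
    rank_of,
    tabulate_community,
)

FULL = Lineage("Arthropoda", "Insecta", "Coleoptera", "Curculionidae", "Acalles", "Acalles dubius")
SIBLING = Lineage("Arthropoda", "Insecta", "Coleoptera", "Curculionidae", "Acalles", "Acalles echinatus")
OTHER_FAMILY = Lineage("Arthropoda", "Insecta", "Coleoptera", "Cerambycidae", "Pyrrhidium", "Pyrrhidium sanguineum")
PRIMATE = Lineage("Chordata", "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens")


def _hit(q="q1", s="s1", lineage=FULL, ident=99.0, cov=100.0, e=1e-50, bits=400.0):
    return HitRecord(q, s, lineage, ident, cov, e, bits)


class TestLineage:
    def test_prefix_invariant(self):
        with pytest.raises(ValueError):
            Lineage(phylum="Arthropoda", order="Coleoptera")  # missing class

    def test_truncation(self):
        assert FULL.truncated_to("genus").species is None
        assert FULL.truncated_to("genus").genus == "Acalles"
        assert FULL.truncated_to(None) == Lineage()

    def test_deepest_rank(self):
        assert FULL.deepest_rank() == "species"
        assert FULL.truncated_to("family").deepest_rank() == "family"
        assert Lineage().deepest_rank() is None


def test_parse_lineage_fasta(tmp_path):
    p = tmp_path / "ref.fasta"
    p.write_text(
        ">AB1 root_1;Eukaryota_2759;Arthropoda_6656;Insecta_50557;"
        "Coleoptera_7041;Curculionidae_7042;Acalles_99;Acalles dubius_100\nACGT\n"
        ">AB2###root_1;Eukaryota_2759;Chordata_7711;Mammalia_40674\nACGT\n"
    )
    m = parse_lineage_fasta(p)
    assert m["AB1"] == FULL
    assert m["AB2"] == Lineage("Chordata", "Mammalia")


class TestParseHits:
    def test_thirteen_column_row(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t99.1\t215\t2\t0\t1\t215\t1\t215\t1e-50\t390\t100\n")
        hits, unresolved = parse_hits(p, {"s1": FULL})
        assert len(hits) == 1 and not unresolved
        h = hits[0]
        assert (h.identity, h.coverage) == (99.1, 100.0)
        assert h.evalue == pytest.approx(1e-50)

    def test_unresolved_subject_reported(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\tmissing\t99.1\t215\t2\t0\t1\t215\t1\t215\t1e-50\t390\t100\n")
        hits, unresolved = parse_hits(p, {"s1": FULL})
        assert hits == [] and unresolved == ["missing"]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert parse_hits(p, {}) == ([], [])

    def test_twelve_columns_need_query_lengths(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t99.1\t215\t2\t0\t1\t215\t1\t215\t1e-50\t390\n")
        with pytest.raises(ValueError, match="query_lengths"):
            parse_hits(p, {"s1": FULL})
        hits, _ = parse_hits(p, {"s1": FULL}, query_lengths={"q1": 215})
        assert hits[0].coverage == pytest.approx(100.0)


class TestFilterHits:
    def test_evalue_threshold(self):
        out = filter_hits([_hit(e=1e-2)])
        assert out["q1"] == []

    def test_identity_and_coverage_floors(self):
        out = filter_hits([_hit(ident=79.9), _hit(s="s2", cov=79.0)])
        assert out["q1"] == []

    def test_ties_at_cutoff_all_retained(self):
        hits = [_hit(s=f"s{i}", bits=500 - i) for i in range(19)]
        hits += [_hit(s="s19", bits=400), _hit(s="s20", bits=400)]  # ranks 20, 21 tied
        hits += [_hit(s=f"s{i}", bits=300 - i) for i in range(21, 25)]
        out = filter_hits(hits, top_n=20)
        assert len(out["q1"]) == 21

    def test_sorted_by_bitscore(self):
        out = filter_hits([_hit(s="a", bits=10), _hit(s="b", bits=20)])
        assert [h.subject_id for h in out["q1"]] == ["b", "a"]


class TestLca:
    def test_single_lineage_is_itself(self):
        assert lca([FULL]) == FULL

    def test_two_species_one_genus(self):
        assert lca([FULL, SIBLING]) == FULL.truncated_to("genus")

    def test_sharing_only_order(self):
        assert lca([FULL, OTHER_FAMILY]) == FULL.truncated_to("order")

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            lca([])

    @given(st.lists(st.sampled_from([FULL, SIBLING, OTHER_FAMILY, PRIMATE]), min_size=1, max_size=6))
    def test_idempotent_and_order_invariant(self, lineages):
        result = lca(lineages)
        assert lca([result]) == result
        assert lca(list(reversed(lineages))) == result
        assert lca(lineages + lineages) == result


class TestAssignTaxonomy:
    def test_species_level(self):
        a = assign_taxonomy([_hit(ident=99.2)])
        assert a.assigned_rank == "species" and a.lineage == FULL

    def test_tied_top_hits_lca_to_genus(self):
        hits = [_hit(s="s1", ident=98.6, bits=400), _hit(s="s2", lineage=SIBLING, ident=98.3, bits=400)]
        a = assign_taxonomy(hits)
        assert a.assigned_rank == "genus"
        assert a.top_identity == 98.6
        assert a.n_tied_top_hits == 2

    @pytest.mark.parametrize(
        "ident,rank", [(99.0, "species"), (97.0, "genus"), (92.0, "family"), (85.0, "order")]
    )
    def test_rank_thresholds(self, ident, rank):
        a = assign_taxonomy([_hit(ident=ident)])
        assert a.assigned_rank == rank

    def test_no_hits_unassigned(self):
        a = assign_taxonomy([], query_id="qX")
        assert a.assigned_rank == "unassigned" and a.query_id == "qX"

    def test_rank_monotone_in_identity(self):
        """Raising the top identity never coarsens the assigned rank."""
        depth = {"unassigned": -1, "higher": 0, "order": 1, "family": 2, "genus": 3, "species": 4}
        last = -1
        for ident in [80, 85, 89.9, 90, 92, 95.9, 96, 97.5, 98, 99, 100]:
            a = assign_taxonomy([_hit(ident=ident)])
            assert depth[a.assigned_rank] >= last
            last = depth[a.assigned_rank]


class TestExcludeNontarget:
    def test_insect_kept_primate_excluded(self):
        asg = [
            assign_taxonomy([_hit(ident=99.0)]),
            assign_taxonomy([_hit(q="q2", lineage=PRIMATE, ident=99.0)]),
        ]
        kept, excluded = exclude_nontarget(asg)
        assert [a.query_id for a in kept] == ["q1"]
        assert excluded[0][1] == "nontarget"

    def test_collembola_kept(self):
        springtail = Lineage("Arthropoda", "Collembola", "Entomobryomorpha", "Entomobryidae")
        a = assign_taxonomy([_hit(lineage=springtail, ident=92.0)])
        kept, _ = exclude_nontarget([a])
        assert kept

    def test_unresolved_lineage_too_general(self):
        from swabdiv.taxonomy import TaxonAssignment

        bare = TaxonAssignment("q3", Lineage(), "unassigned", 85.0, 1)
        kept, excluded = exclude_nontarget([bare])
        assert not kept and excluded[0][1] == "too_general"


class TestTabulateCommunity:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["query_id", "sample_id", "reads"])

    def test_same_species_collapses(self):
        a1 = assign_taxonomy([_hit(q="q1", ident=99.0)])
        a2 = assign_taxonomy([_hit(q="q2", ident=98.5)])
        cm = tabulate_community(
            [a1, a2], self._counts([("q1", "s1", 10), ("q2", "s1", 5)])
        )
        assert cm.counts.shape == (1, 1)
        assert cm.counts.iloc[0, 0] == 15

    def test_one_taxon_two_samples(self):
        a1 = assign_taxonomy([_hit(q="q1", ident=99.0)])
        cm = tabulate_community(
            [a1], self._counts([("q1", "s1", 3), ("q1", "s2", 7)])
        )
        assert list(cm.counts["Acalles dubius"]) == [3, 7]

    def test_read_conservation(self):
        a1 = assign_taxonomy([_hit(q="q1", ident=99.0)])
        a2 = assign_taxonomy([_hit(q="q2", lineage=OTHER_FAMILY, ident=91.0)])
        rows = self._counts([("q1", "s1", 10), ("q2", "s1", 20), ("q3", "s1", 5)])
        cm = tabulate_community([a1, a2], rows)  # q3 has no assignment
        assert cm.counts.to_numpy().sum() == 30

    def test_empty(self):
        cm = tabulate_community([], self._counts([]))
        assert cm.counts.empty


@pytest.mark.parametrize(
    "lineage,expected",
    [
        (FULL, "species"),
        (FULL.truncated_to("family"), "family"),
        (FULL.truncated_to("order"), "order"),
        (Lineage("Arthropoda"), "higher"),
    ],
)
def test_rank_of(lineage, expected):
    assert rank_of(lineage) == expected


def test_naive_search_recovers_known_taxa():
    """Error-free queries against a toy reference come back as exact
    species-level assignments of their true taxa."""
    from swabdiv import synthdata

    spec = synthdata.SimSpec(
        n_orders=2, families_per_order=2, genera_per_family=1, species_per_genus=1, seed=9
    )
    _, lineages, seqs = synthdata.make_reference(spec)
    hits = naive_search({f"q_{sid}": s for sid, s in seqs.items()}, seqs, lineages)
    filtered = filter_hits(hits)
    for qid, qhits in filtered.items():
        a = assign_taxonomy(qhits)
        true_sid = qid[2:]
        assert a.assigned_rank == "species"
        assert a.lineage == lineages[true_sid]
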
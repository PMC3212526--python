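import itertools

import pytest

from bhlh_survey import phylo
from bhlh_survey.orthology import (
    InGroupConfig,
    MethodResult,
    MONO,
    NM,
    NM_FAMILY,
    OrthologyError,
    categorize,
    categorize_printed,
    run_ingroup_analysis,
    select_ingroup,
)
from bhlh_survey.simulate import mutate_motif

FAST = InGroupConfig(nj_replicates=200, mp_replicates=50, ml_replicates=200,
                     seed=7)


def _mr(method, partner, bs, flag=None):
    if flag is None:
        flag = MONO if partner else NM
    return MethodResult(method=method, partner=partner, bootstrap=bs,
                        flag=flag)


# ---------------------------------------------------------------------------
# categorisation logic against the published bootstrap patterns


def test_all_methods_strong_is_category_1():
    """The (99, 92, 99) single-partner pattern: unambiguous orthology."""
    res = [_mr("NJ", "Mash1", 99), _mr("MP", "Mash1", 92),
           _mr("ML-surrogate", "Mash1", 99)]
    call = categorize("GpAsh1-like", res)
    assert call.category == 1
    assert call.partner == "Mash1"


def test_one_weak_method_is_category_2():
    """The (90, 21, 82) pattern: two methods above 50, parsimony weak."""
    res = [_mr("NJ", "TCF4", 90), _mr("MP", "TCF4", 21),
           _mr("ML-surrogate", "TCF4", 82)]
    call = categorize("GpTCF4-like", res)
    assert call.category == 2
    assert "MP" in call.sub_label


def test_two_family_only_methods_is_category_3():
    """The (82, n/m*, n/m*) pattern: only one method finds the partner."""
    res = [_mr("NJ", "TF12", 82),
           _mr("MP", None, None, NM_FAMILY),
           _mr("ML-surrogate", None, None, NM_FAMILY)]
    call = categorize("GpTF12-like", res)
    assert call.category == 3


def test_boundary_bootstrap_of_50_counts_as_weak():
    res = [_mr("NJ", "X", 96), _mr("MP", "X", 50),
           _mr("ML-surrogate", None, None, NM_FAMILY)]
    assert categorize("c", res).category == 3
    res2 = [_mr("NJ", "X", 96), _mr("MP", "X", 51),
            _mr("ML-surrogate", None, None, NM_FAMILY)]
    assert categorize("c", res2).category == 2


def test_no_partner_anywhere_is_category_4_and_fallback_runs():
    res = [_mr("NJ", None, None, NM_FAMILY), _mr("MP", None, None, NM),
           _mr("ML-surrogate", None, None, NM)]
    called = {}

    def fallback():
        called["yes"] = True
        return (_mr("NJ", "WholeProt", 88), _mr("MP", "WholeProt", 77),
                _mr("ML-surrogate", "WholeProt", 91))

    call = categorize("c", res, fallback=fallback)
    assert called and call.category == 4
    assert call.partner == "WholeProt"
    assert call.sub_label == "whole-protein"


def test_category_function_is_total():
    """Every flag/support combination maps to exactly one category."""
    options = [
        ("P", 99.0, MONO), ("P", 45.0, MONO), (None, None, NM_FAMILY),
        (None, None, NM),
    ]
    for combo in itertools.product(options, repeat=3):
        res = [
            MethodResult(method=m, partner=p, bootstrap=b, flag=f)
            for m, (p, b, f) in zip(("NJ", "MP", "ML-surrogate"), combo)
        ]
        call = categorize("c", res)
        assert call.category in (1, 2, 3, 4)


def test_raising_a_bootstrap_never_demotes_the_category(rng):
    """Monotonicity: increasing any support keeps or improves category."""
    for _ in range(100):
        supports = rng.integers(0, 101, size=3)
        res = [_mr(m, "P", float(b))
               for m, b in zip(("NJ", "MP", "ML-surrogate"), supports)]
        before = categorize("c", res).category
        k = int(rng.integers(3))
        bumped = list(supports)
        bumped[k] = min(100, bumped[k] + int(rng.integers(1, 50)))
        res2 = [_mr(m, "P", float(b))
                for m, b in zip(("NJ", "MP", "ML-surrogate"), bumped)]
        after = categorize("c", res2).category
        assert after <= before


def test_method_result_invariant():
    with pytest.raises(OrthologyError):
        MethodResult(method="NJ", partner="x", bootstrap=90, flag=NM)


# ---------------------------------------------------------------------------
# printed-table categorisation


def test_printed_patterns_map_to_published_categories():
    assert categorize_printed("99", "92", "99") == 1
    assert categorize_printed("90", "21", "82") == 2
    assert categorize_printed("82", "n/m*", "n/m*") == 3
    assert categorize_printed("60", "40", "n/m*") == 3
    assert categorize_printed("100", "59", "n/m*", whole_protein=True) == 4


def test_printed_table_category_census():
    """Applied to the packaged gene listing the rule reproduces the
    published count of 83 fully supported members and the four
    whole-protein fallback members."""
    from bhlh_survey.introns import load_table1

    t1 = load_table1()
    counts = {}
    for _, row in t1.iterrows():
        c = categorize_printed(row["nj"], row["mp"], row["ml"],
                               row["flag"] == "whole_protein")
        counts[c] = counts.get(c, 0) + 1
    assert counts[1] == 83
    assert counts[4] == 4
    assert sum(counts.values()) == 107


# ---------------------------------------------------------------------------
# in-group analysis on synthetic references


def test_candidate_identical_to_reference_pairs_with_it(mouse_set, outgroup):
    """A candidate equal to one reference forms a full-support NJ cherry
    with exactly that reference."""
    fam = [r for r in mouse_set if r.family == "MyoD"]
    others = [r for r in mouse_set if r.family == "Oligo"][:4]
    ingroup = fam + others
    cand = fam[1].sequence
    res = run_ingroup_analysis("cand", cand, ingroup, outgroup, FAST)
    nj = res[0]
    assert nj.method == "NJ"
    assert nj.partner == fam[1].id
    assert nj.bootstrap == 100.0


def test_mutated_candidate_recovers_its_member(mouse_set, outgroup):
    fam = [r for r in mouse_set if r.family == "Mad"]
    others = [r for r in mouse_set if r.family == "Myc"][:3]
    cand = mutate_motif(fam[2], 0.05, True, 5)
    res = run_ingroup_analysis("cand", cand, fam + others, outgroup, FAST)
    call = categorize("cand", res, {r.id: r for r in fam + others})
    assert call.partner == fam[2].id
    assert call.family == "Mad"
    assert call.category <= 2


def test_symmetric_candidate_gets_family_monophyly_flag(outgroup):
    """A candidate exactly between two references cannot resolve a single
    partner; it must carry the family-level n/m* flag (or n/m), not a
    partner."""
    from bhlh_survey.catalog import ReferenceMotif

    # the two family members form a tight cherry; the candidate is exactly
    # equidistant from both and attaches outside the cherry
    a = "DD" + "A" * 58
    b = "AADD" + "A" * 56
    cand = "A" * 20 + "W" * 10 + "A" * 30
    refs = [
        ReferenceMotif("famA_1", "Myc", "B", a),
        ReferenceMotif("famA_2", "Myc", "B", b),
        ReferenceMotif("other_1", "Max", "B",
                       "".join("KRHED"[(i * 7) % 5] for i in range(60))),
    ]
    res = run_ingroup_analysis("cand", cand, refs, outgroup, FAST)
    nj = res[0]
    assert nj.partner is None
    assert nj.flag in (NM_FAMILY, NM)


def test_select_ingroup_returns_nearest_family(mouse_set, outgroup):
    """A candidate planted inside one family selects that family (plus
    enough neighbours to fill the in-group)."""
    cand_seq = mutate_motif(
        [r for r in mouse_set if r.family == "HIF"][0], 0.03, True, 9
    )
    labels = ["cand"] + [r.id for r in mouse_set] + [outgroup.id]
    seqs = [cand_seq] + [r.sequence for r in mouse_set] + [outgroup.sequence]
    tree = phylo.neighbor_joining(phylo.pairwise_distances(labels, seqs))
    ingroup = select_ingroup("cand", tree, mouse_set, min_ingroup=4)
    assert {r.family for r in ingroup} >= {"HIF"}
    assert len([r for r in ingroup if r.family == "HIF"]) == len(
        [r for r in mouse_set if r.family == "HIF"]
    )


def test_select_ingroup_unknown_candidate(mouse_set):
    labels = [r.id for r in mouse_set[:5]]
    seqs = [r.sequence for r in mouse_set[:5]]
    tree = phylo.neighbor_joining(phylo.pairwise_distances(labels, seqs))
    with pytest.raises(OrthologyError, match="ghost"):
        select_ingroup("ghost", tree, mouse_set)


def test_figure_s3_style_ingroup(mouse_set, outgroup):
    """One candidate plus nine same-group references and the outgroup:
    the analysis pairs the candidate with its source member in all three
    methods with strong support (the published GpAsh1 setup)."""
    group_a = [r for r in mouse_set if r.group == "A"]
    fam = [r for r in group_a if r.family == "ASCa"]
    fill = [r for r in group_a if r.family in ("ASCb", "MyoD")][: 9 - len(fam)]
    ingroup = fam + fill
    assert len(ingroup) == 9
    cand = mutate_motif(fam[0], 0.04, True, 21)
    res = run_ingroup_analysis("GpAsh1-like", cand, ingroup, outgroup, FAST)
    call = categorize("GpAsh1-like", res, {r.id: r for r in ingroup})
    assert call.partner == fam[0].id
    assert call.category <= 2
    assert all(r.flag == MONO for r in res if r.method == "NJ")
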
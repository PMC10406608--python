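"""Repertoire classifiers: boundary behaviour and planted exactness."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genecontent.classify import (
    classify_hgs,
    classify_ssp,
    classify_tf,
    classify_transporter,
    conservation,
    dynamics_rank,
    fungal_specific_domains,
    hg_fungal_domain_flag,
    majority_annotation,
    novel_core,
    protist_conserved_lost,
    shannon_diversity,
)
from genecontent.dollo import aggregate_events
from genecontent.simulate import (
    FamilyProfile,
    simulate_annotations,
    simulate_gene_content,
    simulate_species_tree,
)
from genecontent.trees import Tree


# ------------------------------------------------------------- conservation


@pytest.mark.parametrize(
    "present,group_size,expected",
    [(7, 10, 0.70), (0, 10, 0.0), (10, 10, 1.0)],
)
def test_conservation_fraction(present, group_size, expected):
    group = {f"s{i}" for i in range(group_size)}
    hg = {f"s{i}" for i in range(present)}
    assert conservation(hg, group) == pytest.approx(expected)


def test_conservation_rejects_empty_group():
    with pytest.raises(ValueError):
        conservation({"x"}, set())


# ------------------------------------------------------------ majority rules


@pytest.mark.parametrize(
    "flags,expected",
    [
        ([True, True, False, False], False),  # exactly 50% is not a majority
        ([True, True, True, False], True),
        ([True], True),
        ([False, False], False),
    ],
)
def test_majority_is_strict(flags, expected):
    assert majority_annotation(flags) is expected


def test_majority_of_empty_group_rejected():
    with pytest.raises(ValueError):
        majority_annotation([])


# ---------------------------------------------------------- fungal domains


def test_fungal_specific_domain_thresholds():
    table = pd.DataFrame(
        {
            "Holomycota": [99, 98, 100, 0],
            "Holozoa": [1, 2, 0, 0],
        },
        index=["d99", "d98", "d100", "dzero"],
    )
    with pytest.warns(RuntimeWarning, match="zero-count"):
        out = fungal_specific_domains(table)
    assert out == {"d99", "d100"}


@pytest.mark.parametrize(
    "carriers,total,expected",
    [(3, 4, True), (0, 4, False), (4, 4, True), (2, 4, False)],
)
def test_hg_fungal_domain_75_percent_rule(carriers, total, expected):
    doms = [{"fsd"} if i < carriers else set() for i in range(total)]
    assert hg_fungal_domain_flag(doms, {"fsd"}) is expected


# ------------------------------------------------------------- TF calling


def test_tf_family_from_majority_dbd():
    doms = [{"C2H2"}] * 3 + [set()] * 2  # 60% carry the DBD
    fam = classify_tf(doms, {"C2H2": "C2H2-like"}, set())
    assert fam == "C2H2-like"


def test_tf_vetoed_by_exclusion_domain():
    doms = [{"C2H2", "M12-peptidase"}] * 3 + [set()] * 2
    fam = classify_tf(doms, {"C2H2": "C2H2-like"}, {"M12-peptidase"})
    assert fam is None


def test_no_dbd_no_tf():
    assert classify_tf([set(), {"other"}], {"C2H2": "C2H2-like"}, set()) is None


# ------------------------------------------------------------- transporters


def _locs(label, score, n):
    return [(label, score)] * n


def test_transporter_requires_pm_mode_and_score():
    doms = [{"MFS"}] * 7 + [set()] * 3
    assert classify_transporter(doms, {"MFS"}, _locs("plasma membrane", 20, 10))
    assert not classify_transporter(doms, {"MFS"}, _locs("cytosol", 20, 10))
    assert not classify_transporter(doms, {"MFS"}, _locs("plasma membrane", 15, 10))
    assert not classify_transporter([set()] * 10, {"MFS"}, _locs("plasma membrane", 20, 10))


def test_transporter_localization_tie_fails():
    doms = [{"MFS"}] * 4
    locs = [("plasma membrane", 20.0)] * 2 + [("cytosol", 20.0)] * 2
    assert not classify_transporter(doms, {"MFS"}, locs)


# --------------------------------------------------------------------- SSP


@pytest.mark.parametrize(
    "length,sp,tm,expected",
    [(299, True, False, True), (300, True, False, False),
     (100, True, True, False), (100, False, False, False)],
)
def test_ssp_rule(length, sp, tm, expected):
    assert classify_ssp(length, sp, tm) is expected


# -------------------------------------------------- conserved / novel sets


def _toy_event_setup():
    t = Tree.from_newick("(((A,B),(C,D)),(E,F));")
    # f_lost: in protist side {E,F} + early clade, absent in "Dikarya" {C,D}
    fams = pd.DataFrame(
        {
            "A": [1, 1, 0],
            "B": [1, 1, 0],
            "C": [0, 1, 1],
            "D": [0, 1, 1],
            "E": [1, 0, 0],
            "F": [1, 0, 0],
        },
        index=["f_lost", "f_novel", "f_dikarya"],
    )
    em = aggregate_events(fams, t)
    return t, fams, em


def test_protist_conserved_lost_planted():
    t, fams, em = _toy_event_setup()
    holomycota = t.mrca_tips(["A", "B", "C", "D"])
    # f_lost emerged at the root (above the Holomycota node) and is absent
    # from the Dikarya species C, D
    hg_species = {
        f: set(fams.columns[fams.loc[f] > 0]) for f in fams.index
    }
    groups = {"protists": {"E", "F"}, "early": {"A", "B"}}
    out = protist_conserved_lost(
        hg_species, groups, em, dikarya_species={"C", "D"},
        holomycota_node=holomycota,
    )
    assert out == {"f_lost"}


def test_novel_core_requires_late_origin_and_conservation():
    t, fams, em = _toy_event_setup()
    reference = t.mrca_tips(["A", "B", "C", "D"])  # "LUFA"
    hg_species = {f: set(fams.columns[fams.loc[f] > 0]) for f in fams.index}
    out = novel_core(em.family_gain_node, hg_species, t, reference)
    # f_dikarya gained at MRCA(C,D), strictly below the reference, fully kept
    assert out == {"f_dikarya"}


def test_novel_core_conservation_boundary(balanced4):
    gain = balanced4.mrca_tips(["A", "B"])
    gains = {"h": gain}
    assert novel_core(gains, {"h": {"A", "B"}}, balanced4, balanced4.root) == {"h"}
    # half of the clade (< 70%) is not enough
    assert novel_core(gains, {"h": {"A"}}, balanced4, balanced4.root) == set()
    # origin at the reference node itself never counts
    at_ref = {"h": balanced4.root}
    assert novel_core(at_ref, {"h": {"A", "B", "C", "D"}}, balanced4, balanced4.root) == set()


# ----------------------------------------------------------------- dynamics


def test_dynamics_rank_formula(caterpillar5):
    t = caterpillar5
    path = [t.root]
    while not t.is_tip(path[-1]):
        path.append(t.children[path[-1]][0])
    fams = pd.DataFrame(
        {"A": [1, 2, 1], "B": [1, 2, 0], "C": [1, 1, 0],
         "D": [1, 1, 0], "E": [1, 1, 0]},
        index=["flat", "doubled", "tipgain"],
    )
    em = aggregate_events(fams, t)
    ranked = dynamics_rank(em, path)
    scores = dict(zip(ranked["hg"], ranked["net_change_score"]))
    assert scores["flat"] == 0
    assert scores["doubled"] == pytest.approx(1.0)  # 1 -> 2 on one branch


def test_dynamics_rank_rejects_non_chain(balanced4):
    t = balanced4
    fams = pd.DataFrame({"A": [1], "B": [1], "C": [1], "D": [1]}, index=["f"])
    em = aggregate_events(fams, t)
    a, b = t.tip_index()["A"], t.tip_index()["B"]
    with pytest.raises(ValueError, match="chain"):
        dynamics_rank(em, [a, b])


def test_newly_gained_family_contributes_its_copy_count(balanced4):
    t = balanced4
    ab = t.mrca_tips(["A", "B"])
    fams = pd.DataFrame({"A": [3], "B": [3], "C": [0], "D": [0]}, index=["f"])
    em = aggregate_events(fams, t)
    ranked = dynamics_rank(em, [t.root, ab])
    # parent copies 0 -> denominator clamped to 1; contribution = 3
    assert ranked["net_change_score"].iloc[0] == pytest.approx(3.0)


# ------------------------------------------------------------------ shannon


@pytest.mark.parametrize(
    "counts,expected",
    [([5], 0.0), ([1, 1], math.log(2)), ([3, 1], 0.5623351446188083)],
)
def test_shannon_values(counts, expected):
    assert shannon_diversity(counts) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=8))
def test_shannon_bounded_by_log_richness(counts):
    if sum(counts) == 0:
        with pytest.raises(ValueError):
            shannon_diversity(counts)
        return
    h = shannon_diversity(counts)
    k = sum(1 for c in counts if c > 0)
    assert -1e-12 <= h <= math.log(k) + 1e-12
    if k > 1 and len(set(c for c in counts if c > 0)) == 1:
        assert h == pytest.approx(math.log(k))


# ---------------------------------------- planted end-to-end classification


def test_planted_positives_and_negatives_classified_exactly():
    t = simulate_species_tree(6, seed=42)
    m, _ = simulate_gene_content(
        t, duplication_rate=0.0, loss_rate=0.0, n_families=8, seed=43,
        origin="root",
    )
    fams = list(m.index)
    profiles = {
        fams[0]: FamilyProfile(domains={"ZnF": 1.0}, localization="nucleus"),
        fams[1]: FamilyProfile(
            domains={"MFS": 1.0}, localization="plasma membrane",
            loc_score=(25.0, 0.5),
        ),
        fams[2]: FamilyProfile(
            localization="extracellular", signal_peptide_prob=1.0,
            length=(150, 10),
        ),
        fams[3]: FamilyProfile(
            domains={"ZnF": 1.0, "PepM": 1.0}, localization="nucleus"
        ),
    }
    ann = simulate_annotations(m, profiles=profiles, seed=44)
    membership = dict(zip(ann["protein"], ann["family"]))
    table = classify_hgs(
        ann,
        membership,
        dbd_families={"ZnF": "Zn-finger"},
        exclusion_domains={"PepM"},
        transporter_domains={"MFS"},
    ).set_index("hg")
    assert table.loc[fams[0], "tf_family"] == "Zn-finger"
    assert table.loc[fams[1], "transporter"]
    assert table.loc[fams[2], "ssp"] and table.loc[fams[2], "extracellular"]
    assert table.loc[fams[3], "tf_family"] is None  # vetoed planted negative
    negatives = [f for f in fams[4:]]
    assert not table.loc[negatives, "transporter"].any()
    assert not table.loc[negatives, "ssp"].any()
    assert (table.loc[negatives, "tf_family"].isna()).all()


def test_classifiers_are_order_independent():
    t = simulate_species_tree(5, seed=50)
    m, _ = simulate_gene_content(t, n_families=6, seed=51, loss_rate=0.0)
    ann = simulate_annotations(m, seed=52)
    membership = dict(zip(ann["protein"], ann["family"]))
    a = classify_hgs(ann, membership)
    b = classify_hgs(ann.sample(frac=1, random_state=7), membership)
    pd.testing.assert_frame_equal(
        a.sort_values("hg").reset_index(drop=True),
        b.sort_values("hg").reset_index(drop=True),
    )
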
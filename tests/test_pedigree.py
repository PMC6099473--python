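"""Kinship, inbreeding and pedigree-structure unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socped.pedigree import (
    Pedigree,
    PedigreeRecord,
    PedigreeValidationError,
    read_pedigree,
    write_pedigree,
)

from conftest import grandmother_pedigree, half_sib_pedigree, trio_pedigree


# ------------------------------------------------------------- exact values

@pytest.mark.parametrize(
    "ped_factory, op, args, expected",
    [
        (trio_pedigree, "inbreeding", ("incest_off",), 0.25),
        (half_sib_pedigree, "inbreeding", ("y",), 0.125),
        (grandmother_pedigree, "kinship", ("gm", "gs"), 0.125),
        (trio_pedigree, "kinship", ("sire", "dam"), 0.0),
        (trio_pedigree, "kinship", ("sire", "sire"), 0.5),
        (trio_pedigree, "kinship", ("dam", "daughter"), 0.25),
        (half_sib_pedigree, "inbreeding", ("s",), 0.0),
    ],
)
def test_analytic_identities(ped_factory, op, args, expected):
    """Textbook kinship/inbreeding values on toy pedigrees are exact."""
    ped = ped_factory()
    if op == "inbreeding":
        assert ped.inbreeding(*args).f == pytest.approx(expected, abs=1e-15)
    else:
        assert ped.kinship(*args).kinship == pytest.approx(expected, abs=1e-15)


def test_self_kinship_of_inbred_individual():
    ped = trio_pedigree()
    # k(i,i) = (1 + f)/2 with f = 0.25
    assert ped.kinship("incest_off", "incest_off").kinship == pytest.approx(0.625)


def test_kinship_unknown_id_raises():
    with pytest.raises(KeyError):
        trio_pedigree().kinship("sire", "nobody")


# ------------------------------------------------------------- validation

def test_duplicate_id_rejected():
    with pytest.raises(PedigreeValidationError, match="duplicate"):
        Pedigree([PedigreeRecord("a"), PedigreeRecord("a")])


def test_self_parentage_rejected():
    with pytest.raises(PedigreeValidationError, match="self-parentage"):
        Pedigree([PedigreeRecord("a", sire="a")])


def test_cycle_rejected():
    # a is its own grandparent via b
    with pytest.raises(PedigreeValidationError, match="cycle"):
        Pedigree([
            PedigreeRecord("a", sire="b"),
            PedigreeRecord("b", sire="a"),
        ])


def test_sex_inconsistent_parent_rejected():
    with pytest.raises(PedigreeValidationError, match="female"):
        Pedigree([
            PedigreeRecord("mom", sex="female"),
            PedigreeRecord("kid", sire="mom"),
        ])


# -------------------------------------------------------------------- IO

@pytest.mark.parametrize("dialect", ["csv", "linkage"])
def test_roundtrip_simulated_pedigree(tmp_path, small_study, dialect):
    """Simulator output survives a write/read cycle unchanged."""
    ped = small_study.pedigree
    path = tmp_path / f"ped.{dialect}"
    write_pedigree(ped, path, dialect=dialect)
    back = read_pedigree(path, dialect=dialect)
    assert set(back.ids) == set(ped.ids)
    for i in ped.ids:
        assert back.parents(i) == ped.parents(i)
        assert back[i].sex == ped[i].sex
        if dialect == "csv":
            assert back[i].cohort == ped[i].cohort


def test_read_trio_csv(tmp_path):
    p = tmp_path / "trio.csv"
    p.write_text("id,sire,dam,cohort,sex\nc,s,d,2000,male\ns,,,1999,male\nd,,,1999,female\n")
    ped = read_pedigree(p)
    assert len(ped) == 3
    assert ped.parents("c") == ("s", "d")
    assert ped.is_founder("s")


def test_read_cycle_file_rejected(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("id,sire,dam,cohort,sex\na,b,,,male\nb,a,,,male\n")
    with pytest.raises(PedigreeValidationError, match="cycle"):
        read_pedigree(p)


# ------------------------------------------------- relationship matrix / A

def test_trio_relationship_matrix():
    ped = Pedigree([
        PedigreeRecord("f1", sex="male"),
        PedigreeRecord("f2", sex="female"),
        PedigreeRecord("c", "f1", "f2"),
    ])
    A = ped.relationship_matrix(["f1", "f2", "c"])
    expect = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
    np.testing.assert_allclose(A, expect, atol=1e-12)


def test_inbred_diagonal_is_one_plus_f():
    ped = half_sib_pedigree()
    A = ped.relationship_matrix(["y"])
    assert A[0, 0] == pytest.approx(1.125)


def test_tabular_equals_recursive_on_simulated_pedigree(small_study):
    """Cross-algorithm oracle: A[i,j] == 2 k(i,j) element-wise."""
    ped = small_study.pedigree
    rng = np.random.default_rng(0)
    focal = list(rng.choice(ped.ids, size=25, replace=False))
    ids = sorted(ped.ancestors(*focal), key=ped.ids.index)[:200]
    # keep the set ancestrally closed after truncation
    ids = sorted(ped.ancestors(*ids), key=ped.ids.index)
    A = ped.relationship_matrix(ids)
    for a in range(0, len(ids), 7):
        for b in range(a, len(ids), 11):
            k = ped.kinship(ids[a], ids[b]).kinship
            assert abs(A[a, b] - 2 * k) < 1e-9
    # PSD up to numerical tolerance
    w = np.linalg.eigvalsh(A)
    assert w.min() > -1e-8


def test_inbreeding_all_matches_pairwise_recursion(small_study):
    ped = small_study.pedigree
    f_all = ped.inbreeding_all()
    rng = np.random.default_rng(1)
    for i in rng.choice(ped.ids, size=60, replace=False):
        assert f_all[i] == pytest.approx(ped.inbreeding(i).f, abs=1e-12)


def test_f_values_are_dyadic_rationals(small_study):
    """Finite-pedigree f values are dyadic; scaling by 2^40 gives integers."""
    f_all = small_study.pedigree.inbreeding_all()
    scaled = np.array(list(f_all.values())) * 2.0**40
    np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-3)


# --------------------------------------------------------------- gene drop

def test_gene_drop_matches_exact_kinship():
    ped = trio_pedigree()
    res = ped.gene_drop_kinship("dam", "incest_off", n_reps=100_000, seed=42)
    exact = ped.kinship("dam", "incest_off").kinship
    assert abs(res.estimate - exact) < 4 * max(res.se, 1e-6)


def test_gene_drop_founders_exactly_zero():
    ped = trio_pedigree()
    res = ped.gene_drop_kinship("sire", "dam", n_reps=5000, seed=0)
    assert res.estimate == 0.0


def test_gene_drop_deterministic_given_seed():
    ped = half_sib_pedigree()
    a = ped.gene_drop_kinship("a", "b", n_reps=20_000, seed=9)
    b = ped.gene_drop_kinship("a", "b", n_reps=20_000, seed=9)
    assert a.estimate == b.estimate


def test_gene_drop_requires_reps():
    with pytest.raises(ValueError):
        trio_pedigree().gene_drop_kinship("sire", "dam", n_reps=0)


# ----------------------------------------------- completeness / restriction

def test_known_grandparent_counts():
    ped = Pedigree([
        PedigreeRecord("g1", sex="male"), PedigreeRecord("g2", sex="female"),
        PedigreeRecord("g3", sex="male"), PedigreeRecord("g4", sex="female"),
        PedigreeRecord("p1", "g1", "g2", sex="male"),
        PedigreeRecord("p2", "g3", "g4", sex="female"),
        PedigreeRecord("kid", "p1", "p2"),
    ])
    assert ped.known_grandparent_count("g1") == 0  # founder
    assert ped.known_grandparent_count("p1") == 0  # parents are founders
    assert ped.known_grandparent_count("kid") == 4


def test_restriction_monotone_and_correct(small_study):
    ped = small_study.pedigree
    sets = [ped.restrict(m) for m in range(5)]
    for lo, hi in zip(sets[1:], sets[:-1]):
        assert lo <= hi
    for i in sets[4]:
        assert ped.known_grandparent_count(i) == 4
    for i in sets[0]:
        s, d = ped.parents(i)
        assert s is not None and d is not None


def test_inbred_fraction_rises_with_restriction(default_study):
    """Tighter completeness restrictions concentrate detectable inbreeding."""
    ped = default_study.pedigree
    f_all = ped.inbreeding_all()
    measured = set(default_study.nestlings["id"])
    fracs = []
    for m in (0, 1, 3):
        ids = ped.restrict(m) & measured
        fracs.append(np.mean([f_all[i] > 1e-12 for i in ids]))
    assert fracs[0] <= fracs[1] + 0.01
    assert fracs[2] > fracs[0]


# ------------------------------------------------------------- route labels

def test_relationship_labels():
    trio = trio_pedigree()
    assert trio.classify_relationship("sire", "daughter") == "father_daughter"
    assert trio.classify_relationship("incest_off", "daughter") == "mother_son"
    assert trio.classify_relationship("sire", "dam") == "unrelated"
    hs = half_sib_pedigree()
    assert hs.classify_relationship("a", "b") == "paternal_half_sib"
    gm = grandmother_pedigree()
    assert gm.classify_relationship("gs", "gm") == "grandmother_grandson"
    # label-implied kinship agrees with the kinship operation
    assert gm.kinship("gs", "gm").kinship == pytest.approx(0.125)


def test_grandfather_granddaughter_label():
    ped = Pedigree([
        PedigreeRecord("gf", sex="male"), PedigreeRecord("gm", sex="female"),
        PedigreeRecord("son", "gf", "gm", sex="male"),
        PedigreeRecord("w", sex="female"),
        PedigreeRecord("gd", "son", "w", sex="female"),
    ])
    assert ped.classify_relationship("gf", "gd") == "grandfather_granddaughter"


def test_other_related_label():
    # great-grandmother: related (k = 0.0625) but no named route
    ped = Pedigree([
        PedigreeRecord("ggm", sex="female"), PedigreeRecord("x1", sex="male"),
        PedigreeRecord("gm2", "x1", "ggm", sex="female"),
        PedigreeRecord("x2", sex="male"),
        PedigreeRecord("mom", "x2", "gm2", sex="female"),
        PedigreeRecord("x3", sex="male"),
        PedigreeRecord("boy", "x3", "mom", sex="male"),
    ])
    assert ped.classify_relationship("boy", "ggm") == "other_related"


# ---------------------------------------------------------- property tests

@st.composite
def random_pedigrees(draw):
    """Random valid pedigrees: each individual may draw parents from the
    preceding individuals (males as sires, females as dams)."""
    n = draw(st.integers(min_value=2, max_value=40))
    sexes = draw(st.lists(st.sampled_from(["male", "female"]),
                          min_size=n, max_size=n))
    records = []
    males, females = [], []
    for k in range(n):
        name = f"i{k}"
        sire = dam = None
        if males and draw(st.booleans()):
            sire = draw(st.sampled_from(males))
        if females and draw(st.booleans()):
            dam = draw(st.sampled_from(females))
        records.append(PedigreeRecord(name, sire, dam, sex=sexes[k]))
        (males if sexes[k] == "male" else females).append(name)
    return Pedigree(records)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(random_pedigrees(), st.data())
def test_kinship_symmetry_and_consistency(ped, data):
    ids = ped.ids
    i = data.draw(st.sampled_from(ids))
    j = data.draw(st.sampled_from(ids))
    kij = ped.kinship(i, j).kinship
    assert kij == ped.kinship(j, i).kinship
    assert kij >= 0.0
    # f equals parental kinship; missing parent means f = 0
    s, d = ped.parents(i)
    f = ped.inbreeding(i).f
    if s is None or d is None:
        assert f == 0.0
    else:
        assert f == pytest.approx(ped.kinship(s, d).kinship, abs=1e-15)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(random_pedigrees())
def test_tabular_matches_recursive_everywhere(ped):
    ids = ped.ids
    A = ped.relationship_matrix(ids)
    for a in range(len(ids)):
        for b in range(a, len(ids)):
            assert abs(A[a, b] - 2 * ped.kinship(ids[a], ids[b]).kinship) < 1e-9
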
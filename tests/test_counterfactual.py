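"""Faithful-pedigree counterfactual, contingency tables, Fisher's exact
test (with a full-enumeration oracle) and the hurdle model."""

import itertools

import numpy as np
import pytest
from scipy import stats

from socped import counterfactual as cf
from socped.pedigree import Pedigree, PedigreeRecord, PedigreeValidationError

from conftest import annotate_nestlings


def _ms_toy():
    """Mother-son social pair whose offspring has a distant genetic sire."""
    ped = Pedigree([
        PedigreeRecord("mom", sex="female"),
        PedigreeRecord("m1", sex="male"),
        PedigreeRecord("son", "m1", "mom", sex="male"),
        PedigreeRecord("m2", sex="male"),
        PedigreeRecord("off", "m2", "mom", sex="female"),
    ])
    assignments = [cf.SocialAssignment("off", "son", "m2")]
    return ped, assignments


def test_faithful_substitution_mother_son_gives_quarter():
    """An extra-pair offspring of a mother-son social pair becomes, in
    the faithful pedigree, the child of the son: f = k(mom, son) = 0.25."""
    ped, assignments = _ms_toy()
    assert ped.inbreeding("off").f == 0.0
    faithful = cf.build_faithful_pedigree(ped, assignments)
    assert faithful.inbreeding("off").f == pytest.approx(0.25)


def test_faithful_identity_when_social_equals_genetic():
    ped, _ = _ms_toy()
    assignments = [cf.SocialAssignment("off", "m2", "m2")]
    faithful = cf.build_faithful_pedigree(ped, assignments)
    assert faithful.parents("off") == ped.parents("off")
    assert assignments[0].ep_status == "WP"


def test_faithful_substitution_cycle_detected():
    # social father is the offspring's own descendant
    ped = Pedigree([
        PedigreeRecord("mom", sex="female"),
        PedigreeRecord("m1", sex="male"),
        PedigreeRecord("off", "m1", "mom", sex="female"),
        PedigreeRecord("m3", sex="male"),
        PedigreeRecord("grandson", "m3", "off", sex="male"),
    ])
    with pytest.raises(PedigreeValidationError, match="faithful"):
        cf.build_faithful_pedigree(
            ped, [cf.SocialAssignment("off", "grandson", "m1")]
        )


def test_faithful_idempotent_on_simulated_study(small_study):
    ped = small_study.pedigree
    assignments = cf.assignments_from_study(
        ped, small_study.broods, small_study.nestlings
    )
    once = cf.build_faithful_pedigree(ped, assignments)
    twice = cf.build_faithful_pedigree(once, assignments)
    assert once.inbreeding_all() == twice.inbreeding_all()


def test_one_generation_variant(small_study):
    ped, assignments = _ms_toy()
    f1 = cf.faithful_f_one_generation(ped, assignments)
    assert f1["off"] == pytest.approx(0.25)


def test_faithful_raises_inbreeding_on_defaults(default_study):
    """Had all females been faithful, more offspring would be inbred."""
    ped = default_study.pedigree
    nestlings = default_study.nestlings
    ids = ped.restrict(1) & set(nestlings["id"])
    assignments = cf.assignments_from_study(ped, default_study.broods, nestlings)
    faithful = cf.build_faithful_pedigree(ped, assignments)
    con = cf.inbreeding_contrast(ped, faithful, ids, assignments)
    counts = con.observed_faithful.counts
    assert counts[1, 0] >= counts[0, 0]  # faithful inbred >= observed inbred
    assert counts.sum(axis=1)[0] == counts.sum(axis=1)[1] == len(ids)
    # faithful f is defined and non-negative for every id
    assert all(v >= 0 for v in con.f_faithful.values())
    # WPO are more often inbred than EPO in this kin-structured system
    we = con.wp_ep.counts
    wp_rate = we[0, 0] / we[0].sum()
    ep_rate = we[1, 0] / we[1].sum()
    assert wp_rate > ep_rate


def test_zero_epp_means_no_substitution():
    from socped.simulate import SimulationParams, simulate_population

    params = SimulationParams(
        n_territories=20, n_years=10, seed=4,
        epp_logit=(-30.0, 0.0, 0.0), epp_brood_sd=0.0,
        force_mother_son_epp=False,
    )
    study = simulate_population(params)
    assert study.nestlings["ep_status"].eq("WP").all()
    ped = study.pedigree
    assignments = cf.assignments_from_study(ped, study.broods, study.nestlings)
    faithful = cf.build_faithful_pedigree(ped, assignments)
    ids = set(study.nestlings["id"])
    con = cf.inbreeding_contrast(ped, faithful, ids, assignments)
    assert (con.observed_faithful.counts[0] == con.observed_faithful.counts[1]).all()


# -------------------------------------------------------------- tables

def test_contingency_table_margins_and_percentages():
    t = cf.ContingencyTable2x2(
        np.array([[130, 1597], [115, 2589]]), ("WP", "EP"), ("inbred", "outbred")
    )
    assert t.total == 4431
    np.testing.assert_array_equal(t.row_totals, [1727, 2704])
    pcts = t.row_percentages()
    assert pcts[0, 0] == pytest.approx(7.527, abs=0.01)
    assert pcts[1, 0] == pytest.approx(4.253, abs=0.01)


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        cf.ContingencyTable2x2(np.array([[1, 2, 3], [4, 5, 6]]), ("a", "b"), ("c", "d"))
    with pytest.raises(ValueError):
        cf.ContingencyTable2x2(np.array([[-1, 2], [3, 4]]), ("a", "b"), ("c", "d"))


# ---------------------------------------------------------------- fisher

def _enumerated_two_sided_p(table):
    """Oracle: sum hypergeometric probabilities <= that of the observed
    table, enumerating the whole conditional distribution."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_matches_enumeration_on_all_small_tables():
    hits = 0
    for a, b, c, d in itertools.product(range(5), repeat=4):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        t = cf.ContingencyTable2x2(np.array([[a, b], [c, d]]), ("r1", "r2"), ("c1", "c2"))
        res = cf.fisher_exact(t)
        assert res.p_value == pytest.approx(
            _enumerated_two_sided_p(np.array([[a, b], [c, d]])), abs=1e-9
        )
        assert 0 < res.p_value <= 1
        hits += 1
    assert hits > 300


def test_fisher_identical_rows_p_one():
    t = cf.ContingencyTable2x2(np.array([[7, 13], [7, 13]]), ("a", "b"), ("c", "d"))
    assert cf.fisher_exact(t).p_value == pytest.approx(1.0)


def test_fisher_zero_margin_flagged():
    t = cf.ContingencyTable2x2(np.array([[0, 10], [0, 12]]), ("a", "b"), ("c", "d"))
    res = cf.fisher_exact(t)
    assert res.p_value == 1.0
    assert np.isnan(res.odds_ratio)
    assert res.flags


# ---------------------------------------------------------------- hurdle

def test_hurdle_wp_more_inbred_on_defaults(default_nestlings):
    """Stage 1: within-pair offspring are more likely to be inbred than
    extra-pair offspring (positive WP log-odds, CI excluding zero)."""
    s1, s2 = cf.fit_hurdle_inbreeding(default_nestlings, exclude_mother_son=True)
    assert s1.params["WP"] > 0
    assert not s1.covers("WP", 0.0)
    assert s2 is not None
    assert s2.n_obs >= 30


def test_hurdle_null_when_no_kin_structure():
    """With globally dispersing females there is no kin structure, so
    WP and EP offspring are equally likely to be inbred."""
    from socped.simulate import SimulationParams, simulate_population

    params = SimulationParams(seed=8, female_local_settle_prob=0.0,
                              n_territories=40, n_years=16)
    study = simulate_population(params)
    nest = annotate_nestlings(study)
    s1, _ = cf.fit_hurdle_inbreeding(nest, exclude_mother_son=True)
    assert s1.covers("WP", 0.0)


def test_hurdle_small_inbred_subset_skips_stage2(small_study):
    nest = annotate_nestlings(small_study).copy()
    nest["f"] = 0.0
    nest.loc[nest.index[:10], "f"] = 0.125  # only 10 inbred
    s1, s2 = cf.fit_hurdle_inbreeding(nest, exclude_mother_son=True)
    assert s2 is None
    assert any("stage 2 skipped" in f for f in s1.flags)


def test_hurdle_requires_mother_son_column(small_study):
    nest = small_study.nestlings
    with pytest.raises(ValueError, match="is_mother_son"):
        cf.fit_hurdle_inbreeding(nest, exclude_mother_son=True)


def test_hurdle_helper_sensitivity_flag(default_nestlings):
    s1, _ = cf.fit_hurdle_inbreeding(
        default_nestlings, exclude_mother_son=True, include_helpers=True
    )
    assert "helper1" in s1.params.index and "helper2plus" in s1.params.index


def test_assignments_ep_status_consistency(small_study):
    assignments = cf.assignments_from_study(
        small_study.pedigree, small_study.broods, small_study.nestlings
    )
    status = {a.offspring_id: a.ep_status for a in assignments}
    merged = small_study.nestlings
    mismatches = sum(
        1 for r in merged.itertuples(index=False)
        if r.id in status and status[r.id] != r.ep_status
    )
    assert mismatches == 0
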
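import numpy as np
import pandas as pd
import pytest

from socped.pedigree import Pedigree, PedigreeRecord
from socped.simulate import SimulationParams, simulate_population


@pytest.fixture(scope="session")
def default_study():
    """One full-size simulated study population (the study conditions)."""
    return simulate_population(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A small population for cheap model tests."""
    return simulate_population(SimulationParams(n_territories=24, n_years=12, seed=7))


def annotate_nestlings(study, min_grandparents=1):
    """Measured nestlings restricted by pedigree completeness, with the
    mother-son flag merged in from the brood table."""
    nest = study.nestlings
    ms = dict(zip(study.broods["nest_id"], study.broods["is_mother_son"]))
    nest = nest.assign(is_mother_son=nest["nest_id"].map(ms).fillna(False))
    ids = study.pedigree.restrict(min_grandparents) & set(nest["id"])
    return nest[nest["id"].isin(ids)].reset_index(drop=True)


@pytest.fixture(scope="session")
def default_nestlings(default_study):
    return annotate_nestlings(default_study)


def redraw_mass(study, rng):
    """Redraw nestling mass conditional on the realized population.

    Keeps the pedigree, broods and covariates fixed and redraws every
    stochastic mass component (breeding values down the pedigree, nest,
    cohort, hatch-interval and residual deviates).  Used for estimator-
    calibration (coverage) tests without demographic feedback.
    """
    mm = study.params.mass_model
    ped = study.pedigree
    f = ped.inbreeding_all()
    sd_a = np.sqrt(mm.var_additive)
    bv = {}
    for i in ped.ids:
        s, d = ped.parents(i)
        if s is None and d is None:
            bv[i] = rng.normal(0.0, sd_a)
        else:
            mid = 0.5 * (bv.get(s, 0.0) + bv.get(d, 0.0))
            shrink = 1.0 - 0.5 * (f.get(s, 0.0) + f.get(d, 0.0))
            n_known = (s is not None) + (d is not None)
            # unknown parent side contributes founder-level variance
            var_ms = (0.5 * shrink + 0.25 * (2 - n_known)) * mm.var_additive
            bv[i] = mid + rng.normal(0.0, np.sqrt(max(var_ms, 0.0)))
    nest = study.nestlings.copy()
    nests = pd.unique(nest["nest_id"])
    cohorts = pd.unique(nest["cohort"])
    nest_dev = dict(zip(nests, rng.normal(0.0, np.sqrt(mm.var_nest), len(nests))))
    coh_dev = dict(zip(cohorts, rng.normal(0.0, np.sqrt(mm.var_cohort), len(cohorts))))
    hat_dev = rng.normal(0.0, np.sqrt(mm.var_hatch), 12)
    lp = np.array([
        mm.linear_predictor(
            f=r.f, male=r.sex == "male", brood_size=r.brood_size,
            n_helpers=r.n_helpers, age_days=r.age_days,
            pre1992=r.era == "pre-1992",
        )
        for r in nest.itertuples(index=False)
    ])
    mass = (
        lp
        + nest["nest_id"].map(nest_dev).to_numpy()
        + nest["cohort"].map(coh_dev).to_numpy()
        + hat_dev[nest["hatch_interval"].to_numpy() - 1]
        + np.array([bv[i] for i in nest["id"]])
        + rng.normal(0.0, np.sqrt(mm.var_residual), len(nest))
    )
    nest["mass_g"] = mass
    return nest


def trio_pedigree():
    """Founder pair, daughter, and an offspring of sire x daughter."""
    return Pedigree([
        PedigreeRecord("sire", sex="male"),
        PedigreeRecord("dam", sex="female"),
        PedigreeRecord("daughter", "sire", "dam", sex="female"),
        PedigreeRecord("incest_off", "sire", "daughter"),
    ])


def half_sib_pedigree():
    """One sire, two unrelated dams, half-sib pair and their offspring."""
    return Pedigree([
        PedigreeRecord("s", sex="male"),
        PedigreeRecord("d1", sex="female"),
        PedigreeRecord("d2", sex="female"),
        PedigreeRecord("a", "s", "d1", sex="male"),
        PedigreeRecord("b", "s", "d2", sex="female"),
        PedigreeRecord("y", "a", "b"),
    ])


def grandmother_pedigree():
    """Grandmother -> daughter -> grandson, all via unrelated founders."""
    return Pedigree([
        PedigreeRecord("gm", sex="female"),
        PedigreeRecord("gf", sex="male"),
        PedigreeRecord("dau", "gf", "gm", sex="female"),
        PedigreeRecord("m2", sex="male"),
        PedigreeRecord("gs", "m2", "dau", sex="male"),
    ])
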
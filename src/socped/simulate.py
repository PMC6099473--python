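"""Agent-based simulator of a cooperatively breeding songbird population.

Generates synthetic study populations with the social and demographic
structure the downstream analyses assume:

* a ring of territories, each held by a dominant (social) pair plus a
  queue of male helpers, usually sons of the breeding female;
* obligate female natal dispersal (so father-daughter social pairs never
  form) and territory inheritance by the oldest helper on the dominant
  male's death, which can create mother-son social pairs;
* per-offspring extra-pair paternity whose log-odds depend on the
  helper class (0 / 1 / 2+), forced to certainty in mother-son pairs
  (mothers never breed with their sons, socially paired or helping);
* extra-pair sires drawn from dominant males on nearby territories
  (extra-group by construction);
* nestling mass built from fixed effects (inbreeding coefficient, sex,
  brood size, helpers, measurement age, weighing-protocol era) plus
  nest, cohort, hatch-interval, additive-genetic and residual deviates,
  with breeding values transmitted as midparent plus a Mendelian
  sampling deviate shrunk by parental inbreeding;
* survival to independence as a Bernoulli on a logistic model of
  age/era-adjusted mass.

The generator records its full ground truth (parameters and realized
breeding values) so parameter-recovery tests can compare fitted models
against the generating process.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord

__all__ = [
    "MassModelParams",
    "SurvivalModelParams",
    "SimulationParams",
    "SyntheticStudy",
    "simulate_population",
    "summarize_study",
]


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class MassModelParams:
    """Generating model for nestling mass (grams).

    ``intercept_at_day7`` is the expected mass of an outbred female
    nestling measured at day 7 in the 1992+ era from an unassisted brood
    of size 0 (brood size enters uncentred, as in the analysis model).
    Variance components are in g^2.
    """

    intercept_at_day7: float = 7.35
    male_effect: float = 0.15
    brood_size_effect: float = -0.05
    helper1_effect: float = 0.09
    helper2plus_effect: float = 0.20
    inbreeding_effect: float = -3.64
    era_effect: float = 0.62  # offset for the pre-1992 weighing protocol
    age_effect: float = 2.16  # per day, around day 7
    age2_effect: float = -0.09  # per day^2
    var_nest: float = 0.23
    var_cohort: float = 0.01
    var_hatch: float = 0.01
    var_additive: float = 0.10
    var_residual: float = 0.19

    def linear_predictor(
        self,
        *,
        f: float,
        male: bool,
        brood_size: int,
        n_helpers: int,
        age_days: int,
        pre1992: bool,
    ) -> float:
        helper_eff = (
            self.helper2plus_effect
            if n_helpers >= 2
            else self.helper1_effect if n_helpers == 1 else 0.0
        )
        return (
            self.intercept_at_day7
            + self.inbreeding_effect * f
            + (self.male_effect if male else 0.0)
            + self.brood_size_effect * brood_size
            + helper_eff
            + self.age_effect * (age_days - 7)
            + self.age2_effect * (age_days**2 - 49)
            + (self.era_effect if pre1992 else 0.0)
        )


@dataclass(frozen=True)
class SurvivalModelParams:
    """Logistic model of fledgling survival to independence.

    The linear predictor acts on day-7 / era-adjusted mass so the mass
    effect is per gram on the logit scale.
    """

    intercept: float = -2.07
    mass_effect: float = 0.33
    inbreeding_effect: float = 0.0  # direct f effect beyond the mass route


@dataclass(frozen=True)
class SimulationParams:
    """Demographic rates and generative coefficients.

    Defaults describe the study population the analyses target: 60-90
    territories monitored over 26 cohorts, broods of 3-5 nestlings,
    roughly half of breeding attempts unassisted, a few percent of
    broods with mother-son social pairs, and ~61% extra-pair offspring.
    """

    n_territories: int = 75
    n_years: int = 26
    first_cohort: int = 1988
    #: distribution of the number of breeding attempts per female-year
    broods_per_female_per_year: tuple[float, ...] = (0.30, 0.45, 0.25)  # P(1), P(2), P(3)
    #: distribution of clutch size 3..5
    clutch_size: tuple[float, ...] = (0.45, 0.45, 0.10)
    nest_failure_prob: float = 0.45  # whole-clutch predation before hatching
    early_loss_prob: float = 0.08  # per-nestling loss before measurement age
    #: extra early-loss log-odds per unit of the nestling's f (0 = no
    #: selective disappearance; used only for power checks)
    early_loss_f_effect: float = 0.0
    adult_survival: float = 0.85  # males; helpers and dominants alike
    female_adult_survival: float = 0.54  # female dispersal+mortality off-site
    juvenile_survival: float = 0.50  # independence -> recruitment next season
    helper_retention: float = 0.80  # P(surviving son queues on natal territory)
    #: per-offspring extra-pair log-odds by helper class (intercept, +1
    #: helper, +2+ helpers); mother-son pairs are forced to 1 regardless
    epp_logit: tuple[float, float, float] = (0.47, 0.53, 1.17)
    #: sd of a per-brood deviate on the extra-pair logit: between-brood
    #: overdispersion in female infidelity beyond the helper-class effect
    epp_brood_sd: float = 0.7
    force_mother_son_epp: bool = True
    #: extra-group sires are dominant males drawn from beyond the female-
    #: dispersal neighbourhood, across a large slice of the study area
    ep_sire_min_distance: int = 3
    ep_sire_max_distance: int = 30
    #: locally recruited females settle within this ring distance of the
    #: natal territory when a vacancy allows; short female dispersal makes
    #: social partners more related, on average, than extra-pair sires
    #: drawn from farther away
    female_dispersal_window: int = 2
    #: probability that a vacancy is filled by a short-dispersing local
    #: female when one is available (otherwise any disperser or immigrant)
    female_local_settle_prob: float = 0.6
    immigrant_rate: float = 1.40  # expected unrelated immigrant females / territory-year
    #: probability a male vacancy with no resident helper is filled by an
    #: unrelated off-site immigrant rather than a local floater (the study
    #: site sits inside a larger unmonitored population)
    male_immigrant_prob: float = 0.65
    mass_model: MassModelParams = field(default_factory=MassModelParams)
    survival_model: SurvivalModelParams = field(default_factory=SurvivalModelParams)
    seed: int = 0

    def validate(self) -> None:
        for name, dist in (
            ("broods_per_female_per_year", self.broods_per_female_per_year),
            ("clutch_size", self.clutch_size),
        ):
            if abs(sum(dist) - 1.0) > 1e-9 or any(p < 0 for p in dist):
                raise ValueError(f"{name} must be a probability distribution")
        for name in (
            "nest_failure_prob",
            "early_loss_prob",
            "adult_survival",
            "female_adult_survival",
            "juvenile_survival",
            "helper_retention",
            "male_immigrant_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        mm = self.mass_model
        for name in ("var_nest", "var_cohort", "var_hatch", "var_additive", "var_residual"):
            if getattr(mm, name) < 0:
                raise ValueError(f"mass_model.{name} must be >= 0")
        if self.n_territories < 3 or self.n_years < 1:
            raise ValueError("need >= 3 territories and >= 1 year")
        if self.immigrant_rate < 0 or not (
            1 <= self.ep_sire_min_distance <= self.ep_sire_max_distance
        ):
            raise ValueError(
                "immigrant_rate >= 0 and 1 <= ep_sire_min_distance <= "
                "ep_sire_max_distance required"
            )
        if not 0.0 <= self.female_local_settle_prob <= 1.0:
            raise ValueError("female_local_settle_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticStudy:
    """A simulated study population plus its generating ground truth."""

    pedigree: Pedigree
    broods: pd.DataFrame
    nestlings: pd.DataFrame
    params: SimulationParams
    breeding_values: dict[str, float]

    def truth(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "breeding_values": self.breeding_values,
        }

    def write(self, outdir) -> None:
        """Write pedigree.csv, broods.csv, nestlings.csv, truth.json."""
        import pathlib

        from .pedigree import write_pedigree

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.pedigree, out / "pedigree.csv")
        self.broods.to_csv(out / "broods.csv", index=False)
        self.nestlings.to_csv(out / "nestlings.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth(), fh, indent=1)


class _Bird:
    __slots__ = ("id", "sex", "cohort", "sire", "dam", "bv", "f", "natal")

    def __init__(self, id, sex, cohort, sire, dam, bv, f=0.0, natal=None):
        self.id = id
        self.sex = sex
        self.cohort = cohort
        self.sire = sire
        self.dam = dam
        self.bv = bv
        self.f = f
        self.natal = natal  # territory index of the natal nest


class _Territory:
    __slots__ = ("male", "female", "helpers")

    def __init__(self, male=None, female=None):
        self.male = male
        self.female = female
        self.helpers: list[_Bird] = []  # ranked queue, oldest first


def simulate_population(params: SimulationParams | None = None) -> SyntheticStudy:
    """Run the agent-based simulation; fully reproducible from the seed."""
    params = params if params is not None else SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    mm = params.mass_model
    sm = params.survival_model

    counter = 0

    def new_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:06d}"

    sd_a = np.sqrt(mm.var_additive)
    records: list[PedigreeRecord] = []
    birds: dict[str, _Bird] = {}
    f_cache: dict[tuple[str, str], float] = {}

    bv_store: dict[str, float] = {}

    def founder(sex: str, cohort: int) -> _Bird:
        b = _Bird(new_id("F"), sex, cohort, None, None, float(rng.normal(0.0, sd_a)))
        birds[b.id] = b
        bv_store[b.id] = b.bv
        records.append(PedigreeRecord(b.id, None, None, cohort, sex))
        return b

    # pairwise-kinship helper on the growing pedigree (memoized locally;
    # the final Pedigree object recomputes everything independently)
    def kin(i: str | None, j: str | None) -> float:
        if i is None or j is None:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + birds[i].f)
        key = (i, j) if i < j else (j, i)
        v = f_cache.get(key)
        if v is not None:
            return v
        bi, bj = birds[i], birds[j]
        # decompose the younger (later-created) individual; ids are
        # assigned in birth order so lexical order matches depth
        if bi.cohort > bj.cohort or (bi.cohort == bj.cohort and bi.id > bj.id):
            i, j = j, i
            bi, bj = bj, bi
        if bj.sire is None and bj.dam is None:
            v = 0.0
        else:
            v = 0.5 * (kin(i, bj.sire) + kin(i, bj.dam))
        f_cache[key] = v
        return v

    # ------------------------------------------------------------ initial
    territories = [_Territory() for _ in range(params.n_territories)]
    for t in territories:
        t.male = founder("male", params.first_cohort - 1)
        t.female = founder("female", params.first_cohort - 1)

    brood_rows: list[dict] = []
    nestling_rows: list[dict] = []
    cohort_dev = {
        params.first_cohort + y: rng.normal(0.0, np.sqrt(mm.var_cohort))
        for y in range(params.n_years)
    }
    hatch_dev = rng.normal(0.0, np.sqrt(mm.var_hatch), size=12)
    era_cutoff = 1992
    nest_counter = 0

    clutch_sizes = np.array([3, 4, 5])
    attempts_choices = np.array([1, 2, 3])

    for year in range(params.n_years):
        cohort = params.first_cohort + year
        recruits_female: list[_Bird] = []
        recruits_male: list[_Bird] = []

        for ti, terr in enumerate(territories):
            mother = terr.female
            father = terr.male
            n_help = len(terr.helpers)
            helper_class = min(n_help, 2)
            is_mother_son = father.dam == mother.id
            k_soc = kin(father.id, mother.id)
            ep_lp = (
                params.epp_logit[0]
                + (params.epp_logit[1] if helper_class == 1 else 0.0)
                + (params.epp_logit[2] if helper_class == 2 else 0.0)
            )

            # candidate extra-group sires: dominant males 1..D territories
            # away on the ring, never a son of the mother
            cand = []
            seen_terr = {ti}
            max_d = min(params.ep_sire_max_distance, params.n_territories // 2)
            for dist in range(params.ep_sire_min_distance, max_d + 1):
                for tj in ((ti + dist) % params.n_territories,
                           (ti - dist) % params.n_territories):
                    if tj in seen_terr:
                        continue
                    seen_terr.add(tj)
                    m = territories[tj].male
                    if m is not None and m.dam != mother.id:
                        cand.append(m)
            if is_mother_son and params.force_mother_son_epp and not cand:
                continue  # no outbred mating opportunity: no offspring

            n_attempts = int(rng.choice(attempts_choices, p=params.broods_per_female_per_year))
            for _ in range(n_attempts):
                if rng.random() < params.nest_failure_prob:
                    continue  # whole clutch predated
                clutch = int(rng.choice(clutch_sizes, p=params.clutch_size))
                nest_counter += 1
                nest_id = f"N{nest_counter:05d}"
                hatch_interval = int(rng.integers(1, 13))
                nest_eff = rng.normal(0.0, np.sqrt(mm.var_nest))
                if is_mother_son and params.force_mother_son_epp:
                    p_ep = 1.0
                else:
                    p_ep = _invlogit(ep_lp + rng.normal(0.0, params.epp_brood_sd))
                measured: list[dict] = []
                for _k in range(clutch):
                    if cand and rng.random() < p_ep:
                        sire = cand[int(rng.integers(len(cand)))]
                        ep = True
                    else:
                        sire = father
                        ep = False
                    f_off = kin(sire.id, mother.id)
                    sex = "male" if rng.random() < 0.5 else "female"
                    bv = 0.5 * (sire.bv + mother.bv) + rng.normal(
                        0.0,
                        np.sqrt(max(0.5 * (1.0 - 0.5 * (sire.f + mother.f)), 0.0))
                        * sd_a,
                    )
                    chick = _Bird(
                        new_id("I"), sex, cohort, sire.id, mother.id, bv, f_off, natal=ti
                    )
                    birds[chick.id] = chick
                    bv_store[chick.id] = bv
                    records.append(
                        PedigreeRecord(chick.id, sire.id, mother.id, cohort, sex)
                    )
                    # pre-measurement loss (whole clutch hatched; losses
                    # between hatching and the day 5-8 weighing visit)
                    p_loss = _invlogit(
                        np.log(params.early_loss_prob / (1 - params.early_loss_prob))
                        + params.early_loss_f_effect * f_off
                    ) if params.early_loss_prob > 0 else 0.0
                    if rng.random() < p_loss:
                        continue  # died before measurement; stays in pedigree
                    age = int(rng.integers(5, 9))
                    pre1992 = cohort < era_cutoff
                    mu = mm.linear_predictor(
                        f=f_off,
                        male=sex == "male",
                        brood_size=0,  # filled in after brood size is known
                        n_helpers=helper_class,
                        age_days=age,
                        pre1992=pre1992,
                    )
                    measured.append(
                        dict(
                            id=chick.id,
                            nest_id=nest_id,
                            cohort=cohort,
                            hatch_interval=hatch_interval,
                            sex=sex,
                            age_days=age,
                            era="pre-1992" if pre1992 else "1992+",
                            f=f_off,
                            ep_status="EP" if ep else "WP",
                            n_helpers=helper_class,
                            _mu=mu,
                            _nest=nest_eff,
                            _bird=chick,
                        )
                    )
                brood_size = len(measured)
                if brood_size == 0:
                    continue
                for row in measured:
                    mu = row.pop("_mu") + mm.brood_size_effect * brood_size
                    chick = row.pop("_bird")
                    mass = (
                        mu
                        + row.pop("_nest")
                        + cohort_dev[cohort]
                        + hatch_dev[row["hatch_interval"] - 1]
                        + chick.bv
                        + rng.normal(0.0, np.sqrt(mm.var_residual))
                    )
                    mass_adj = (
                        mass
                        - mm.age_effect * (row["age_days"] - 7)
                        - mm.age2_effect * (row["age_days"] ** 2 - 49)
                        - (mm.era_effect if row["era"] == "pre-1992" else 0.0)
                    )
                    logit_s = (
                        sm.intercept
                        + sm.mass_effect * mass_adj
                        + sm.inbreeding_effect * row["f"]
                    )
                    survived = rng.random() < _invlogit(logit_s)
                    row.update(
                        mass_g=round(float(mass), 4),
                        survived=bool(survived),
                        brood_size=brood_size,
                    )
                    nestling_rows.append(row)
                    if survived and rng.random() < params.juvenile_survival:
                        (recruits_male if chick.sex == "male" else recruits_female).append(chick)
                n_epo_m = sum(1 for r in measured if r["ep_status"] == "EP")
                brood_rows.append(
                    dict(
                        nest_id=nest_id,
                        territory=ti,
                        mother_id=mother.id,
                        social_father_id=father.id,
                        cohort=cohort,
                        hatch_interval=hatch_interval,
                        n_helpers=helper_class,
                        clutch_size=clutch,
                        brood_size=brood_size,
                        n_epo=n_epo_m,
                        n_wpo=brood_size - n_epo_m,
                        k_soc=k_soc,
                        is_mother_son=is_mother_son,
                        mother_age="1yo" if cohort - mother.cohort <= 1 else "older",
                        father_age="1yo" if cohort - father.cohort <= 1 else "older",
                    )
                )

        # -------------------------------------------------- end of season
        # mortality of dominants and helpers
        for terr in territories:
            if rng.random() > params.adult_survival:
                terr.male = None
            if rng.random() > params.female_adult_survival:
                terr.female = None
            terr.helpers = [h for h in terr.helpers if rng.random() < params.adult_survival]

        # surviving sons may queue as helpers on the natal territory
        floaters_male: list[_Bird] = []
        by_mother: dict[str, list[_Bird]] = {}
        for b in recruits_male:
            by_mother.setdefault(b.dam, []).append(b)
        for terr in territories:
            resident_mother = terr.female.id if terr.female is not None else None
            if resident_mother and resident_mother in by_mother:
                for son in by_mother.pop(resident_mother):
                    if rng.random() < params.helper_retention:
                        terr.helpers.append(son)
                    else:
                        floaters_male.append(son)
        for rest in by_mother.values():
            floaters_male.extend(rest)
        rng.shuffle(floaters_male)

        # territory inheritance: oldest helper fills a male vacancy
        for terr in territories:
            if terr.male is None and terr.helpers:
                terr.male = terr.helpers.pop(0)
        for terr in territories:
            if terr.male is None:
                if floaters_male and rng.random() >= params.male_immigrant_prob:
                    terr.male = floaters_male.pop()
                else:
                    terr.male = founder("male", cohort)

        # obligate female dispersal: daughters never settle on the natal
        # territory and never pair with their sire; settlement is biased
        # toward vacancies near the natal territory (short dispersal)
        n_imm = rng.poisson(params.immigrant_rate * params.n_territories)
        female_pool = list(recruits_female) + [founder("female", cohort) for _ in range(n_imm)]
        rng.shuffle(female_pool)
        T = params.n_territories

        def ring_dist(a: int, b: int) -> int:
            d = abs(a - b)
            return min(d, T - d)

        for ti, terr in enumerate(territories):
            if terr.female is not None:
                continue
            ok = [
                idx
                for idx, cand_f in enumerate(female_pool)
                if cand_f.natal != ti and cand_f.sire != terr.male.id
            ]
            local = [
                idx
                for idx in ok
                if female_pool[idx].natal is not None
                and ring_dist(female_pool[idx].natal, ti)
                <= params.female_dispersal_window
            ]
            if local and rng.random() < params.female_local_settle_prob:
                pick = local[int(rng.integers(len(local)))]
            elif ok:
                pick = ok[int(rng.integers(len(ok)))]
            else:
                pick = None
            if pick is not None:
                terr.female = female_pool.pop(pick)
            else:
                terr.female = founder("female", cohort)
            # a new breeding female dissolves the old queue's maternal link
            # only socially; helpers stay on the territory

    pedigree = Pedigree(records)
    broods = pd.DataFrame(brood_rows)
    nestlings = pd.DataFrame(
        nestling_rows,
        columns=[
            "id",
            "nest_id",
            "cohort",
            "hatch_interval",
            "sex",
            "age_days",
            "era",
            "f",
            "ep_status",
            "n_helpers",
            "mass_g",
            "survived",
            "brood_size",
        ],
    )
    return SyntheticStudy(pedigree, broods, nestlings, params, bv_store)


def summarize_study(study: SyntheticStudy, inbred_threshold: float = 1e-12) -> pd.Series:
    """Calibration summary: the population-level rates the analyses use.

    Reports the fraction of unassisted broods, the helper-class
    distribution, the percentage of mother-son social pairs, the
    percentage of extra-pair offspring, and the percentage of inbred
    individuals at each pedigree-completeness restriction level.
    """
    broods, nestlings = study.broods, study.nestlings
    out: dict[str, float] = {}
    n_broods = len(broods)
    out["n_broods"] = float(n_broods)
    out["n_nestlings"] = float(len(nestlings))
    if n_broods == 0:
        for k in ("pct_unassisted", "pct_helper1", "pct_helper2plus",
                  "pct_mother_son_broods", "pct_epo"):
            out[k] = 0.0
        return pd.Series(out)
    out["pct_unassisted"] = 100.0 * (broods.n_helpers == 0).mean()
    out["pct_helper1"] = 100.0 * (broods.n_helpers == 1).mean()
    out["pct_helper2plus"] = 100.0 * (broods.n_helpers >= 2).mean()
    out["pct_mother_son_broods"] = 100.0 * broods.is_mother_son.mean()
    out["pct_epo"] = 100.0 * nestlings.ep_status.eq("EP").mean()
    ped = study.pedigree
    f_all = ped.inbreeding_all()
    for min_gp in range(5):
        ids = ped.restrict(min_gp) & set(nestlings.id)
        if ids:
            frac = np.mean([f_all[i] > inbred_threshold for i in sorted(ids)])
        else:
            frac = 0.0
        out[f"pct_inbred_min{min_gp}gp"] = 100.0 * frac
        out[f"n_min{min_gp}gp"] = float(len(ids))
    return pd.Series(out)
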
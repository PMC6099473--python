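"""Consequences of infidelity for inbreeding: the faithful-pedigree
counterfactual, WP/EP inbreeding contrasts and the two-step hurdle model.

The *faithful pedigree* replaces every offspring's genetic sire with its
mother's social partner, representing the relatedness structure that
would have arisen had all females always been faithful.  Comparing
inbreeding rates between the observed and faithful pedigrees measures
how much infidelity reduces inbreeding at the population level.

Because pedigree inbreeding coefficients are zero-heavy, the offspring-
level analysis is a hurdle: stage 1 models whether an offspring is
inbred at all (binomial on within-pair status), stage 2 models log f
among the inbred only (Gaussian on within-pair status).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import BinomialMixedModel
from .lmm import LinearMixedModel
from .pedigree import F_EPS, Pedigree, PedigreeRecord, PedigreeValidationError
from .results import MixedModelResults

__all__ = [
    "SocialAssignment",
    "ContingencyTable2x2",
    "FisherResult",
    "assignments_from_study",
    "build_faithful_pedigree",
    "faithful_f_one_generation",
    "inbreeding_contrast",
    "fisher_exact",
    "InbreedingHurdleModel",
    "fit_hurdle_inbreeding",
]


@dataclass(frozen=True)
class SocialAssignment:
    """Genetic vs social paternity for one offspring."""

    offspring_id: str
    social_father_id: str
    genetic_father_id: str

    @property
    def ep_status(self) -> str:
        return "EP" if self.social_father_id != self.genetic_father_id else "WP"


@dataclass
class ContingencyTable2x2:
    """A 2x2 count table with labelled rows/columns and row percentages."""

    counts: np.ndarray
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("need a 2x2 table of non-negative counts")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        tot = self.row_totals.astype(float)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, 100.0 * self.counts / tot, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    flags: tuple[str, ...] = ()


def assignments_from_study(
    pedigree: Pedigree,
    broods: pd.DataFrame,
    nestlings: pd.DataFrame | None = None,
) -> list[SocialAssignment]:
    """Derive per-offspring social assignments from a brood table.

    Measured nestlings are matched to their nest's social father via
    ``nest_id``; remaining pedigree offspring (e.g. chicks lost before
    measurement) are matched on (dam, cohort), which is unambiguous when
    a female keeps one social partner within a season.  Offspring whose
    mother has no brood record (founder mothers outside the monitored
    pairs) receive no assignment.
    """
    nest_to_father = dict(zip(broods["nest_id"], broods["social_father_id"]))
    dam_year_father: dict[tuple[str, int], str] = {}
    for row in broods.itertuples(index=False):
        dam_year_father[(row.mother_id, int(row.cohort))] = row.social_father_id
    by_nest: dict[str, str] = {}
    if nestlings is not None:
        by_nest = dict(zip(nestlings["id"], nestlings["nest_id"]))
    out = []
    for i in pedigree.ids:
        rec = pedigree[i]
        if rec.sire is None or rec.dam is None:
            continue
        social = None
        nest = by_nest.get(i)
        if nest is not None:
            social = nest_to_father.get(nest)
        if social is None and rec.cohort is not None:
            social = dam_year_father.get((rec.dam, int(rec.cohort)))
        if social is not None:
            out.append(SocialAssignment(i, social, rec.sire))
    return out


def build_faithful_pedigree(
    ped: Pedigree, assignments: list[SocialAssignment]
) -> Pedigree:
    """Pedigree in which every assigned offspring's sire is its social father.

    The substitution is applied to all individuals simultaneously
    (ancestors included), so descendants' kinship is computed on the
    fully substituted pedigree.  Idempotent: re-applying the same
    assignments leaves the result unchanged.  A substitution that makes
    an offspring its own ancestor raises a validation error naming the
    chain.
    """
    sub = {}
    for a in assignments:
        if a.offspring_id not in ped:
            raise KeyError(f"assignment for unknown offspring {a.offspring_id!r}")
        sub[a.offspring_id] = a.social_father_id
    records = []
    for i in ped.ids:
        rec = ped[i]
        sire = sub.get(i, rec.sire)
        records.append(PedigreeRecord(i, sire, rec.dam, rec.cohort, rec.sex))
    # declared-founder social fathers absent from ped get auto-added
    try:
        return Pedigree(records)
    except PedigreeValidationError as err:
        raise PedigreeValidationError(
            f"faithful substitution breaks the pedigree: {err}"
        ) from err


def faithful_f_one_generation(
    ped: Pedigree, assignments: list[SocialAssignment]
) -> dict[str, float]:
    """Sensitivity variant: substitute the sire for the focal individual
    only, keeping all ancestors as observed.

    f_faithful(i) = kinship(social father of i, dam of i) on the
    *observed* pedigree.
    """
    out = {}
    for a in assignments:
        dam = ped.dam(a.offspring_id)
        if dam is None or a.social_father_id not in ped:
            continue
        out[a.offspring_id] = ped.kinship(a.social_father_id, dam).kinship
    return out


@dataclass
class InbreedingContrast:
    """Observed-vs-faithful and WP-vs-EP inbred/outbred tables."""

    observed_faithful: ContingencyTable2x2
    wp_ep: ContingencyTable2x2
    f_observed: dict[str, float]
    f_faithful: dict[str, float]


def inbreeding_contrast(
    ped: Pedigree,
    faithful: Pedigree,
    ids: set[str],
    assignments: list[SocialAssignment] | None = None,
    threshold: float = F_EPS,
) -> InbreedingContrast:
    """Cross-tabulate inbred (f > threshold) vs outbred offspring.

    Rows of the first table are observed vs faithful pedigree; rows of
    the second are within-pair vs extra-pair status under the observed
    pedigree (requires ``assignments``).
    """
    ids = sorted(ids)
    for i in ids:
        ped[i], faithful[i]
    f_obs_all = ped.inbreeding_all()
    f_fai_all = faithful.inbreeding_all()
    f_obs = {i: f_obs_all[i] for i in ids}
    f_fai = {i: f_fai_all[i] for i in ids}
    obs_inbred = sum(1 for i in ids if f_obs[i] > threshold)
    fai_inbred = sum(1 for i in ids if f_fai[i] > threshold)
    n = len(ids)
    table_of = ContingencyTable2x2(
        np.array([[obs_inbred, n - obs_inbred], [fai_inbred, n - fai_inbred]]),
        ("observed", "faithful"),
        ("inbred", "outbred"),
    )
    wp = ep = wp_in = ep_in = 0
    if assignments:
        status = {a.offspring_id: a.ep_status for a in assignments}
        for i in ids:
            st = status.get(i)
            if st is None:
                continue
            inbred = f_obs[i] > threshold
            if st == "WP":
                wp += 1
                wp_in += inbred
            else:
                ep += 1
                ep_in += inbred
    table_we = ContingencyTable2x2(
        np.array([[wp_in, wp - wp_in], [ep_in, ep - ep_in]]),
        ("within_pair", "extra_pair"),
        ("inbred", "outbred"),
    )
    return InbreedingContrast(table_of, table_we, f_obs, f_fai)


def fisher_exact(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test with the sample odds ratio.

    The p-value sums hypergeometric probabilities no larger than that of
    the observed table (scipy's two-sided convention).  A zero margin
    makes the odds ratio undefined: flagged, with p = 1.
    """
    c = table.counts
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        return FisherResult(1.0, float("nan"), ("zero margin: odds ratio undefined",))
    res = stats.fisher_exact(c, alternative="two-sided")
    a, b, cc, d = c.ravel().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        orat = (a * d) / (b * cc) if b * cc > 0 else float("inf")
    return FisherResult(float(res.pvalue), float(orat))


class InbreedingHurdleModel:
    """Two-step hurdle model of offspring inbreeding by paternity class.

    Stage 1: binomial mixed model of inbred status (f > 0) on within-
    pair status (EP reference), random intercepts for nest and cohort.
    Stage 2: linear mixed model of log(f) among inbred offspring only,
    same fixed and random structure.  Mother-son broods are excluded by
    default (their infidelity is structural, not informative).  Helper
    class is deliberately omitted (it is confounded with extra-pair
    rates) unless ``include_helpers`` is set for sensitivity analysis.
    """

    def __init__(
        self,
        nestlings: pd.DataFrame,
        exclude_mother_son: bool = True,
        include_helpers: bool = False,
        threshold: float = F_EPS,
        min_inbred: int = 30,
    ):
        df = nestlings.reset_index(drop=True)
        for col in ("id", "nest_id", "cohort", "f", "ep_status"):
            if col not in df.columns:
                raise ValueError(f"hurdle model requires column {col!r}")
        if exclude_mother_son:
            if "is_mother_son" not in df.columns:
                raise ValueError(
                    "exclude_mother_son requires an is_mother_son column "
                    "(merge the brood table on nest_id)"
                )
            df = df[~df["is_mother_son"].astype(bool)].reset_index(drop=True)
        self.nestlings = df
        self.exclude_mother_son = exclude_mother_son
        self.include_helpers = include_helpers
        self.threshold = threshold
        self.min_inbred = min_inbred

    def _design(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(len(df)), (df["ep_status"] == "WP").astype(float)]
        names = ["const", "WP"]
        if self.include_helpers:
            cols += [
                (df["n_helpers"].astype(int) == 1).astype(float),
                (df["n_helpers"].astype(int) >= 2).astype(float),
            ]
            names += ["helper1", "helper2plus"]
        return np.column_stack(cols), names

    def fit(self) -> tuple[MixedModelResults, MixedModelResults | None]:
        df = self.nestlings
        inbred = (df["f"].astype(float) > self.threshold).astype(int)
        X, names = self._design(df)
        stage1 = BinomialMixedModel(
            inbred.to_numpy(),
            X,
            names,
            vc={"nest": df["nest_id"], "cohort": df["cohort"]},
        ).fit()
        stage1.extra["stage"] = 1
        sub = df[inbred.astype(bool)].reset_index(drop=True)
        if len(sub) < self.min_inbred:
            stage1.flags.append(
                f"stage 2 skipped: only {len(sub)} inbred offspring "
                f"(< {self.min_inbred})"
            )
            return stage1, None
        X2, names2 = self._design(sub)
        stage2 = LinearMixedModel(
            np.log(sub["f"].astype(float)),
            X2,
            names2,
            vc={"nest": sub["nest_id"], "cohort": sub["cohort"]},
        ).fit(compute_vc_se=False)
        stage2.extra["stage"] = 2
        return stage1, stage2


def fit_hurdle_inbreeding(
    nestlings: pd.DataFrame,
    exclude_mother_son: bool = True,
    include_helpers: bool = False,
) -> tuple[MixedModelResults, MixedModelResults | None]:
    """Functional form of :class:`InbreedingHurdleModel`."""
    return InbreedingHurdleModel(
        nestlings, exclude_mother_son, include_helpers
    ).fit()
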
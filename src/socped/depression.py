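"""Inbreeding depression in nestling mass and fledgling survival.

The mass model is a linear mixed "animal model": nestling mass on the
inbreeding coefficient f plus rearing covariates, with nest, cohort,
hatch-interval and additive-genetic random effects (the latter with
pedigree covariance 2k).  Fitting the additive genetic term guards the
f coefficient against bias from heritable resemblance among relatives
and yields a heritability estimate as a by-product.

The survival model is a binomial mixed model of survival from fledging
to independence, fitted with and without (age/era-adjusted) mass as a
covariate to ask whether any inbreeding effect on survival acts through
body mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glmm import BinomialMixedModel
from .lmm import LinearMixedModel
from .pedigree import Pedigree
from .results import MixedModelResults

__all__ = [
    "NestlingMassModel",
    "FledglingSurvivalModel",
    "fit_mass_model",
    "fit_survival_model",
    "mass_adjustment",
    "NESTLING_COLUMNS",
]

NESTLING_COLUMNS = [
    "id",
    "nest_id",
    "cohort",
    "hatch_interval",
    "sex",
    "age_days",
    "era",
    "mass_g",
    "survived",
    "f",
    "ep_status",
    "n_helpers",
    "brood_size",
]


def _check_nestlings(df: pd.DataFrame, min_n: int) -> pd.DataFrame:
    missing = [c for c in NESTLING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"nestling table missing columns: {missing}")
    if len(df) < min_n:
        raise ValueError(f"need >= {min_n} nestlings; got {len(df)}")
    return df.reset_index(drop=True)


def _base_design(df: pd.DataFrame, interaction: bool) -> tuple[np.ndarray, list[str]]:
    """f + helpers + brood size + sex (+ f x helpers) shared block."""
    h1 = (df["n_helpers"].astype(int) == 1).astype(float)
    h2 = (df["n_helpers"].astype(int) >= 2).astype(float)
    f = df["f"].astype(float)
    cols = [
        np.ones(len(df)),
        f,
        h1,
        h2,
        df["brood_size"].astype(float),
        (df["sex"] == "male").astype(float),
    ]
    names = ["const", "f", "helper1", "helper2plus", "brood_size", "male"]
    if interaction:
        cols += [f * h1, f * h2]
        names += ["f:helper1", "f:helper2plus"]
    return np.column_stack(cols), names


class NestlingMassModel:
    """Animal model for nestling mass (grams).

    Fixed effects: f, helper class, brood size, sex, measurement age
    (centred at day 7, linear + quadratic) and weighing-protocol era;
    random effects: nest, cohort, hatch interval and (optionally) the
    additive genetic effect with pedigree covariance.
    """

    def __init__(
        self,
        nestlings: pd.DataFrame,
        pedigree: Pedigree | None = None,
        animal_term: bool = True,
        interaction: bool = False,
        min_n: int = 200,
    ):
        df = _check_nestlings(nestlings, min_n)
        if animal_term:
            if pedigree is None:
                raise ValueError("animal_term requires a pedigree")
            missing = [i for i in df["id"] if i not in pedigree]
            if missing:
                raise ValueError(
                    f"{len(missing)} nestlings absent from pedigree, e.g. {missing[:3]}"
                )
        if np.var(df["f"].astype(float)) == 0:
            self._flag = "degenerate: f is constant, coefficient undefined"
        else:
            self._flag = None
        self.nestlings = df
        self.pedigree = pedigree
        self.animal_term = animal_term
        self.interaction = interaction

    def _design(self) -> tuple[np.ndarray, list[str]]:
        df = self.nestlings
        X, names = _base_design(df, self.interaction)
        age_c = df["age_days"].astype(float) - 7.0
        X = np.column_stack(
            [X, age_c, age_c**2, (df["era"] == "pre-1992").astype(float)]
        )
        names += ["age_c", "age_c2", "pre1992"]
        return X, names

    def fit(self, **fit_kws) -> MixedModelResults:
        df = self.nestlings
        X, names = self._design()
        if self._flag:
            res = LinearMixedModel(
                df["mass_g"], np.ones((len(df), 1)), ["const"],
                vc={"nest": df["nest_id"]},
            )._degenerate_fit(self._flag)
            return res
        model = LinearMixedModel(
            df["mass_g"].astype(float),
            X,
            names,
            vc={
                "nest": df["nest_id"],
                "cohort": df["cohort"],
                "hatch_interval": df["hatch_interval"],
            },
            animal_ids=df["id"].tolist() if self.animal_term else None,
            pedigree=self.pedigree if self.animal_term else None,
        )
        return model.fit(**fit_kws)


class FledglingSurvivalModel:
    """Binomial mixed model of fledgling survival to independence.

    Fixed effects: f, helper class, brood size, sex, and optionally
    age/era-adjusted nestling mass; random effects: nest, cohort, hatch
    interval.
    """

    def __init__(
        self,
        nestlings: pd.DataFrame,
        with_mass: bool = False,
        interaction: bool = False,
        min_n: int = 200,
    ):
        self.nestlings = _check_nestlings(nestlings, min_n)
        self.with_mass = with_mass
        self.interaction = interaction

    def fit(self) -> MixedModelResults:
        df = self.nestlings
        X, names = _base_design(df, self.interaction)
        if self.with_mass:
            X = np.column_stack([X, mass_adjustment(df)])
            names = names + ["mass_adj"]
        model = BinomialMixedModel(
            df["survived"].astype(int).to_numpy(),
            X,
            names,
            vc={
                "nest": df["nest_id"],
                "cohort": df["cohort"],
                "hatch_interval": df["hatch_interval"],
            },
        )
        res = model.fit()
        res.extra["with_mass"] = self.with_mass
        return res


def fit_mass_model(
    nestlings: pd.DataFrame,
    ped: Pedigree | None = None,
    animal_term: bool = True,
    interaction: bool = False,
    **fit_kws,
) -> MixedModelResults:
    """Functional form of :class:`NestlingMassModel`."""
    return NestlingMassModel(nestlings, ped, animal_term, interaction).fit(**fit_kws)


def fit_survival_model(
    nestlings: pd.DataFrame,
    with_mass: bool = False,
    interaction: bool = False,
) -> MixedModelResults:
    """Functional form of :class:`FledglingSurvivalModel`."""
    return FledglingSurvivalModel(nestlings, with_mass, interaction).fit()


def plot_inbreeding_depression(nestlings: pd.DataFrame, ax=None):
    """Diagnostic scatter of age/era-adjusted mass against f, with
    group means for the common f values overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    adj = mass_adjustment(nestlings)
    f = nestlings["f"].astype(float).reset_index(drop=True)
    ax.scatter(f, adj, s=6, alpha=0.25, color="0.6", linewidths=0)
    means = adj.groupby(f.round(4)).agg(["mean", "count"])
    big = means[means["count"] >= 5]
    ax.plot(big.index, big["mean"], "k_", markersize=14, markeredgewidth=2)
    ax.set_xlabel("inbreeding coefficient f")
    ax.set_ylabel("mass at day 7, 1992+ scale (g)")
    return ax


def mass_adjustment(nestlings: pd.DataFrame) -> pd.Series:
    """Mass residualized to the day-7, 1992+ measurement scale.

    Fits mass ~ age + age^2 + era with a nest random intercept, then
    removes the age and era components so that a record measured at day
    7 in the 1992+ era is returned unchanged.
    """
    df = nestlings.reset_index(drop=True)
    for col in ("age_days", "mass_g", "era", "nest_id"):
        if col not in df.columns:
            raise ValueError(f"mass adjustment requires column {col!r}")
    age_c = df["age_days"].astype(float) - 7.0
    pre = (df["era"] == "pre-1992").astype(float)
    X = np.column_stack([np.ones(len(df)), age_c, age_c**2, pre])
    names = ["const", "age_c", "age_c2", "pre1992"]
    fit = LinearMixedModel(
        df["mass_g"].astype(float), X, names, vc={"nest": df["nest_id"]}
    ).fit(compute_vc_se=False)
    adj = (
        df["mass_g"].astype(float)
        - fit.params["age_c"] * age_c
        - fit.params["age_c2"] * age_c**2
        - fit.params["pre1992"] * pre
    )
    adj.name = "mass_adj"
    return adj
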
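"""Brood-level models of extra-pair paternity.

The response is the brood's (extra-pair, within-pair) offspring split;
the question is whether the kinship between the social partners
(``k_soc``) and/or the social environment (helper class) predict female
infidelity.  Because mother-son social pairs show complete infidelity,
every model exists in two versions: with and without those pairs — the
contrast between the two fits is the analysis.

Also provides the "selective disappearance" checks: whether social-pair
kinship predicts clutch size or survival of nestlings to measurement
age, which would bias extra-pair rates upward if inbred within-pair
embryos died before sampling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glmm import BinomialMixedModel, expand_binomial
from .lmm import LinearMixedModel
from .results import MixedModelResults

__all__ = [
    "EPPModel",
    "fit_epp_model",
    "selective_disappearance_checks",
    "BROOD_COLUMNS",
]

BROOD_COLUMNS = [
    "nest_id",
    "mother_id",
    "social_father_id",
    "cohort",
    "hatch_interval",
    "n_helpers",
    "clutch_size",
    "brood_size",
    "n_epo",
    "n_wpo",
    "k_soc",
    "is_mother_son",
    "mother_age",
    "father_age",
]


def _check_broods(broods: pd.DataFrame, min_broods: int = 30) -> pd.DataFrame:
    missing = [c for c in BROOD_COLUMNS if c not in broods.columns]
    if missing:
        raise ValueError(f"brood table missing columns: {missing}")
    bad = broods["n_epo"] + broods["n_wpo"] != broods["brood_size"]
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} broods violate n_epo + n_wpo == brood_size"
        )
    if len(broods) < min_broods:
        raise ValueError(f"need >= {min_broods} broods; got {len(broods)}")
    return broods


class EPPModel:
    """Binomial mixed model of the proportion of extra-pair offspring.

    Fixed effects: social-pair kinship ``k_soc``, helper class (0
    reference), mother age and social-father age (1-year-old reference);
    optionally the kinship x helper interaction.  Random intercepts:
    mother, social father, cohort.

    Parameters
    ----------
    broods
        Brood table (one row per brood, see :data:`BROOD_COLUMNS`).
    include_mother_son
        When False, broods whose social pair is a mother and her son are
        dropped before fitting (their infidelity is structural).
    interaction
        Add k_soc x helper-class terms.
    """

    def __init__(
        self,
        broods: pd.DataFrame,
        include_mother_son: bool = True,
        interaction: bool = False,
    ):
        broods = _check_broods(broods)
        if not include_mother_son:
            broods = broods[~broods["is_mother_son"].astype(bool)]
            if len(broods) < 30:
                raise ValueError("fewer than 30 broods after mother-son exclusion")
        self.broods = broods.reset_index(drop=True)
        self.interaction = interaction
        self.include_mother_son = include_mother_son

    def _design(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        h1 = (df["n_helpers"].astype(int) == 1).astype(float)
        h2 = (df["n_helpers"].astype(int) >= 2).astype(float)
        cols = [
            np.ones(len(df)),
            df["k_soc"].astype(float),
            h1,
            h2,
            (df["mother_age"] == "older").astype(float),
            (df["father_age"] == "older").astype(float),
        ]
        names = ["const", "k_soc", "helper1", "helper2plus", "mother_older", "father_older"]
        if self.interaction:
            cols += [df["k_soc"].astype(float) * h1, df["k_soc"].astype(float) * h2]
            names += ["k_soc:helper1", "k_soc:helper2plus"]
        return np.column_stack(cols), names

    def fit(self) -> MixedModelResults:
        rows = expand_binomial(
            self.broods["n_epo"], self.broods["n_wpo"], self.broods
        )
        X, names = self._design(rows)
        model = BinomialMixedModel(
            rows["_y"].to_numpy(),
            X,
            names,
            vc={
                "mother": rows["mother_id"],
                "social_father": rows["social_father_id"],
                "cohort": rows["cohort"],
                # brood-level latent residual: overdispersion between
                # broods beyond mother/father/cohort
                "brood": rows["nest_id"],
            },
        )
        res = model.fit()
        res.extra["n_broods"] = len(self.broods)
        res.extra["include_mother_son"] = self.include_mother_son
        return res


def fit_epp_model(
    broods: pd.DataFrame,
    include_mother_son: bool = True,
    interaction: bool = False,
) -> MixedModelResults:
    """Functional form of :class:`EPPModel` (build + fit)."""
    return EPPModel(broods, include_mother_son, interaction).fit()


def selective_disappearance_checks(
    broods: pd.DataFrame,
) -> tuple[MixedModelResults, MixedModelResults]:
    """Does social-pair kinship predict clutch size or early survival?

    Returns a pair of fits: (a) clutch size ~ k_soc with a cohort random
    intercept (Gaussian), and (b) survival to measurement age, a
    binomial on (brood_size, clutch_size - brood_size) ~ k_soc with a
    cohort random intercept.  A null k_soc effect in both is the
    no-selective-disappearance condition.
    """
    broods = _check_broods(broods)
    losses = broods["clutch_size"] - broods["brood_size"]
    if (losses < 0).any():
        raise ValueError("brood_size exceeds clutch_size in some broods")
    X = np.column_stack([np.ones(len(broods)), broods["k_soc"].astype(float)])
    names = ["const", "k_soc"]
    if np.var(broods["clutch_size"].astype(float)) == 0:
        clutch_fit = MixedModelResults(
            params=pd.Series(float("nan"), index=names),
            bse=pd.Series(float("nan"), index=names),
            vcomp=pd.Series(float("nan"), index=["cohort", "residual"]),
            n_obs=len(broods),
            method="REML (sparse MME, Powell)",
            converged=False,
            flags=["degenerate: clutch size has zero variance"],
        )
    else:
        clutch_fit = LinearMixedModel(
            broods["clutch_size"].astype(float),
            X,
            names,
            vc={"cohort": broods["cohort"]},
        ).fit(compute_vc_se=False)
    rows = expand_binomial(broods["brood_size"], losses, broods)
    Xs = np.column_stack([np.ones(len(rows)), rows["k_soc"].astype(float)])
    surv_fit = BinomialMixedModel(
        rows["_y"].to_numpy(), Xs, names, vc={"cohort": rows["cohort"]}
    ).fit()
    return clutch_fit, surv_fit
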
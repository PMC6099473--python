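"""End-to-end pipeline driver and summary tables.

``run_pipeline`` chains the whole analysis — simulate (or load) a study
population, restrict to pedigree-complete individuals, summarize
kinship/inbreeding categories, fit the infidelity and inbreeding-
depression models, and run the faithful-pedigree counterfactual —
writing both machine-readable (JSON/TSV) and human-readable reports.
Every number in the text report is taken from the machine-readable
bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import counterfactual as cf
from .depression import FledglingSurvivalModel, NestlingMassModel
from .infidelity import EPPModel, selective_disappearance_checks
from .pedigree import F_EPS, Pedigree, read_pedigree
from .results import MixedModelResults
from .simulate import SimulationParams, simulate_population, summarize_study

__all__ = ["PipelineConfig", "run_pipeline", "table1_summary", "pct"]

log = logging.getLogger("socped")


def pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in reports."""
    from decimal import ROUND_HALF_UP, Decimal

    if total == 0:
        return 0.0
    raw = Decimal(100 * count) / Decimal(total)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either provide input paths (``pedigree_path`` etc.) or leave them
    None to simulate a population with ``sim_params``.
    """

    outdir: str | pathlib.Path = "socped_out"
    seed: int = 0
    pedigree_path: str | None = None
    broods_path: str | None = None
    nestlings_path: str | None = None
    sim_params: SimulationParams | None = None
    min_grandparents: int = 1
    inbred_threshold: float = F_EPS
    animal_term: bool = True
    exclude_mother_son_hurdle: bool = True

    def __post_init__(self):
        if not 0 <= self.min_grandparents <= 4:
            raise ValueError("min_grandparents must be in 0..4")


def _kin_category(k: float) -> str:
    if k >= 0.25:
        return "high"
    if k >= 0.125:
        return "moderate"
    if k > F_EPS:
        return "low"
    return "zero"


def table1_summary(
    ped: Pedigree, broods: pd.DataFrame, ids: set[str]
) -> pd.DataFrame:
    """Kinship-between-social-partners and inbreeding category table.

    Panel A: percentage of broods by social-pair kinship category (all
    k_soc > 0, then high >= 0.25, moderate [0.125, 0.25), low (0,
    0.125)), with relationship-route labels for pairs at moderate+
    kinship.  Panel B: the same for individual inbreeding coefficients
    over the restricted id set.
    """
    rows = []
    n_broods = len(broods)
    cats = broods["k_soc"].map(_kin_category)
    n_rel = int((cats != "zero").sum())
    rows.append(("A_pairs", "all_k>0", n_rel, n_broods, pct(n_rel, n_broods)))
    for cat in ("high", "moderate", "low"):
        n = int((cats == cat).sum())
        rows.append(("A_pairs", cat, n, n_broods, pct(n, n_broods)))
    routes = broods.loc[cats.isin(["high", "moderate"])]
    route_counts: dict[str, int] = {}
    for r in routes.itertuples(index=False):
        label = ped.classify_relationship(r.social_father_id, r.mother_id)
        route_counts[label] = route_counts.get(label, 0) + 1
    for label, n in sorted(route_counts.items()):
        rows.append(("A_routes", label, n, n_broods, pct(n, n_broods)))

    f_all = ped.inbreeding_all()
    ids = sorted(ids)
    n_ids = len(ids)
    fcats = pd.Series({i: _kin_category(f_all[i]) for i in ids})
    n_inbred = int((fcats != "zero").sum())
    rows.append(("B_individuals", "all_f>0", n_inbred, n_ids, pct(n_inbred, n_ids)))
    for cat in ("high", "moderate", "low"):
        n = int((fcats == cat).sum())
        rows.append(("B_individuals", cat, n, n_ids, pct(n, n_ids)))
    iroutes: dict[str, int] = {}
    for i in fcats.index[fcats.isin(["high", "moderate"])]:
        s, d = ped.parents(i)
        label = ped.classify_relationship(s, d)
        iroutes[label] = iroutes.get(label, 0) + 1
    for label, n in sorted(iroutes.items()):
        rows.append(("B_routes", label, n, n_ids, pct(n, n_ids)))
    return pd.DataFrame(
        rows, columns=["panel", "category", "count", "total", "percent"]
    )


def _fit_record(name: str, fit: MixedModelResults | None) -> dict:
    if fit is None:
        return {"name": name, "fitted": False}
    ci = fit.conf_int()
    return {
        "name": name,
        "fitted": True,
        "converged": fit.converged,
        "flags": list(fit.flags),
        "n_obs": fit.n_obs,
        "coefficients": {
            k: {
                "estimate": float(fit.params[k]),
                "se": float(fit.bse[k]),
                "ci_lower": float(ci.loc[k, "lower"]),
                "ci_upper": float(ci.loc[k, "upper"]),
            }
            for k in fit.params.index
        },
        "variance_components": {k: float(v) for k, v in fit.vcomp.items()},
        "extra": {
            k: v for k, v in fit.extra.items() if isinstance(v, (int, float, bool, str))
        },
    }


def _load_or_simulate(config: PipelineConfig):
    if config.pedigree_path:
        ped = read_pedigree(config.pedigree_path)
        broods = pd.read_csv(config.broods_path)
        nestlings = pd.read_csv(config.nestlings_path)
        return ped, broods, nestlings, None
    params = config.sim_params or SimulationParams(seed=config.seed)
    if config.sim_params is not None and config.sim_params.seed != config.seed:
        params = dataclasses.replace(params, seed=config.seed)
    study = simulate_population(params)
    return study.pedigree, study.broods, study.nestlings, study


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle (also written
    to ``config.outdir``).

    Stage failures are caught per stage and recorded in the bundle's
    ``errors`` section rather than aborting the whole run.
    """
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": {
        k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
        for k, v in dataclasses.asdict(config).items()
    }, "errors": {}}

    ped, broods, nestlings, study = _load_or_simulate(config)
    log.info("inputs: %d pedigree records, %d broods, %d nestlings",
             len(ped), len(broods), len(nestlings))

    if study is not None:
        bundle["calibration"] = summarize_study(study).to_dict()
        study.write(out / "data")

    restricted = ped.restrict(config.min_grandparents)
    analysis_ids = restricted & set(nestlings["id"])
    log.info("restriction min_grandparents=%d keeps %d of %d measured nestlings",
             config.min_grandparents, len(analysis_ids), len(nestlings))
    bundle["restriction"] = {
        "min_grandparents": config.min_grandparents,
        "n_retained": len(analysis_ids),
        "n_measured": len(nestlings),
    }

    nest_ms = dict(zip(broods["nest_id"], broods["is_mother_son"]))
    nestlings = nestlings.assign(
        is_mother_son=nestlings["nest_id"].map(nest_ms).fillna(False)
    )
    ann = nestlings[nestlings["id"].isin(analysis_ids)].reset_index(drop=True)

    # ---- kinship/inbreeding category table
    try:
        t1 = table1_summary(ped, broods, analysis_ids)
        t1.to_csv(out / "table1_summary.tsv", sep="\t", index=False)
        bundle["table1"] = t1.to_dict(orient="records")
    except Exception as err:  # noqa: BLE001 - stage isolation
        bundle["errors"]["table1"] = repr(err)

    # ---- brood-level infidelity models
    try:
        fits = {
            "epp_with_mother_son": EPPModel(broods, include_mother_son=True).fit(),
            "epp_without_mother_son": EPPModel(broods, include_mother_son=False).fit(),
        }
        clutch_fit, surv_fit = selective_disappearance_checks(broods)
        fits["selective_disappearance_clutch"] = clutch_fit
        fits["selective_disappearance_survival"] = surv_fit
        bundle["infidelity"] = [_fit_record(k, v) for k, v in fits.items()]
    except Exception as err:  # noqa: BLE001
        bundle["errors"]["infidelity"] = repr(err)

    # ---- inbreeding depression
    try:
        mass_fit = NestlingMassModel(
            ann, ped, animal_term=config.animal_term
        ).fit()
        surv_nomass = FledglingSurvivalModel(ann, with_mass=False).fit()
        surv_mass = FledglingSurvivalModel(ann, with_mass=True).fit()
        bundle["depression"] = [
            _fit_record("mass_animal_model", mass_fit),
            _fit_record("survival_without_mass", surv_nomass),
            _fit_record("survival_with_mass", surv_mass),
        ]
    except Exception as err:  # noqa: BLE001
        bundle["errors"]["depression"] = repr(err)

    # ---- counterfactual
    try:
        assignments = cf.assignments_from_study(ped, broods, nestlings)
        faithful = cf.build_faithful_pedigree(ped, assignments)
        contrast = cf.inbreeding_contrast(
            ped, faithful, analysis_ids, assignments, config.inbred_threshold
        )
        fr_of = cf.fisher_exact(contrast.observed_faithful)
        fr_we = cf.fisher_exact(contrast.wp_ep)
        stage1, stage2 = cf.fit_hurdle_inbreeding(
            ann, exclude_mother_son=config.exclude_mother_son_hurdle
        )
        bundle["counterfactual"] = {
            "observed_faithful": {
                "counts": contrast.observed_faithful.counts.tolist(),
                "row_percent": contrast.observed_faithful.row_percentages().tolist(),
                "fisher_p": fr_of.p_value,
                "odds_ratio": fr_of.odds_ratio,
            },
            "wp_ep": {
                "counts": contrast.wp_ep.counts.tolist(),
                "row_percent": contrast.wp_ep.row_percentages().tolist(),
                "fisher_p": fr_we.p_value,
                "odds_ratio": fr_we.odds_ratio,
            },
            "hurdle": [
                _fit_record("stage1_inbred_status", stage1),
                _fit_record("stage2_log_f", stage2),
            ],
        }
    except Exception as err:  # noqa: BLE001
        bundle["errors"]["counterfactual"] = repr(err)

    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    _write_text_report(bundle, out / "report.txt")
    return bundle


def _write_text_report(bundle: dict, path) -> None:
    lines = ["socped pipeline report", "=" * 40, ""]
    r = bundle.get("restriction", {})
    lines.append(
        f"Restriction: >= {r.get('min_grandparents')} known grandparents; "
        f"{r.get('n_retained')} of {r.get('n_measured')} measured nestlings retained."
    )
    if "calibration" in bundle:
        lines.append("")
        lines.append("Calibration summary (simulated study):")
        for k, v in bundle["calibration"].items():
            lines.append(f"  {k}: {v:.1f}")
    for section in ("infidelity", "depression"):
        for recd in bundle.get(section, []):
            lines.append("")
            lines.append(f"[{section}] {recd['name']}:")
            if not recd.get("fitted"):
                lines.append("  not fitted")
                continue
            for k, c in recd["coefficients"].items():
                lines.append(
                    f"  {k:>16s}: {c['estimate']: .3f} ({c['se']:.3f}) "
                    f"[{c['ci_lower']: .3f}, {c['ci_upper']: .3f}]"
                )
            if recd["flags"]:
                lines.append(f"  flags: {recd['flags']}")
    cfb = bundle.get("counterfactual")
    if cfb:
        lines.append("")
        lines.append("[counterfactual] observed vs faithful pedigree:")
        lines.append(f"  counts: {cfb['observed_faithful']['counts']}")
        lines.append(f"  Fisher p: {cfb['observed_faithful']['fisher_p']:.2e}")
        lines.append("[counterfactual] WP vs EP inbred/outbred:")
        lines.append(f"  counts: {cfb['wp_ep']['counts']}")
        lines.append(f"  Fisher p: {cfb['wp_ep']['fisher_p']:.2e}")
    if bundle.get("errors"):
        lines.append("")
        lines.append(f"stage errors: {bundle['errors']}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
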
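"""Shared results container for the package's mixed models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MixedModelResults"]


@dataclass
class MixedModelResults:
    """Estimates, uncertainties and diagnostics from a mixed-model fit.

    ``params``/``bse`` are fixed effects on the link scale; ``vcomp``
    holds variance components (natural scale, >= 0).  ``flags`` collects
    non-fatal diagnostics (non-convergence, separation, degenerate
    inputs); a model that cannot be fitted meaningfully is returned
    flagged rather than raised.
    """

    params: pd.Series
    bse: pd.Series
    vcomp: pd.Series
    n_obs: int
    method: str
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    vcomp_se: pd.Series | None = None
    loglike: float | None = None
    extra: dict = field(default_factory=dict)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def covers(self, name: str, value: float, alpha: float = 0.05) -> bool:
        """Whether the (1 - alpha) Wald CI for ``name`` contains ``value``."""
        ci = self.conf_int(alpha).loc[name]
        return bool(ci["lower"] <= value <= ci["upper"])

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Mixed model fit ({self.method}); n_obs = {self.n_obs}; "
            f"converged = {self.converged}",
        ]
        if self.flags:
            lines.append("flags: " + "; ".join(self.flags))
        lines.append("")
        lines.append("Fixed effects:")
        lines.append(self.to_frame().round(4).to_string())
        lines.append("")
        lines.append("Variance components:")
        vdf = pd.DataFrame({"variance": self.vcomp})
        if self.vcomp_se is not None:
            vdf["se"] = self.vcomp_se
        lines.append(vdf.round(4).to_string())
        for k, v in self.extra.items():
            lines.append(f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<MixedModelResults: {self.method}, n={self.n_obs}, converged={self.converged}>"
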
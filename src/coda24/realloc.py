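"""Compositional time reallocation (isotemporal substitution).

Given a fitted compositional model and a base composition — by convention
the sample's compositional geometric mean closed to 1440 min — the engine
predicts the wellbeing difference associated with moving ``delta`` minutes
from one behaviour to another while holding the 24-hour total constant:

    d = [ilr(base with delta moved) - ilr(base)]' beta_ilr

Covariates cancel in the difference, so only the ILR coefficient block and
its covariance matter. The standard error is the delta-method form
``sqrt(dz' Cov(beta) dz)`` and intervals use the fitting module's t(G-1)
reference. The ILR map is nonlinear in delta, so A->B and B->A differences
are antisymmetric only to first order in delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coda import Composition, ilr_pivot
from .models import FittedCompositionModel

__all__ = [
    "ReallocationSpec",
    "ReallocationEstimate",
    "InfeasibleReallocationError",
    "reallocate",
    "predict_difference",
    "reallocation_grid",
]


class InfeasibleReallocationError(ValueError):
    """The requested shift would empty (or overdraw) the donor behaviour."""


@dataclass(frozen=True)
class ReallocationSpec:
    """Grid settings: how much time to move, between which behaviours."""

    delta: float = 30.0  # minutes
    pairs: tuple[tuple[str, str], ...] | None = None  # None -> all ordered pairs
    level: float = 0.95

    def resolved_pairs(self, parts: Sequence[str]) -> tuple[tuple[str, str], ...]:
        if self.pairs is not None:
            return self.pairs
        return tuple(permutations(parts, 2))


@dataclass(frozen=True)
class ReallocationEstimate:
    """Predicted outcome difference for one (from, to, outcome) cell."""

    from_part: str
    to_part: str
    delta: float
    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float

    @property
    def significant(self) -> bool:
        """CI excludes zero at the stated level."""
        return self.ci_low > 0 or self.ci_high < 0

    @property
    def per_minute(self) -> float:
        return self.estimate / self.delta if self.delta else 0.0

    def as_dict(self) -> dict:
        return {
            "from": self.from_part,
            "to": self.to_part,
            "delta_min": self.delta,
            "outcome": self.outcome,
            "beta": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "beta_per_min": self.per_minute,
            "significant": self.significant,
        }


def reallocate(
    base: Composition, from_part: str, to_part: str, delta: float
) -> Composition:
    """Move ``delta`` minutes from one behaviour to another; total preserved."""
    if from_part not in base.parts or to_part not in base.parts:
        raise KeyError(f"parts must be among {base.parts}")
    if from_part == to_part:
        raise ValueError("donor and recipient behaviours must differ")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta >= base[from_part]:
        raise InfeasibleReallocationError(
            f"cannot move {delta} min out of {from_part} "
            f"({base[from_part]:.1f} min available)"
        )
    vals = base.values.copy()
    i, j = base.parts.index(from_part), base.parts.index(to_part)
    vals[i] -= delta
    vals[j] += delta
    return Composition(base.parts, vals, base.closure_constant)


def predict_difference(
    model: FittedCompositionModel,
    base: Composition,
    from_part: str,
    to_part: str,
    delta: float,
    level: float = 0.95,
) -> ReallocationEstimate:
    """Predicted outcome change for one reallocation, with its t(G-1) CI."""
    if set(base.parts) != set(model.spec.parts):
        raise ValueError(
            f"model parts {model.spec.parts} do not match base parts {base.parts}"
        )
    basis = model.spec.basis
    if delta == 0:
        dz = np.zeros(len(base.parts) - 1)
    else:
        shifted = reallocate(base, from_part, to_part, delta)
        dz = ilr_pivot(shifted, basis).z - ilr_pivot(base, basis).z
    beta = model.ilr_beta()
    cov = model.ilr_cov()
    est = float(dz @ beta)
    se = float(np.sqrt(dz @ cov @ dz))
    tcrit = stats.t.ppf(0.5 + level / 2, model.df_inference)
    return ReallocationEstimate(
        from_part=from_part,
        to_part=to_part,
        delta=delta,
        outcome=model.spec.outcome,
        estimate=est,
        se=se,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        level=level,
    )


def reallocation_grid(
    models: Mapping[str, FittedCompositionModel],
    base: Composition,
    spec: ReallocationSpec | None = None,
) -> pd.DataFrame:
    """All ordered behaviour pairs x all outcomes as a tidy estimate table.

    ``models`` maps outcome name to a fitted model (any single rotation per
    outcome — the prediction is basis-consistent because each model supplies
    both its coefficients and the basis they live in).
    """
    spec = spec or ReallocationSpec()
    rows = []
    for outcome, model in models.items():
        for from_part, to_part in spec.resolved_pairs(base.parts):
            est = predict_difference(
                model, base, from_part, to_part, spec.delta, level=spec.level
            )
            rows.append(est.as_dict())
    return pd.DataFrame(rows)
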
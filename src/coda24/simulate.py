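"""Synthetic cohort generator with known ground truth.

The generator emulates a cross-sectional school-based study of adolescent
24-hour movement behaviours and wellbeing: n = 124 analysed adolescents
(ages 13-17) across 7 school clusters, 4-part daily time-use compositions
whose compositional geometric mean sits at the study's descriptive centre
(sleep 473.0, SED 680.9, LPA 250.7, MVPA 35.3 min), and five wellbeing
domain scores generated from a linear model in ILR coordinates with age,
gender and additive school effects.

Generative family
-----------------
Compositions are logistic-normal: ILR coordinates are drawn from a
multivariate normal centred at the ILR image of the target centre, then
mapped back to the simplex and closed to 1440 min. The default ILR
covariance is constructed from a target variation matrix whose ordering
matches the study's co-dependence structure (sleep-SED most co-dependent,
MVPA pairs most distinct). Outcomes are

    y = mean + (z - mu_z)' beta_z + (age - mean age) beta_age
        + female beta_gender + school effect + noise

with every ingredient stored in :class:`SyntheticTruth` so downstream fits
can be checked against the parameters that generated the data. All draws
come from ``numpy.random.default_rng`` (PCG64): a fixed seed reproduces the
dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .coda import (
    CANONICAL_PARTS,
    Composition,
    IlrBasis,
    close,
    ilr_pivot,
    ilr_transform,
)
from .wellbeing import DOMAINS, N_ITEMS, DEFAULT_ITEM_MAPPING

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "default_ilr_covariance",
    "generate_compositions",
    "generate_demographics",
    "generate_outcomes",
    "generate_item_responses",
    "generate_analysis_dataset",
    "generate_study",
]

#: Study-centre geometric means, minutes/day (sleep, SED, LPA, MVPA).
TARGET_GM: tuple[float, ...] = (473.0, 680.9, 250.7, 35.3)

#: Target pairwise log-ratio variances. The three waking/sleep pairs use the
#: study's printed values; MVPA pairs (unpublished) are set large enough to
#: keep MVPA the most compositionally distinct behaviour, with a log-variance
#: consistent with the reported arithmetic-vs-geometric MVPA gap.
DEFAULT_VARIATION: dict[frozenset, float] = {
    frozenset(("sleep", "sed")): 0.054,
    frozenset(("sleep", "lpa")): 0.063,
    frozenset(("sed", "lpa")): 0.088,
    frozenset(("sleep", "mvpa")): 0.38,
    frozenset(("sed", "mvpa")): 0.42,
    frozenset(("lpa", "mvpa")): 0.46,
}

#: Wellbeing domain means at the cohort's covariate centre (scale units).
DOMAIN_MEANS: dict[str, float] = {
    "engagement": 3.39,
    "perseverance": 3.62,
    "optimism": 3.61,
    "connectedness": 4.35,
    "happiness": 3.92,
}

#: Default true compositional effect per domain, expressed as a centred
#: (clr-scale) gradient over (sleep, SED, LPA, MVPA). Only happiness carries
#: a non-null effect by default: LPA up, SED down — the direction the study
#: design is built to detect. The magnitudes are the sum-zero projection of
#: plausible pivot-scale coefficients; signs, not magnitudes, are the target.
DEFAULT_CLR_BETA: dict[str, tuple[float, float, float, float]] = {
    "engagement": (0.0, 0.0, 0.0, 0.0),
    "perseverance": (0.0, 0.0, 0.0, 0.0),
    "optimism": (0.0, 0.0, 0.0, 0.0),
    "connectedness": (0.0, 0.0, 0.0, 0.0),
    "happiness": (-0.23, -0.96, 1.04, 0.15),
}


def _variation_to_clr_cov(
    variation: Mapping[frozenset, float], parts: tuple[str, ...]
) -> np.ndarray:
    """Centred log-ratio covariance implied by a target variation matrix.

    Uses the standard identity Sigma_clr = -(1/2) G T G with G the centring
    projector; T must be realisable (the result must be PSD).
    """
    D = len(parts)
    T = np.zeros((D, D))
    for i in range(D):
        for j in range(D):
            if i != j:
                T[i, j] = variation[frozenset((parts[i], parts[j]))]
    G = np.eye(D) - np.ones((D, D)) / D
    cov = -0.5 * G @ T @ G
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10:
        raise ValueError("target variation matrix is not realisable (clr cov not PSD)")
    return cov


def default_ilr_covariance(
    variation: Mapping[frozenset, float] | None = None,
) -> np.ndarray:
    """3x3 ILR covariance (canonical pivot basis) from a target variation matrix."""
    variation = variation or DEFAULT_VARIATION
    parts = CANONICAL_PARTS
    cov_clr = _variation_to_clr_cov(variation, parts)
    V = IlrBasis(parts).contrast_matrix(parts)
    return V.T @ cov_clr @ V


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    n_participants: int = 124
    n_schools: int = 7
    target_gm: tuple[float, ...] = TARGET_GM
    ilr_covariance: np.ndarray | None = None  # None -> default_ilr_covariance()
    clr_beta: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLR_BETA)
    )
    beta_age: float = -0.05  # per year
    beta_gender: float = -0.10  # female vs male
    school_sd: float = 0.15  # between-school outcome SD
    noise_sd: float = 0.60  # residual outcome SD
    item_sd: float = 0.25  # item-level noise around the domain score
    age_mean: float = 14.8
    age_sd: float = 1.0
    p_gender: tuple[float, float, float] = (0.492, 0.460, 0.048)  # male/female/other
    day_sd: float = 0.10  # day-to-day ILR scatter around the person mean
    seed: int = 0

    def resolved_ilr_cov(self) -> np.ndarray:
        if self.ilr_covariance is None:
            return default_ilr_covariance()
        cov = np.asarray(self.ilr_covariance, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("ilr_covariance must be symmetric 3x3")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("ilr_covariance must be positive semi-definite")
        return cov

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SyntheticTruth:
    """The parameters and latent quantities behind a generated dataset."""

    beta_ilr: dict[str, np.ndarray]  # per-domain ILR coefficients, canonical basis
    beta_age: float
    beta_gender: float
    intercepts: dict[str, float]
    school_effects: dict[str, np.ndarray]  # per-domain, one value per school
    noiseless: pd.DataFrame  # per-participant outcomes before residual noise
    mu_ilr: np.ndarray

    def as_jsonable(self) -> dict:
        return {
            "beta_ilr": {d: list(map(float, b)) for d, b in self.beta_ilr.items()},
            "beta_age": self.beta_age,
            "beta_gender": self.beta_gender,
            "intercepts": self.intercepts,
            "school_effects": {
                d: list(map(float, v)) for d, v in self.school_effects.items()
            },
            "mu_ilr": list(map(float, self.mu_ilr)),
            "rng": "numpy default_rng (PCG64)",
        }


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Deterministic factor L with L L' = cov, valid for any PSD matrix."""
    w, U = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _draw_ilr(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    mu = ilr_pivot(close(config.target_gm)).z
    L = _psd_factor(config.resolved_ilr_cov())
    return mu + rng.standard_normal((n, 3)) @ L.T


def generate_compositions(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[Composition]:
    """Draw logistic-normal daily compositions centred at the target centre."""
    rng = rng if rng is not None else config.rng()
    Z = _draw_ilr(config, config.n_participants, rng)
    basis = IlrBasis(CANONICAL_PARTS)
    V = basis.contrast_matrix(CANONICAL_PARTS)
    vals = np.exp(Z @ V.T)
    return [close(v) for v in vals]


def generate_demographics(
    config: GeneratorConfig, rng: np.random.Generator | None = None, n: int | None = None
) -> pd.DataFrame:
    """Ages (13-17), gender and school assignment for ``n`` participants."""
    rng = rng if rng is not None else config.rng()
    n = n if n is not None else config.n_participants
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 13.0, 17.0)
    gender = rng.choice(["male", "female", "other"], size=n, p=config.p_gender)
    school = rng.integers(0, config.n_schools, size=n)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": np.round(age, 1),
            "gender": gender,
            "school": [f"S{s}" for s in school],
        }
    )


def generate_outcomes(
    Z: np.ndarray,
    demographics: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Wellbeing domain scores from the linear model in ILR coordinates.

    Returns the (continuous, unclipped) outcomes and the full ground truth.
    Clipping into [1, 5] happens only when item responses are rendered.
    """
    rng = rng if rng is not None else config.rng()
    Z = np.asarray(Z, dtype=float)
    n = len(demographics)
    if Z.shape != (n, 3):
        raise ValueError(f"Z must be ({n}, 3); got {Z.shape}")
    basis = IlrBasis(CANONICAL_PARTS)
    V = basis.contrast_matrix(CANONICAL_PARTS)
    mu_ilr = ilr_pivot(close(config.target_gm)).z
    # centring the covariates keeps each domain's population mean at its
    # configured level regardless of the effect sizes
    female = (demographics["gender"] == "female").to_numpy(float) - config.p_gender[1]
    age_c = demographics["age"].to_numpy(float) - config.age_mean
    schools = sorted(demographics["school"].unique())
    school_ix = demographics["school"].map({s: i for i, s in enumerate(schools)})

    beta_ilr: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    school_effects: dict[str, np.ndarray] = {}
    noiseless = {}
    outcomes = {}
    for d in DOMAINS:
        b_clr = np.asarray(config.clr_beta[d], dtype=float)
        if len(b_clr) != 4:
            raise ValueError(f"clr_beta[{d}] must have 4 entries")
        b_clr = b_clr - b_clr.mean()  # enforce the centred representation
        b_ilr = V.T @ b_clr
        eff = rng.normal(0.0, config.school_sd, len(schools)) if config.school_sd else np.zeros(len(schools))
        mean_y = (
            DOMAIN_MEANS[d]
            + (Z - mu_ilr) @ b_ilr
            + age_c * config.beta_age
            + female * config.beta_gender
            + eff[school_ix]
        )
        y = mean_y + (
            rng.normal(0.0, config.noise_sd, n) if config.noise_sd else 0.0
        )
        beta_ilr[d] = b_ilr
        intercepts[d] = DOMAIN_MEANS[d]
        school_effects[d] = eff
        noiseless[d] = mean_y
        outcomes[d] = y
    truth = SyntheticTruth(
        beta_ilr=beta_ilr,
        beta_age=config.beta_age,
        beta_gender=config.beta_gender,
        intercepts=intercepts,
        school_effects=school_effects,
        noiseless=pd.DataFrame(noiseless, index=demographics.index),
        mu_ilr=mu_ilr,
    )
    return pd.DataFrame(outcomes, index=demographics.index), truth


def generate_item_responses(
    scores: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    mapping: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Render domain scores as 20 Likert items (rounded, clipped to 1..5).

    With zero item noise each item equals the rounded domain score, so
    re-scoring recovers the domain mean up to discretisation.
    """
    rng = rng if rng is not None else config.rng()
    mapping = dict(mapping) if mapping is not None else DEFAULT_ITEM_MAPPING
    n = len(scores)
    cols = {}
    for item in range(1, N_ITEMS + 1):
        target = scores[mapping[item]].to_numpy(float)
        noisy = target + (rng.normal(0.0, config.item_sd, n) if config.item_sd else 0.0)
        cols[f"item_{item:02d}"] = np.clip(np.rint(noisy), 1, 5).astype(int)
    return pd.DataFrame(cols, index=scores.index)


def generate_analysis_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """One tidy analysis table: composition, demographics and outcomes.

    This is the regression-ready dataset (participants already past all
    inclusion filters); :func:`generate_study` produces the messier upstream
    files including excluded participants.
    """
    rng = config.rng()
    demo = generate_demographics(config, rng)
    Z = _draw_ilr(config, config.n_participants, rng)
    basis = IlrBasis(CANONICAL_PARTS)
    V = basis.contrast_matrix(CANONICAL_PARTS)
    comp = pd.DataFrame(
        close(v).values for v in np.exp(Z @ V.T)
    )
    comp.columns = list(CANONICAL_PARTS)
    outcomes, truth = generate_outcomes(Z, demo, config, rng)
    df = pd.concat(
        [demo.reset_index(drop=True), comp.reset_index(drop=True), outcomes.reset_index(drop=True)],
        axis=1,
    )
    return df, truth


def _day_summaries_for(
    pid: str,
    comp_minutes: np.ndarray,
    n_days: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    wear_low: float = 16.0,
    wear_high: float = 24.0,
) -> list[dict]:
    """Per-day rows scattering around a participant's mean composition."""
    z0 = ilr_transform(comp_minutes[None, :], CANONICAL_PARTS, IlrBasis(CANONICAL_PARTS))[0]
    V = IlrBasis(CANONICAL_PARTS).contrast_matrix(CANONICAL_PARTS)
    rows = []
    for day in range(1, n_days + 1):
        z = z0 + rng.normal(0.0, config.day_sd, 3)
        vals = close(np.exp(V @ z)).values
        rows.append(
            {
                "participant_id": pid,
                "day": day,
                "sleep_min": round(float(vals[0]), 1),
                "sed_min": round(float(vals[1]), 1),
                "lpa_min": round(float(vals[2]), 1),
                "mvpa_min": round(float(vals[3]), 1),
                "wear_hours": round(float(rng.uniform(wear_low, wear_high)), 1),
            }
        )
    return rows


def generate_study(
    config: GeneratorConfig,
    n_device_missing: int = 5,
    n_too_few_days: int = 30,
    n_low_wear: int = 30,
    n_invalid_wellbeing: int = 4,
) -> dict:
    """Generate the full enrolled study, exclusions included.

    Returns a dict with the enrolment ``roster``, long ``days`` table,
    wide ``items`` table, ``demographics``, the analysis ``dataset`` of
    included participants, and the ``truth`` object. Default exclusion
    counts reproduce a 193-enrolled / 124-analysed flow.
    """
    rng = config.rng()
    demo = generate_demographics(config, rng)
    Z = _draw_ilr(config, config.n_participants, rng)
    basis = IlrBasis(CANONICAL_PARTS)
    V = basis.contrast_matrix(CANONICAL_PARTS)
    comp_minutes = np.stack([close(v).values for v in np.exp(Z @ V.T)])
    outcomes, truth = generate_outcomes(Z, demo, config, rng)
    items = generate_item_responses(outcomes.clip(1.0, 5.0), config, rng)

    day_rows: list[dict] = []
    item_rows: list[dict] = []
    roster: list[dict] = []

    for i, pid in enumerate(demo["participant_id"]):
        n_days = int(rng.integers(4, 8))
        day_rows += _day_summaries_for(pid, comp_minutes[i], n_days, config, rng)
        item_rows.append({"participant_id": pid, **items.iloc[i].to_dict()})
        roster.append({"participant_id": pid, "status": "included"})

    n_inc = config.n_participants
    next_id = n_inc

    def _new_pid() -> str:
        nonlocal next_id
        pid = f"P{next_id:04d}"
        next_id += 1
        return pid

    extra_Z = _draw_ilr(
        config, n_device_missing + n_too_few_days + n_low_wear + n_invalid_wellbeing, rng
    )
    extra_minutes = np.stack([close(v).values for v in np.exp(extra_Z @ V.T)])
    k = 0
    for _ in range(n_device_missing):  # no accelerometer file at all
        roster.append({"participant_id": _new_pid(), "status": "device_missing"})
        k += 1
    for _ in range(n_too_few_days):  # only 2 days recorded
        pid = _new_pid()
        day_rows += _day_summaries_for(pid, extra_minutes[k], 2, config, rng)
        roster.append({"participant_id": pid, "status": "fewer_than_3_valid_days"})
        k += 1
    for _ in range(n_low_wear):  # days present but all under the wear threshold
        pid = _new_pid()
        day_rows += _day_summaries_for(
            pid,
            extra_minutes[k],
            int(rng.integers(4, 8)),
            config,
            rng,
            wear_low=8.0,
            wear_high=15.9,
        )
        roster.append({"participant_id": pid, "status": "under_16h_wear"})
        k += 1
    for _ in range(n_invalid_wellbeing):  # valid movement, broken questionnaire
        pid = _new_pid()
        day_rows += _day_summaries_for(pid, extra_minutes[k], 5, config, rng)
        bad = {f"item_{j:02d}": int(rng.integers(1, 6)) for j in range(1, N_ITEMS + 1)}
        bad["item_07"] = np.nan  # missing item invalidates the sheet
        item_rows.append({"participant_id": pid, **bad})
        roster.append({"participant_id": pid, "status": "invalid_wellbeing"})
        k += 1

    dataset = pd.concat(
        [
            demo.reset_index(drop=True),
            pd.DataFrame(comp_minutes, columns=list(CANONICAL_PARTS)),
            outcomes.reset_index(drop=True),
        ],
        axis=1,
    )
    return {
        "roster": pd.DataFrame(roster),
        "days": pd.DataFrame(day_rows),
        "items": pd.DataFrame(item_rows),
        "demographics": demo,
        "dataset": dataset,
        "truth": truth,
        "config": config,
    }
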
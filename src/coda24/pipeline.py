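"""End-to-end study pipeline: ingest or simulate, filter, analyse, report.

Stages mirror the study workflow:

1. **ingest / simulate** — read day-level movement summaries, wellbeing item
   sheets and demographics (or generate them synthetically with known truth);
2. **process** — valid-day filtering, per-participant compositions,
   wellbeing scoring, and the inclusion-flow tally;
3. **analyse** — descriptives (arithmetic and compositional geometric means,
   percentage shares), the variation matrix, the four rotated ILR
   regressions per wellbeing domain, and the 30-min reallocation grid;
4. **report** — delimited tables plus a JSON payload, with the run config
   serialised alongside so any run is reproducible from its output folder.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coda, movement, realloc, wellbeing
from .coda import CANONICAL_PARTS, Composition, close, geometric_mean_composition
from .models import fit_rotations, model_diagnostics, rotation_table
from .simulate import GeneratorConfig, generate_study
from .wellbeing import DOMAINS

log = logging.getLogger("coda24")

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "descriptives", "process_study"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    out_dir: str | Path = "results/run"
    # Either input paths ...
    days_path: str | None = None
    items_path: str | None = None
    demographics_path: str | None = None
    mapping_path: str | None = None
    # ... or a synthetic generator.
    generator: GeneratorConfig | None = None
    closure_constant: float = 1440.0
    delta: float = 30.0
    alpha: float = 0.05
    pivot_order: tuple[str, ...] = CANONICAL_PARTS

    def as_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            cov = g.get("ilr_covariance")
            g["ilr_covariance"] = None if cov is None else np.asarray(cov).tolist()
            g["clr_beta"] = {k: list(v) for k, v in g["clr_beta"].items()}
            d["generator"] = g
        return d


@dataclass
class StudyReport:
    """All computed tables of one run, with the n each was computed on."""

    flow: movement.InclusionFlow
    descriptives: dict
    variation: coda.VariationMatrix
    regressions: pd.DataFrame
    reallocations: pd.DataFrame
    diagnostics: dict
    n_analysed: int
    base_composition: Composition


def descriptives(dataset: pd.DataFrame) -> dict:
    """Cohort descriptive summary in the study's reporting layout.

    Arithmetic mean +/- SD of raw minutes per behaviour, the compositional
    geometric mean closed to 1440 with 1-d.p. percentage shares, wellbeing
    domain means +/- SD, and demographic counts.
    """
    comps = [close(row) for row in dataset[list(CANONICAL_PARTS)].to_numpy(float)]
    gm = geometric_mean_composition(comps)
    shares = np.round(gm.percentages, 1)
    out = {
        "n": int(len(dataset)),
        "arithmetic_mean_min": {
            p: round(float(dataset[p].mean()), 1) for p in CANONICAL_PARTS
        },
        "arithmetic_sd_min": {
            p: round(float(dataset[p].std(ddof=1)), 1) for p in CANONICAL_PARTS
        },
        "geometric_mean_min": {
            p: round(float(v), 1) for p, v in zip(CANONICAL_PARTS, gm.values)
        },
        "geometric_mean_pct": {p: float(s) for p, s in zip(CANONICAL_PARTS, shares)},
    }
    if "age" in dataset:
        out["age_mean"] = round(float(dataset["age"].mean()), 1)
        out["age_sd"] = round(float(dataset["age"].std(ddof=1)), 1)
    if "gender" in dataset:
        counts = dataset["gender"].value_counts()
        out["gender_counts"] = {k: int(v) for k, v in counts.items()}
        out["gender_pct"] = {
            k: round(100.0 * v / len(dataset), 1) for k, v in counts.items()
        }
    present = [d for d in DOMAINS if d in dataset]
    if present:
        out["epoch_means"] = {d: round(float(dataset[d].mean()), 2) for d in present}
        out["epoch_sds"] = {
            d: round(float(dataset[d].std(ddof=1)), 2) for d in present
        }
    return out


def process_study(
    days: pd.DataFrame,
    items: pd.DataFrame,
    demographics: pd.DataFrame,
    roster: pd.DataFrame | None = None,
    mapping: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, movement.InclusionFlow]:
    """Filter, score and merge the raw tables into the analysis dataset.

    Returns the per-participant analysis table (only included participants)
    and the inclusion-flow tally over everyone on the roster.
    """
    day_cols = set(movement.DAY_COLUMNS)
    if not day_cols <= set(days.columns):
        raise ValueError(
            f"day table missing columns: {sorted(day_cols - set(days.columns))}"
        )
    item_cols_req = {"participant_id"} | {
        f"item_{i:02d}" for i in range(1, wellbeing.N_ITEMS + 1)
    }
    if not item_cols_req <= set(items.columns):
        raise ValueError(
            f"item table missing columns: {sorted(item_cols_req - set(items.columns))}"
        )
    if "participant_id" not in demographics.columns:
        raise ValueError("demographics table missing column: participant_id")
    all_ids = (
        list(roster["participant_id"].astype(str))
        if roster is not None
        else sorted(
            set(demographics["participant_id"].astype(str))
            | set(days["participant_id"].astype(str))
        )
    )
    day_objs: dict[str, list[movement.DaySummary]] = {}
    for row in days.itertuples(index=False):
        day_objs.setdefault(str(row.participant_id), []).append(
            movement.DaySummary(
                participant_id=str(row.participant_id),
                day_index=int(row.day),
                sed_min=float(row.sed_min),
                lpa_min=float(row.lpa_min),
                mpa_min=float(row.mvpa_min),
                vpa_min=0.0,
                sleep_min=float(row.sleep_min),
                wear_hours=float(row.wear_hours),
            )
        )
    item_cols = [f"item_{i:02d}" for i in range(1, wellbeing.N_ITEMS + 1)]
    items_by_id = {
        str(r["participant_id"]): tuple(
            None if pd.isna(r[c]) else int(r[c]) for c in item_cols
        )
        for _, r in items.iterrows()
    }
    demo_by_id = demographics.set_index(demographics["participant_id"].astype(str))

    statuses = []
    rows = []
    for pid in all_ids:
        if pid not in day_objs:
            statuses.append({"participant_id": pid, "status": "device_missing"})
            continue
        validity = movement.filter_valid(day_objs[pid])
        if not validity.included:
            statuses.append({"participant_id": pid, "status": validity.reason})
            continue
        if pid not in items_by_id:
            statuses.append({"participant_id": pid, "status": "invalid_wellbeing"})
            continue
        response = wellbeing.EpochResponse(pid, items_by_id[pid])
        try:
            scores = wellbeing.score_epoch(response, mapping)
        except wellbeing.InvalidResponseError:
            statuses.append({"participant_id": pid, "status": "invalid_wellbeing"})
            continue
        comp = movement.participant_composition(validity.valid_days)
        row = {"participant_id": pid, **comp.as_dict(), **scores.as_dict()}
        if pid in demo_by_id.index:
            for c in ("age", "gender", "school"):
                if c in demo_by_id.columns:
                    row[c] = demo_by_id.loc[pid, c]
        row["n_valid_days"] = validity.n_valid
        rows.append(row)
        statuses.append({"participant_id": pid, "status": "included"})
    flow = movement.inclusion_flow(pd.DataFrame(statuses))
    return pd.DataFrame(rows), flow


def analyse(
    dataset: pd.DataFrame,
    delta: float = 30.0,
    alpha: float = 0.05,
    outcomes: tuple[str, ...] = DOMAINS,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, Composition, coda.VariationMatrix]:
    """Rotated regressions, reallocation grid and diagnostics for a dataset."""
    comps = [close(row) for row in dataset[list(CANONICAL_PARTS)].to_numpy(float)]
    variation = coda.variation_matrix(comps)
    base = geometric_mean_composition(comps)

    reg_tables = []
    primary_models = {}
    diagnostics = {}
    for outcome in outcomes:
        fits = fit_rotations(dataset, outcome, alpha=alpha)
        reg_tables.append(rotation_table(fits))
        primary_models[outcome] = fits[CANONICAL_PARTS[0]]
        diagnostics[outcome] = model_diagnostics(fits[CANONICAL_PARTS[0]])
    regressions = pd.concat(reg_tables, ignore_index=True)
    grid = realloc.reallocation_grid(
        primary_models, base, realloc.ReallocationSpec(delta=delta)
    )
    return regressions, grid, diagnostics, base, variation


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute every stage and write tables under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage=ingest")
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        study = generate_study(gen)
        days, items, demo, roster = (
            study["days"],
            study["items"],
            study["demographics"],
            study["roster"],
        )
        days.to_csv(out / "input_days.csv", index=False)
        items.to_csv(out / "input_items.csv", index=False)
        demo.to_csv(out / "input_demographics.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(study["truth"].as_jsonable(), fh, indent=2)
    else:
        if not (config.days_path and config.items_path and config.demographics_path):
            raise ValueError("either a generator or all three input paths required")
        days = pd.read_csv(config.days_path)
        items = pd.read_csv(config.items_path)
        demo = pd.read_csv(config.demographics_path)
        roster = None
    mapping = (
        wellbeing.read_item_mapping(config.mapping_path)
        if config.mapping_path
        else None
    )

    log.info("stage=process n_days_rows=%d", len(days))
    dataset, flow = process_study(days, items, demo, roster, mapping)
    log.info("stage=process included=%d of enrolled=%d", flow.final, flow.enrolled)

    log.info("stage=analyse n=%d", len(dataset))
    desc = descriptives(dataset)
    regressions, grid, diagnostics, base, variation = analyse(
        dataset, delta=config.delta, alpha=config.alpha
    )

    log.info("stage=report out=%s", out)
    dataset.to_csv(out / "analysis_dataset.csv", index=False)
    regressions.to_csv(out / "regressions.csv", index=False)
    grid.to_csv(out / "reallocations.csv", index=False)
    pd.DataFrame(
        variation.entries, index=variation.labels, columns=variation.labels
    ).to_csv(out / "variation_matrix.csv")
    payload = {
        "config": config.as_jsonable(),
        "inclusion_flow": flow.as_dict(),
        "descriptives": desc,
        "diagnostics": diagnostics,
        "n_analysed": int(len(dataset)),
        "base_composition": base.as_dict(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    return StudyReport(
        flow=flow,
        descriptives=desc,
        variation=variation,
        regressions=regressions,
        reallocations=grid,
        diagnostics=diagnostics,
        n_analysed=int(len(dataset)),
        base_composition=base,
    )
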
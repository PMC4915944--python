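"""Trial scheduler and synthetic-data generator for the speed-matching study.

The design crosses 3 reference/test contrast pairs (3%/15%, 3%/95%, 15%/95%)
with 4 reference speeds (1, 4, 8, 12 deg/s), giving 12 conditions.  The two
low speeds form a "low-speed" block (2 staircases per condition per session,
420 trials/session); the two high speeds a "high-speed" block (8 staircases
per condition per session, 1680 trials/session).  Over the 5 sessions this
pools to 10 staircases per low-speed condition and 40 per high-speed
condition.  High-speed conditions are sampled more densely because speed
judgments above 8 deg/s are more variable.

`generate_dataset` runs every scheduled staircase for a given generative
observer, with one child seed per staircase spawned from the master seed so
any staircase is reproducible in isolation.  `pse_summary` reduces a dataset
to the fitting method's sole input: per-condition mean PSE and the squared
standard error of a single staircase's PSE (the sample variance across
staircases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .models import ObserverSpec, observer_from_dict, observer_to_dict
from .staircase import QuestConfig, StaircaseResult, TrialRecord, run_staircase

__all__ = [
    "Condition",
    "ExperimentDesign",
    "Dataset",
    "build_design",
    "generate_dataset",
    "pse_summary",
    "trials_to_frame",
    "staircases_to_frame",
    "save_dataset",
    "load_dataset",
]

REFERENCE_SPEEDS = (1.0, 4.0, 8.0, 12.0)  # deg/s
CONTRAST_PAIRS = ((0.03, 0.15), (0.03, 0.95), (0.15, 0.95))  # (reference, test)
LOW_SPEED_BLOCK = (1.0, 4.0)
HIGH_SPEED_BLOCK = (8.0, 12.0)

TRIAL_LOG_COLUMNS = [
    "session",
    "condition_id",
    "staircase_id",
    "trial_index",
    "v_ref",
    "c_ref",
    "v_test",
    "c_test",
    "reference_side",
    "response_test_faster",
]

PSE_TABLE_COLUMNS = [
    "condition_id",
    "v_ref",
    "c_ref",
    "c_test",
    "n_staircases",
    "mean_pse",
    "sem2_pse",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the design: a reference speed and a contrast pair."""

    v_ref: float  # deg/s
    c_ref: float  # fraction; always the lower contrast
    c_test: float  # fraction
    condition_id: str = ""
    block: str = ""  # "low_speed" | "high_speed"

    def __post_init__(self):
        if self.v_ref <= 0:
            raise ValueError("v_ref must be positive")
        if not (0 < self.c_ref < self.c_test <= 1):
            raise ValueError("require 0 < c_ref < c_test <= 1")
        if not self.condition_id:
            cid = f"v{self.v_ref:g}_c{100 * self.c_ref:g}-{100 * self.c_test:g}"
            object.__setattr__(self, "condition_id", cid)
        if not self.block:
            block = "low_speed" if self.v_ref in LOW_SPEED_BLOCK else "high_speed"
            object.__setattr__(self, "block", block)
        if self.block not in ("low_speed", "high_speed"):
            raise ValueError("block must be 'low_speed' or 'high_speed'")


@dataclass(frozen=True)
class ExperimentDesign:
    conditions: tuple
    sessions: int = 5
    staircases_per_session: tuple = (("low_speed", 2), ("high_speed", 8))
    trials_per_staircase: int = 35
    spatial_frequency: float = 2.0  # cycles/deg

    def __post_init__(self):
        if self.sessions < 1:
            raise ValueError("sessions must be at least 1")
        if self.trials_per_staircase < 1:
            raise ValueError("trials_per_staircase must be at least 1")
        per_session = dict(self.staircases_per_session)
        if set(per_session) != {"low_speed", "high_speed"}:
            raise ValueError("staircases_per_session must map both blocks")
        if any(n < 1 for n in per_session.values()):
            raise ValueError("staircase counts must be at least 1")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def staircase_counts(self) -> Dict[str, int]:
        return dict(self.staircases_per_session)

    def block_conditions(self, block: str) -> List[Condition]:
        return [c for c in self.conditions if c.block == block]

    def trials_per_block_session(self, block: str) -> int:
        """Trials one session spends in a block."""
        n_cond = len(self.block_conditions(block))
        return n_cond * self.staircase_counts[block] * self.trials_per_staircase

    def staircases_per_condition(self, condition: Condition) -> int:
        """Staircases pooled over all sessions for one condition."""
        return self.sessions * self.staircase_counts[condition.block]

    def quest_config(self, **overrides) -> QuestConfig:
        return QuestConfig(n_trials=self.trials_per_staircase, **overrides)


@dataclass(frozen=True)
class Dataset:
    """A complete synthetic experiment, retaining its generating observer."""

    design: ExperimentDesign
    observer: ObserverSpec
    staircases: tuple
    master_seed: int

    def __post_init__(self):
        object.__setattr__(self, "staircases", tuple(self.staircases))
        counts: Dict[str, int] = {}
        for sc in self.staircases:
            counts[sc.condition_id] = counts.get(sc.condition_id, 0) + 1
        for cond in self.design.conditions:
            expected = self.design.staircases_per_condition(cond)
            if counts.get(cond.condition_id, 0) != expected:
                raise ValueError(
                    f"condition {cond.condition_id}: expected {expected} staircases, "
                    f"found {counts.get(cond.condition_id, 0)}"
                )

    @property
    def trials(self) -> List[TrialRecord]:
        return [t for sc in self.staircases for t in sc.trials]


def build_design(
    sessions: int = 5,
    staircases_low: int = 2,
    staircases_high: int = 8,
    trials_per_staircase: int = 35,
    spatial_frequency: float = 2.0,
    reference_speeds=REFERENCE_SPEEDS,
    contrast_pairs=CONTRAST_PAIRS,
) -> ExperimentDesign:
    """Default design: 12 conditions, 420 + 1680 trials per session."""
    conditions = tuple(
        Condition(v_ref=v, c_ref=lo, c_test=hi)
        for v in reference_speeds
        for (lo, hi) in contrast_pairs
    )
    return ExperimentDesign(
        conditions=conditions,
        sessions=sessions,
        staircases_per_session=(("low_speed", staircases_low), ("high_speed", staircases_high)),
        trials_per_staircase=trials_per_staircase,
        spatial_frequency=spatial_frequency,
    )


def generate_dataset(
    observer: ObserverSpec,
    design: Optional[ExperimentDesign] = None,
    master_seed: int = 0,
    quest: Optional[QuestConfig] = None,
) -> Dataset:
    """Simulate every scheduled staircase of the design.

    One child seed per staircase is spawned from ``master_seed`` with
    ``numpy.random.SeedSequence`` in a fixed enumeration order (session, then
    condition, then repeat), so the dataset is fully reproducible and any
    single staircase can be re-run in isolation.
    """
    design = design if design is not None else build_design()
    if quest is None:
        quest = design.quest_config()
    elif quest.n_trials != design.trials_per_staircase:
        raise ValueError("quest.n_trials must equal design.trials_per_staircase")
    schedule = [
        (session, cond, rep)
        for session in range(1, design.sessions + 1)
        for cond in design.conditions
        for rep in range(design.staircase_counts[cond.block])
    ]
    children = np.random.SeedSequence(master_seed).spawn(len(schedule))
    staircases = []
    counters: Dict[str, int] = {}
    for (session, cond, _rep), child in zip(schedule, children):
        sc_id = counters.get(cond.condition_id, 0)
        counters[cond.condition_id] = sc_id + 1
        staircases.append(
            run_staircase(
                observer,
                cond,
                quest,
                np.random.default_rng(child),
                session=session,
                staircase_id=sc_id,
            )
        )
    return Dataset(
        design=design, observer=observer, staircases=staircases, master_seed=master_seed
    )


def pse_summary(dataset: Dataset) -> pd.DataFrame:
    """Per-condition PSE table: the fitting method's sole input.

    ``mean_pse`` is the mean PSE over the pooled staircases; ``sem2_pse`` is
    the squared standard error of a *single* staircase's PSE estimate, i.e.
    the sample variance (ddof=1) across staircases.  Sessions are pooled.
    """
    by_cond: Dict[str, List[float]] = {}
    for sc in dataset.staircases:
        by_cond.setdefault(sc.condition_id, []).append(sc.pse)
    rows = []
    for cond in dataset.design.conditions:
        pses = np.asarray(by_cond[cond.condition_id])
        if pses.size < 2:
            raise ValueError(
                f"condition {cond.condition_id}: need >=2 staircases for a variance"
            )
        rows.append(
            {
                "condition_id": cond.condition_id,
                "v_ref": cond.v_ref,
                "c_ref": cond.c_ref,
                "c_test": cond.c_test,
                "n_staircases": int(pses.size),
                "mean_pse": float(pses.mean()),
                "sem2_pse": float(pses.var(ddof=1)),
            }
        )
    return pd.DataFrame(rows, columns=PSE_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def trials_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows = [
        {col: getattr(t, col) for col in TRIAL_LOG_COLUMNS} for t in dataset.trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def staircases_to_frame(dataset: Dataset) -> pd.DataFrame:
    rows = [
        {
            "condition_id": sc.condition_id,
            "session": sc.session,
            "staircase_id": sc.staircase_id,
            "pse": sc.pse,
            "n_trials": sc.n_trials,
        }
        for sc in dataset.staircases
    ]
    return pd.DataFrame(rows)


def normalize_contrast(values) -> np.ndarray:
    """Accept contrast as fraction or percent; return fractions."""
    values = np.asarray(values, dtype=float)
    return np.where(values > 1.0, values / 100.0, values)


def read_pse_table(path) -> pd.DataFrame:
    """Read a per-condition PSE table (CSV).  Contrasts may be percent or fraction."""
    table = pd.read_csv(path)
    missing = set(PSE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"PSE table is missing columns: {sorted(missing)}")
    table = table.copy()
    table["c_ref"] = normalize_contrast(table["c_ref"])
    table["c_test"] = normalize_contrast(table["c_test"])
    return table[PSE_TABLE_COLUMNS]


def save_dataset(dataset: Dataset, out_dir) -> None:
    """Write a dataset directory: trial log, staircase PSEs, summary, metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_to_frame(dataset).to_csv(out / "trials.csv", index=False)
    staircases_to_frame(dataset).to_csv(out / "staircases.csv", index=False)
    pse_summary(dataset).to_csv(out / "pse_table.csv", index=False)
    meta = {
        "master_seed": dataset.master_seed,
        "observer": observer_to_dict(dataset.observer),
        "design": {
            "sessions": dataset.design.sessions,
            "staircases_per_session": dict(dataset.design.staircases_per_session),
            "trials_per_staircase": dataset.design.trials_per_staircase,
            "spatial_frequency": dataset.design.spatial_frequency,
            "conditions": [
                {
                    "condition_id": c.condition_id,
                    "v_ref": c.v_ref,
                    "c_ref": c.c_ref,
                    "c_test": c.c_test,
                    "block": c.block,
                }
                for c in dataset.design.conditions
            ],
        },
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_dataset(in_dir) -> Dataset:
    """Reload a dataset directory written by `save_dataset`."""
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    conditions = tuple(
        Condition(
            v_ref=c["v_ref"],
            c_ref=c["c_ref"],
            c_test=c["c_test"],
            condition_id=c["condition_id"],
            block=c["block"],
        )
        for c in meta["design"]["conditions"]
    )
    design = ExperimentDesign(
        conditions=conditions,
        sessions=meta["design"]["sessions"],
        staircases_per_session=tuple(meta["design"]["staircases_per_session"].items()),
        trials_per_staircase=meta["design"]["trials_per_staircase"],
        spatial_frequency=meta["design"]["spatial_frequency"],
    )
    observer = observer_from_dict(meta["observer"])
    trials = pd.read_csv(src / "trials.csv")
    stair_frame = pd.read_csv(src / "staircases.csv")
    cond_by_id = {c.condition_id: c for c in conditions}
    staircases = []
    grouped = trials.groupby(["condition_id", "session", "staircase_id"], sort=False)
    pse_lookup = {
        (r.condition_id, r.session, r.staircase_id): r.pse
        for r in stair_frame.itertuples()
    }
    for (cid, session, sc_id), group in grouped:
        records = [
            TrialRecord(
                session=int(r.session),
                condition_id=str(r.condition_id),
                staircase_id=int(r.staircase_id),
                trial_index=int(r.trial_index),
                v_ref=float(r.v_ref),
                c_ref=float(r.c_ref),
                v_test=float(r.v_test),
                c_test=float(r.c_test),
                reference_side=str(r.reference_side),
                response_test_faster=bool(r.response_test_faster),
            )
            for r in group.itertuples()
        ]
        staircases.append(
            StaircaseResult(
                condition_id=str(cid),
                session=int(session),
                pse=float(pse_lookup[(cid, session, sc_id)]),
                n_trials=len(records),
                trials=records,
                staircase_id=int(sc_id),
            )
        )
    if set(cond_by_id) != {sc.condition_id for sc in staircases}:
        raise ValueError("trial log does not cover the declared conditions")
    return Dataset(
        design=design,
        observer=observer,
        staircases=staircases,
        master_seed=meta["master_seed"],
    )
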
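"""Contrast-dependent bias summaries and report rendering.

The headline summary of a speed-matching dataset is the contrast-dependent
bias (CDB): the ratio of the high-contrast (test) grating's speed to the
low-contrast (reference) grating's speed at the PSE.  CDB < 1 means lowering
contrast lowered perceived speed (the Thompson effect); a veridical observer
sits at 1.  Because the reference is always the lower-contrast grating, CDB is
simply mean PSE / reference speed per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .experiment import Condition, Dataset, pse_summary
from .fitting import FitResult, predict_pse, reconstruct_prior
from .models import contrast_gain

__all__ = ["CDBRecord", "compute_cdb", "cdb_frame", "render_report"]


@dataclass(frozen=True)
class CDBRecord:
    condition_id: str
    v_ref: float
    contrast_pair: str  # e.g. "3/15"
    cdb: float
    sem: float  # standard error of the CDB over staircases

    def __post_init__(self):
        if self.cdb <= 0:
            raise ValueError("cdb must be positive")


def _pair_label(c_ref: float, c_test: float) -> str:
    return f"{100 * c_ref:g}/{100 * c_test:g}"


def compute_cdb(table: pd.DataFrame) -> List[CDBRecord]:
    """Per-condition CDB from a PSE table.

    The test grating is always the higher-contrast one, so CDB = mean test
    PSE / reference speed.  The standard error of the CDB over staircases is
    sqrt(sem2_pse / n) / v_ref, with sem2_pse the across-staircase variance.
    """
    records = []
    for r in table.itertuples():
        sem = float(np.sqrt(r.sem2_pse / r.n_staircases) / r.v_ref) if r.n_staircases else 0.0
        records.append(
            CDBRecord(
                condition_id=str(r.condition_id),
                v_ref=float(r.v_ref),
                contrast_pair=_pair_label(r.c_ref, r.c_test),
                cdb=float(r.mean_pse / r.v_ref),
                sem=sem,
            )
        )
    return records


def cdb_frame(table: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in compute_cdb(table)])


def _fit_overlay(fit: FitResult, conditions: Sequence[Condition]) -> pd.DataFrame:
    """Model CDB overlay: predict_pse / v_ref, the same path as the fit itself."""
    rows = []
    for cond in conditions:
        try:
            pse = predict_pse(fit.observer, cond, fit.variant)
        except ValueError:  # non-invertible condition for this fit: no overlay point
            pse = float("nan")
        rows.append(
            {
                "condition_id": cond.condition_id,
                "v_ref": cond.v_ref,
                "contrast_pair": _pair_label(cond.c_ref, cond.c_test),
                "cdb": pse / cond.v_ref,
            }
        )
    return pd.DataFrame(rows)


def render_report(
    dataset: Dataset,
    fits: Sequence[FitResult] = (),
    out_dir="report",
    fit_labels: Optional[Sequence[str]] = None,
) -> List[Path]:
    """Write CDB plots, prior/likelihood-component curves and a JSON summary.

    One CDB-vs-speed panel per contrast pair with one overlay line per fitted
    model; for each fit, panels of the reconstructed prior, g(v) and h(c).
    Returns the list of files written (a deterministic set).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    table = pse_summary(dataset)
    data = cdb_frame(table)
    labels = list(fit_labels) if fit_labels is not None else [
        f"{f.variant} fit {i}" for i, f in enumerate(fits)
    ]
    if len(labels) != len(fits):
        raise ValueError("fit_labels must match fits")
    overlays = [_fit_overlay(f, dataset.design.conditions) for f in fits]

    pairs = sorted(data["contrast_pair"].unique(), key=lambda s: float(s.split("/")[0]))
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, pair in zip(axes, pairs):
        sub = data[data["contrast_pair"] == pair].sort_values("v_ref")
        ax.errorbar(sub["v_ref"], sub["cdb"], yerr=sub["sem"], fmt="ko", label="data")
        for overlay, label in zip(overlays, labels):
            osub = overlay[overlay["contrast_pair"] == pair].sort_values("v_ref")
            ax.plot(osub["v_ref"], osub["cdb"], "-", label=label)
        ax.axhline(1.0, color="gray", lw=0.5, ls="--")
        ax.set_title(f"contrast {pair}%")
        ax.set_xlabel("reference speed (deg/s)")
    axes[0].set_ylabel("CDB (v_HC / v_LC)")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    cdb_path = out / "cdb.png"
    fig.savefig(cdb_path, dpi=120)
    plt.close(fig)
    written.append(cdb_path)

    if fits:
        speed_grid = np.geomspace(0.5, 16, 100)
        contrast_grid = np.linspace(0.01, 1.0, 100)
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for fit, label in zip(fits, labels):
            prior_curve = reconstruct_prior(fit.observer.prior, speed_grid)
            axes[0].semilogy(speed_grid, prior_curve, label=label)
            axes[1].plot(speed_grid, fit.observer.likelihood.g_at(speed_grid), label=label)
            axes[2].plot(
                contrast_grid,
                contrast_gain(fit.observer.likelihood.contrast, contrast_grid),
                label=label,
            )
        axes[0].set_title("reconstructed prior (unnormalized)")
        axes[0].set_xlabel("speed (deg/s)")
        axes[1].set_title("g(v)")
        axes[1].set_xlabel("speed (deg/s)")
        axes[2].set_title("h(c)")
        axes[2].set_xlabel("contrast (fraction)")
        axes[2].legend(fontsize=8)
        fig.tight_layout()
        comp_path = out / "components.png"
        fig.savefig(comp_path, dpi=120)
        plt.close(fig)
        written.append(comp_path)

    summary = {
        "n_conditions": len(dataset.design.conditions),
        "n_staircases": len(dataset.staircases),
        "cdb": data.to_dict(orient="records"),
        "fits": [
            {
                "label": label,
                "variant": fit.variant,
                "sse": fit.sse,
                "r2": fit.r2,
                "cdb_pred": overlay.to_dict(orient="records"),
            }
            for fit, label, overlay in zip(fits, labels, overlays)
        ],
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    written.append(summary_path)
    return written
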
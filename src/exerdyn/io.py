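"""Result serialization: trajectory CSV, sweep CSV, R0 JSON reports.

Floats are written with ``repr`` (shortest round-trip form), so a
write-then-read cycle reproduces values bitwise.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import pandas as pd

from .errors import ExerdynError
from .reproduction import R0Result
from .sensitivity import SweepResult, plateau_change_pct
from .simulation import Trajectory

TRAJECTORY_HEADER = ("t", "S", "E1", "E2", "N")


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with header ``t,S,E1,E2,N``."""
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(TRAJECTORY_HEADER)
            for t, s, e1, e2 in zip(traj.times, traj.S, traj.E1, traj.E2):
                writer.writerow(
                    [repr(float(t)), repr(float(s)), repr(float(e1)), repr(float(e2)),
                     repr(float(s) + float(e1) + float(e2))]
                )
    except OSError as exc:
        raise ExerdynError(f"cannot write trajectory to {path}: {exc}") from exc


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back into a DataFrame (columns t,S,E1,E2,N)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise ExerdynError(f"cannot read trajectory from {path}: {exc}") from exc
    missing = set(TRAJECTORY_HEADER) - set(frame.columns)
    if missing:
        raise ExerdynError(
            f"trajectory file {path} is missing columns: {sorted(missing)}"
        )
    return frame


def r0_report(result: R0Result) -> dict:
    """JSON-serializable report for an R0 computation."""
    report: dict = {
        "value": result.value,
        "method": result.method.value,
        "classification": result.classification.value,
    }
    if result.coefficients is not None:
        report["coefficients"] = {
            "A": result.coefficients.A,
            "B": result.coefficients.B,
            "C": result.coefficients.C,
        }
    if result.persistence_inequality is not None:
        report["persistence_inequality"] = result.persistence_inequality
    return report


def write_r0_json(result: R0Result, path: str | Path) -> None:
    """Write an R0 report as JSON: {value, method, classification, ...}."""
    path = Path(path)
    try:
        path.write_text(json.dumps(r0_report(result), indent=2) + "\n")
    except OSError as exc:
        raise ExerdynError(f"cannot write R0 report to {path}: {exc}") from exc


def write_sweep_csv(
    result: SweepResult, path: str | Path, baseline_plateau_S: float | None = None
) -> None:
    """Write a sensitivity sweep as CSV.

    Columns: ``parameter,value,plateau_S,pct_change_vs_baseline``. The
    percent change is computed against ``baseline_plateau_S`` (by default
    the plateau at the first grid point); missing plateaus are left empty.
    """
    path = Path(path)
    settled = [v for v in result.plateau_S if not math.isnan(v)]
    if baseline_plateau_S is None:
        baseline_plateau_S = settled[0] if settled else math.nan
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["parameter", "value", "plateau_S", "pct_change_vs_baseline"]
            )
            for value, plateau in zip(result.grid, result.plateau_S):
                if math.isnan(plateau):
                    writer.writerow([result.parameter, repr(value), "", ""])
                else:
                    pct = (
                        plateau_change_pct(baseline_plateau_S, plateau)
                        if baseline_plateau_S and not math.isnan(baseline_plateau_S)
                        else ""
                    )
                    writer.writerow(
                        [result.parameter, repr(value), repr(plateau),
                         repr(pct) if pct != "" else ""]
                    )
    except OSError as exc:
        raise ExerdynError(f"cannot write sweep to {path}: {exc}") from exc
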
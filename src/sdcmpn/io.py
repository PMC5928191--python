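"""Delimited-text readers and JSON writers for the assay formats.

All formats are plain text.  Tube time series are long-format tables with
columns tube_id, tier, replicate, day, fluorescence, f_start; score
tables have one row per tier (tier_index, positives, replicates,
inoculum); calibration tables are two columns (cells_per_ml,
fluorescence); dose-response tables have dose, rv and optional ci_low,
ci_high, censored columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .dose_response import DoseResponsePoint
from .growth_qc import FluorescenceSample
from .mpn import MpnResult, ScoreMatrix
from .scoring import TubeSeries

__all__ = [
    "read_score_table",
    "read_calibration_table",
    "read_tube_series",
    "read_dose_response_table",
    "write_tube_series",
    "result_to_dict",
    "write_result_json",
]


def read_score_table(path: str | Path, sep: str = r"\s+|,", ) -> tuple[ScoreMatrix, list[float]]:
    """Read a per-tier score table: tier_index, positives, replicates, inoculum."""
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.sort_values("tier_index")
    reps = df["replicates"].unique()
    if len(reps) != 1:
        raise ValueError("replicate counts must be equal across tiers")
    scores = ScoreMatrix(tuple(int(p) for p in df["positives"]), int(reps[0]))
    return scores, [float(v) for v in df["inoculum"]]


def read_calibration_table(path: str | Path) -> tuple[list[float], list[float]]:
    """Read calibration points: cells_per_ml, fluorescence."""
    df = pd.read_csv(path, sep=r"\s+|,", engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    return [float(x) for x in df["cells_per_ml"]], [float(x) for x in df["fluorescence"]]


def read_tube_series(path: str | Path) -> list[TubeSeries]:
    """Read long-format tube time series into TubeSeries objects."""
    df = pd.read_csv(path, sep=r"\s+|,", engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    tubes = []
    for (_, tier, rep), grp in df.groupby(["tube_id", "tier", "replicate"], sort=True):
        grp = grp.sort_values("day")
        samples = tuple(FluorescenceSample(t=float(r.day), F=float(r.fluorescence))
                        for r in grp.itertuples())
        f_start = float(grp["f_start"].iloc[0]) if "f_start" in grp else samples[0].F
        tubes.append(TubeSeries(tier=int(tier), replicate=int(rep),
                                samples=samples, f_start=f_start))
    return tubes


def write_tube_series(tubes: Sequence[TubeSeries], path: str | Path) -> None:
    rows = []
    for tube in tubes:
        tube_id = f"T{tube.tier}R{tube.replicate}"
        for s in tube.samples:
            rows.append((tube_id, tube.tier, tube.replicate, s.t, s.F, tube.f_start))
    pd.DataFrame(rows, columns=["tube_id", "tier", "replicate", "day",
                                "fluorescence", "f_start"]).to_csv(path, index=False)


def read_dose_response_table(path: str | Path) -> list[DoseResponsePoint]:
    """Read dose-response points: dose, rv [, ci_low, ci_high, censored]."""
    df = pd.read_csv(path, sep=r"\s+|,", engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    points = []
    for row in df.itertuples():
        points.append(DoseResponsePoint(
            dose=float(row.dose),
            rv=float(row.rv),
            ci_low=float(row.ci_low) if "ci_low" in df else None,
            ci_high=float(row.ci_high) if "ci_high" in df else None,
            censored=bool(getattr(row, "censored", False)),
        ))
    return points


def result_to_dict(result: MpnResult, design: Any = None) -> dict:
    out = {
        "mpn": result.mpn,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "n_viable": result.n_viable,
        "sigma_ln": result.sigma_ln,
        "flags": list(result.flags),
    }
    if design is not None:
        out["design"] = dataclasses.asdict(design)
    return out


def write_result_json(result: MpnResult, path: str | Path, design: Any = None) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result, design), indent=2) + "\n")
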
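"""Flat-file I/O: sweep and epi series CSV, fit-result JSON, run metadata.

CSV dialect: comma-separated UTF-8 with a mandatory header row and '.'
decimals; scientific notation is accepted on input.  Every run writes a
metadata JSON (config echo, seed, library versions) alongside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .epi import EpiFitResult, EpiRecord, RateRatioPoint
from .fitting import DispersionRatioRow, FitResult
from .simulate import SweepPoint

SWEEP_COLUMNS = ["mu1", "mean_dose", "events", "trials", "rate"]
EPI_COLUMNS = ["period", "births", "deaths", "burden"]


def write_sweep_csv(points: Sequence[SweepPoint], path) -> None:
    df = pd.DataFrame(
        {
            "mu1": [p.mu1 for p in points],
            "mean_dose": [p.mean_dose for p in points],
            "events": [p.events for p in points],
            "trials": [p.trials for p in points],
            "rate": [p.rate for p in points],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_sweep_csv(path) -> list[SweepPoint]:
    """Parse a sweep CSV; rates are recomputed from events/trials, never trusted."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # surface the offending file, not a pandas trace
        raise ValueError(f"cannot parse sweep CSV {path}: {exc}") from exc
    missing = [c for c in SWEEP_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"sweep CSV {path} lacks columns {missing}")
    return [
        SweepPoint(
            mu1=float(r.mu1),
            mean_dose=float(r.mean_dose),
            events=int(r.events),
            trials=int(r.trials),
        )
        for r in df.itertuples()
    ]


def write_epi_csv(records: Sequence[EpiRecord], path) -> None:
    pd.DataFrame(
        {
            "period": [r.period for r in records],
            "births": [r.births for r in records],
            "deaths": [r.deaths for r in records],
            "burden": [r.burden for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_epi_csv(path) -> list[EpiRecord]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"cannot parse epi CSV {path}: {exc}") from exc
    missing = [c for c in EPI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epi CSV {path} lacks columns {missing}")
    return [
        EpiRecord(period=int(r.period), births=int(r.births), deaths=int(r.deaths), burden=float(r.burden))
        for r in df.itertuples()
    ]


def write_rate_ratio_csv(points: Sequence[RateRatioPoint], path) -> None:
    pd.DataFrame(
        {
            "burden": [p.burden for p in points],
            "ratio": [p.ratio for p in points],
            "sd": [p.sd for p in points],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_dispersion_table_csv(rows: Sequence[DispersionRatioRow], sigma1: float, path) -> None:
    """Table of predicted rates with/without dose dispersion, labelled by the sweep's sigma1."""
    pd.DataFrame(
        {
            "mu1": [r.mu1 for r in rows],
            "mean_dose": [r.mean_dose for r in rows],
            f"predicted_sigma1_{sigma1:g}": [r.predicted_with for r in rows],
            "predicted_sigma1_0": [r.predicted_without for r in rows],
            "ratio": [r.ratio for r in rows],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def fit_result_to_dict(fit: FitResult | EpiFitResult) -> dict:
    d = dataclasses.asdict(fit)
    d["se_scaling"] = "gauss-newton curvature scaled by sqrt(deviance/df)"
    return d


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o).__name__}")


def write_metadata(path, config: dict, seed) -> None:
    """Record the run configuration, seed, and library versions next to the outputs."""
    import scipy

    from . import __version__

    write_json(
        {
            "config": config,
            "seed": seed if isinstance(seed, int) else repr(seed),
            "versions": {
                "logndose": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "python": platform.python_version(),
            },
        },
        path,
    )
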
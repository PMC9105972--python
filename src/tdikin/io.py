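"""Serialization: mechanisms/rates as YAML, curves as tidy CSV, results as JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .assays import EllmanParams, ProgressCurve, curves_to_frame, frame_to_curves
from .mechanisms import Mechanism, RateConstantSet

__all__ = [
    "save_model",
    "load_model",
    "save_curves",
    "load_curves",
    "write_json",
]


def save_model(path, mechanism: Mechanism, rates: Mapping[str, float] | None = None) -> None:
    """Write a mechanism (and optionally its rate constants) as YAML."""
    doc = mechanism.to_dict()
    if rates is not None:
        doc["rates"] = {k: float(v) for k, v in rates.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> tuple[Mechanism, RateConstantSet | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mech = Mechanism.from_dict(doc)
    rates = RateConstantSet(doc["rates"]) if "rates" in doc else None
    return mech, rates


def save_curves(path, curves: Sequence[ProgressCurve]) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def load_curves(path, ellman: EllmanParams | None = None) -> list[ProgressCurve]:
    import pandas as pd

    return frame_to_curves(pd.read_csv(path), ellman=ellman)


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
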
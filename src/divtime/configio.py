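"""YAML serialisation of calibration sets and scenario configurations.

Calibration config schema::

    root:
      kind: uniform
      min_age: 52.0
      max_age: 85.0
    nodes:
      - kind: offset_exponential
        offset: 10.4
        mean: 58.0
        clade: [Meliphagidae_1, Meliphagidae_2]
    constraints:
      - [taxonA, taxonB, ...]      # uncalibrated monophyly constraints
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .calibrations import Calibration, CalibrationSet

__all__ = [
    "calibration_set_to_yaml",
    "calibration_set_from_yaml",
    "load_calibrations",
    "save_calibrations",
]


def _cal_to_dict(cal: Calibration) -> dict:
    d: dict = {"kind": cal.kind}
    if cal.clade:
        d["clade"] = sorted(cal.clade)
    if cal.kind == "uniform":
        d["min_age"] = float(cal.min_age)
        d["max_age"] = float(cal.max_age)
    else:
        d["offset"] = float(cal.offset)
        d["mean"] = float(cal.mean)
    return d


def _cal_from_dict(d: dict) -> Calibration:
    kind = d["kind"]
    clade = frozenset(d.get("clade", ()))
    if kind == "uniform":
        lo, hi = float(d["min_age"]), float(d["max_age"])
        if lo > hi:
            import warnings

            warnings.warn(f"uniform window reversed ({lo}, {hi}); normalising", stacklevel=2)
            lo, hi = hi, lo
        return Calibration.uniform(lo, hi, clade=clade)
    if kind == "offset_exponential":
        return Calibration.offset_exponential(float(d["offset"]), float(d["mean"]), clade=clade)
    raise ValueError(f"unknown calibration kind {kind!r}")


def calibration_set_to_yaml(cals: CalibrationSet) -> str:
    doc = {
        "root": _cal_to_dict(cals.root),
        "nodes": [_cal_to_dict(c) for c in cals.nodes],
        "constraints": [sorted(c) for c in cals.extra_constraints],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def calibration_set_from_yaml(text: str) -> CalibrationSet:
    doc = yaml.safe_load(text)
    return CalibrationSet(
        root=_cal_from_dict(doc["root"]),
        nodes=[_cal_from_dict(d) for d in doc.get("nodes", [])],
        extra_constraints=[frozenset(c) for c in doc.get("constraints", [])],
    )


def save_calibrations(cals: CalibrationSet, path: str | Path) -> None:
    Path(path).write_text(calibration_set_to_yaml(cals))


def load_calibrations(path: str | Path) -> CalibrationSet:
    return calibration_set_from_yaml(Path(path).read_text())
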
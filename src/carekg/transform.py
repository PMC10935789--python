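"""Deterministic transformation of raw sensor values into medical categories.

Blood pressure, fasting glucose and weight readings from smart devices are
mapped onto the guideline categories in ``data/thresholds.yaml`` (formulated
after Chinese chronic-disease care standards); smart-mattress bed-occupancy
intervals are summarised into nighttime-exit frequency and longest continuous
lying time.  Each classifier is total over its admissible input range and
returns the graph node name the elder should currently be linked to.

Conventions the printed standard leaves open, resolved here:

* blood pressure combines systolic and diastolic with OR and takes the
  highest satisfied degree (usual hypertension-guideline practice);
* glucose intervals are half-open [low, high), so a boundary value such as
  6.1 belongs to the upper band, and the uncovered strip [8.2, 8.3) is
  normalised into Poor;
* glucose below 4.4 is a distinct BelowRange category carrying a
  ``hypoglycemia`` flag (degree stays 0 so severity remains monotone in the
  measured value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Any

import yaml

from .errors import InputError
from .schema import _data_path


@dataclass(frozen=True)
class CategoryResult:
    family: str            # blood_pressure | glucose | bmi | mattress
    category: str          # human-readable category name
    degree: int            # severity rank, 0 = normal/best
    value: Any             # echoed numeric input (tuple for blood pressure)
    node_name: str         # graph node the elder links to for this family
    flags: tuple[str, ...] = ()
    metrics: dict[str, float] = field(default_factory=dict)


class SensorThresholds:
    """Threshold configuration loaded from the versioned YAML file."""

    def __init__(self, path: str | Path | None = None):
        path = _data_path("thresholds.yaml") if path is None else Path(path)
        with open(path, encoding="utf-8") as fh:
            self.cfg = yaml.safe_load(fh)

    # ------------------------------------------------------- blood pressure

    def classify_blood_pressure(self, sbp: float, dbp: float) -> CategoryResult:
        """Degree = highest degree whose SBP-or-DBP condition is met."""
        bp = self.cfg["blood_pressure"]
        lo_s, hi_s = bp["input_range"]["sbp"]
        lo_d, hi_d = bp["input_range"]["dbp"]
        if not (lo_s <= sbp <= hi_s) or not (lo_d <= dbp <= hi_d):
            raise InputError(f"blood pressure ({sbp}, {dbp}) outside "
                             f"[{lo_s},{hi_s}]x[{lo_d},{hi_d}] mmHg")
        best = {"degree": 0, "name": bp["normal_name"]}
        for rule in bp["degrees"]:
            if (sbp >= rule["sbp"] or dbp >= rule["dbp"]) and rule["degree"] > best["degree"]:
                best = rule
        return CategoryResult(
            family="blood_pressure",
            category=best["name"],
            degree=best["degree"],
            value=(sbp, dbp),
            node_name=best["name"],
        )

    # -------------------------------------------------------------- glucose

    def classify_glucose(self, value: float) -> CategoryResult:
        glu = self.cfg["glucose"]
        lo, hi = glu["input_range"]
        if not (lo <= value <= hi):
            raise InputError(f"glucose {value} outside [{lo}, {hi}] mmol/L")
        for band in glu["categories"]:
            low = band["low"] if band["low"] is not None else float("-inf")
            high = band["high"] if band["high"] is not None else float("inf")
            if low <= value < high:
                return CategoryResult(
                    family="glucose",
                    category=band["name"],
                    degree=band["degree"],
                    value=value,
                    node_name=glu["node_names"][band["name"]],
                    flags=tuple(band.get("flags", ())),
                )
        raise InputError(f"glucose {value} not covered by any band")  # pragma: no cover

    # ------------------------------------------------------------------ bmi

    def classify_bmi(self, weight: float, height: float) -> CategoryResult:
        cfg = self.cfg["bmi"]
        lo_w, hi_w = cfg["input_range"]["weight"]
        lo_h, hi_h = cfg["input_range"]["height"]
        if not (lo_w <= weight <= hi_w):
            raise InputError(f"weight {weight} outside [{lo_w}, {hi_w}] kg")
        if not (lo_h <= height <= hi_h):
            raise InputError(f"height {height} outside [{lo_h}, {hi_h}] m")
        bmi = weight / height**2
        for band in cfg["categories"]:
            low = band["low"] if band["low"] is not None else float("-inf")
            high = band["high"] if band["high"] is not None else float("inf")
            if low <= bmi < high:
                return CategoryResult(
                    family="bmi",
                    category=band["name"],
                    degree=band["degree"],
                    value=round(bmi, 2),
                    node_name=cfg["node_names"][band["name"]],
                )
        raise InputError(f"BMI {bmi} not covered")  # pragma: no cover

    # ------------------------------------------------------------- mattress

    def summarize_mattress(
        self, intervals: list[tuple[datetime, datetime]]
    ) -> CategoryResult:
        """Summarise one night's bed-occupancy intervals.

        ``intervals`` are (enter, leave) pairs within one 24-hour window.
        Nighttime exit frequency counts the out-of-bed gaps between the
        configured night window bounds (22:00-06:00 by default); the
        prolonged-lying metric is the longest single interval in hours.
        """
        cfg = self.cfg["mattress"]
        ivs = sorted(intervals)
        for (a0, a1) in ivs:
            if a1 <= a0:
                raise InputError(f"empty or inverted interval {a0}..{a1}")
        for (a0, a1), (b0, _) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise InputError(f"overlapping intervals at {b0}")
        if ivs and ivs[-1][1] - ivs[0][0] > timedelta(hours=24):
            raise InputError("intervals span more than one 24-h window")

        night_start = time.fromisoformat(cfg["night_window"][0])
        night_end = time.fromisoformat(cfg["night_window"][1])

        def in_night(t: datetime) -> bool:
            # window crosses midnight (22:00 -> 06:00)
            return t.time() >= night_start or t.time() < night_end

        exits = sum(
            1 for (_, leave), (enter, _) in zip(ivs, ivs[1:])
            if in_night(leave) or in_night(enter)
        )
        longest = max(((b - a).total_seconds() / 3600 for a, b in ivs), default=0.0)

        flags = []
        if exits > cfg["max_night_exits"]:
            flags.append("frequent_night_exits")
        if longest > cfg["max_lying_hours"]:
            flags.append("prolonged_lying")
        flagged = bool(flags)
        return CategoryResult(
            family="mattress",
            category="abnormal bed rest" if flagged else "normal bed rest",
            degree=1 if flagged else 0,
            value=len(ivs),
            node_name=cfg["node_names"]["flagged" if flagged else "normal"],
            flags=tuple(flags),
            metrics={"night_exits": float(exits), "longest_lying_h": round(longest, 3)},
        )

    # ---------------------------------------------------------- family info

    def family_node_names(self, family: str) -> set[str]:
        """All category node names a family can produce (for edge rewiring)."""
        cfg = self.cfg[family]
        if family == "blood_pressure":
            return {cfg["normal_name"]} | {r["name"] for r in cfg["degrees"]}
        if family in ("glucose", "bmi"):
            return set(cfg["node_names"].values())
        if family == "mattress":
            return set(cfg["node_names"].values())
        raise InputError(f"unknown sensor family {family!r}")

    def risk_rule(self, family: str) -> dict | None:
        return (self.cfg.get("risk") or {}).get(family)


_DEFAULT: SensorThresholds | None = None


def default_thresholds() -> SensorThresholds:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = SensorThresholds()
    return _DEFAULT


def classify_blood_pressure(sbp: float, dbp: float) -> CategoryResult:
    return default_thresholds().classify_blood_pressure(sbp, dbp)


def classify_glucose(value: float) -> CategoryResult:
    return default_thresholds().classify_glucose(value)


def classify_bmi(weight: float, height: float) -> CategoryResult:
    return default_thresholds().classify_bmi(weight, height)


def summarize_mattress(intervals: list[tuple[datetime, datetime]]) -> CategoryResult:
    return default_thresholds().summarize_mattress(intervals)
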
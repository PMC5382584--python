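"""NADH-coupled ATPase kinetics analysis.

In the coupled assay, ATP hydrolysis is regenerated through pyruvate
kinase/lactate dehydrogenase so that each ATP turned over oxidizes one
NADH.  NADH absorbs at 340 nm and NAD+ does not, so the A340 slope reports
the hydrolysis rate:

    activity [nmol/min/mg] = |slope| / (eps * l)  [M/s]
                             * volume [L] * 60 [s/min] * 1e9 [nmol/mol]
                             / enzyme_mass [mg]

with eps the NADH extinction coefficient (default 6220 /M/cm at 340 nm)
and l the optical path length (default 0.55 cm, a 200 uL microplate well).
Relative Vmax is the ratio of a condition's specific activity to the basal
(no-oxyanion) one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EPSILON_NADH_340",
    "DEFAULT_PATH_LENGTH_CM",
    "AssayTrace",
    "ActivityTable",
    "fit_initial_rate",
    "auto_linear_window",
    "specific_activity",
    "relative_vmax",
    "oxyanion_effect_report",
]

logger = logging.getLogger("groovescope")

#: NADH molar extinction coefficient at 340 nm, 1/(M cm)
EPSILON_NADH_340 = 6220.0
#: Optical path length of a 200 uL 96-well microplate, cm
DEFAULT_PATH_LENGTH_CM = 0.55


@dataclass
class AssayTrace:
    """An A340(t) time course plus the metadata needed to convert slopes."""

    times: np.ndarray  # s
    a340: np.ndarray  # absorbance units
    enzyme: str = ""
    condition: str = "basal"
    enzyme_mass: float = 0.0  # mg
    volume: float = 0.0  # L
    path_length: float = DEFAULT_PATH_LENGTH_CM  # cm
    extinction_coeff: float = EPSILON_NADH_340  # 1/(M cm)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.times.shape != self.a340.shape or self.times.ndim != 1:
            raise ValueError("times and a340 must be 1-D and equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.a340)):
            raise ValueError("a340 contains non-finite values")

    def to_tsv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.a340]),
            delimiter="\t",
            header="time_s\ta340",
            comments="",
            fmt="%.8g",
        )


@dataclass
class ActivityTable:
    """Specific activities per enzyme and condition, plus relative Vmax.

    ``rows[enzyme][condition] = (vmax, uncertainty)`` in nmol/min/mg;
    ``relative[enzyme][condition]`` is the ratio vs that enzyme's basal.
    """

    rows: dict = field(default_factory=dict)
    relative: dict = field(default_factory=dict)
    basal_condition: str = "basal"

    def add(self, enzyme: str, condition: str, vmax: float, uncertainty: float = 0.0):
        if vmax < 0:
            raise ValueError("vmax must be >= 0")
        self.rows.setdefault(enzyme, {})[condition] = (float(vmax), float(uncertainty))


def fit_initial_rate(
    trace: AssayTrace, window: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """OLS slope of A340 vs time over a window: (slope AU/s, stderr, r^2).

    ``window=None`` fits the full trace.  The slope of an active enzyme is
    negative (NADH consumption); a positive slope only triggers a warning.
    """
    if window is None:
        mask = np.ones(len(trace.times), dtype=bool)
    else:
        start, end = window
        mask = (trace.times >= start) & (trace.times <= end)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points in the fit window")
    t, a = trace.times[mask], trace.a340[mask]
    res = stats.linregress(t, a)
    if res.slope > 0:
        logger.warning(
            "positive A340 slope (%.3g AU/s) for %s/%s: no net NADH consumption",
            res.slope, trace.enzyme, trace.condition,
        )
    r_squared = float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0
    return float(res.slope), float(res.stderr), r_squared


def auto_linear_window(
    trace: AssayTrace, min_points: int = 10, r2_threshold: float = 0.99
) -> tuple[float, float]:
    """Longest window starting at t0 whose linear fit keeps r^2 >= threshold.

    Scans end points from the full trace backwards and returns the first
    (longest) window meeting the threshold; falls back to the first
    ``min_points`` samples if none does.
    """
    n = len(trace.times)
    if n < min_points:
        raise ValueError(f"trace has {n} points; need >= {min_points}")
    for end in range(n, min_points - 1, -1):
        res = stats.linregress(trace.times[:end], trace.a340[:end])
        if not math.isnan(res.rvalue) and res.rvalue**2 >= r2_threshold:
            return float(trace.times[0]), float(trace.times[end - 1])
    return float(trace.times[0]), float(trace.times[min_points - 1])


def specific_activity(slope: float, trace: AssayTrace) -> float:
    """Convert an A340 slope (AU/s) into nmol ATP/min/mg enzyme."""
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    for name in ("extinction_coeff", "path_length", "volume", "enzyme_mass"):
        if getattr(trace, name) <= 0:
            raise ValueError(f"{name} must be positive")
    rate_m_per_s = abs(slope) / (trace.extinction_coeff * trace.path_length)
    return rate_m_per_s * trace.volume * 60.0 * 1e9 / trace.enzyme_mass


def relative_vmax(table: ActivityTable, rounding: int | None = None) -> ActivityTable:
    """Fill ``table.relative`` with vmax(condition)/vmax(basal) per enzyme.

    ``rounding`` (decimals) produces additionally-rounded values under the
    ``"<condition>_rounded"`` keys; the unrounded ratio is always stored.
    """
    basal = table.basal_condition
    for enzyme, conditions in table.rows.items():
        if basal not in conditions:
            raise ValueError(f"enzyme {enzyme!r} has no {basal!r} measurement")
        v_basal = conditions[basal][0]
        if v_basal == 0:
            raise ValueError(f"enzyme {enzyme!r}: zero basal vmax")
        rel = {}
        for condition, (v, _) in conditions.items():
            ratio = v / v_basal
            rel[condition] = ratio
            if rounding is not None:
                rel[f"{condition}_rounded"] = round(ratio, rounding)
        table.relative[enzyme] = rel
    return table


def _ratio_uncertainty(a: float, sa: float, b: float, sb: float) -> float:
    """Propagate sd of a/b: ratio * sqrt((sa/a)^2 + (sb/b)^2)."""
    if a == 0 or b == 0:
        return float("nan")
    return abs(a / b) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2)


def oxyanion_effect_report(
    table: ActivityTable,
    conditions: tuple[str, ...] = ("arsenite", "antimonite"),
) -> pd.DataFrame:
    """Tabulate basal and per-oxyanion Vmax with relative values.

    Columns: enzyme, basal, basal_sd, then per condition vmax, sd, relative
    and propagated relative_sd.  Missing conditions leave empty cells (NaN).
    """
    if not table.rows:
        raise ValueError("empty activity table")
    relative_vmax(table)
    basal = table.basal_condition
    records = []
    for enzyme, conds in table.rows.items():
        v0, s0 = conds[basal]
        row = {"enzyme": enzyme, "basal": v0, "basal_sd": s0}
        for condition in conditions:
            if condition in conds:
                v, s = conds[condition]
                row[condition] = v
                row[f"{condition}_sd"] = s
                row[f"{condition}_relative"] = table.relative[enzyme][condition]
                row[f"{condition}_relative_sd"] = _ratio_uncertainty(v, s, v0, s0)
            else:
                row[condition] = np.nan
                row[f"{condition}_sd"] = np.nan
                row[f"{condition}_relative"] = np.nan
                row[f"{condition}_relative_sd"] = np.nan
        records.append(row)
    return pd.DataFrame.from_records(records)
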
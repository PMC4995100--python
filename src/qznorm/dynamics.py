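"""Per-nucleosome H2A.Z occupancy statistics across two conditions.

Occupancy at a nucleosome is summarized in a 120-bp window around its dyad
as (Z/T), the H2A.Z-to-input ratio, and (Z/A), the H2A.Z-to-H2A ratio.
Condition deltas of these ratios — delta(Z/T) and delta(Z/A) — quantify
H2A.Z gain or loss after a perturbation. Significance thresholds are
calibrated on a no-perturbation control: a dyad is called changed when its
delta falls more than two standard deviations from the control median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import DyadAnnotation, Track, ValidationError
from .profiles import window_signal

__all__ = [
    "ChangeThresholds",
    "relative_occupancy",
    "za_ratio",
    "za_track",
    "delta_za_track",
    "dynamics_table",
    "classify_change",
    "group_summary",
]

#: Window input signal (CPM units) below which a ratio is masked undefined
#: rather than reported as an unstable quotient.
DEFAULT_INPUT_FLOOR = 1.0


@dataclass
class ChangeThresholds:
    """Control-calibrated significance band: median +/- 2 SD of control deltas.

    The center is the control *median* and the spread the sample standard
    deviation about the control mean, exactly as the calibration is defined;
    ``robust=True`` swaps the spread for 1.4826 * MAD. ``degenerate`` flags
    a zero spread (all control deltas equal).
    """

    center: float
    spread: float
    degenerate: bool = False

    @property
    def upper(self) -> float:
        return self.center + 2.0 * self.spread

    @property
    def lower(self) -> float:
        return self.center - 2.0 * self.spread

    def to_dict(self) -> dict:
        return {
            "center": self.center,
            "spread": self.spread,
            "upper": self.upper,
            "lower": self.lower,
            "degenerate": self.degenerate,
        }


def relative_occupancy(
    Z: Track,
    T: Track,
    dyads: DyadAnnotation,
    halfwidth: int = 60,
    input_floor: float = DEFAULT_INPUT_FLOOR,
) -> np.ndarray:
    """(Z/T) per dyad: windowed H2A.Z signal over windowed input signal.

    Both tracks must already be normalized (same CPM scale). Dyads whose
    input window signal is below ``input_floor`` — or whose window leaves
    the chromosome — are masked NaN.
    """
    wz = window_signal(Z, dyads, halfwidth)
    wt = window_signal(T, dyads, halfwidth)
    out = np.full(len(dyads), np.nan)
    ok = np.isfinite(wz) & np.isfinite(wt) & (wt >= input_floor)
    out[ok] = wz[ok] / wt[ok]
    return out


def za_ratio(
    Z: Track,
    A: Track,
    dyads: DyadAnnotation,
    halfwidth: int = 60,
    input_floor: float = DEFAULT_INPUT_FLOOR,
) -> np.ndarray:
    """(Z/A) per dyad, masked where the H2A window signal is below the floor."""
    wz = window_signal(Z, dyads, halfwidth)
    wa = window_signal(A, dyads, halfwidth)
    out = np.full(len(dyads), np.nan)
    ok = np.isfinite(wz) & np.isfinite(wa) & (wa >= input_floor)
    out[ok] = wz[ok] / wa[ok]
    return out


def za_track(
    Z: Track,
    A: Track,
    window: int = 147,
    pseudocount: float = 1.0,
) -> Track:
    """Genome-browser (Z/A) trace: windowed Z over windowed A, regularized.

    At every basepair the ratio of the centered ``window``-bp running sums
    of Z and A is computed with ``pseudocount`` added to the denominator,
    so the trace is finite everywhere including H2A-free gaps. The ratio is
    deliberately non-linear in occupancy; the pseudocount (in CPM units)
    is part of the track's definition and recorded in its metadata.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    data: dict[str, np.ndarray] = {}
    half_lo = window // 2
    half_hi = window - half_lo
    for chrom in Z.data:
        if chrom not in A.data:
            raise ValidationError(f"chromosome {chrom!r} missing from H2A track")
        z = Z.data[chrom]
        a = A.data[chrom]
        if len(z) != len(a):
            raise ValidationError(f"track length mismatch on {chrom}")
        cz = np.concatenate(([0.0], np.cumsum(z)))
        ca = np.concatenate(([0.0], np.cumsum(a)))
        pos = np.arange(len(z))
        lo = np.clip(pos - half_lo, 0, len(z))
        hi = np.clip(pos + half_hi, 0, len(z))
        zwin = cz[hi] - cz[lo]
        awin = ca[hi] - ca[lo]
        data[chrom] = zwin / (awin + pseudocount)
    track = Track(data, fraction=None, normalized=True)
    return track


def delta_za_track(za_before: Track, za_after: Track) -> Track:
    """Per-basepair delta(Z/A): after-condition trace minus before."""
    data = {}
    for chrom, before in za_before.data.items():
        after = za_after.data.get(chrom)
        if after is None or len(after) != len(before):
            raise ValidationError(f"delta(Z/A) track mismatch on {chrom}")
        data[chrom] = after - before
    return Track(data, fraction=None, normalized=True)


def dynamics_table(
    dyads: DyadAnnotation,
    cond1: dict[str, Track],
    cond2: dict[str, Track],
    halfwidth: int = 60,
    input_floor: float = DEFAULT_INPUT_FLOOR,
) -> pd.DataFrame:
    """Per-dyad occupancy statistics across two conditions.

    ``cond1``/``cond2`` map fraction tags {"T", "A", "Z"} to normalized
    tracks of the respective condition. Deltas are condition2 - condition1
    and are NaN (undefined) wherever either constituent window is masked.
    """
    for d, name in ((cond1, "cond1"), (cond2, "cond2")):
        missing = {"T", "A", "Z"} - set(d)
        if missing:
            raise ValidationError(f"{name} lacks fraction tracks: {sorted(missing)}")
    df = dyads.frame[["chrom", "dyad", "strand", "role"]].copy()
    df["rel_occ_cond1"] = relative_occupancy(
        cond1["Z"], cond1["T"], dyads, halfwidth, input_floor
    )
    df["rel_occ_cond2"] = relative_occupancy(
        cond2["Z"], cond2["T"], dyads, halfwidth, input_floor
    )
    df["za_cond1"] = za_ratio(cond1["Z"], cond1["A"], dyads, halfwidth, input_floor)
    df["za_cond2"] = za_ratio(cond2["Z"], cond2["A"], dyads, halfwidth, input_floor)
    df["delta_rel"] = df["rel_occ_cond2"] - df["rel_occ_cond1"]
    df["delta_za"] = df["za_cond2"] - df["za_cond1"]
    return df


def classify_change(
    deltas: np.ndarray,
    control_deltas: np.ndarray,
    robust: bool = False,
) -> tuple[ChangeThresholds, np.ndarray, dict[str, float]]:
    """Classify per-dyad deltas against control-calibrated thresholds.

    Thresholds are the control median +/- two standard deviations of the
    control deltas. Deltas above the upper threshold are "up", below the
    lower "down", between them "unchanged"; NaN deltas are "undefined".

    Returns
    -------
    (thresholds, classes, fractions)
        ``classes`` is an object array of labels aligned with ``deltas``;
        ``fractions`` reports the share of *defined* deltas per class plus
        ``outside`` = up + down.
    """
    control = np.asarray(control_deltas, dtype=np.float64)
    control = control[np.isfinite(control)]
    if len(control) < 3:
        raise ValidationError("need >= 3 defined control deltas to calibrate thresholds")
    center = float(np.median(control))
    if robust:
        spread = float(1.4826 * np.median(np.abs(control - np.median(control))))
    else:
        spread = float(np.std(control, ddof=1))
    thresholds = ChangeThresholds(center=center, spread=spread, degenerate=spread == 0.0)

    deltas = np.asarray(deltas, dtype=np.float64)
    classes = np.full(len(deltas), "undefined", dtype=object)
    defined = np.isfinite(deltas)
    classes[defined & (deltas > thresholds.upper)] = "up"
    classes[defined & (deltas < thresholds.lower)] = "down"
    classes[defined & (deltas <= thresholds.upper) & (deltas >= thresholds.lower)] = "unchanged"

    n_def = int(defined.sum())
    fractions = {}
    for label in ("up", "down", "unchanged"):
        fractions[label] = float((classes == label).sum() / n_def) if n_def else float("nan")
    fractions["outside"] = fractions["up"] + fractions["down"]
    fractions["n_defined"] = n_def
    return thresholds, classes, fractions


def group_summary(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
) -> pd.DataFrame:
    """Median / quartiles / range of one column per group (box-plot stats).

    NaN values are excluded per group; group sizes are reported alongside.
    """
    if value_col not in table or group_col not in table:
        raise ValidationError("value or grouping column missing from table")
    def _stats(s: pd.Series) -> pd.Series:
        v = s.dropna()
        return pd.Series(
            {
                "n": len(v),
                "median": v.median(),
                "q1": v.quantile(0.25),
                "q3": v.quantile(0.75),
                "min": v.min(),
                "max": v.max(),
            }
        )
    out = table.groupby(group_col, sort=True)[value_col].apply(_stats).unstack()
    out["n"] = out["n"].astype(int)
    out["iqr"] = out["q3"] - out["q1"]
    return out
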
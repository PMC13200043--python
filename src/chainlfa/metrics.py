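"""Capture-efficiency data analysis for the supernatant-depletion assay.

The experimental companion of the simulations measures antigen capture by
nanochains directly: incubate antigen with functionalized nanochains (with
or without a rotating field), pull the chains down magnetically, and assay
the supernatant.  Capture efficiency is the depleted fraction,

    efficiency (%) = (C0 - Cs) / C0 * 100,

and the rotation benefit is the plain ratio of efficiencies with and
without rotation (fold improvement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CaptureMeasurement:
    """One replicate of a supernatant-depletion measurement (ng/mL)."""

    C0: float             # initial antigen concentration
    Cs: float             # supernatant concentration after separation
    replicate: int | str = 0

    def __post_init__(self) -> None:
        if not self.C0 > 0:
            raise ValueError(f"C0 must be > 0, got {self.C0}")
        if self.Cs < 0:
            raise ValueError(f"Cs must be >= 0, got {self.Cs}")


def capture_efficiency(m: CaptureMeasurement) -> float:
    """Capture efficiency percent, (C0 - Cs)/C0 * 100.

    May fall outside [0, 100] for noisy measurements with Cs > C0; such
    values are returned as-is (the aggregation step flags them).
    """
    return (m.C0 - m.Cs) / m.C0 * 100.0


def fold_improvement(eff_rotating: float, eff_static: float) -> float:
    """Ratio of rotating to static capture efficiency."""
    if eff_static == 0:
        raise ZeroDivisionError(
            "fold improvement undefined for zero static efficiency")
    return eff_rotating / eff_static


def aggregate_efficiencies(measurements: list[CaptureMeasurement]) -> dict:
    """Mean +- sample standard deviation over replicates.

    Returns a dict with per-replicate efficiencies, mean, sd (ddof=1, nan
    for a single replicate), n and an out-of-range flag.
    """
    if not measurements:
        raise ValueError("no measurements")
    effs = [capture_efficiency(m) for m in measurements]
    n = len(effs)
    mean = sum(effs) / n
    sd = math.sqrt(sum((e - mean) ** 2 for e in effs) / (n - 1)) if n > 1 else float("nan")
    return {"efficiencies": effs, "mean": mean, "sd": sd, "n": n,
            "out_of_range": any(not 0 <= e <= 100 for e in effs)}


def capture_table(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize a measurement table with columns
    (condition, replicate, C0_ng_ml, Cs_ng_ml).

    Returns (per-condition summary, pairwise fold-improvement table of
    every condition against every other condition's mean efficiency).
    """
    required = {"condition", "replicate", "C0_ng_ml", "Cs_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    rows = []
    for cond, sub in df.groupby("condition", sort=False):
        ms = [CaptureMeasurement(C0=r.C0_ng_ml, Cs=r.Cs_ng_ml,
                                 replicate=r.replicate)
              for r in sub.itertuples()]
        agg = aggregate_efficiencies(ms)
        rows.append({"condition": cond, "mean_eff": agg["mean"],
                     "sd": agg["sd"], "n": agg["n"],
                     "out_of_range": agg["out_of_range"]})
    summary = pd.DataFrame(rows)
    folds = []
    for _, a in summary.iterrows():
        for _, b in summary.iterrows():
            if a.condition == b.condition or b.mean_eff == 0:
                continue
            folds.append({"numerator": a.condition, "denominator": b.condition,
                          "fold": a.mean_eff / b.mean_eff})
    return summary, pd.DataFrame(folds)
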
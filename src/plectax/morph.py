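"""Diagnostic ratios and morphotype classification.

Two ratios separate the observed morphotypes: c' (tail length divided by
anal body width) and the amphid aperture width relative to neck width.
Short-tailed specimens have c' below 3 and a small amphid (ratio averaging
0.14); long-tailed specimens have c' above 5 and a large amphid (ratio
averaging 0.26).  Specimens whose c' falls between the thresholds are
reported as an explicit intermediate class rather than silently forced into
either morphotype; printed labels, where available, are carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .io import MorphTable

SHORT_TAIL = "short_tail"
LONG_TAIL = "long_tail"
INTERMEDIATE = "intermediate"
UNDETERMINED = "undetermined"

#: Printed precision of the two ratios (decimal places).
CPRIME_DECIMALS = 1
AMPHID_RATIO_DECIMALS = 2


def round_half_up(x: float, decimals: int) -> float:
    """Round half away from zero at a fixed number of decimals (the printed
    convention), avoiding binary round-half-even surprises."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MorphotypeThresholds:
    short_max_cprime: float = 3.0
    long_min_cprime: float = 5.0

    def __post_init__(self):
        if self.short_max_cprime > self.long_min_cprime:
            raise ValueError("short threshold exceeds long threshold")


@dataclass(frozen=True)
class MorphRecord:
    nid: str
    stage: str
    tail_length_um: float
    anal_body_width_um: float
    amphid_width_um: Optional[float]
    neck_width_um: Optional[float]
    c_prime: float
    amphid_ratio: Optional[float]


def derive_ratios(row, rounding: str = "full") -> MorphRecord:
    """Compute c' and the amphid/neck ratio for one measurement row.

    ``row`` is a mapping (or pandas row) with the morphometric-table
    columns.  ``rounding='as-printed'`` reports c' to 1 decimal and the
    amphid ratio to 2 decimals, half-up; missing amphid or neck values
    propagate to a missing ratio.
    """
    if rounding not in ("full", "as-printed"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    tail = float(row["tail_length"])
    abw = float(row["anal_body_width"])
    if tail <= 0 or abw <= 0:
        raise ValueError(f"non-positive measurement for {row['nid']!r}")
    c_prime = tail / abw
    amphid = row.get("amphid_width") if hasattr(row, "get") else row["amphid_width"]
    neck = row.get("neck_width") if hasattr(row, "get") else row["neck_width"]
    ratio: Optional[float] = None
    if amphid is not None and neck is not None and not (
            pd.isna(amphid) or pd.isna(neck)):
        amphid, neck = float(amphid), float(neck)
        if amphid <= 0 or neck <= 0:
            raise ValueError(f"non-positive amphid/neck width for {row['nid']!r}")
        ratio = amphid / neck
    if rounding == "as-printed":
        c_prime = round_half_up(c_prime, CPRIME_DECIMALS)
        if ratio is not None:
            ratio = round_half_up(ratio, AMPHID_RATIO_DECIMALS)
    return MorphRecord(
        nid=str(row["nid"]), stage=str(row["stage"]),
        tail_length_um=tail, anal_body_width_um=abw,
        amphid_width_um=None if pd.isna(amphid) else float(amphid),
        neck_width_um=None if pd.isna(neck) else float(neck),
        c_prime=c_prime, amphid_ratio=ratio,
    )


def classify_morphotype(rec, thresholds: MorphotypeThresholds = MorphotypeThresholds()
                        ) -> str:
    """Morphotype from c': short below, long above, intermediate between."""
    c_prime = rec.c_prime if isinstance(rec, MorphRecord) else float(rec)
    if c_prime is None or np.isnan(c_prime):
        return UNDETERMINED
    if c_prime < thresholds.short_max_cprime:
        return SHORT_TAIL
    if c_prime > thresholds.long_min_cprime:
        return LONG_TAIL
    return INTERMEDIATE


def add_ratios(table: MorphTable | pd.DataFrame, rounding: str = "full",
               thresholds: MorphotypeThresholds = MorphotypeThresholds()
               ) -> pd.DataFrame:
    """Per-specimen ratios and morphotype calls for a whole table."""
    df = (table.df if isinstance(table, MorphTable) else table).copy()
    recs = [derive_ratios(row, rounding) for _, row in df.iterrows()]
    df["c_prime"] = [r.c_prime for r in recs]
    df["amphid_ratio"] = [np.nan if r.amphid_ratio is None else r.amphid_ratio
                          for r in recs]
    df["morphotype"] = [classify_morphotype(r, thresholds) for r in recs]
    return df


def morph_group_summary(df: pd.DataFrame, by: str = "morphotype",
                        measurements: Optional[list[str]] = None) -> pd.DataFrame:
    """Per-group mean / sd / min / max / n for each measurement and ratio.

    Standard deviation is the sample (n-1) estimate; missing values are
    skipped and ``n`` counts the non-missing ones.  Single-measurement
    groups report a missing sd and a degenerate range.
    """
    if measurements is None:
        measurements = [c for c in ("tail_length", "anal_body_width",
                                    "amphid_width", "neck_width",
                                    "c_prime", "amphid_ratio") if c in df.columns]
    rows = []
    for grp, sub in df.groupby(by, sort=True):
        if len(sub) == 0:
            continue
        for meas in measurements:
            vals = pd.to_numeric(sub[meas], errors="coerce").dropna()
            if vals.empty:
                continue
            rows.append({
                by: grp, "measurement": meas,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "min": float(vals.min()), "max": float(vals.max()),
                "n": int(len(vals)),
            })
    return pd.DataFrame(rows).set_index([by, "measurement"])


def compare_with_printed(table: MorphTable | pd.DataFrame,
                         tolerance: float = 0.05) -> pd.DataFrame:
    """Recompute the printed ratio columns and flag disagreements.

    Expects ``c_prime_printed`` / ``amphid_ratio_printed`` columns.  A row
    whose recomputed ratio differs from the printed value by more than
    ``tolerance`` is flagged (``discrepant``) instead of silently failed;
    the returned frame carries both values for every row.
    """
    df = table.df if isinstance(table, MorphTable) else table
    out = add_ratios(df, rounding="full")
    res = pd.DataFrame({"nid": out["nid"]})
    for col, printed_col, nd in (
            ("c_prime", "c_prime_printed", CPRIME_DECIMALS),
            ("amphid_ratio", "amphid_ratio_printed", AMPHID_RATIO_DECIMALS)):
        if printed_col not in df.columns:
            continue
        printed = pd.to_numeric(df[printed_col], errors="coerce")
        recomputed = out[col]
        res[f"{col}_printed"] = printed
        res[f"{col}_recomputed"] = recomputed
        res[f"{col}_rounded"] = recomputed.map(
            lambda v, nd=nd: np.nan if pd.isna(v) else round_half_up(v, nd))
        res[f"{col}_discrepant"] = (
            (recomputed - printed).abs() > tolerance) & printed.notna()
    flag_cols = [c for c in res.columns if c.endswith("_discrepant")]
    res["discrepant"] = res[flag_cols].any(axis=1)
    return res
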
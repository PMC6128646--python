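"""Competitive-growth fitness from flow-cytometry event tables.

A mutant (GFP-) is co-cultured 1:1 with a GFP+ wild-type reference, with and
without toxicant; a parallel reference competition runs untagged wild type
(GFP-) against the same GFP+ strain. After gating out dead cells
(DAPI-permeable, high 450/50 signal), debris (scatter box) and doublets
(FSC-A/FSC-H pulse-shape band), events are classified GFP+/GFP- on the
530/30 (FITC) channel, excluding an ambiguous mid-intensity band.

The mutant fraction in each sample is W = GFP- / (GFP- + GFP+). With
subscripts m (mutant run), r (reference run) and * (toxicant present):

    W_n  = W_m  / W_r        (normalizes away GFP+ cells that silenced GFP)
    W_n* = W_m* / W_r*
    growth ratio = W_n* / W_n

A growth ratio of 1 means the toxicant does not change the mutant's
competitive fitness; values below 1 quantify sensitivity. The raw
mutant-to-reference count ratio W_N = GFP-/GFP+ has an assay detection
floor (default 0.03, set by residual autofluorescence); results below it
are flagged, never clamped, so downstream statistics can censor explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GateConfig",
    "GFPCounts",
    "CompetitionResult",
    "TTestResult",
    "apply_gates",
    "classify_gfp",
    "growth_ratio",
    "replicate_test",
    "read_events",
]

REQUIRED_COLUMNS = ["FSC_A", "FSC_H", "SSC", "DAPI", "FITC", "PE"]

#: default assay detection floor for the mutant/reference count ratio
DETECTION_FLOOR = 0.03


@dataclass
class GateConfig:
    """Thresholds for the gating cascade and GFP classification.

    All intensities are linear arbitrary units. The three hard gates are
    intersective (order-independent): viability (DAPI <= dapi_max), a
    scatter box on FSC-A and SSC, and a doublet band on the FSC-A/FSC-H
    ratio (pulse area outgrows pulse height for adhered cell pairs — a
    shape criterion that stays valid when genotoxins elongate cells).
    FITC above ``gfp_positive_min`` is GFP+, below the ambiguous interval
    GFP-, inside the interval excluded.
    """

    dapi_max: float = 300.0
    fsc_a_bounds: tuple[float, float] = (150.0, 1e5)
    ssc_bounds: tuple[float, float] = (50.0, 1e5)
    doublet_ratio_bounds: tuple[float, float] = (0.8, 1.4)
    gfp_ambiguous: tuple[float, float] = (1e2, 1e3)
    gfp_positive_min: float = 1e3

    def __post_init__(self):
        for name in ("fsc_a_bounds", "ssc_bounds", "doublet_ratio_bounds", "gfp_ambiguous"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered interval, got ({lo}, {hi})")
        if self.gfp_ambiguous[1] > self.gfp_positive_min:
            raise ValueError(
                "the ambiguous FITC interval must lie below (or end at) the "
                "GFP-positive threshold"
            )
        if self.dapi_max <= 0:
            raise ValueError("dapi_max must be positive")


def _validate_events(events: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    block = events[REQUIRED_COLUMNS]
    if block.isna().any().any():
        raise ValueError("event table has missing intensities")
    if (block < 0).any().any():
        raise ValueError("intensities must be non-negative")


def apply_gates(
    events: pd.DataFrame, config: GateConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the three hard gates; return (retained events, attrition report).

    The gates use intersection semantics — each mask is computed on the full
    input, so permuting their order cannot change the retained set. The
    attrition report lists, per gate, how many events that gate alone
    removes and the running sequential remainder in the conventional order
    (viability, scatter box, doublet band).
    """
    config = config or GateConfig()
    _validate_events(events)
    n = len(events)
    if n == 0:
        raise ValueError("empty event table")
    viable = events["DAPI"] <= config.dapi_max
    box = events["FSC_A"].between(*config.fsc_a_bounds) & events["SSC"].between(
        *config.ssc_bounds
    )
    ratio = events["FSC_A"] / events["FSC_H"]
    singlet = ratio.between(*config.doublet_ratio_bounds)

    masks = {"viability": viable, "scatter_box": box, "doublet_band": singlet}
    keep = viable & box & singlet
    if not keep.any():
        raise ValueError("all events removed by gating; sample is uninterpretable")

    running = pd.Series(True, index=events.index)
    rows = []
    for gate, mask in masks.items():
        removed_alone = int((~mask).sum())
        running &= mask
        rows.append(
            {
                "gate": gate,
                "removed_alone": removed_alone,
                "remaining_sequential": int(running.sum()),
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["n_input"] = n
    report.attrs["total_attrition"] = 1.0 - keep.sum() / n
    return events[keep], report


@dataclass(frozen=True)
class GFPCounts:
    n_gfp_pos: int
    n_gfp_neg: int
    n_ambiguous: int

    @property
    def fraction_gfp_neg(self) -> float:
        """W = GFP- / (GFP- + GFP+); needs at least one GFP+ event."""
        if self.n_gfp_pos == 0:
            raise ValueError("no GFP+ events; the normalizing fraction is undefined")
        return self.n_gfp_neg / (self.n_gfp_neg + self.n_gfp_pos)

    @property
    def count_ratio(self) -> float:
        """W_N = GFP- count / GFP+ count (detection-floor statistic)."""
        if self.n_gfp_pos == 0:
            raise ValueError("no GFP+ events; the count ratio is undefined")
        return self.n_gfp_neg / self.n_gfp_pos


def classify_gfp(events: pd.DataFrame, config: GateConfig | None = None) -> GFPCounts:
    """Split gated events into GFP+ / GFP- / ambiguous-excluded on FITC."""
    config = config or GateConfig()
    _validate_events(events)
    fitc = events["FITC"]
    lo, hi = config.gfp_ambiguous
    pos = fitc > config.gfp_positive_min
    ambiguous = fitc.between(lo, hi) & ~pos
    neg = ~pos & ~ambiguous
    return GFPCounts(int(pos.sum()), int(neg.sum()), int(ambiguous.sum()))


@dataclass(frozen=True)
class CompetitionResult:
    w_m: float
    w_r: float
    w_m_star: float
    w_r_star: float
    w_n: float
    w_n_star: float
    growth_ratio: float
    normalized_growth: float  # W_N = mutant/reference count ratio, treated
    below_detection: bool


def growth_ratio(
    mutant_untreated: GFPCounts,
    mutant_treated: GFPCounts,
    reference_untreated: GFPCounts,
    reference_treated: GFPCounts,
    detection_floor: float = DETECTION_FLOOR,
) -> CompetitionResult:
    """Normalized competitive growth ratio from the four gated samples.

    W_m(*) and W_r(*) are the GFP- fractions of the mutant and reference
    runs; W_n = W_m/W_r and W_n* = W_m*/W_r* cancel the small percentage of
    GFP+ cells that lost fluorescence, and the growth ratio is W_n*/W_n.
    The treated mutant run's count ratio W_N is compared against the
    detection floor and flagged — not clamped — when below it.
    """
    w_m = mutant_untreated.fraction_gfp_neg
    w_m_star = mutant_treated.fraction_gfp_neg
    w_r = reference_untreated.fraction_gfp_neg
    w_r_star = reference_treated.fraction_gfp_neg
    if w_r == 0 or w_r_star == 0:
        raise ValueError("reference GFP- fraction is zero; normalization undefined")
    if w_m == 0:
        raise ValueError("untreated mutant fraction is zero; growth ratio undefined")
    w_n = w_m / w_r
    w_n_star = w_m_star / w_r_star
    w_big_n = mutant_treated.count_ratio
    return CompetitionResult(
        w_m=w_m,
        w_r=w_r,
        w_m_star=w_m_star,
        w_r_star=w_r_star,
        w_n=w_n,
        w_n_star=w_n_star,
        growth_ratio=w_n_star / w_n,
        normalized_growth=w_big_n,
        below_detection=w_big_n < detection_floor,
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


def replicate_test(ratios_a, ratios_b, welch: bool = False) -> TTestResult:
    """Two-sample two-tailed Student's t-test on replicate growth ratios.

    Pooled-variance by default (``welch=True`` switches to the
    unequal-variance form). The degenerate case of two zero-variance groups
    with equal means is reported as t = 0, p = 1.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, float(a.size + b.size - 2))
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a CSV event table with the six required channel columns."""
    events = pd.read_csv(path)
    _validate_events(events)
    return events
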
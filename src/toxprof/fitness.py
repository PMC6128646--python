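"""Growth-inhibition scoring and sensitive-mutant calling.

The growth-inhibition (GI) score of a mutant is the normalized log2 ratio of
its barcode frequency in the control versus the treatment sample, divided by
the number of pool doublings g:

    GI_i = log2(f_control,i / f_treatment,i) / g

Normalizing by relative frequency (rather than raw counts) cancels
sequencing-depth differences and keeps scores meaningful for slow-growing
mutants; dividing by g puts the score on a per-doubling scale, so a mutant
that completely fails to grow under treatment lands near GI = 1 and an
unaffected mutant at 0.

Sensitive mutants are then called by robust standardization — deviation of
each GI score from the screen median in units of the normalized
interquartile range (NIQR = IQR / 1.349, which estimates the SD under
normality) — followed by a tail-area false discovery rate on the upper tail
(sensitivity is one-sided: treatment depletes sensitive mutants). The FDR
step is realized as Benjamini–Hochberg on one-sided normal p-values with a
configurable null proportion pi0 (default 1, conservative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_abundance",
    "gi_scores",
    "robust_z",
    "tail_fdr",
    "call_sensitive",
    "classify_expressivity",
    "score_screen",
]

#: Phi^-1(0.75) - Phi^-1(0.25): divides the IQR so NIQR estimates the SD
#: of a normal sample.
NIQR_CONSTANT = 1.349

CALL_BOTH = "sensitive_both"
CALL_ONE = "sensitive_one"
CALL_NONE = "not_sensitive"


def relative_abundance(counts, pseudocount: float = 0.5) -> np.ndarray:
    """Pseudocounted relative frequencies, summing to 1.

    freq_i = (count_i + pseudocount) / sum_j (count_j + pseudocount).
    The default pseudocount of 0.5 keeps mutants that vanish from the
    treatment pool (the strongest phenotypes) at finite GI scores.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-d vector")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = counts + pseudocount
    total = shifted.sum()
    if total <= 0:
        raise ValueError("all counts are zero; provide a positive pseudocount")
    return shifted / total


def gi_scores(control_freq, treatment_freq, doublings: float) -> np.ndarray:
    """Per-doubling log2 depletion scores, GI = log2(control/treatment)/g."""
    c = np.asarray(control_freq, dtype=float)
    t = np.asarray(treatment_freq, dtype=float)
    if c.shape != t.shape:
        raise ValueError("control and treatment frequencies must align")
    if not (doublings > 0 and np.isfinite(doublings)):
        raise ValueError("doublings must be positive and finite")
    if np.any(t == 0) or np.any(c == 0):
        raise ValueError(
            "zero frequencies are undefined under log2; recompute the "
            "frequencies with a positive pseudocount"
        )
    return np.log2(c / t) / doublings


def robust_z(gi_vector, niqr_constant: float = NIQR_CONSTANT) -> np.ndarray:
    """Deviation from the median in NIQR units.

    z_i = (GI_i - median) / (IQR / 1.349). Quantiles use linear
    interpolation. NaN entries (mutants missing from a screen) propagate as
    NaN; the location and scale come from the finite values only, of which
    at least 4 are required.
    """
    x = np.asarray(gi_vector, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 4:
        raise ValueError("robust z needs at least 4 finite GI scores")
    q25, q50, q75 = np.percentile(finite, [25, 50, 75], method="linear")
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("degenerate screen: interquartile range is zero")
    return (x - q50) / (iqr / niqr_constant)


def tail_fdr(z_vector, pi0: float = 1.0) -> np.ndarray:
    """Upper-tail FDR q-values for robust z scores.

    One-sided p_i = 1 - Phi(z_i) under the standard-normal null implied by
    the robust standardization, then the step-up envelope
    q_i = min_{j: p_j >= p_i} (pi0 * M * p_j / rank_j), clipped to [0, 1]
    (Benjamini–Hochberg with a null-proportion factor). Monotone
    non-decreasing in p by construction.
    """
    z = np.asarray(z_vector, dtype=float)
    if z.size == 0:
        raise ValueError("empty z vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("z scores must be finite")
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    p = stats.norm.sf(z)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def score_screen(
    control_counts,
    treatment_counts,
    doublings: float = 5.0,
    pseudocount: float = 0.5,
    pi0: float = 1.0,
    index=None,
    screen_id: str = "screen",
) -> pd.DataFrame:
    """Counts -> GI -> robust z -> q for one screen, with an audit trail.

    Returns a DataFrame (indexed by mutant if ``index`` is given) carrying
    the control/treatment frequencies alongside gi, z and q so every score
    can be traced back to its inputs.
    """
    cf = relative_abundance(control_counts, pseudocount)
    tf = relative_abundance(treatment_counts, pseudocount)
    gi = gi_scores(cf, tf, doublings)
    z = robust_z(gi)
    q = tail_fdr(z, pi0=pi0)
    df = pd.DataFrame(
        {
            "control_freq": cf,
            "treatment_freq": tf,
            "gi": gi,
            "z": z,
            "q": q,
        },
        index=index,
    )
    df.attrs.update(
        {"screen_id": screen_id, "doublings": doublings, "pseudocount": pseudocount, "pi0": pi0}
    )
    return df


def call_sensitive(
    q_by_screen: pd.DataFrame,
    cutoff: float = 0.1,
    rule: str = "both",
) -> pd.DataFrame:
    """Label mutants from per-screen q-values.

    ``q_by_screen`` has one column per screen; NaN marks a mutant absent
    from that screen (library versions differ between screens, so partial
    coverage is the norm, and it is reported per mutant). A mutant is
    ``sensitive_both`` when it has data in at least two screens and passes
    the cutoff in every screen with data; ``sensitive_one`` when it passes
    in at least one; otherwise ``not_sensitive``. Mutants covered by a
    single screen can at best be ``sensitive_one``.

    ``rule`` selects which labels count as positive calls in the boolean
    ``selected`` column: "both" (default) or "any".
    """
    if rule not in ("both", "any"):
        raise ValueError("rule must be 'both' or 'any'")
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    q = q_by_screen.astype(float)
    has_data = q.notna()
    if (has_data.sum(axis=1) < 1).any():
        raise ValueError("every mutant needs q from at least one screen")
    passes = (q <= cutoff) & has_data
    n_screens = has_data.sum(axis=1)
    n_pass = passes.sum(axis=1)
    call = np.where(
        (n_screens >= 2) & (n_pass == n_screens),
        CALL_BOTH,
        np.where(n_pass >= 1, CALL_ONE, CALL_NONE),
    )
    out = q.copy()
    out["n_screens"] = n_screens
    out["n_pass"] = n_pass
    out["call"] = call
    out["selected"] = (
        out["call"] == CALL_BOTH if rule == "both" else out["call"] != CALL_NONE
    )
    return out


def classify_expressivity(
    calls: pd.DataFrame,
    gi: pd.Series,
    thresholds: tuple[float, float] | None = None,
) -> pd.Series:
    """Ordinal strength labels (high/medium/low) for called mutants.

    GI at or above the upper threshold is "high", between the thresholds
    "medium", below the lower one "low"; mutants without a positive call
    get NA. With ``thresholds=None`` the cut points default to the tertiles
    of GI among called mutants. These categories are advisory: they are not
    comparable to strength categories derived from orthogonal assays (e.g.
    plate-based spot tests), which may be passed through as annotations
    instead.
    """
    called = calls["call"] != CALL_NONE
    gi = gi.reindex(calls.index)
    if thresholds is None:
        vals = gi[called].dropna()
        if vals.empty:
            return pd.Series(pd.NA, index=calls.index, dtype="object")
        thresholds = tuple(np.quantile(vals, [1 / 3, 2 / 3]))
    lo, hi = thresholds
    if not lo <= hi:
        raise ValueError(f"thresholds must be ordered, got ({lo}, {hi})")
    labels = pd.Series(pd.NA, index=calls.index, dtype="object")
    labels[called & (gi >= hi)] = "high"
    labels[called & (gi >= lo) & (gi < hi)] = "medium"
    labels[called & (gi < lo)] = "low"
    return labels
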
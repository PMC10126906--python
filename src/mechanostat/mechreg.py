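"""Conditional-probability mechanoregulation analysis and the CCR.

For each (re)modeling event (formation, quiescence, resorption) the
mechanical-signal values observed at surface voxels are pooled, normalized
by the 99th percentile of all observed values, and binned at 1% of that
cap.  Within each bin the per-event counts are first normalized by the
event totals — removing any dependence on the global imbalance between
events — and then converted to conditional probabilities
``p(event | bin)``.  A probability of 1/3 in a bin means the signal carries
no information about the event there.

The correct classification rate (CCR) summarizes how well two signal
thresholds ``t_r <= t_f`` separate the three events into low (resorption),
middle (quiescence) and high (formation) intervals: a 3x3 confusion matrix
is filled with the summed conditional probabilities of each event in each
interval and the normalized trace is maximized by an exhaustive sweep of
all threshold pairs on the bin boundaries.  CCR = 1 is a perfect ternary
classification; 1/3 is the random-classifier baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EVENTS",
    "N_BINS",
    "ConditionalProbabilityCurves",
    "CCRResult",
    "conditional_probabilities",
    "compute_ccr",
]

#: event order used throughout (ascending expected signal)
EVENTS = ("resorption", "quiescence", "formation")

N_BINS = 100


@dataclass
class ConditionalProbabilityCurves:
    """Per-bin conditional probabilities of the three (re)modeling events.

    ``probabilities`` has shape (100, 3) with columns in ``EVENTS`` order;
    rows of unpopulated bins are NaN and flagged in ``populated``.
    ``cap`` is the 99th-percentile normalization value in signal units;
    bin b covers normalized signal [b, b+1) percent of the cap.
    """

    probabilities: np.ndarray
    populated: np.ndarray
    counts: np.ndarray = None
    totals: dict = field(default_factory=dict)
    cap: float = float("nan")
    degenerate: bool = False

    @classmethod
    def from_probabilities(
        cls, probabilities: np.ndarray, cap: float = float("nan")
    ) -> "ConditionalProbabilityCurves":
        """Build curves directly from a (100, 3) probability array.

        Intended for calibration studies; bins whose probabilities are all
        NaN are marked unpopulated, the rest must sum to 1.
        """
        p = np.asarray(probabilities, dtype=np.float64)
        if p.shape != (N_BINS, 3):
            raise ValueError(f"expected shape ({N_BINS}, 3), got {p.shape}")
        populated = ~np.all(np.isnan(p), axis=1)
        sums = p[populated].sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("populated bins must have probabilities summing to 1")
        return cls(p, populated, cap=cap)


@dataclass
class CCRResult:
    """Optimal ternary classification of (re)modeling events by signal."""

    ccr: float
    t_r: float  # normalized signal, % of the 99th-percentile cap
    t_f: float
    confusion: np.ndarray  # rows: predicted interval, cols: event (EVENTS order)
    degenerate: bool = False


def conditional_probabilities(
    table: pd.DataFrame, cap: float | None = None
) -> ConditionalProbabilityCurves:
    """Event-conditional probability curves over normalized signal bins.

    Per bin b and event e: ``p(e|b) = (n_e(b)/N_e) / sum_e' (n_e'(b)/N_e')``
    where ``N_e`` is the event's total count.  Signal values above the
    99th-percentile cap fall into the top bin.  ``cap`` overrides the
    per-table percentile, e.g. with a value pooled across the animals of a
    group.
    """
    if len(table) == 0:
        raise ValueError("empty surface table")
    sig = table["signal"].to_numpy(dtype=np.float64)
    if np.any(np.isnan(sig)):
        raise ValueError("table has unsampled signal values")
    if cap is None:
        cap = float(np.percentile(sig, 99))
    if cap <= 0:
        raise ValueError("nonpositive 99th-percentile signal cap")
    bins = np.clip((sig / cap * N_BINS).astype(np.int64), 0, N_BINS - 1)

    counts = np.zeros((N_BINS, 3))
    totals = {}
    events = table["event"].to_numpy()
    for j, e in enumerate(EVENTS):
        sel = events == e
        totals[e] = int(sel.sum())
        counts[:, j] = np.bincount(bins[sel], minlength=N_BINS)
    degenerate = any(t == 0 for t in totals.values())

    norm = np.zeros_like(counts)
    for j, e in enumerate(EVENTS):
        if totals[e] > 0:
            norm[:, j] = counts[:, j] / totals[e]
    denom = norm.sum(axis=1)
    populated = denom > 0
    probs = np.full((N_BINS, 3), np.nan)
    probs[populated] = norm[populated] / denom[populated, None]
    return ConditionalProbabilityCurves(
        probs, populated, counts=counts, totals=totals, cap=cap, degenerate=degenerate
    )


def compute_ccr(curves: ConditionalProbabilityCurves) -> CCRResult:
    """Maximum correct classification rate over all threshold pairs.

    Sweeps every pair of bin boundaries ``t_r <= t_f``; bins below ``t_r``
    form the resorption interval, bins in ``[t_r, t_f)`` the quiescence
    interval, bins at/above ``t_f`` the formation interval.  Empty bins are
    excluded from both the confusion sums and the denominator, so the
    confusion matrix totals the number of populated bins.  Ties are broken
    toward the smallest ``(t_r, t_f)``.
    """
    pop_idx = np.flatnonzero(curves.populated)
    if len(pop_idx) == 0:
        raise ValueError("no populated bins")
    P = curves.probabilities[pop_idx]  # (nb, 3) in EVENTS order
    nb = len(pop_idx)
    # prefix sums: cum[i, j] = sum of first i bins' p(event j)
    cum = np.vstack([np.zeros(3), np.cumsum(P, axis=0)])
    R, Q, F = cum[:, 0], cum[:, 1], cum[:, 2]

    best = (-np.inf, 0, 0)
    for i in range(nb + 1):
        for j in range(i, nb + 1):
            trace = R[i] + (Q[j] - Q[i]) + (F[nb] - F[j])
            if trace > best[0] + 1e-12:
                best = (trace, i, j)
    trace, i, j = best

    # boundary index k in populated-bin space -> normalized signal (%)
    def boundary(k: int) -> float:
        if k < nb:
            return float(pop_idx[k])  # lower edge of populated bin k
        return float(pop_idx[-1] + 1)  # upper edge of the last one

    confusion = np.zeros((3, 3))
    confusion[0] = cum[i] - cum[0]  # resorption interval
    confusion[1] = cum[j] - cum[i]  # quiescence interval
    confusion[2] = cum[nb] - cum[j]  # formation interval
    return CCRResult(
        ccr=trace / nb,
        t_r=boundary(i),
        t_f=boundary(j),
        confusion=confusion,
        degenerate=nb == 1,
    )
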
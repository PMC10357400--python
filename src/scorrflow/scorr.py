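"""Transit-time-aware single-particle colocalization (Scorr).

Each upstream ("red") peak carries its own speed estimate: the particle
crossed a beam of known width ΔX2 in its measured transit time PT2, so
v2 = ΔX2 / PT2. The algorithm predicts where that specific particle
should reappear in the downstream ("blue") channel and matches peak by
peak, instead of applying one global lag to the whole trajectory:

1. **Coarse shift** — assume the speed stays constant between lasers:
   the predicted travel time over the inter-laser distance ΔX3 is
   PT3 = ΔX3 / v2, i.e. ``t_pred = t_red + PT2 * ΔX3 / ΔX2``.
2. **W1 gating** — blue peaks within ``W1`` of the coarse prediction
   become candidates. W1 is a density knob: at high particle density it
   must shrink so that the wrong neighbor's transit time is not used in
   the fine shift.
3. **Fine shift** — for each candidate, refine the travel-time estimate
   with the average of the speeds measured at the two beams,
   ``v_avg = (v1 + v2) / 2`` with v1 = ΔX1 / PT1, and recompute
   ΔT = |t_blue − t_pred|.
4. **W2 acceptance** — pairs with ΔT ≤ W2 are colocalization proposals.
   W2 rejects particles whose speed changed unpredictably between beams
   (e.g. wall interactions).
5. **Conflict resolution** — when a peak is claimed more than once, the
   pairing with the smallest ΔT wins; ties go to the pairing whose
   transit time changed the least between lasers. Losers re-enter the
   pool and may take their next-best surviving candidate; this iterates
   to a fixed point, so the result is one-to-one.

Because every shift is particle-specific, order swaps between lasers are
harmless and the method is insensitive to bright contaminants that drag
a global cross-correlation lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matching import MatchSet, build_matchset, sort_peaks

_VELOCITY_AVERAGES = ("arithmetic", "harmonic")


@dataclass(frozen=True)
class LaserGeometry:
    """Beam widths and separation of the two-laser interrogation region.

    ``dx1`` — downstream (blue) beam width, μm; ``dx2`` — upstream (red)
    beam width, μm; ``dx3`` — center-to-center distance between the
    beams, μm. Peak times are beam-center crossing times.
    """

    dx1: float = 1.0
    dx2: float = 1.0
    dx3: float = 15.0

    def __post_init__(self) -> None:
        if self.dx1 <= 0 or self.dx2 <= 0 or self.dx3 <= 0:
            raise ValueError("all geometry distances must be positive")


@dataclass(frozen=True)
class ScorrParams:
    """Cutoff windows and algorithm options.

    ``w1`` gates candidates after the coarse shift; ``w2`` is the final
    acceptance window on ΔT after the fine shift (both ms). ``fine=False``
    stops after the coarse shift (for ablation studies).
    ``velocity_average`` selects how the two per-beam speeds combine in
    the fine shift. ``tie_tol`` is the ΔT equality tolerance (ms) below
    which the transit-time-change tie-break applies.
    """

    w1: float = 2.0
    w2: float = 4.0
    fine: bool = True
    velocity_average: str = "arithmetic"
    tie_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("w1 and w2 must be positive")
        if self.velocity_average not in _VELOCITY_AVERAGES:
            raise ValueError(f"velocity_average must be one of {_VELOCITY_AVERAGES}")
        if self.tie_tol <= 0:
            raise ValueError("tie_tol must be positive")


def _check_positive_pt(pt, what: str) -> np.ndarray:
    pt = np.asarray(pt, dtype=float)
    if np.any(~(pt > 0)):
        raise ValueError(f"{what} transit times must be positive")
    return pt


def predicted_travel_time(
    geom: LaserGeometry,
    pt2,
    pt1=None,
    velocity_average: str = "arithmetic",
):
    """Predicted red-to-blue travel time PT3 (ms).

    With only the upstream transit time ``pt2`` this is the coarse
    (constant-speed) estimate ``ΔX3 / v2``. Given the candidate's
    downstream transit time ``pt1`` as well, the speed between the beams
    is taken as the average of v1 and v2 (arithmetic by default;
    harmonic corresponds to a constant-acceleration transit).
    """
    pt2 = _check_positive_pt(pt2, "red (upstream)")
    v2 = geom.dx2 / pt2
    if pt1 is None:
        v_eff = v2
    else:
        pt1 = _check_positive_pt(pt1, "blue (downstream)")
        v1 = geom.dx1 / pt1
        if velocity_average == "arithmetic":
            v_eff = 0.5 * (v1 + v2)
        else:
            v_eff = 2.0 / (1.0 / v1 + 1.0 / v2)
    out = geom.dx3 / v_eff
    return float(out) if np.ndim(out) == 0 else out


def coarse_shift(t_red, pt_red, geom: LaserGeometry):
    """Coarse predicted blue-channel appearance time (ms).

    Constant-speed assumption: ``t_red + PT2 * ΔX3 / ΔX2``. Accepts
    scalars or arrays.
    """
    out = np.asarray(t_red, dtype=float) + predicted_travel_time(geom, pt_red)
    return float(out) if np.ndim(out) == 0 else out


def fine_shift(t_red, pt_red, pt_blue, geom: LaserGeometry, velocity_average: str = "arithmetic"):
    """Fine predicted appearance time using both beams' transit times."""
    out = np.asarray(t_red, dtype=float) + predicted_travel_time(
        geom, pt_red, pt_blue, velocity_average
    )
    return float(out) if np.ndim(out) == 0 else out


def select_candidates(t_pred: float, blue_peaks: pd.DataFrame, w1: float) -> pd.DataFrame:
    """Blue peaks within ``w1`` of a coarse prediction, ordered by ΔT.

    ``blue_peaks`` must be sorted by ``t_center_ms``; the lookup is a
    binary search, so cost is logarithmic in the table size plus the
    number of candidates returned.
    """
    bt = blue_peaks["t_center_ms"].to_numpy()
    lo = np.searchsorted(bt, t_pred - w1, side="left")
    hi = np.searchsorted(bt, t_pred + w1, side="right")
    cand = blue_peaks.iloc[lo:hi].copy()
    cand["delta_t_ms"] = np.abs(cand["t_center_ms"].to_numpy() - t_pred)
    return cand.sort_values("delta_t_ms", kind="mergesort")


def resolve_conflicts(proposals: pd.DataFrame, tie_tol: float = 1e-6) -> pd.DataFrame:
    """Reduce colocalization proposals to a one-to-one matching.

    ``proposals`` needs columns ``red_idx``, ``blue_idx``, ``delta_t_ms``
    and ``rel_pt_change``. The surviving set is the fixed point of:
    among all live proposals take the one with minimum ΔT (ties within
    ``tie_tol`` broken by the smallest relative transit-time change
    |PT1 − PT2| / PT2, then by ΔT), fix that pairing, drop every other
    proposal touching either peak, repeat. Implemented as a single
    sorted greedy sweep, which computes the same fixed point.
    """
    if proposals.empty:
        return proposals.copy()
    dt = proposals["delta_t_ms"].to_numpy(dtype=float)
    rel = proposals["rel_pt_change"].to_numpy(dtype=float)
    bucket = np.round(dt / tie_tol).astype(np.int64)
    order = np.lexsort((dt, rel, bucket))
    red = proposals["red_idx"].to_numpy()
    blue = proposals["blue_idx"].to_numpy()
    red_taken: set = set()
    blue_taken: set = set()
    keep = []
    for i in order:
        r, b = red[i], blue[i]
        if r in red_taken or b in blue_taken:
            continue
        red_taken.add(r)
        blue_taken.add(b)
        keep.append(i)
    keep.sort()
    return proposals.iloc[keep].reset_index(drop=True)


def scorr_colocalize(
    red_peaks: pd.DataFrame,
    blue_peaks: pd.DataFrame,
    geom: LaserGeometry,
    params: ScorrParams | None = None,
) -> MatchSet:
    """Run the full transit-time colocalization pipeline.

    ``red_peaks``/``blue_peaks`` are peak tables (``t_center_ms`` and
    ``pt_ms`` required); row order is irrelevant. Returns a
    :class:`~scorrflow.matching.MatchSet` whose ``proposals`` attribute
    holds the pre-resolution candidate pairs (used for double-
    colocalization statistics).
    """
    params = params or ScorrParams()
    for name, df in (("red", red_peaks), ("blue", blue_peaks)):
        if "pt_ms" not in df.columns:
            raise ValueError(
                f"{name} peak table has no 'pt_ms' column: transit times are "
                "required — run scorrflow.peakdetect.detect_peaks first"
            )
    red = sort_peaks(red_peaks)
    blue = sort_peaks(blue_peaks)
    stage = "fine" if params.fine else "coarse"
    if red.empty or blue.empty:
        empty = pd.DataFrame(columns=["red_idx", "blue_idx", "delta_t_ms", "rel_pt_change"])
        return build_matchset(red, blue, [], [], [], stage, "scorr", proposals=empty)

    rt = red["t_center_ms"].to_numpy(dtype=float)
    rpt = _check_positive_pt(red["pt_ms"], "red (upstream)")
    bt = blue["t_center_ms"].to_numpy(dtype=float)
    bpt = _check_positive_pt(blue["pt_ms"], "blue (downstream)")

    t_pred_coarse = rt + rpt * (geom.dx3 / geom.dx2)
    lo = np.searchsorted(bt, t_pred_coarse - params.w1, side="left")
    hi = np.searchsorted(bt, t_pred_coarse + params.w1, side="right")
    counts = hi - lo
    total = int(counts.sum())
    red_i = np.repeat(np.arange(rt.size), counts)
    group_start = np.repeat(np.cumsum(counts) - counts, counts)
    blue_j = np.repeat(lo, counts) + (np.arange(total) - group_start)

    if params.fine:
        t_pred = fine_shift(rt[red_i], rpt[red_i], bpt[blue_j], geom, params.velocity_average)
    else:
        t_pred = t_pred_coarse[red_i]
    t_pred = np.atleast_1d(t_pred)
    delta_t = np.abs(bt[blue_j] - t_pred)
    accept = delta_t <= params.w2
    proposals = pd.DataFrame(
        {
            "red_idx": red_i[accept],
            "blue_idx": blue_j[accept],
            "delta_t_ms": delta_t[accept],
            "rel_pt_change": np.abs(bpt[blue_j[accept]] - rpt[red_i[accept]]) / rpt[red_i[accept]],
        }
    )
    kept = resolve_conflicts(proposals, params.tie_tol)
    return build_matchset(
        red,
        blue,
        kept["red_idx"].to_numpy(),
        kept["blue_idx"].to_numpy(),
        kept["delta_t_ms"].to_numpy(),
        stage,
        "scorr",
        proposals=proposals,
    )
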
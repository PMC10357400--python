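"""Shared match-set container for colocalization results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MATCH_COLUMNS = [
    "red_idx",
    "blue_idx",
    "red_t_center_ms",
    "blue_t_center_ms",
    "delta_t_ms",
    "pt_red_ms",
    "pt_blue_ms",
    "stage",
]


@dataclass
class MatchSet:
    """One-to-one pairing of peaks across two channels.

    ``matches`` has one row per accepted pair (columns ``MATCH_COLUMNS``
    plus ``red_true_id``/``blue_true_id`` and brightness columns when the
    input peak tables carried them). ``red_idx``/``blue_idx`` are
    positional indices into the time-sorted input tables.
    ``proposals``, when present, holds the candidate pairs that survived
    the acceptance window *before* conflict resolution — the raw material
    for double-colocalization statistics.
    """

    matches: pd.DataFrame
    unmatched_red: pd.DataFrame
    unmatched_blue: pd.DataFrame
    method: str
    proposals: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    def to_frame(self) -> pd.DataFrame:
        out = self.matches.copy()
        out["method"] = self.method
        return out

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def build_matchset(
    red: pd.DataFrame,
    blue: pd.DataFrame,
    red_pos: np.ndarray,
    blue_pos: np.ndarray,
    delta_t: np.ndarray,
    stage,
    method: str,
    proposals: pd.DataFrame | None = None,
) -> MatchSet:
    """Assemble a :class:`MatchSet` from positional pair indices.

    ``red``/``blue`` must already be sorted by ``t_center_ms`` with a
    clean RangeIndex; ``red_pos``/``blue_pos`` index into them.
    """
    red_pos = np.asarray(red_pos, dtype=int)
    blue_pos = np.asarray(blue_pos, dtype=int)
    data = {
        "red_idx": red_pos,
        "blue_idx": blue_pos,
        "red_t_center_ms": red["t_center_ms"].to_numpy()[red_pos],
        "blue_t_center_ms": blue["t_center_ms"].to_numpy()[blue_pos],
        "delta_t_ms": np.asarray(delta_t, dtype=float),
        "pt_red_ms": red["pt_ms"].to_numpy()[red_pos],
        "pt_blue_ms": blue["pt_ms"].to_numpy()[blue_pos],
        "stage": stage if not np.isscalar(stage) else np.repeat(stage, len(red_pos)),
    }
    matches = pd.DataFrame(data, columns=MATCH_COLUMNS)
    if "true_particle_id" in red.columns and "true_particle_id" in blue.columns:
        matches["red_true_id"] = red["true_particle_id"].to_numpy()[red_pos]
        matches["blue_true_id"] = blue["true_particle_id"].to_numpy()[blue_pos]
    if "brightness_class" in red.columns and "brightness_class" in blue.columns:
        matches["red_brightness"] = red["brightness_class"].to_numpy()[red_pos]
        matches["blue_brightness"] = blue["brightness_class"].to_numpy()[blue_pos]
    un_red = red.drop(index=np.unique(red_pos)).reset_index(drop=True)
    un_blue = blue.drop(index=np.unique(blue_pos)).reset_index(drop=True)
    return MatchSet(
        matches=matches,
        unmatched_red=un_red,
        unmatched_blue=un_blue,
        method=method,
        proposals=proposals,
    )


def sort_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Return a copy sorted by center time with a clean RangeIndex.

    Ties on ``t_center_ms`` are broken by transit time and height so the
    result is invariant to the input row order.
    """
    by = [c for c in ("t_center_ms", "pt_ms", "height") if c in peaks.columns]
    return peaks.sort_values(by, kind="mergesort", ignore_index=True)
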
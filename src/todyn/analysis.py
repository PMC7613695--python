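"""Ensemble post-processing: populations, coordinates, relaxation channels.

Implements the bookkeeping the photodynamics protocol prescribes after the
trajectories have run: adiabatic population curves with terminated
trajectories carried forward in their assumed final state (S0 after internal
conversion, T1 after triplet trapping), internal-coordinate time series, and
classification of each trajectory into photorelaxation channels by the
geometry at its termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .fssh import FAILED, IC_TO_S0, TIMEOUT, TRAPPED_T1

__all__ = ["ChannelSummary", "adiabatic_populations", "internal_coordinates",
           "classify_channel", "summarize_ensemble", "CHANNELS"]

CHANNELS = ("ring-opening-CO", "NH-fission", "photostabilising",
            "CO5-opening", "other")

#: Default geometric thresholds (Å): a ring C–O bond beyond 1.8 Å at
#: termination marks ring opening; by analogy the same cutoff marks N–H
#: fission.  Config-exposed, the N–H value is a chosen default.
DEFAULT_THRESHOLDS = {"r_CO": 1.8, "r_NH": 1.8}


@dataclass
class ChannelSummary:
    """Ensemble-level channel statistics.

    ``fractions`` are exact rationals over the non-excluded trajectories;
    ``percent`` the nearest-percent roundings the field usually quotes.
    """

    counts: dict
    fractions: dict
    percent: dict
    manifold_split: dict          # channel -> {"singlet": n, "triplet": n}
    initial_state_counts: dict
    initial_state_percent: dict
    n_total: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.counts:
            rows.append({
                "channel": ch,
                "count": self.counts[ch],
                "fraction": float(self.fractions[ch]),
                "percent": self.percent[ch],
                "singlet": self.manifold_split[ch]["singlet"],
                "triplet": self.manifold_split[ch]["triplet"],
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "fractions": {k: [v.numerator, v.denominator]
                          for k, v in self.fractions.items()},
            "percent": dict(self.percent),
            "manifold_split": {k: dict(v) for k, v in self.manifold_split.items()},
            "initial_state_counts": dict(self.initial_state_counts),
            "initial_state_percent": dict(self.initial_state_percent),
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
        }


def _carried_state(traj):
    """Label the trajectory occupies after termination, per the protocol's
    assumptions (S0 after internal conversion, T1 if triplet-trapped)."""
    if traj.outcome is None:
        return None
    if traj.outcome.reason == IC_TO_S0:
        return "S0"
    if traj.outcome.reason == TRAPPED_T1:
        return "T1"
    return None


def _label_at(traj, i):
    m, r = traj.active_multiplicity[i], traj.active_rank[i]
    return f"S{r}" if m == 0 else f"T{r + 1}"


def adiabatic_populations(ensemble, time_grid=None, state_labels=None) -> pd.DataFrame:
    """Fraction of trajectories in each labelled adiabatic state over time.

    Terminated trajectories count in their carried state (S0 or T1) from
    their termination time onward; failed trajectories are excluded.
    """
    live = [t for t in ensemble if not t.failed and len(t.times)]
    if not live:
        raise ValueError("no usable trajectories in the ensemble")
    if time_grid is None:
        t_end = max(t.times[-1] for t in live)
        dt = live[0].times[1] - live[0].times[0] if len(live[0].times) > 1 else 1.0
        time_grid = np.arange(0.0, t_end + 0.5 * dt, dt)
    if state_labels is None:
        labels = set()
        for t in live:
            for i in range(len(t.times)):
                labels.add(_label_at(t, i))
            carried = _carried_state(t)
            if carried:
                labels.add(carried)
        state_labels = sorted(labels)
    counts = {lab: np.zeros(len(time_grid)) for lab in state_labels}
    for traj in live:
        carried = _carried_state(traj)
        idx = np.searchsorted(traj.times, time_grid, side="right") - 1
        for j, i in enumerate(idx):
            if i < 0:
                i = 0
            if time_grid[j] > traj.times[-1] + 1e-9:
                lab = carried if carried else _label_at(traj, len(traj.times) - 1)
            else:
                lab = _label_at(traj, i)
            counts[lab][j] += 1
    n = len(live)
    data = {"time_fs": time_grid}
    for lab in state_labels:
        data[lab] = counts[lab] / n
    return pd.DataFrame(data)


def internal_coordinates(traj, coordinate_names, model=None) -> pd.DataFrame:
    """Per-step values of named internal coordinates.

    The tilt angle is reported as an absolute value (the two out-of-plane
    directions are equivalent for the analysis).
    """
    names = (tuple(model.coord_names) if model is not None
             else ("r_CO", "r_CS", "theta_tilt", "r_NH"))
    data = {"time_fs": traj.times}
    for cn in coordinate_names:
        if cn not in names:
            raise KeyError(f"unknown coordinate {cn!r}; available: {names}")
        col = traj.coords[:, names.index(cn)]
        if cn == "theta_tilt":
            col = np.abs(col)
        data[cn] = col
    return pd.DataFrame(data)


def classify_channel(traj, thresholds=None, model=None):
    """Channel label and manifold of one terminated trajectory.

    Precedence: ring C–O dissociation, then N–H fission, then (if the
    trajectory ended on the gap criterion) the photostabilising channel;
    timeouts with no threshold crossed fall into ``other``.  Failed
    trajectories are never classified.
    """
    if traj.outcome is None or traj.outcome.reason == FAILED:
        raise ValueError("only terminated, non-failed trajectories are classified")
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    names = (tuple(model.coord_names) if model is not None
             else ("r_CO", "r_CS", "theta_tilt", "r_NH"))
    q_end = traj.coords[-1]
    manifold = traj.outcome.final_manifold
    if manifold == "unknown":
        manifold = "singlet" if traj.active_multiplicity[-1] == 0 else "triplet"
    if "r_CO" in names and q_end[names.index("r_CO")] > th["r_CO"]:
        return "ring-opening-CO", manifold
    if "r_NH" in names and q_end[names.index("r_NH")] > th["r_NH"]:
        return "NH-fission", manifold
    if traj.outcome.reason in (IC_TO_S0, TRAPPED_T1):
        return "photostabilising", manifold
    return "other", manifold


def summarize_ensemble(ensemble, thresholds=None, model=None,
                       initial_counts=None) -> ChannelSummary:
    """Channel counts, exact fractions and nearest-percent report.

    ``initial_counts`` may override the initial-state tally (e.g. when
    summarising a reported ensemble from its printed counts alone).
    """
    usable = [t for t in ensemble if not t.failed]
    excluded = len(ensemble) - len(usable)
    if not usable:
        raise ValueError("all trajectories excluded; nothing to summarise")
    counts = {ch: 0 for ch in CHANNELS}
    split = {ch: {"singlet": 0, "triplet": 0} for ch in CHANNELS}
    init_counts: dict = {}
    for traj in usable:
        ch, man = classify_channel(traj, thresholds, model)
        counts[ch] += 1
        split[ch][man] += 1
        lab = traj.initial_state_label
        init_counts[lab] = init_counts.get(lab, 0) + 1
    if initial_counts is not None:
        init_counts = dict(initial_counts)
    n = len(usable)
    fractions = {ch: Fraction(counts[ch], n) for ch in CHANNELS}
    percent = {ch: round(100 * counts[ch] / n) for ch in CHANNELS}
    n_init = sum(init_counts.values())
    init_pct = {k: round(100 * v / n_init) for k, v in init_counts.items()} \
        if n_init else {}
    return ChannelSummary(counts=counts, fractions=fractions, percent=percent,
                          manifold_split=split,
                          initial_state_counts=init_counts,
                          initial_state_percent=init_pct,
                          n_total=len(ensemble), n_excluded=excluded)


def initial_state_percentages(counts: dict) -> dict:
    """Nearest-percent initial-state shares from printed counts."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty count table")
    return {k: round(100 * v / n) for k, v in counts.items()}
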
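"""Population curves, internal coordinates and channel classification."""

import numpy as np
import pandas as pd
import pytest

from todyn.analysis import (adiabatic_populations, classify_channel,
                            initial_state_percentages, internal_coordinates,
                            summarize_ensemble)
from todyn.fssh import (FAILED, IC_TO_S0, TIMEOUT, TRAPPED_T1,
                        TerminationOutcome, Trajectory)


def make_traj(n_steps=5, coords_end=(1.4, 1.7, 10.0, 1.0), reason=IC_TO_S0,
              manifold="singlet", label="S1", start_label="S2", mult=0, rank=1,
              dt=0.5):
    """Hand-built minimal trajectory for classification tests."""
    nt = n_steps
    coords = np.tile(np.array([1.37, 1.64, 0.0, 1.01]), (nt, 1))
    coords[-1] = coords_end
    outcome = None
    if reason is not None:
        outcome = TerminationOutcome(reason, (nt - 1) * dt, manifold, label)
    return Trajectory(
        times=np.arange(nt) * dt,
        coords=coords,
        momenta=np.zeros((nt, 4)),
        energies=np.zeros((nt, 7)),
        active=np.full(nt, 2, dtype=int),
        populations=np.zeros((nt, 7)),
        active_multiplicity=np.full(nt, mult, dtype=int),
        active_rank=np.full(nt, rank, dtype=int),
        gap_to_ground=np.full(nt, 1.0),
        hops=[],
        outcome=outcome,
        seed=0,
        initial_state_label=start_label,
    )


class TestInitialStateBookkeeping:
    def test_printed_counts_give_printed_percentages(self):
        """141 initial conditions split 120/16/5 across S2/S3/S1 round to
        85%, 11%, 4%."""
        pct = initial_state_percentages({"S2": 120, "S3": 16, "S1": 5})
        assert pct == {"S2": 85, "S3": 11, "S1": 4}

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            initial_state_percentages({})


class TestPopulations:
    def test_t0_populations_equal_initial_fractions(self):
        ens = ([make_traj(start_label="S2", rank=2) for _ in range(6)]
               + [make_traj(start_label="S1", rank=1) for _ in range(2)])
        pops = adiabatic_populations(ens)
        # every trajectory is S-rank at every step (mult 0); at t=0 the
        # active-rank split is 6:2
        row0 = pops.iloc[0]
        assert np.isclose(row0["S2"], 6 / 8)
        assert np.isclose(row0["S1"], 2 / 8)

    def test_populations_sum_to_one_everywhere(self):
        ens = ([make_traj(n_steps=4) for _ in range(3)]
               + [make_traj(n_steps=9, reason=TRAPPED_T1, manifold="triplet",
                            label="T1", mult=1, rank=0)])
        pops = adiabatic_populations(ens)
        state_cols = [c for c in pops.columns if c != "time_fs"]
        assert np.allclose(pops[state_cols].sum(axis=1), 1.0, atol=1e-12)

    def test_terminated_trajectories_carried_in_final_state(self):
        """After internal conversion a trajectory counts in S0; after
        triplet trapping it counts in T1."""
        ens = [make_traj(n_steps=3, reason=IC_TO_S0),
               make_traj(n_steps=3, reason=TRAPPED_T1, manifold="triplet",
                         label="T1", mult=1, rank=0),
               make_traj(n_steps=11, reason=TIMEOUT)]
        pops = adiabatic_populations(ens)
        late = pops.iloc[-1]
        assert np.isclose(late["S0"], 1 / 3)
        assert np.isclose(late["T1"], 1 / 3)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            adiabatic_populations([])


class TestInternalCoordinates:
    def test_static_trajectory_reports_reference_values(self):
        tr = make_traj(n_steps=4, coords_end=(1.37, 1.64, 0.0, 1.01))
        frame = internal_coordinates(tr, ["r_CO", "r_CS", "theta_tilt"])
        assert np.allclose(frame["r_CO"], 1.37)
        assert np.allclose(frame["r_CS"], 1.64)
        assert np.allclose(frame["theta_tilt"], 0.0)

    def test_tilt_angle_reported_as_absolute_value(self):
        tr = make_traj(n_steps=4)
        tr.coords[:, 2] = [-30.0, 15.0, -10.0, 5.0]
        mirrored = make_traj(n_steps=4)
        mirrored.coords[:, 2] = [30.0, -15.0, 10.0, -5.0]
        a = internal_coordinates(tr, ["theta_tilt"])
        b = internal_coordinates(mirrored, ["theta_tilt"])
        assert np.array_equal(a["theta_tilt"], b["theta_tilt"])
        assert np.all(a["theta_tilt"] >= 0)

    def test_unknown_coordinate_lists_available_names(self):
        with pytest.raises(KeyError, match="r_CS"):
            internal_coordinates(make_traj(), ["nope"])

    def test_dissociating_bond_monotone_after_last_turning_point(self, model):
        """A ring-opening trajectory's C–O distance increases monotonically
        once the C–O momentum stays positive (checked against the stored
        momenta, an independent record of the motion)."""
        from todyn.fssh import DynamicsConfig, run_ensemble
        from todyn.wigner import normal_modes, sample_wigner, select_excitation_window
        modes = normal_modes(model)
        ens = sample_wigner(modes, 120, seed=31)
        ics, _ = select_excitation_window(ens, model, (4.5, 4.7), seed=32)
        trajs = run_ensemble(model, ics[:40], DynamicsConfig(seed=33))
        opened = [t for t in trajs if t.outcome is not None and not t.failed
                  and t.coords[-1, 0] > 1.8]
        assert opened, "expected at least one ring-opening trajectory"
        tr = opened[0]
        p_co = tr.momenta[:, 0]
        neg = np.where(p_co < 0)[0]
        last_turn = neg[-1] + 1 if len(neg) else 0
        r = internal_coordinates(tr, ["r_CO"])["r_CO"].to_numpy()
        assert np.all(np.diff(r[last_turn:]) > -1e-12)


class TestClassification:
    def test_ring_opening_precedence(self):
        tr = make_traj(coords_end=(1.85, 1.7, 5.0, 1.9))   # both bonds long
        assert classify_channel(tr) == ("ring-opening-CO", "singlet")

    def test_nh_fission(self):
        tr = make_traj(coords_end=(1.5, 1.7, 5.0, 1.95))
        assert classify_channel(tr) == ("NH-fission", "singlet")

    def test_gap_closure_with_intact_bonds_is_photostabilising(self):
        tr = make_traj(coords_end=(1.40, 1.80, 30.0, 1.02),
                       reason=TRAPPED_T1, manifold="triplet", label="T1",
                       mult=1, rank=0)
        assert classify_channel(tr) == ("photostabilising", "triplet")

    def test_timeout_without_thresholds_is_other(self):
        tr = make_traj(coords_end=(1.45, 1.75, 20.0, 1.05), reason=TIMEOUT)
        assert classify_channel(tr) == ("other", "singlet")

    def test_failed_trajectories_never_classified(self):
        tr = make_traj()
        tr.outcome = TerminationOutcome(FAILED, 1.0, "unknown", "none")
        with pytest.raises(ValueError):
            classify_channel(tr)

    def test_custom_threshold_respected(self):
        tr = make_traj(coords_end=(1.75, 1.7, 5.0, 1.0))
        assert classify_channel(tr)[0] == "photostabilising"
        assert classify_channel(tr, thresholds={"r_CO": 1.7})[0] == "ring-opening-CO"


class TestSummaries:
    def test_degenerate_ensemble_fraction_is_one(self):
        ens = [make_traj(coords_end=(2.0, 1.7, 5.0, 1.0)) for _ in range(5)]
        s = summarize_ensemble(ens)
        assert s.fractions["ring-opening-CO"] == 1
        assert s.percent["ring-opening-CO"] == 100

    def test_fractions_sum_to_one(self):
        ens = ([make_traj(coords_end=(2.0, 1.7, 5, 1.0)) for _ in range(3)]
               + [make_traj(coords_end=(1.4, 1.8, 25, 1.0)) for _ in range(4)]
               + [make_traj(coords_end=(1.4, 1.7, 5, 2.1)) for _ in range(2)])
        s = summarize_ensemble(ens)
        assert sum(s.fractions.values()) == 1

    def test_order_and_shard_invariance(self):
        ens = ([make_traj(coords_end=(2.0, 1.7, 5, 1.0)) for _ in range(3)]
               + [make_traj(coords_end=(1.4, 1.8, 25, 1.0)) for _ in range(4)])
        a = summarize_ensemble(ens)
        b = summarize_ensemble(ens[::-1])
        assert a.counts == b.counts
        sh1 = summarize_ensemble(ens[:3] + ens[3:])
        assert sh1.counts == a.counts

    def test_independent_recount_matches(self, model):
        """Channel fractions recomputed by a direct tally over the raw
        trajectory records agree exactly with the summary."""
        from todyn.fssh import DynamicsConfig, run_ensemble
        from todyn.wigner import normal_modes, sample_wigner, select_excitation_window
        modes = normal_modes(model)
        ens = sample_wigner(modes, 80, seed=41)
        ics, _ = select_excitation_window(ens, model, (4.5, 4.7), seed=42)
        trajs = run_ensemble(model, ics[:20], DynamicsConfig(max_time_fs=400.0,
                                                             seed=43))
        s = summarize_ensemble(trajs)
        # independent tally straight off the raw records
        tally = {"ring-opening-CO": 0, "NH-fission": 0, "photostabilising": 0,
                 "CO5-opening": 0, "other": 0}
        for t in trajs:
            if t.failed:
                continue
            if t.coords[-1, 0] > 1.8:
                tally["ring-opening-CO"] += 1
            elif t.coords[-1, 3] > 1.8:
                tally["NH-fission"] += 1
            elif t.outcome.reason in (IC_TO_S0, TRAPPED_T1):
                tally["photostabilising"] += 1
            else:
                tally["other"] += 1
        assert tally == s.counts

    def test_all_excluded_rejected(self):
        tr = make_traj()
        tr.outcome = TerminationOutcome(FAILED, 1.0, "unknown", "none")
        with pytest.raises(ValueError):
            summarize_ensemble([tr])

    def test_summary_reports_exact_rationals_and_rounding(self):
        ens = ([make_traj(coords_end=(2.0, 1.7, 5, 1.0)) for _ in range(120)]
               + [make_traj(coords_end=(1.4, 1.8, 25, 1.0)) for _ in range(16)]
               + [make_traj(coords_end=(1.4, 1.7, 5, 2.1)) for _ in range(5)])
        s = summarize_ensemble(ens, initial_counts={"S2": 120, "S3": 16, "S1": 5})
        assert s.initial_state_percent == {"S2": 85, "S3": 11, "S1": 4}
        from fractions import Fraction
        assert s.fractions["ring-opening-CO"] == Fraction(120, 141)
        assert s.percent["ring-opening-CO"] == 85
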
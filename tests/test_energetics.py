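"""Body model, positive-increment work, and cost of transport."""
import numpy as np
import pytest
from scipy.stats import spearmanr

from gapcross.anthro import ENERGY_POOLS, default_table
from gapcross.energetics import (
    com_trajectory,
    cost_of_transport,
    internal_work,
    positive_increment_work,
    traversal_energetics,
    work_breakdown,
)
from gapcross.kinematics import (
    detect_stance_phases,
    identify_traversal,
    lowpass_filter,
    segment_steps,
)
from gapcross.types import GRAVITY, MARKER_LABELS, MarkerTrajectorySet, WorkBreakdown

from conftest import PARTICIPANT, clean_trial


# ---------------------------------------------------------------------------
# positive_increment_work
# ---------------------------------------------------------------------------
class TestPositiveIncrementWork:
    def test_monotone_rise_telescopes(self):
        e = np.linspace(0.0, 343.35, 500)
        assert positive_increment_work(e) == pytest.approx(343.35)

    def test_constant_energy_zero_work(self):
        assert positive_increment_work(np.full(200, 7.5)) == 0.0

    def test_sinusoid_matches_dense_grid_oracle(self):
        # 70 kg point mass, 0.02 m vertical oscillation, one 1 Hz cycle
        m, amp, f = 70.0, 0.02, 1.0

        def energy(t):
            z = amp * np.sin(2 * np.pi * f * t)
            v = 2 * np.pi * f * amp * np.cos(2 * np.pi * f * t)
            return m * GRAVITY * z + 0.5 * m * v**2

        coarse = positive_increment_work(energy(np.arange(121) / 120.0))
        oracle = positive_increment_work(energy(np.linspace(0, 1, 120001)))
        assert coarse == pytest.approx(oracle, rel=0.005)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(3)
        e = np.cumsum(rng.normal(size=400))
        whole = positive_increment_work(e, (0, 399))
        parts = sum(
            positive_increment_work(e, w) for w in [(0, 120), (120, 277), (277, 399)]
        )
        assert whole == pytest.approx(parts, abs=1e-12)

    def test_datum_invariance(self):
        rng = np.random.default_rng(4)
        e = np.cumsum(rng.normal(size=300))
        assert positive_increment_work(e) == pytest.approx(
            positive_increment_work(e + 123.4), abs=1e-9
        )

    def test_empty_window_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert positive_increment_work(np.arange(10.0), (5, 5)) == 0.0

    def test_antiphase_exchange_cancels_when_pooled(self):
        t = np.linspace(0, 1, 200)
        e1 = np.sin(2 * np.pi * t)
        e2 = -e1
        assert positive_increment_work(e1 + e2) == 0.0
        assert positive_increment_work(e1) > 0
        assert positive_increment_work(e2) > 0


# ---------------------------------------------------------------------------
# body model
# ---------------------------------------------------------------------------
def _static_pose(n):
    """A plausible static posture, one frame repeated n times."""
    leg = PARTICIPANT.leg_length
    base = {
        "ANK": (0.0, 0.10, 0.07),
        "MT5": (0.15, 0.10, 0.03),
        "KNEE": (0.03, 0.10, 0.48),
        "HIP": (0.0, 0.10, leg),
        "SHO": (0.01, 0.18, leg + 0.49),
        "ELB": (0.01, 0.21, leg + 0.16),
        "WRI": (0.01, 0.21, leg - 0.10),
    }
    markers = {}
    for side, sign in (("L", 1.0), ("R", -1.0)):
        for name, (x, y, z) in base.items():
            markers[f"{side}_{name}"] = np.tile([x, sign * y, z], (n, 1))
    return markers


def _rigid_translate(markers, disp):
    """Translate every marker by the per-frame displacement array (n, 3)."""
    return {k: v + disp for k, v in markers.items()}


class TestBodyModel:
    def test_all_markers_coincident_com_at_point(self):
        p = np.array([0.3, -0.2, 1.1])
        markers = {lb: np.tile(p, (50, 1)) for lb in MARKER_LABELS}
        mset = MarkerTrajectorySet(120.0, markers, PARTICIPANT)
        model = com_trajectory(mset)
        np.testing.assert_allclose(model.com, np.tile(p, (50, 1)), atol=1e-12)

    def test_rigid_translation_zero_internal_work(self):
        n = 240
        t = np.arange(n) / 120.0
        disp = np.column_stack([1.2 * t, np.zeros(n), 0.1 * np.sin(2 * np.pi * t)])
        mset = MarkerTrajectorySet(
            120.0, _rigid_translate(_static_pose(n), disp), PARTICIPANT
        )
        assert internal_work(com_trajectory(mset)) == pytest.approx(0.0, abs=1e-9)

    def test_single_oscillating_forearm_drives_arm_pool(self):
        n = 480
        t = np.arange(n) / 120.0
        markers = _static_pose(n)
        markers["L_WRI"] = markers["L_WRI"] + np.column_stack(
            [0.15 * np.sin(2 * np.pi * t), np.zeros(n), np.zeros(n)]
        )
        model = com_trajectory(MarkerTrajectorySet(120.0, markers, PARTICIPANT))
        pools = model.pool_energies()
        works = {k: positive_increment_work(e) for k, e in pools.items()}
        total = internal_work(model)
        assert total == pytest.approx(sum(works.values()), abs=1e-9)
        # the moving forearm shifts the whole-body CoM, so the other pools
        # pick up a little recoil motion in the CoM-relative frame; the
        # active arm still carries nearly all the internal work
        assert works["left_arm"] > 0.95 * total
        assert works["left_arm"] == max(works.values())

    def test_quasistatic_lift_approaches_mgh(self):
        n = 1201  # 10 s lift
        u = np.arange(n) / (n - 1)
        h = 0.3
        rise = h * u * u * (3 - 2 * u)
        disp = np.column_stack([np.zeros(n), np.zeros(n), rise])
        model = com_trajectory(
            MarkerTrajectorySet(120.0, _rigid_translate(_static_pose(n), disp), PARTICIPANT)
        )
        wb = work_breakdown(model, (0, n - 1), distance=1.0)
        assert wb.w_com == pytest.approx(PARTICIPANT.mass * GRAVITY * h, rel=0.01)

    def test_pools_partition_the_limbs(self):
        pools = dict(ENERGY_POOLS)
        assert set(pools) == {"trunk", "left_arm", "right_arm", "left_leg", "right_leg"}
        segs = [s for members in pools.values() for s in members]
        assert len(segs) == len(set(segs)) == 11

    def test_missing_marker_error_names_marker(self):
        markers = _static_pose(30)
        markers["R_KNEE"][10] = np.nan
        with pytest.raises(ValueError, match="R_KNEE"):
            com_trajectory(MarkerTrajectorySet(120.0, markers, PARTICIPANT))

    def test_rotational_energy_optional_and_nonnegative(self):
        n = 480
        t = np.arange(n) / 120.0
        markers = _static_pose(n)
        markers["L_WRI"] = markers["L_WRI"] + np.column_stack(
            [0.15 * np.sin(2 * np.pi * t), np.zeros(n), np.zeros(n)]
        )
        mset = MarkerTrajectorySet(120.0, markers, PARTICIPANT)
        w_off = internal_work(com_trajectory(mset, default_table(False)))
        w_on = internal_work(com_trajectory(mset, default_table(True)))
        assert w_on >= w_off


# ---------------------------------------------------------------------------
# cost of transport
# ---------------------------------------------------------------------------
class TestCostOfTransport:
    def test_worked_arithmetic(self):
        wb = WorkBreakdown(w_com=100.0, w_int=40.0, distance=1.0)
        cot_tot, cot_com = cost_of_transport(wb, mass=70.0)
        assert cot_tot == pytest.approx(2.0)
        assert cot_com == pytest.approx(100.0 / 70.0)

    def test_zero_work_zero_cost(self):
        cot_tot, cot_com = cost_of_transport(
            WorkBreakdown(0.0, 0.0, distance=2.0), mass=70.0
        )
        assert cot_tot == 0.0 and cot_com == 0.0

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            cost_of_transport(WorkBreakdown(1.0, 1.0, 0.0), mass=70.0)


def _traversal_cost(kw):
    spec, mset = clean_trial(**kw)
    ev_l = detect_stance_phases(mset, "left")
    ev_r = detect_stance_phases(mset, "right")
    steps = segment_steps(ev_l, ev_r, mset)
    trav = identify_traversal(
        steps, spec.obstacle, mset.meta["truth"].obstacle_span, spec.strategy
    )
    return traversal_energetics(mset, trav)


class TestTraversalEnergetics:
    def test_work_identity_and_fractions(self):
        cost = _traversal_cost(dict(strategy="IN", depth=0.3, length=0.8))
        assert cost.work.w_tot == pytest.approx(
            sum(s.work.w_tot for s in cost.steps), abs=1e-9
        )
        assert cost.step_fractions_tot.sum() == pytest.approx(1.0, abs=1e-6)
        assert cost.cot_tot >= cost.cot_com
        for s in cost.steps:
            assert s.cot_tot >= s.cot_com >= 0.0

    def test_step_up_dominates_deep_in_traversal(self):
        cost = _traversal_cost(dict(strategy="IN", depth=0.5, length=0.8))
        # the final traversal step is the step back up onto the trackway
        assert int(np.argmax(cost.step_fractions_tot)) == len(cost.steps) - 1

    def test_in_cost_increases_with_depth(self):
        cots = [
            _traversal_cost(dict(strategy="IN", depth=d, length=0.8)).cot_tot
            for d in (0.1, 0.2, 0.3, 0.4, 0.5)
        ]
        assert all(b >= a for a, b in zip(cots, cots[1:]))

    def test_over_cost_increases_with_length_not_depth(self):
        cots = [
            _traversal_cost(dict(strategy="OVER", depth=0.3, length=ln)).cot_tot
            for ln in (0.5, 0.65, 0.8, 0.95, 1.1)
        ]
        assert all(b >= a for a, b in zip(cots, cots[1:]))
        shallow = _traversal_cost(dict(strategy="OVER", depth=0.1, length=0.8)).cot_tot
        deep = _traversal_cost(dict(strategy="OVER", depth=0.5, length=0.8)).cot_tot
        assert shallow == pytest.approx(deep, rel=1e-6)

    def test_measured_surfaces_intersect_within_grid(self):
        over_short = _traversal_cost(dict(strategy="OVER", depth=0.5, length=0.5)).cot_tot
        in_short = _traversal_cost(dict(strategy="IN", depth=0.5, length=0.5)).cot_tot
        over_long = _traversal_cost(dict(strategy="OVER", depth=0.1, length=1.1)).cot_tot
        in_long = _traversal_cost(dict(strategy="IN", depth=0.1, length=1.1)).cot_tot
        assert over_short < in_short  # short & deep: crossing is cheaper
        assert in_long < over_long    # long & shallow: going through is cheaper


class TestComRoundTrip:
    def test_com_height_matches_designed_profile(self, in_trial):
        _, mset = in_trial
        truth = mset.meta["truth"]
        filtered = lowpass_filter(mset)
        com_z = com_trajectory(filtered).com[:, 2]
        # away from filter edge effects
        sl = slice(30, len(com_z) - 30)
        assert np.max(np.abs(com_z[sl] - truth.com_z[sl])) < 0.005

    def test_cot_com_tracks_cot_tot_across_conditions(self):
        tots, coms = [], []
        for kw in [
            dict(strategy="IN", depth=0.1, length=0.8),
            dict(strategy="IN", depth=0.3, length=0.8),
            dict(strategy="IN", depth=0.5, length=0.8),
            dict(strategy="OVER", depth=0.3, length=0.5),
            dict(strategy="OVER", depth=0.3, length=0.8),
            dict(strategy="OVER", depth=0.3, length=1.1),
            dict(strategy="IN", depth=0.4, length=0.95, steps_in_base=2),
            dict(strategy="OVER", depth=0.2, length=0.95),
        ]:
            cost = _traversal_cost(kw)
            tots.append(cost.cot_tot)
            coms.append(cost.cot_com)
        rho = spearmanr(tots, coms).statistic
        assert rho > 0.9
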
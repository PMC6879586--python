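import numpy as np
import pytest

from poreflux import permeation, synthgen
from poreflux.errors import AnnotationError, GeometryError
from poreflux.permeation import (
    PermeationEvent,
    cavity_census,
    compute_current,
    compute_voltage,
    count_crossings,
    count_events_z,
)
from poreflux.units import ELEMENTARY_CHARGE_PA_NS

from _oracles import crossing_oracle, events_to_set
from conftest import make_filter_frame


class TestComputeVoltage:
    def test_working_voltage(self):
        assert compute_voltage(30.0, 10.0) == pytest.approx(300.0)

    def test_zero_field(self):
        assert compute_voltage(0.0, 10.0) == 0.0

    def test_reduced_voltage(self):
        assert compute_voltage(15.0, 10.0) == pytest.approx(150.0)

    def test_nonpositive_box(self):
        with pytest.raises(ValueError):
            compute_voltage(30.0, 0.0)

    def test_bilinearity(self, rng):
        e, lz = rng.uniform(1, 50), rng.uniform(1, 20)
        assert compute_voltage(2 * e, lz) == pytest.approx(2 * compute_voltage(e, lz))
        assert compute_voltage(e, 3 * lz) == pytest.approx(3 * compute_voltage(e, lz))


class TestCountEventsZ:
    def test_hand_traced_outward_event(self):
        z = np.array([-1.0, -0.2, 0.7, 1.6, 2.0])[:, None]
        pid, direction, entry, done = count_events_z(
            z, 0.0, 1.5, 100.0, delta=0.1, radial_check=False
        )
        assert len(pid) == 1
        assert direction[0] == +1
        assert done[0] == 4
        assert entry[0] == 1  # last frame seen on the cavity side

    def test_excursion_and_return_no_event(self):
        z = np.array([-1.0, 0.5, 1.0, 0.3, -1.0])[:, None]
        pid, *_ = count_events_z(z, 0.0, 1.5, 100.0, delta=0.1, radial_check=False)
        assert len(pid) == 0

    def test_inverted_bounds_raise(self):
        z = np.zeros((3, 1))
        with pytest.raises(GeometryError):
            count_events_z(z, 1.5, 0.0, 100.0, radial_check=False)

    def test_periodic_wrap_is_not_a_crossing(self):
        # jump of 5 with box 6 is a wrap; no event despite the side change
        z = np.array([2.5, 2.6, -2.5, -2.5])[:, None]
        pid, *_ = count_events_z(z, 0.0, 1.5, 6.0, delta=0.1, radial_check=False)
        assert len(pid) == 0

    def test_direct_jump_without_inside_frame_counts(self):
        z = np.array([-1.0, 2.0])[:, None]
        rd = np.full((2, 1), 5.0)  # far off-axis, but never seen between bounds
        pid, direction, *_ = count_events_z(
            z, 0.0, 1.5, 100.0, delta=0.1, rdist=rd, r_cut=0.6, radial_check=True
        )
        assert len(pid) == 1 and direction[0] == 1

    def test_radial_check_rejects_off_axis_transit(self):
        z = np.array([-1.0, 0.7, 2.0])[:, None]
        rd = np.array([[0.0], [2.0], [0.0]])  # between bounds but 2 nm off axis
        pid, *_ = count_events_z(
            z, 0.0, 1.5, 100.0, delta=0.1, rdist=rd, r_cut=0.6, radial_check=True
        )
        assert len(pid) == 0
        pid, *_ = count_events_z(z, 0.0, 1.5, 100.0, delta=0.1, radial_check=False)
        assert len(pid) == 1

    @pytest.mark.parametrize("radial", [False, True])
    def test_random_walks_match_oracle(self, radial, rng):
        for _ in range(3):
            z = np.cumsum(rng.normal(0, 0.35, size=(2000, 200)), axis=0) - 1.0
            rd = np.abs(rng.normal(0, 0.5, size=z.shape))
            got = count_events_z(
                z, 0.0, 1.5, 100.0, delta=0.1, rdist=rd, r_cut=0.6, radial_check=radial
            )
            want = crossing_oracle(
                z, 0.0, 1.5, 100.0, delta=0.1, rdist=rd, r_cut=0.6, radial_check=radial
            )
            assert events_to_set(zip(*got)) == events_to_set(want)

    def test_time_reversal_antisymmetry(self, rng):
        z = np.cumsum(rng.normal(0, 0.4, size=(1500, 100)), axis=0)
        fwd = count_events_z(z, 0.0, 1.5, 100.0, radial_check=False)
        rev = count_events_z(z[::-1], 0.0, 1.5, 100.0, radial_check=False)
        n_out_f = int(np.sum(fwd[1] == 1))
        n_in_f = int(np.sum(fwd[1] == -1))
        n_out_r = int(np.sum(rev[1] == 1))
        n_in_r = int(np.sum(rev[1] == -1))
        assert (n_out_f, n_in_f) == (n_in_r, n_out_r)
        assert n_out_f + n_in_f > 0  # non-trivial instance

    def test_conservation_of_compartment_label(self, rng):
        z = np.cumsum(rng.normal(0, 0.4, size=(1000, 150)), axis=0)
        pid, direction, *_ = count_events_z(z, 0.0, 1.5, 100.0, delta=0.1, radial_check=False)

        def label(v):  # latched side over the series
            lab = 0
            for x in v:
                if x < -0.1:
                    lab = -1
                elif x > 1.6:
                    lab = 1
            return lab

        def first_label(v):
            for x in v:
                if x < -0.1:
                    return -1
                if x > 1.6:
                    return 1
            return 0

        for p in range(z.shape[1]):
            net = int(np.sum(direction[pid == p]))
            start, end = first_label(z[:, p]), label(z[:, p])
            if start != 0:
                assert 2 * net == end - start


class TestComputeCurrent:
    def test_single_crossing_unit_time(self):
        ev = [PermeationEvent(0, "ion", +1, 0, 1)]
        est = compute_current(ev, 1.0)
        assert est.current == pytest.approx(160.218, abs=1e-3)
        assert est.current == pytest.approx(ELEMENTARY_CHARGE_PA_NS)

    def test_no_events_zero_current(self):
        est = compute_current([], 10.0)
        assert est.current == 0.0

    def test_paper_scale_53_in_500ns(self):
        ev = [PermeationEvent(i, "ion", +1, 0, 1) for i in range(53)]
        est = compute_current(ev, 500.0)
        assert est.current == pytest.approx(16.983, abs=1e-3)

    def test_net_counting(self):
        ev = [
            PermeationEvent(0, "ion", +1, 0, 1),
            PermeationEvent(1, "ion", +1, 0, 2),
            PermeationEvent(2, "ion", -1, 0, 3),
        ]
        est = compute_current(ev, 1.0)
        assert est.n_out == 2 and est.n_in == 1
        assert est.current == pytest.approx(ELEMENTARY_CHARGE_PA_NS)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            compute_current([], 0.0)

    def test_ci_brackets_estimate_equal_times(self):
        rng = np.random.default_rng(0)
        ev = []
        times = {}
        for r in range(6):
            times[r] = 100.0
            for i in range(int(rng.integers(3, 12))):
                ev.append(PermeationEvent(i, "ion", +1, 0, 1, replica=r))
        est = compute_current(ev, times, n_boot=2000, seed=1)
        assert est.ci_low <= est.current <= est.ci_high


class TestEndToEndCounting:
    def test_pipeline_matches_ground_truth_log(self, small_system):
        ens, ann, log = small_system
        for r, rep in enumerate(ens.replicas):
            events = count_crossings(rep, ann, replica_id=r)
            assert sum(e.direction for e in events) == log.net_crossings[r]

    def test_event_fields(self, small_system):
        ens, ann, _ = small_system
        events = count_crossings(ens.replicas[0], ann, replica_id=3)
        for e in events:
            assert e.species == "ion"
            assert e.replica == 3
            assert e.completion_frame >= e.entry_frame

    def test_explicit_bounds(self, small_system):
        ens, ann, log = small_system
        events = count_crossings(ens.replicas[0], ann, sf_bounds=(0.0, 1.5))
        assert sum(e.direction for e in events) == log.net_crossings[0]

    def test_bad_bounds(self, small_system):
        ens, ann, _ = small_system
        with pytest.raises(GeometryError):
            count_crossings(ens.replicas[0], ann, sf_bounds=(1.5, 0.0))

    def test_current_calibration_smoke(self):
        # planted 0.1 net crossings/ns; full 100-seed version in acceptance
        spec = synthgen.SynthSpec(
            net_rate=0.1, n_frames=1000, n_replicas=5, seed=77,
            n_cavity_waters=0, n_site_waters=0,
        )
        ens, ann, log = synthgen.generate_ensemble(spec)
        ev, times = [], {}
        for r, rep in enumerate(ens.replicas):
            ev.extend(count_crossings(rep, ann, replica_id=r))
            times[r] = rep.duration
        est = compute_current(ev, times, n_boot=2000, seed=0)
        assert est.current == pytest.approx(0.1 * ELEMENTARY_CHARGE_PA_NS, rel=0.35)


class TestCavityCensus:
    def _with_gate(self, ion_positions, water_positions):
        frame, ann = make_filter_frame(
            ion_positions=ion_positions, water_positions=water_positions
        )
        # append 4 gate atoms whose COM is the origin shifted down
        gate_pts = np.array(
            [[0.5, 0.5, -1.4], [-0.5, 0.5, -1.4], [-0.5, -0.5, -1.4], [0.5, -0.5, -1.4]]
        )
        n0 = frame.shape[0]
        frame = np.vstack([frame, gate_pts])
        ann.gate = {"A88": tuple(range(n0, n0 + 4))}
        return frame, ann

    def test_no_waters(self):
        frame, ann = self._with_gate(ion_positions=[(0, 0, -1.2)], water_positions=[])
        assert cavity_census(frame, ann, radius=1.0) == (0, 1)

    def test_constructed_distances(self):
        waters = [(0.5, 0, -1.4), (0, 0.5, -1.4), (0, 0, -0.9), (1.5, 0, -1.4), (0, 0, 0.5)]
        frame, ann = self._with_gate(ion_positions=[], water_positions=waters)
        n_w, n_i = cavity_census(frame, ann, radius=1.0)
        assert n_w == 3 and n_i == 0

    def test_brute_force_random(self, rng):
        waters = rng.uniform(-2, 2, (50, 3))
        ions = rng.uniform(-2, 2, (10, 3))
        frame, ann = self._with_gate(ion_positions=ions, water_positions=waters)
        com = frame[list(ann.gate["A88"])].mean(axis=0)
        want_w = sum(np.linalg.norm(w - com) < 1.0 for w in waters)
        want_i = sum(np.linalg.norm(i - com) < 1.0 for i in ions)
        assert cavity_census(frame, ann, radius=1.0) == (want_w, want_i)

    def test_missing_role(self):
        frame, ann = make_filter_frame(ion_positions=[(0, 0, 0)])
        with pytest.raises(AnnotationError):
            cavity_census(frame, ann)

    def test_bad_radius(self):
        frame, ann = self._with_gate([], [])
        with pytest.raises(ValueError):
            cavity_census(frame, ann, radius=0.0)

    def test_generator_cavity_water_count(self, small_system):
        ens, ann, log = small_system
        n_w, _ = cavity_census(ens.replicas[0].coords[0], ann, radius=1.0)
        assert n_w == log.n_cavity_waters
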
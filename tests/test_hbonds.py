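"""H-bond detection (vs brute force), kinetics, Eyring free energy, RDF/CN
and water-orientation classification."""

import numpy as np
import pytest
from scipy import constants as const

from ringff.hbonds import (HBondCriteria, HBondTimeSeries, Water,
                           detect_hbonds, hbond_free_energy,
                           intervals_from_series, obd_and_cn, occupancy,
                           orientation, rdf, residence_time, site_report)
from ringff.io import REPORT_COLUMNS, TrajectoryFrame
from ringff.synth import (gen_hbond_markov, gen_hydration_shell,
                          gen_uniform_gas)


def _frame(coords, box=4.0):
    return TrajectoryFrame(time=0.0, coordinates=np.asarray(coords, float),
                           box=np.array([box] * 3))


class TestDetect:
    def test_ideal_geometry_is_one_bond(self):
        # donor O at origin, H on the O->N axis, acceptor N at 0.28 nm
        fr = _frame([[1.0, 1.0, 1.0], [1.1, 1.0, 1.0], [1.28, 1.0, 1.0]])
        s = detect_hbonds([fr, fr], donors=[1], hydrogens=[2], acceptors=[3])
        assert list(s.counts) == [1, 1]

    def test_cutoff_excludes_at_036(self):
        fr = _frame([[1.0, 1.0, 1.0], [1.1, 1.0, 1.0], [1.36, 1.0, 1.0]])
        s = detect_hbonds([fr, fr], donors=[1], hydrogens=[2], acceptors=[3])
        assert list(s.counts) == [0, 0]

    def test_angle_criterion_excludes_bent_hydrogen(self):
        # H at 45 degrees off the D->A axis
        fr = _frame([[1.0, 1.0, 1.0], [1.07, 1.07, 1.0], [1.30, 1.0, 1.0]])
        s = detect_hbonds([fr, fr], donors=[1], hydrogens=[2], acceptors=[3])
        assert list(s.counts) == [0, 0]

    def test_minimum_image_bond_across_boundary(self):
        # donor near one box face, acceptor wrapped across the boundary
        fr = _frame([[0.05, 1.0, 1.0], [1.95, 1.0, 1.0], [1.75, 1.0, 1.0]], box=2.0)
        s = detect_hbonds([fr, fr], donors=[1], hydrogens=[2], acceptors=[3])
        assert list(s.counts) == [1, 1]

    def test_hydrogen_without_parent_donor_rejected(self):
        fr = _frame([[0, 0, 0], [0.1, 0, 0]])
        with pytest.raises(ValueError, match="parent donor"):
            detect_hbonds([fr, fr], donors=[1], hydrogens=[2, 2], acceptors=[2])

    @staticmethod
    def _brute_force_count(frame, donor_pairs, acceptors, crit):
        n = 0
        box = frame.box
        for d, h in donor_pairs:
            for a in acceptors:
                if a in (d, h):
                    continue
                rd = frame.coordinates[d - 1]
                rh = frame.coordinates[h - 1]
                ra = frame.coordinates[a - 1]
                da = ra - rd
                da -= box * np.round(da / box)
                dh = rh - rd
                dh -= box * np.round(dh / box)
                dist = np.linalg.norm(da)
                cosv = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
                ang = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
                if dist <= crit.r_donor_acceptor_max and ang <= crit.angle_hda_max:
                    n += 1
        return n

    @pytest.mark.parametrize("seed", range(20))
    def test_vectorized_equals_brute_force_on_random_systems(self, seed):
        rng = np.random.default_rng(seed)
        n_waters = rng.integers(5, 20)
        box = 1.5
        frames = []
        for _ in range(5):
            coords = []
            for _ in range(n_waters):
                o = rng.uniform(0, box, 3)
                h1 = o + rng.normal(0, 0.06, 3)
                h2 = o + rng.normal(0, 0.06, 3)
                coords += [o, h1, h2]
            frames.append(_frame(coords, box=box))
        donors = [3 * i + 1 for i in range(n_waters) for _ in range(2)]
        hydrogens = [3 * i + 2 + k for i in range(n_waters) for k in range(2)]
        acceptors = [3 * i + 1 for i in range(n_waters)]
        crit = HBondCriteria()
        series = detect_hbonds(frames, donors, hydrogens, acceptors, crit)
        expected = [self._brute_force_count(fr, list(zip(donors, hydrogens)),
                                            acceptors, crit) for fr in frames]
        assert list(series.counts) == expected


class TestOccupancy:
    def test_constant_bonding(self):
        s = HBondTimeSeries("x", "both", np.array([1, 1, 1, 1]), 2.0)
        occ = occupancy(s)
        assert occ.aver == pytest.approx(1.0)
        assert occ.percent == pytest.approx(100.0)

    def test_alternating_counts(self):
        s = HBondTimeSeries("x", "both", np.array([0, 2, 0, 2]), 2.0)
        occ = occupancy(s)
        assert occ.aver == pytest.approx(1.0)
        assert occ.percent == pytest.approx(50.0)

    def test_markov_occupancy_matches_theory_within_3_se(self):
        fx = gen_hbond_markov(tau_bound=2.0, tau_free=2.0, dt=0.5,
                              duration_ns=50.0, seed=1)
        occ = occupancy(fx.series)
        p = fx.occupancy
        n_eff = 50_000.0 / (fx.tau_bound + fx.tau_free)  # ~independent cycles
        se = 100.0 * np.sqrt(p * (1 - p) / n_eff)
        assert abs(occ.percent - 100.0 * p) < 3 * se


class TestResidenceTime:
    def test_exponential_interval_recovery(self):
        rng = np.random.default_rng(7)
        iv = rng.exponential(2.11, size=10_000)
        res = residence_time(iv)
        assert res.flag == "ok"
        assert res.tau == pytest.approx(2.11, rel=0.05)
        assert res.lifetime == pytest.approx(1.0 / res.tau, rel=1e-12)

    def test_single_frame_intervals_flag_short_lived(self):
        res = residence_time(np.full(50, 2.0), dt=2.0)
        assert res.flag == "short-lived"
        assert res.tau <= 2.0 + 1e-12

    def test_insufficient_sampling_flagged(self):
        res = residence_time(np.array([1.0, 2.0, 3.0]))
        assert res.flag == "insufficient"
        assert np.isnan(res.tau)

    def test_intervals_from_series_drops_censored_runs(self):
        s = HBondTimeSeries("x", "both", np.array([1, 1, 0, 1, 1, 1, 0, 1]), 2.0)
        iv = intervals_from_series(s)
        # leading [1,1] and trailing [1] runs are censored
        np.testing.assert_allclose(iv, [6.0])


class TestEyring:
    @pytest.mark.parametrize("tau, expected", [(2.11, 6.38), (9.49, 10.11)])
    def test_printed_pairs(self, tau, expected):
        assert hbond_free_energy(tau) == pytest.approx(expected, abs=0.005)

    def test_fixed_point_at_h_over_kt(self):
        tau0 = const.h / (const.k * 298.15) * 1e12  # ps
        assert hbond_free_energy(tau0) == pytest.approx(0.0, abs=1e-9)

    def test_rt_ln2_doubling_identity(self):
        rt_ln2 = const.R * 298.15 / 1000.0 * np.log(2.0)
        diff = hbond_free_energy(2.11) - hbond_free_energy(1.055)
        assert diff == pytest.approx(rt_ln2, abs=1e-12)

    def test_monotone_increasing(self):
        taus = np.geomspace(0.01, 100, 25)
        dgs = [hbond_free_energy(t) for t in taus]
        assert np.all(np.diff(dgs) > 0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            hbond_free_energy(0.0)


class TestRDF:
    def test_uniform_gas_is_flat(self):
        # 0.1 nm bins keep the worst (smallest-shell) bin above ~500 counts
        frames, ref, sel = gen_uniform_gas(n_waters=3000, n_frames=100, seed=5)
        curve = rdf(frames, ref, sel, bin_width=0.1)
        far = curve.g[curve.r > 0.3]
        assert np.abs(far - 1.0).max() < 0.05

    def test_single_fixed_water_occupies_one_bin(self):
        center = np.array([1.0, 1.0, 1.0])
        fr = _frame([center, center + [0.28, 0, 0]], box=2.0)
        curve = rdf([fr], 1, [2], bin_width=0.02)
        occupied = np.flatnonzero(curve.g > 0)
        assert len(occupied) == 1
        assert curve.r[occupied[0]] == pytest.approx(0.28, abs=0.02)

    def test_counting_conservation(self):
        frames, ref, sel = gen_uniform_gas(n_waters=500, n_frames=10, seed=6)
        curve = rdf(frames, ref, sel, bin_width=0.02)
        # rho * 4 pi r^2 g integrated to r_max counts the in-sphere population
        integrand = curve.number_density * 4 * np.pi * curve.r ** 2 * curve.g
        n_inside = np.trapezoid(integrand, curve.r)
        box = frames[0].box[0]
        expected = 500 * (4.0 / 3.0 * np.pi * (box / 2) ** 3) / box ** 3
        assert n_inside == pytest.approx(expected, rel=0.05)

    def test_bin_larger_than_quarter_box_rejected(self):
        frames, ref, sel = gen_uniform_gas(n_waters=10, n_frames=1, seed=0)
        with pytest.raises(ValueError, match="box/4"):
            rdf(frames, ref, sel, bin_width=2.0)


class TestShell:
    def test_gaussian_peak_on_flat_background(self):
        r = np.arange(0.01, 1.0, 0.01)
        g = 1.0 + 2.0 * np.exp(-((r - 0.18) / 0.02) ** 2)
        curve_cls = type("C", (), {})
        from ringff.hbonds import RDFCurve
        curve = RDFCurve(r=r, g=g, number_density=33.0)
        shell = obd_and_cn(curve)
        assert shell.qualified
        assert shell.obd == pytest.approx(0.18, abs=0.01)

    def test_flat_rdf_flags_no_shell(self):
        from ringff.hbonds import RDFCurve
        r = np.arange(0.01, 1.0, 0.01)
        curve = RDFCurve(r=r, g=np.ones_like(r), number_density=33.0)
        with pytest.warns(UserWarning, match="no structured"):
            shell = obd_and_cn(curve)
        assert not shell.qualified

    def test_cn_counts_constructed_shell(self):
        fx = gen_hydration_shell(n_waters=150, obd=0.28, n_shell=4,
                                 n_frames=30, orientation_mode="random", seed=2)
        wo = [w.O for w in fx.waters]
        curve = rdf(fx.frames, fx.ref_atom, wo, bin_width=0.02)
        shell = obd_and_cn(curve)
        assert shell.obd == pytest.approx(0.28, abs=0.03)
        assert shell.cn == pytest.approx(4.0, abs=0.5)


class TestOrientation:
    @pytest.mark.parametrize("mode, expected", [("inward", "H-oriented"),
                                                ("outward", "O-oriented"),
                                                ("random", "Undefined")])
    def test_constructed_shells(self, mode, expected):
        fx = gen_hydration_shell(n_waters=60, obd=0.25, n_shell=30,
                                 n_frames=10, orientation_mode=mode, seed=3)
        label, mean_cos = orientation(fx.frames, fx.ref_atom, fx.waters,
                                      shell_radius=0.35)
        assert label == expected
        if mode == "random":
            assert abs(mean_cos) < 0.25

    def test_empty_shell_rejected(self):
        fx = gen_hydration_shell(n_waters=20, obd=0.25, n_shell=0,
                                 n_frames=2, orientation_mode="random", seed=4)
        with pytest.raises(ValueError):
            orientation(fx.frames, fx.ref_atom, fx.waters, shell_radius=0.2)

    def test_non_water_records_rejected(self):
        fx = gen_hydration_shell(n_waters=10, n_shell=5, n_frames=2,
                                 orientation_mode="random", seed=5)
        with pytest.raises(TypeError):
            orientation(fx.frames, fx.ref_atom, [(2, 3, 4)], shell_radius=0.5)


class TestSiteReport:
    def _series_and_intervals(self):
        fx = gen_hbond_markov(tau_bound=3.0, tau_free=1.0, dt=0.5,
                              duration_ns=5.0, seed=6)
        return fx.series, fx.bound_intervals

    def _curves(self):
        fx = gen_hydration_shell(n_waters=100, obd=0.28, n_shell=4,
                                 n_frames=10, orientation_mode="random", seed=7)
        wo = [w.O for w in fx.waters]
        return rdf(fx.frames, fx.ref_atom, wo, bin_width=0.02)

    def test_row_columns_and_consistency(self):
        series, intervals = self._series_and_intervals()
        row = site_report("Toy", series, intervals, self._curves(), "Undefined")
        assert list(row) == REPORT_COLUMNS
        occ = occupancy(series)
        assert row["Percent"] == pytest.approx(round(occ.percent, 2))
        tau = float(row["tau_HB"].split(" ± ")[0])
        lt = float(row["lifetime_HB"].split(" ± ")[0])
        assert lt == pytest.approx(1.0 / tau, abs=0.01)

    def test_sparse_site_renders_dashes(self):
        counts = np.zeros(100, dtype=int)
        counts[50] = 1
        series = HBondTimeSeries("N1", "acceptor", counts, 2.0)
        row = site_report("Toy", series, intervals_from_series(series),
                          self._curves(), "Undefined")
        assert row["tau_HB"] == "–"
        assert row["dG_HB"] == "–"
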
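"""Shell construction, bond-length statistics and the acceptance filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from metalcg.cg_models import get_cg
from metalcg.ligand_detection import (
    BondLengthStats,
    InsufficientSampleError,
    UndefinedRateError,
    avg_normalized_deviation,
    bootstrap_canonical_fit,
    detect_modes,
    element_bond_stats,
    estimate_error_rate,
    fit_resolution_slope,
    initial_shell,
    ligand_accept,
    resolution_adjusted_sd,
    triangular_rule,
    updated_upper_cutoff,
)
from metalcg.structure_io import AtomRecord, MetalSite


def _atom(coords, element="O", rid="A.1", name="OD1"):
    return AtomRecord(
        element=element,
        coords=np.asarray(coords, dtype=float),
        residue_name="ASP",
        residue_id=rid,
        atom_name=name,
    )


def _site(atoms, metal="Zn"):
    return MetalSite(
        site_id="t.M.1",
        metal_element=metal,
        metal_coords=np.zeros(3),
        resolution=2.0,
        candidate_atoms=list(atoms),
    )


def _stats(mean=2.3, sd=0.15, mode=None, slope=0.0, r_avg=2.0, n=100):
    return BondLengthStats(
        metal="Zn", ligand_element="S", mean=mean, sd=sd,
        mode=mode if mode is not None else mean, modes=(mode or mean,),
        n=n, r_avg=r_avg, slope=slope,
    )


class TestInitialShell:
    def test_upper_cutoff_boundary(self):
        site = _site([_atom((3.30, 0, 0))])
        assert initial_shell(site, 1.3, 3.20) == []

    def test_lower_cutoff(self):
        site = _site([_atom((1.0, 0, 0))])
        assert initial_shell(site, 1.3, 3.20) == []

    def test_matches_bruteforce(self, fresh_rng):
        atoms = [_atom(fresh_rng.uniform(-4, 4, size=3), rid=f"A.{i}")
                 for i in range(50)]
        site = _site(atoms)
        got = initial_shell(site, 1.3, 3.2)
        expected = [a for a in atoms if 1.3 <= np.linalg.norm(a.coords) <= 3.2]
        assert got == expected


class TestTriangularRule:
    def test_single_candidate_kept(self):
        atoms = [_atom((2.0, 0, 0))]
        assert triangular_rule((0, 0, 0), atoms) == atoms

    def test_second_shell_carbon_removed(self):
        # O at 2.0 A with its carbon at 3.1 A, d(O,C)=1.4:
        # 3.1 >= 1.5*2.0 and 3.1 >= 1.5*1.4, so the carbon goes
        o = _atom((2.0, 0, 0), element="O")
        c = _atom((3.1, np.sqrt(1.4**2 - 1.1**2), 0), element="C", name="CG")
        assert np.linalg.norm(o.coords - c.coords) == pytest.approx(1.4, abs=1e-9)
        kept = triangular_rule((0, 0, 0), [o, c])
        assert kept == [o]

    def test_equidistant_pair_kept(self):
        a = _atom((2.1, 0, 0), rid="A.1")
        b = _atom((2.1 * np.cos(1.6), 2.1 * np.sin(1.6), 0), rid="A.2")
        assert len(triangular_rule((0, 0, 0), [a, b])) == 2


class TestBootstrapFit:
    def test_perfect_tet_plus_decoy(self):
        tet = get_cg("Tet")
        atoms = [
            _atom(2.3 * np.asarray(p), element="S", rid=f"A.{i+1}", name="SG")
            for i, p in enumerate(tet.ideal_positions)
        ]
        # decoy 60 degrees off one vertex
        v = np.asarray(tet.ideal_positions[0])
        w = np.cross(v, [0, 0, 1.0])
        w /= np.linalg.norm(w)
        decoy = _atom(2.3 * (v * np.cos(1.05) + w * np.sin(1.05)),
                      element="C", rid="D.1", name="CD")
        fit = bootstrap_canonical_fit(_site(atoms + [decoy]), atoms + [decoy])
        assert fit.cg_code == "Tet"
        assert set(fit.ligands) == set(atoms)
        assert fit.angle_variance == pytest.approx(0.0, abs=1e-12)

    def test_exact_oct_beats_subsets(self):
        atoms = [
            _atom(2.1 * np.asarray(p), rid=f"A.{i+1}")
            for i, p in enumerate(get_cg("Oct").ideal_positions)
        ]
        fit = bootstrap_canonical_fit(_site(atoms), atoms)
        assert fit.cg_code == "Oct"
        assert len(fit.ligands) == 6

    def test_matches_exhaustive_oracle(self, fresh_rng):
        # independent re-enumeration of all subsets x round-1 models
        from itertools import combinations

        from metalcg.cg_models import BOOTSTRAP_CODES, angles_from_positions
        from metalcg.structure_io import apply_site_filters

        pts = fresh_rng.normal(size=(6, 3))
        pts = 2.2 * pts / np.linalg.norm(pts, axis=1)[:, None]
        atoms = [_atom(p, rid=f"A.{i+1}") for i, p in enumerate(pts)]
        site = _site(atoms)
        fit = bootstrap_canonical_fit(site, atoms)

        best_var, best_code, best_set = None, None, None
        for code in BOOTSTRAP_CODES:
            model = get_cg(code)
            ideal = np.sort(model.ideal_angles)
            for subset in combinations(atoms, model.coordination_number):
                if not apply_site_filters(site, subset).passed:
                    continue
                obs = np.sort(
                    angles_from_positions([a.coords for a in subset], np.zeros(3)).values()
                )
                var = float(np.var(obs - ideal))
                if best_var is None or var < best_var - 1e-12:
                    best_var, best_code, best_set = var, code, set(subset)
        if fit is None:
            assert best_var is None
        else:
            assert fit.cg_code == best_code
            assert fit.angle_variance == pytest.approx(best_var)
            assert set(fit.ligands) == best_set

    def test_noisy_tet_recovery(self):
        from metalcg.synthetic_data import SyntheticSpec, make_site

        spec = SyntheticSpec(metal="Zn", cg_code="Tet", angle_noise_sd=3.0,
                             bond_noise_sd=0.05, seed=77)
        hits = 0
        for i in range(100):
            site, _ = make_site(spec, i)
            fit = bootstrap_canonical_fit(site, site.ligand_atoms)
            hits += fit is not None and fit.cg_code == "Tet"
        assert hits >= 95


class TestElementBondStats:
    def test_sampling_mean_recovered(self, fresh_rng):
        lengths = fresh_rng.normal(2.34, 0.15, size=1000)
        rows = [("Zn", "S", l, 2.0) for l in lengths]
        stats, whitelist = element_bond_stats(rows)
        st_ = stats[("Zn", "S")]
        assert st_.mean == pytest.approx(2.34, abs=0.02)
        assert st_.sd == pytest.approx(0.15, abs=0.02)
        assert whitelist["Zn"] == ("S",)

    def test_rare_element_dropped_from_whitelist(self, fresh_rng):
        rows = [("Zn", "S", 2.3 + 0.01 * (i % 7), 2.0) for i in range(97)]
        rows += [("Zn", "P", 2.3, 2.0)] * 3  # 3% occurrence
        _, whitelist = element_bond_stats(rows)
        assert "P" not in whitelist["Zn"]

    def test_carbon_never_whitelisted(self):
        rows = [("Zn", "C", 3.0 + 0.001 * i, 2.0) for i in range(50)]
        rows += [("Zn", "S", 2.3, 2.0)] * 50
        stats, whitelist = element_bond_stats(rows)
        assert whitelist["Zn"] == ("S",)
        assert ("Zn", "C") in stats  # retained for cutoff calibration

    def test_empty_input(self):
        stats, whitelist = element_bond_stats([])
        assert stats == {} and whitelist == {}


class TestUpdatedUpperCutoff:
    @pytest.mark.parametrize(
        "mean,sd,carbon,expected",
        [
            (2.341, 0.152, 3.071, 2.782),  # Zn worked example
            (2.481, 0.271, 3.432, 3.092),  # Ca
            (2.063, 0.134, 3.081, 2.639),  # Fe
            (2.697, 0.369, 3.568, 3.317),  # Na
        ],
    )
    def test_midpoint_formula(self, mean, sd, carbon, expected):
        assert updated_upper_cutoff(mean, sd, carbon) == pytest.approx(
            expected, abs=5e-4
        )

    def test_shipped_defaults_consistent(self, metal_params):
        for metal, p in metal_params.items():
            got = updated_upper_cutoff(p.abundant_mean, p.abundant_sd, p.carbon_mode)
            assert got == pytest.approx(p.updated_upper, abs=1e-3), metal

    def test_degenerate_stats_rejected(self):
        with pytest.raises(ValueError):
            updated_upper_cutoff(0.0, 0.0, 0.0)

    def test_missing_carbon_mode_falls_back(self):
        assert updated_upper_cutoff(2.3, 0.1, None, initial_upper=3.2) == 3.2


class TestResolutionAdjustment:
    def test_at_average_resolution_returns_sd_avg(self):
        st_ = _stats(sd=0.15, slope=0.1, r_avg=2.0)
        assert resolution_adjusted_sd(st_, 2.0) == pytest.approx(0.15)

    def test_zero_slope_constant(self):
        st_ = _stats(sd=0.15, slope=0.0, r_avg=2.0)
        assert resolution_adjusted_sd(st_, 3.5) == pytest.approx(0.15)

    def test_linear_arithmetic(self):
        st_ = _stats(sd=0.15, slope=0.1, r_avg=2.0)
        assert resolution_adjusted_sd(st_, 3.0) == pytest.approx(0.25)

    def test_floor_applies(self):
        st_ = _stats(sd=0.05, slope=0.1, r_avg=2.0)
        assert resolution_adjusted_sd(st_, 0.5) == pytest.approx(0.01)


class TestFitResolutionSlope:
    def test_recovers_known_slope(self, fresh_rng):
        true_slope = 0.08
        rows = []
        for el, offset in [("S", 0.10), ("O", 0.18)]:
            for r in np.linspace(1.0, 3.4, 10):
                sd = offset + true_slope * r + fresh_rng.normal(0, 0.005)
                rows.append(("Zn", el, float(r), float(sd), 100))
        assert fit_resolution_slope(rows) == pytest.approx(true_slope, abs=0.01)

    def test_flat_series_gives_zero(self):
        rows = [("Zn", "S", r, 0.15, 100) for r in (1.0, 2.0, 3.0)]
        assert fit_resolution_slope(rows) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_exact_line(self):
        rows = [("Zn", "S", 1.0, 0.10, 100), ("Zn", "S", 3.0, 0.30, 100)]
        assert fit_resolution_slope(rows) == pytest.approx(0.1)

    def test_filters_high_resolution_and_small_bins(self):
        rows = [
            ("Zn", "S", 1.0, 0.10, 100),
            ("Zn", "S", 3.0, 0.30, 100),
            ("Zn", "S", 3.8, 9.99, 100),  # beyond the 3.5 A cap
            ("Zn", "S", 2.0, 9.99, 10),  # too few points
        ]
        assert fit_resolution_slope(rows) == pytest.approx(0.1)

    def test_insufficient_bins_raise(self):
        with pytest.raises(InsufficientSampleError):
            fit_resolution_slope([("Zn", "S", 2.0, 0.15, 100)])


class TestLigandAccept:
    def test_at_mean_accepted(self):
        ok, _ = ligand_accept(2.3, _stats(mean=2.3, sd=0.15), sd_x=0.15)
        assert ok

    def test_beyond_z_rejected(self):
        ok, reason = ligand_accept(2.3 + 2.6 * 0.15, _stats(mean=2.3), sd_x=0.15)
        assert not ok and reason == "z"

    def test_unwhitelisted_element_rejected(self):
        ok, reason = ligand_accept(2.3, None, sd_x=0.15)
        assert not ok and reason == "element"

    def test_acceptance_fraction_matches_normal_model(self, fresh_rng):
        # closed form: 2*Phi(2.5)-1 ~ 0.9876, i.e. ~1.2% false negatives
        closed = 2 * sps.norm.cdf(2.5) - 1
        draws = fresh_rng.normal(2.3, 0.15, size=10**6)
        st_ = _stats(mean=2.3, sd=0.15)
        frac = np.mean(np.abs(draws - 2.3) <= 2.5 * 0.15)
        assert closed == pytest.approx(0.98758, abs=1e-4)
        assert frac == pytest.approx(closed, abs=1e-3)


class TestAvgNormalizedDeviation:
    def test_all_at_mode_zero(self):
        value, flagged = avg_normalized_deviation([2.3, 2.3], [2.3, 2.3], [0.1, 0.1])
        assert value == 0.0 and not flagged

    def test_one_sd_above_flagged(self):
        value, flagged = avg_normalized_deviation(
            [2.4, 2.4], [2.3, 2.3], [0.1, 0.1]
        )
        assert value == pytest.approx(1.0) and flagged

    def test_inflated_vs_normal_site(self):
        sds = [0.1] * 4
        modes = [2.3] * 4
        inflated = [2.3 + 1.5 * 0.1] * 4
        v_bad, f_bad = avg_normalized_deviation(inflated, modes, sds)
        v_ok, f_ok = avg_normalized_deviation(modes, modes, sds)
        assert f_bad and not f_ok
        assert v_bad == pytest.approx(1.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            avg_normalized_deviation([], [], [])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        shift=st.floats(min_value=-3, max_value=3),
        n=st.integers(min_value=1, max_value=6),
    )
    def test_translation_consistency(self, shift, n):
        # adding c*sd to every bond length increases the value by exactly c
        lengths = [2.2 + 0.05 * i for i in range(n)]
        modes = [2.25] * n
        sds = [0.1 + 0.02 * i for i in range(n)]
        base, _ = avg_normalized_deviation(lengths, modes, sds)
        shifted = [l + shift * s for l, s in zip(lengths, sds)]
        moved, _ = avg_normalized_deviation(shifted, modes, sds)
        assert moved - base == pytest.approx(shift, abs=1e-9)


class TestDetectModes:
    def test_unimodal_sample(self, fresh_rng):
        modes = detect_modes(fresh_rng.normal(2.0, 0.1, size=2000))
        assert len(modes) == 1
        assert modes[0] == pytest.approx(2.0, abs=0.02)

    def test_bimodal_sample(self, fresh_rng):
        x = np.concatenate(
            [fresh_rng.normal(2.1, 0.05, 1000), fresh_rng.normal(2.6, 0.05, 1000)]
        )
        modes = detect_modes(x)
        assert len(modes) == 2
        assert sorted(modes) == pytest.approx([2.1, 2.6], abs=0.03)

    def test_constant_sample(self):
        assert detect_modes([2.5] * 40) == (2.5,)

    def test_small_sample_raises(self):
        with pytest.raises(InsufficientSampleError):
            detect_modes([2.0] * 10)


class TestErrorRate:
    @pytest.mark.parametrize(
        "counts,max_valid,expected",
        [
            ({6: 5674, 7: 69, 8: 2}, 6, 0.002113),  # Mg
            ({6: 750, 7: 2}, 6, 0.000443),  # Zn
            ({4: 703, 5: 1557, 6: 1840, 7: 186, 8: 17}, 8, 0.0),  # Na
        ],
    )
    def test_published_count_tables(self, counts, max_valid, expected):
        assert estimate_error_rate(counts, max_valid) == pytest.approx(
            expected, abs=5e-7
        )

    def test_all_below_maximum_gives_zero(self):
        # nothing at or above the valid maximum: numerator 0, rate 0
        assert estimate_error_rate({4: 10, 5: 3}, 6) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_error_rate({6: -1}, 6)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        counts=st.dictionaries(
            st.integers(min_value=1, max_value=9),
            st.integers(min_value=0, max_value=50),
            min_size=1,
        ),
        max_valid=st.integers(min_value=1, max_value=9),
    )
    def test_matches_per_ligand_enumeration(self, counts, max_valid):
        # brute force: enumerate every ligand of every site individually
        excess = 0
        total = 0
        for n, c in counts.items():
            for _ in range(c):
                if n >= max_valid:
                    total += n
                    if n > max_valid:
                        excess += n - max_valid
        if excess == 0:
            assert estimate_error_rate(counts, max_valid) == 0.0
        elif total == 0:
            with pytest.raises(UndefinedRateError):
                estimate_error_rate(counts, max_valid)
        else:
            assert estimate_error_rate(counts, max_valid) == pytest.approx(
                excess / total
            )
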
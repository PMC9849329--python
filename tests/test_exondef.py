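"""Tests of the mechanistic exon-definition model."""

import dataclasses as dc

import numpy as np
import pytest
from scipy.linalg import expm

from cosplice.commitment import psi
from cosplice.exondef import (
    RON_MINIGENE,
    SPECIES,
    ExonDefinitionParams,
    GeneArchitecture,
    InhibitionProfile,
    asymmetry_index,
    compute_delay_schedule,
    effective_rates,
    inhibition_function,
    position_scan,
    rate_matrix,
    simulate_exon_definition,
)


class TestInhibitionFunction:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 1.0), (50.0, 0.5), (-50.0, 0.5), (100.0, 1.0 / 257.0)],
    )
    def test_hill_profile_values(self, x, expected):
        profile = InhibitionProfile(l_up=50.0, r_down=50.0, p=8.0)
        assert inhibition_function(x, profile) == pytest.approx(expected)

    def test_asymmetric_ranges_use_their_own_branch(self):
        profile = InhibitionProfile(l_up=20.0, r_down=80.0, p=4.0)
        assert inhibition_function(-20.0, profile) == pytest.approx(0.5)
        assert inhibition_function(80.0, profile) == pytest.approx(0.5)
        assert inhibition_function(-80.0, profile) < inhibition_function(80.0, profile)


class TestEffectiveRates:
    def test_distant_rbp_leaves_rates_unchanged(self):
        arch = dc.replace(RON_MINIGENE, rbp_pos=0.0, exon_starts=(600.0, 620.0, 660.0),
                          exon_ends=(610.0, 650.0, 690.0))
        profile = InhibitionProfile(l_up=50.0, r_down=50.0, p=8.0)
        k = effective_rates((0.1, 0.2, 0.3), arch, profile)
        assert k == pytest.approx((0.1, 0.2, 0.3), rel=1e-6)

    def test_rbp_on_splice_site_silences_that_exon(self):
        arch = dc.replace(RON_MINIGENE, rbp_pos=443.0)  # exon 2 5'SS
        profile = InhibitionProfile(l_up=50.0, r_down=50.0, p=8.0)
        k = effective_rates((0.1, 0.1, 0.1), arch, profile)
        assert k[1] == 0.0

    def test_half_range_distance_halves_the_rate(self):
        # RBP 50 nt downstream of exon 2's 5'SS, far from its 3'SS
        arch = dc.replace(RON_MINIGENE, rbp_pos=493.0)
        profile = InhibitionProfile(l_up=50.0, r_down=50.0, p=8.0)
        k = effective_rates((0.1, 0.1, 0.1), arch, profile)
        assert k[1] == pytest.approx(0.05, rel=1e-3)

    def test_inhibitor_bounds_below_activator_above(self):
        rng = np.random.default_rng(7)
        base = (0.1, 0.05, 0.2)
        for _ in range(25):
            pos = float(rng.uniform(0, 700))
            arch = dc.replace(RON_MINIGENE, rbp_pos=pos)
            inh = effective_rates(
                base, arch, InhibitionProfile(50, 50, 8, "inhibitor")
            )
            act = effective_rates(
                base, arch, InhibitionProfile(50, 50, 8, "activator")
            )
            assert all(ki <= k for ki, k in zip(inh, base))
            assert all(ka >= k for ka, k in zip(act, base))


class TestDelaySchedule:
    def test_printed_ron_geometry_at_50nt_per_s(self):
        s = compute_delay_schedule(RON_MINIGENE, 50.0)
        assert s.tau1 == pytest.approx(4.2)
        assert s.tau2 == pytest.approx(8.86)
        assert s.tau3 == pytest.approx(13.8)
        assert s.tau6 == pytest.approx(14.0)

    def test_delays_halve_when_vpol_doubles(self):
        s1 = compute_delay_schedule(RON_MINIGENE, 25.0)
        s2 = compute_delay_schedule(RON_MINIGENE, 50.0)
        for name in ("tau1", "tau2", "tau3", "tau4", "tau5", "tau6"):
            assert getattr(s2, name) == pytest.approx(getattr(s1, name) / 2)

    def test_rbp_at_initiation_opens_window_immediately(self):
        arch = dc.replace(RON_MINIGENE, rbp_pos=0.0)
        assert compute_delay_schedule(arch, 50.0).tau4 == 0.0

    def test_events_sorted_even_when_rbp_is_downstream(self):
        arch = dc.replace(RON_MINIGENE, rbp_pos=680.0)
        events = compute_delay_schedule(arch, 50.0).events
        assert events == sorted(events)


def _matrix_exponential_oracle(params, arch, profile, t_end):
    """Independent piecewise propagation of the full 19-state system."""
    from cosplice.exondef import _phase_matrices

    schedule = compute_delay_schedule(arch, params.vpol)
    boundaries, mats = _phase_matrices(params, arch, profile, schedule)
    x = np.zeros(19)
    x[0] = 1.0
    spans = list(zip(boundaries, boundaries[1:] + [t_end]))
    for (t0, t1), A in zip(spans, mats):
        if t1 > t0:
            x = expm(A * (t1 - t0)) @ x
    return x


class TestSimulate:
    def test_ode_matches_matrix_exponential_oracle_on_random_draws(self):
        rng = np.random.default_rng(11)
        profile = InhibitionProfile(50, 50, 8)
        for _ in range(50):
            params = ExonDefinitionParams(
                k1=10 ** rng.uniform(-2, 0), k2=10 ** rng.uniform(-2, 0),
                k3=10 ** rng.uniform(-2, 0), rbp_br=10 ** rng.uniform(-2, 0.5),
                kspli=10 ** rng.uniform(-1.5, 0), kspls=10 ** rng.uniform(-1.5, 0),
                kret=10 ** rng.uniform(-2.5, -1.5), vpol=10 ** rng.uniform(0.5, 2.5),
            )
            arch = dc.replace(RON_MINIGENE, rbp_pos=float(rng.uniform(0, 700)))
            out, state = simulate_exon_definition(
                params, arch, profile, backend="ode", return_state=True
            )
            oracle = _matrix_exponential_oracle(params, arch, profile, 1e4)
            assert np.max(np.abs(state - oracle)) < 1e-8

    def test_probability_conserved_across_phase_boundaries(self):
        from cosplice.exondef import _phase_matrices

        params = ExonDefinitionParams()
        schedule = compute_delay_schedule(RON_MINIGENE, params.vpol)
        boundaries, mats = _phase_matrices(
            params, RON_MINIGENE, InhibitionProfile(), schedule
        )
        x = np.zeros(19)
        x[0] = 1.0
        spans = list(zip(boundaries, boundaries[1:] + [1e4]))
        for (t0, t1), A in zip(spans, mats):
            assert np.allclose(A.sum(axis=0), 0.0, atol=1e-14)
            if t1 > t0:
                x = expm(A * (t1 - t0)) @ x
                assert x.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_post_transcriptional_race(self):
        """With all delays collapsed (huge vpol), no RBP and equal rates, the
        outcome is decided purely by the race into P101 vs P111."""
        params = ExonDefinitionParams(
            k1=0.1, k2=0.1, k3=0.1, rbp_br=0.0, kspli=1.0, kspls=1.0,
            kret=0.0, vpol=1e7,
        )
        out, state = simulate_exon_definition(
            params, RON_MINIGENE, InhibitionProfile(), backend="expm",
            return_state=True,
        )
        oracle = _matrix_exponential_oracle(
            params, RON_MINIGENE, InhibitionProfile(), 1e4
        )
        assert np.max(np.abs(state - oracle)) < 1e-8
        # skipping requires passing through P101 without exon-2 definition;
        # with equal rates inclusion must dominate
        assert out.incl > out.skip > 0

    def test_no_retention_channel_when_kret_zero(self):
        params = ExonDefinitionParams(kret=0.0)
        out = simulate_exon_definition(params, backend="expm")
        assert out.ret == 0.0
        assert out.incl + out.skip == pytest.approx(1.0, abs=1e-6)

    def test_rbp_br_zero_makes_position_and_profile_irrelevant(self):
        params = ExonDefinitionParams(rbp_br=0.0)
        outs = []
        for pos, profile in [
            (100.0, InhibitionProfile(50, 50, 8)),
            (500.0, InhibitionProfile(25, 25, 32)),
            (300.0, InhibitionProfile(50, 50, 8, "activator")),
        ]:
            arch = dc.replace(RON_MINIGENE, rbp_pos=pos)
            outs.append(simulate_exon_definition(params, arch, profile, backend="expm"))
        for o in outs[1:]:
            assert o.incl == pytest.approx(outs[0].incl, abs=1e-12)
            assert o.skip == pytest.approx(outs[0].skip, abs=1e-12)


@pytest.fixture(scope="module")
def scan():
    params = ExonDefinitionParams()
    positions = np.linspace(60, 640, 40)
    return position_scan(
        params, RON_MINIGENE, InhibitionProfile(), positions,
        [5.0, 50.0, 1000.0],
    )


@pytest.fixture(scope="module")
def fig5():
    params = ExonDefinitionParams(vpol=5.0)
    profile = InhibitionProfile(25, 25, 32)
    positions = np.arange(403, 485, 4.0)
    return params, profile, positions


class TestPositionScan:

    def test_position_dependence_disappears_at_fast_elongation(self, scan):
        assert np.ptp(scan["psi"][:, 2]) < 0.02
        assert np.ptp(scan["psi"][:, 0]) > 0.2

    def test_peripheral_positions_reproduce_no_rbp_psi(self, scan):
        # the upstream plateau (positions 60-105, >75 nt from the nearest
        # splice site) reproduces the no-RBP reference
        plateau = scan["positions"] < 106
        assert plateau.sum() >= 3
        for value in scan["psi"][plateau, 1]:
            assert value == pytest.approx(scan["psi_default"][1], abs=0.01)

    def test_rbp_on_middle_exon_suppresses_inclusion_at_slow_elongation(self, scan):
        positions = scan["positions"]
        on_exon2 = (positions > 310) & (positions < 430)
        assert scan["psi"][on_exon2, 0].min() < scan["psi_default"][0] - 0.3


class TestAsymmetry:
    def test_inhibitor_effect_asymmetric_around_exon2_5ss(self, fig5):
        params, profile, positions = fig5
        scan = position_scan(params, RON_MINIGENE, profile, positions, [5.0])
        index = asymmetry_index(scan, 443.0, 30.0)
        assert abs(index) > 0.05

    def test_faster_exon2_definition_increases_asymmetry(self, fig5):
        params, profile, positions = fig5
        ref = position_scan(params, RON_MINIGENE, profile, positions, [5.0])
        fast = position_scan(
            dc.replace(params, k2=5 * params.k2), RON_MINIGENE, profile,
            positions, [5.0],
        )
        assert abs(asymmetry_index(fast, 443.0, 30.0)) > abs(
            asymmetry_index(ref, 443.0, 30.0)
        )

    def test_activator_effect_is_symmetric(self, fig5):
        params, _, positions = fig5
        activator = InhibitionProfile(25, 25, 32, "activator")
        scan = position_scan(params, RON_MINIGENE, activator, positions, [5.0])
        assert abs(asymmetry_index(scan, 443.0, 30.0)) < 0.01

    def test_site_outside_rbp_influence_has_zero_index(self, fig5):
        params, profile, _ = fig5
        positions = np.arange(60, 142, 4.0)  # far from every splice site
        scan = position_scan(params, RON_MINIGENE, profile, positions, [5.0])
        assert asymmetry_index(scan, 100.0, 30.0) == pytest.approx(0.0, abs=1e-9)

    def test_window_outside_scan_rejected(self, fig5):
        params, profile, positions = fig5
        scan = position_scan(params, RON_MINIGENE, profile, positions, [5.0])
        with pytest.raises(ValueError):
            asymmetry_index(scan, 443.0, 500.0)


class TestValidation:
    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            GeneArchitecture(exon_ends=(500.0, 443.0, 690.0))
        with pytest.raises(ValueError):
            GeneArchitecture(rbp_pos=900.0)

    def test_rate_matrix_species_order_matches_module_constant(self):
        A = rate_matrix((0.1, 0.1, 0.1), (0.05, 0.05, 0.05), 0.3, 0.2, 0.2, 0.01)
        assert A.shape == (len(SPECIES), len(SPECIES))
        # absorbing fates: no outflow from ret/Incl/Skip
        for fate in ("ret", "Incl", "Skip"):
            j = SPECIES.index(fate)
            assert A[j, j] == 0.0
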
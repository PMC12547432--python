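"""Surface cascade: PMF, redistribution matrix, monthly stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastisink as ps
from plastisink.fragmentation import monthly_exports


def hand_pmf(k: int, p: float, f: float) -> float:
    """Independent evaluation of the negative-binomial mass PMF."""
    return (
        math.gamma(k + f)
        / (math.gamma(k + 1) * math.gamma(f))
        * p**k
        * (1 - p) ** f
    )


class TestSphereMass:
    @pytest.mark.parametrize(
        "d_um, rho, expected",
        [
            (10000.0, 960.0, 502.6548),  # the 10 mm PE parent particle
            (0.0, 960.0, 0.0),
            (1000.0, 960.0, 0.5026548),  # d^3 scaling: parent value / 1000
        ],
    )
    def test_values(self, d_um, rho, expected):
        assert ps.sphere_mass(d_um, rho) == pytest.approx(expected, rel=1e-6)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            ps.sphere_mass(-1.0, 960.0)
        with pytest.raises(ValueError):
            ps.sphere_mass(100.0, 0.0)


class TestNbMassPmf:
    def test_k0_reduces_to_survival_term(self):
        for p, f in [(0.3, 0.1), (0.5, 2.0), (0.9, 0.4)]:
            assert ps.nb_mass_pmf(0, p, f) == pytest.approx((1 - p) ** f, rel=1e-12)

    def test_k1_default_parameters(self):
        # f * p * (1-p)^f = 0.1 * 0.3 * 0.7^0.1
        assert ps.nb_mass_pmf(1, 0.3, 0.1) == pytest.approx(0.028948833, rel=1e-7)

    @pytest.mark.parametrize("p,f", [(0.3, 0.1), (0.7, 1.5), (0.05, 0.5)])
    def test_matches_hand_evaluation_and_normalises(self, p, f):
        ks = np.arange(0, 400)
        pmf = ps.nb_mass_pmf(ks, p, f)
        for k in range(6):
            assert pmf[k] == pytest.approx(hand_pmf(k, p, f), rel=1e-10)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ps.nb_mass_pmf(1, 1.0, 0.1)
        with pytest.raises(ValueError):
            ps.nb_mass_pmf(1, 0.3, 0.0)
        with pytest.raises(ValueError):
            ps.nb_mass_pmf(-1, 0.3, 0.1)


class TestRedistributionMatrix:
    @pytest.mark.parametrize("conv", ps.fragmentation.K_CONVENTIONS)
    @pytest.mark.parametrize("p,f", [(0.3, 0.1), (0.1, 0.5), (0.5, 0.5), (0.9, 0.2)])
    def test_column_structure(self, conv, p, f):
        scheme = ps.SizeBinScheme()
        m = ps.redistribution_matrix(scheme, p, f, conv).entries
        assert np.all(m >= 0)
        # no entry routes mass to an equal or larger bin (bins are indexed
        # smallest first, so destination rows lie strictly above the diagonal)
        assert np.allclose(np.tril(m), 0.0)
        for i in scheme.nonterminal_indices:
            assert m[:, i].sum() == pytest.approx(1.0, abs=1e-12)
        for i in scheme.terminal_indices:
            assert np.all(m[:, i] == 0.0)

    def test_steps_down_parent_column_fractions(self):
        # k=1..4 downward from the 6 mm bin, renormalised by hand
        p, f = 0.3, 0.1
        w = np.array([hand_pmf(k, p, f) for k in (1, 2, 3, 4)])
        expected = w / w.sum()  # fractions to (1250, 300, 75, 25) µm
        m = ps.redistribution_matrix(p=p, f=f, k_convention="steps_down").entries
        assert m[:4, 4] == pytest.approx(expected[::-1], rel=1e-9)
        assert m[3, 4] == pytest.approx(0.8280, abs=2e-4)
        assert m[2, 4] == pytest.approx(0.1366, abs=2e-4)
        assert m[1, 4] == pytest.approx(0.0287, abs=2e-4)
        assert m[0, 4] == pytest.approx(0.0067, abs=2e-4)

    def test_from_smallest_mirrors_parent_column(self):
        a = ps.redistribution_matrix(k_convention="steps_down").entries[:, 4]
        b = ps.redistribution_matrix(k_convention="from_smallest").entries[:, 4]
        assert b[:4] == pytest.approx(a[:4][::-1], rel=1e-12)

    @pytest.mark.parametrize("conv,dominant_dest", [("steps_down", 3), ("from_smallest", 0)])
    def test_small_p_limit_concentrates_at_k1(self, conv, dominant_dest):
        m = ps.redistribution_matrix(p=1e-6, f=0.1, k_convention=conv).entries
        assert m[dominant_dest, 4] > 0.999999


class TestDegradeStep:
    def test_single_step_from_parent_steps_down(self):
        scheme = ps.SizeBinScheme()
        params = ps.FragmentationParams(k_convention="steps_down")
        matrix = ps.redistribution_matrix(scheme, k_convention="steps_down")
        spec = ps.SurfaceSpectrum.initial(100.0, scheme)
        out = ps.degrade_step(spec, params, matrix)
        assert out.bin_mass[4] == pytest.approx(99.55, rel=1e-12)
        w = np.array([hand_pmf(k, 0.3, 0.1) for k in (1, 2, 3, 4)])
        split = 0.45 * w / w.sum()  # to (1250, 300, 75, 25) µm
        assert out.bin_mass[3] == pytest.approx(split[0], rel=1e-9)  # ~0.3726
        assert out.bin_mass[2] == pytest.approx(split[1], rel=1e-9)  # ~0.0615
        # terminal shares moved straight to the export account
        assert out.bin_mass[0] == out.bin_mass[1] == 0.0
        assert out.exported_cumulative == pytest.approx([split[3], split[2]], rel=1e-9)
        assert out.time_months == 1
        assert out.total_mass == pytest.approx(100.0, rel=1e-12)

    def test_zero_rate_is_identity(self):
        params = ps.FragmentationParams(degradation_rate=0.0)
        matrix = ps.redistribution_matrix()
        spec = ps.SurfaceSpectrum(
            [0.0, 0.0, 1.0, 2.0, 3.0], [0.0, 0.0], 5
        )
        out = ps.degrade_step(spec, params, matrix)
        assert out.bin_mass == pytest.approx(spec.bin_mass)
        assert out.time_months == 6

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            ps.SurfaceSpectrum([0.0, 0.0, -1.0, 0.0, 1.0], [0.0, 0.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        masses=st.lists(st.floats(0.0, 1e3), min_size=3, max_size=3),
        p=st.floats(0.05, 0.95),
        f=st.floats(0.05, 5.0),
        rate=st.floats(0.0, 0.5),
        conv=st.sampled_from(ps.fragmentation.K_CONVENTIONS),
    )
    def test_mass_conserved_for_any_parameters(self, masses, p, f, rate, conv):
        scheme = ps.SizeBinScheme()
        params = ps.FragmentationParams(rate, p, f, conv)
        matrix = ps.redistribution_matrix(scheme, p, f, conv)
        spec = ps.SurfaceSpectrum([0.0, 0.0, *masses], [0.0, 0.0], 0, scheme)
        total0 = spec.total_mass
        for _ in range(5):
            spec = ps.degrade_step(spec, params, matrix)
        assert spec.total_mass == pytest.approx(total0, rel=1e-12, abs=1e-12)
        assert np.all(spec.bin_mass >= 0)

    def test_matches_explicit_transfer_ledger(self):
        """Brute-force per-transfer bookkeeping reproduces the matrix step."""
        scheme = ps.SizeBinScheme()
        p, f, rate = 0.3, 0.1, 0.0045
        params = ps.FragmentationParams(rate, p, f, "from_smallest")
        matrix = ps.redistribution_matrix(scheme, p, f, "from_smallest")
        state = ps.SurfaceSpectrum.initial(502.6548, scheme)
        # independent ledger simulation
        mass = np.array(state.bin_mass)
        exported = np.zeros(2)
        for _ in range(18):
            ledger = []  # (source, dest, amount)
            for i in scheme.nonterminal_indices:
                if i == 0 or mass[i] == 0.0:
                    continue
                eroded = rate * mass[i]
                weights = [hand_pmf(j + 1, p, f) for j in range(i)]
                norm = sum(weights)
                for j in range(i):
                    ledger.append((i, j, eroded * weights[j] / norm))
            # apply the ledger explicitly: subtract per-source totals, add per-dest
            for i in scheme.nonterminal_indices:
                mass[i] -= sum(a for s, d, a in ledger if s == i)
            for _, j, amount in ledger:
                mass[j] += amount
            exported += mass[:2]
            mass[:2] = 0.0
            state = ps.degrade_step(state, params, matrix)
        assert state.bin_mass == pytest.approx(mass, rel=1e-12, abs=1e-12)
        assert state.exported_cumulative == pytest.approx(exported, rel=1e-12)


class TestRunFragmentation:
    def test_zero_months_returns_initial_state(self):
        states = ps.run_fragmentation(months=0, initial_mass_mg=10.0)
        assert len(states) == 1
        assert states[0].bin_mass[-1] == 10.0

    def test_monotonic_trends(self):
        states = ps.run_fragmentation(months=240)
        parent = np.array([s.bin_mass[-1] for s in states])
        assert np.all(np.diff(parent) < 0)  # strictly decreasing while positive
        exports = np.array([s.exported_cumulative for s in states])
        assert np.all(np.diff(exports, axis=0) >= 0)

    def test_century_run_conserves_mass(self):
        states = ps.run_fragmentation(months=1200)
        m0 = states[0].total_mass
        err = max(abs(s.total_mass - m0) / m0 for s in states)
        assert err < 1e-9

    def test_monthly_exports_are_increments(self):
        states = ps.run_fragmentation(months=36)
        inc = monthly_exports(states)
        assert inc.shape == (36, 2)
        assert inc.sum(axis=0) == pytest.approx(states[-1].exported_cumulative)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"degradation_rate": -0.1},
            {"degradation_rate": 1.0},
            {"p": 0.0},
            {"p": 1.5},
            {"f": 0.0},
            {"k_convention": "sideways"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ps.FragmentationParams(**kwargs)
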
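import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylodem.life_history import (
    age_at_maturity,
    compute_all_traits,
    degree_of_parity,
    generation_time,
    max_longevity,
    maturity_probability,
    net_reproductive_rate,
    reproductive_window,
    shape_reproduction,
    shape_survivorship,
)
from phylodem.mpm import MatrixPopulationModel

GOLDEN = (1 + np.sqrt(5)) / 2


class TestRatesAndTimings:
    def test_r0_semelparous(self):
        U = np.array([[0.0, 0.0], [0.5, 0.0]])
        F = np.array([[0.0, 2.0], [0.0, 0.0]])
        assert net_reproductive_rate(U, F) == pytest.approx(1.0)

    def test_r0_golden_leslie(self, golden_leslie):
        _, U, F = golden_leslie
        assert net_reproductive_rate(U, F) == pytest.approx(2.0)

    def test_r0_no_reproduction(self):
        assert net_reproductive_rate(np.array([[0.5]]), np.array([[0.0]])) == 0.0

    def test_generation_time_golden(self, golden_leslie):
        _, U, F = golden_leslie
        assert generation_time(U, F) == pytest.approx(np.log(2) / np.log(GOLDEN))

    def test_generation_time_single_age_class(self):
        # lambda = R0: everyone reproduces at age 1 and dies
        U = np.array([[0.0]])
        F = np.array([[1.7]])
        assert generation_time(U, F) == pytest.approx(1.0)

    def test_generation_time_stationary_guard(self):
        U = np.array([[0.0, 0.0], [1.0 - 1e-13, 0.0]])
        F = np.array([[0.0, 1.0 + 1e-13], [0.0, 0.0]])
        assert np.isnan(generation_time(U, F))

    def test_abar_variant_positive(self, golden_leslie):
        _, U, F = golden_leslie
        t = generation_time(U, F, method="abar")
        assert t > 0


class TestMaxLongevity:
    @pytest.mark.parametrize("p,expected", [(0.5, 7), (0.1, 3)])
    def test_geometric(self, p, expected):
        # strictly-below-1% reading: lx = 0.1^2 = 0.01 does not qualify
        assert max_longevity(np.array([[p]]), np.array([1.0])) == expected

    def test_immediate_death(self):
        assert max_longevity(np.zeros((1, 1)), np.array([1.0])) == 1


class TestMaturation:
    def setup_method(self):
        self.U = np.array([[0.0, 0.0], [0.5, 0.0]])
        self.F = np.array([[0.0, 2.0], [0.0, 0.0]])
        self.c = np.array([1.0, 0.0])

    def test_single_transition_probability(self):
        assert maturity_probability(self.U, self.F, self.c) == pytest.approx(0.5)

    def test_born_mature(self):
        assert maturity_probability(self.U, self.F, np.array([0.0, 1.0])) == 1.0
        assert age_at_maturity(self.U, self.F, np.array([0.0, 1.0])) == 0.0

    def test_two_step_passage_product(self):
        U = np.zeros((3, 3))
        U[1, 0] = 0.5
        U[2, 1] = 0.4
        F = np.zeros((3, 3))
        F[0, 2] = 1.0
        c = np.array([1.0, 0.0, 0.0])
        assert maturity_probability(U, F, c) == pytest.approx(0.2)

    def test_age_at_maturity_single_path(self):
        assert age_at_maturity(self.U, self.F, self.c) == pytest.approx(1.0)

    def test_age_at_maturity_mixture_vs_enumeration(self):
        # from stage 1: mature at age 1 w.p. 0.3, stay w.p. 0.3 then mature
        # at age 2 w.p. 0.3*0.3... — geometric mixture enumerable by brute force
        U = np.array([[0.3, 0.0], [0.3, 0.0]])
        F = np.array([[0.0, 1.0], [0.0, 0.0]])
        c = np.array([1.0, 0.0])
        # brute force over path lengths
        probs = np.array([0.3**k * 0.3 for k in range(60)])  # stay k times, then up
        ages = np.arange(1, 61)
        expected = float((probs * ages).sum() / probs.sum())
        assert age_at_maturity(U, F, c) == pytest.approx(expected, rel=1e-9)

    def test_reproductive_window_one_interval(self):
        assert reproductive_window(self.U, self.F, self.c) == pytest.approx(1.0)

    def test_reproductive_window_self_loop(self):
        U = np.array([[0.0, 0.0], [0.5, 0.5]])
        F = np.array([[0.0, 2.0], [0.0, 0.0]])
        assert reproductive_window(U, F, np.array([1.0, 0.0])) == pytest.approx(2.0)

    def test_window_is_mixture_mean(self):
        # two reproductive stages entered with probs 0.6/0.4 and residual
        # expectancies 2 and 5
        U = np.zeros((3, 3))
        U[1, 1] = 0.5  # eta = 2
        U[2, 2] = 0.8  # eta = 5
        F = np.zeros((3, 3))
        F[0, 1] = F[0, 2] = 1.0
        c = np.array([0.0, 0.6, 0.4])
        assert reproductive_window(U, F, c) == pytest.approx(3.2)

    def test_no_reproductive_stage_raises(self):
        with pytest.raises(ValueError, match="reproductive"):
            maturity_probability(self.U, np.zeros((2, 2)), self.c)


class TestShapes:
    def test_constant_survival_maps_to_zero(self):
        lx = 0.8 ** np.arange(21)
        assert abs(shape_survivorship(lx)) < 1e-6

    def test_sudden_death_near_half(self):
        lx = np.concatenate([np.ones(100), [1e-6]])
        assert shape_survivorship(lx) == pytest.approx(0.5, abs=0.01)

    def test_type_iii_negative(self):
        lx = np.array([1, 0.2, 0.1, 0.08, 0.07, 0.065])
        assert shape_survivorship(lx) < 0

    def test_no_mortality_flagged(self):
        assert np.isnan(shape_survivorship(np.ones(10)))

    def test_constant_reproduction_maps_to_zero(self):
        lx = 0.95 ** np.arange(50)
        mx = np.ones(50)
        assert abs(shape_reproduction(lx, mx)) < 1e-3

    def test_early_burst_near_half(self):
        lx = 0.99 ** np.arange(100)
        mx = np.zeros(100)
        mx[0] = 5.0
        assert shape_reproduction(lx, mx) == pytest.approx(0.5, abs=0.01)

    def test_increasing_reproduction_negative(self):
        lx = 0.9 ** np.arange(30)
        mx = np.linspace(0.1, 3.0, 30)
        assert shape_reproduction(lx, mx) < 0

    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=0.98),
            min_size=4,
            max_size=60,
        )
    )
    def test_shape_bounds_for_monotone_schedules(self, survs):
        lx = np.concatenate([[1.0], np.cumprod(survs)])
        s = shape_survivorship(lx)
        assert -0.5 <= s <= 0.5

    def test_invariant_under_time_rescaling(self):
        # halving the time step (square-root survival, doubled ages) leaves
        # the standardized shape nearly unchanged for an exponential curve
        lx_annual = 0.7 ** np.arange(11)
        lx_fine = (0.7**0.5) ** np.arange(21)
        a = shape_survivorship(lx_annual)
        b = shape_survivorship(lx_fine)
        assert a == pytest.approx(b, abs=1e-9)


class TestParity:
    def test_semelparity_zero(self):
        lx = np.array([1.0, 0.5, 0.25])
        mx = np.array([0.0, 3.0, 0.0])
        assert degree_of_parity(lx, mx) == 0.0

    def test_uniform_two_ages(self):
        lx = np.array([1.0, 0.5])
        mx = np.array([1.0, 2.0])  # lx*mx = (1, 1)
        assert degree_of_parity(lx, mx) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("k", [3, 5, 10])
    def test_uniform_k_ages(self, k):
        lx = np.ones(k)
        mx = np.ones(k)
        assert degree_of_parity(lx, mx) == pytest.approx(np.log(k))


class TestComputeAll:
    def test_golden_leslie_assembly(self, golden_leslie):
        A, U, F = golden_leslie
        m = MatrixPopulationModel(A=A, U=U, F=F)
        t = compute_all_traits(m)
        assert t.R0 == pytest.approx(2.0)
        assert t.T == pytest.approx(np.log(2) / np.log(GOLDEN))
        assert t.p_R == pytest.approx(1.0)  # offspring enter stage 1, which reproduces
        assert t.L_alpha == 0.0

    def test_sterile_model_flags_reproductive_traits(self):
        U = np.diag([0.0, 0.0])
        U[1, 0] = 0.5
        F = np.zeros((2, 2))
        m = MatrixPopulationModel(A=U + F, U=U, F=F)
        t = compute_all_traits(m)
        assert t.R0 == 0.0
        assert np.isnan(t.p_R) and np.isnan(t.s_mx) and np.isnan(t.S)
        assert np.isfinite(t.eta_e)

    def test_single_stage_constant_reproduction(self):
        m = MatrixPopulationModel(
            A=np.array([[1.5]]), U=np.array([[0.5]]), F=np.array([[1.0]])
        )
        t = compute_all_traits(m)
        # geometric lx with constant mx: almost no reproductive senescence,
        # parity = entropy of the geometric reproduction-age distribution
        assert abs(t.s_mx) < 0.06
        assert abs(t.s_lx) < 1e-9
        p = 0.5 ** np.arange(t.L_max + 1)
        p = p / p.sum()
        assert t.S == pytest.approx(float(-(p * np.log(p)).sum()), rel=1e-6)

    def test_leslie_round_trip_from_schedules(self):
        """An age-classified matrix built from explicit lx/mx reproduces the
        schedule-based traits."""
        px = np.array([0.8, 0.6, 0.4])  # survival age->age+1, then death
        mx_true = np.array([0.0, 1.0, 2.0, 3.0])
        n = 4
        U = np.zeros((n, n))
        for j, p in enumerate(px):
            U[j + 1, j] = p
        F = np.zeros((n, n))
        F[0, :] = mx_true
        m = MatrixPopulationModel(A=U + F, U=U, F=F)
        t = compute_all_traits(m)
        lx = np.concatenate([[1.0], np.cumprod(px)])
        assert t.eta_e == pytest.approx(lx.sum())
        assert t.R0 == pytest.approx((lx * mx_true).sum())
        assert t.L_alpha == pytest.approx(1.0)  # first reproduction at age 1
        assert t.p_R == pytest.approx(0.8)
        assert t.S == pytest.approx(
            degree_of_parity(lx, mx_true), rel=1e-9
        )

    def test_maturity_probability_matches_monte_carlo(self):
        rng = np.random.default_rng(17)
        U = np.array([[0.2, 0.0, 0.0], [0.4, 0.5, 0.0], [0.0, 0.3, 0.7]])
        F = np.zeros((3, 3))
        F[0, 2] = 1.0
        c = np.array([1.0, 0.0, 0.0])
        p = maturity_probability(U, F, c)
        n_ind = 100_000
        # absorbing simulation on the transient block
        matured = 0
        counts = np.array([n_ind, 0])
        B = U[:2, :2]
        to_repro = U[2, :2]
        while counts.sum():
            nxt = np.zeros(2, dtype=np.int64)
            for j in range(2):
                if not counts[j]:
                    continue
                probs = np.array(
                    [B[0, j], B[1, j], to_repro[j], 1 - U[:, j].sum()]
                )
                draw = rng.multinomial(counts[j], probs)
                nxt += draw[:2]
                matured += draw[2]
            counts = nxt
        phat = matured / n_ind
        se = np.sqrt(phat * (1 - phat) / n_ind)
        assert abs(p - phat) < 3 * se
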
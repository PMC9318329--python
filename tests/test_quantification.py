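"""Mass-balance and kinetic formulas against independent single-expression oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aminobalance import quantification as q
from aminobalance.quantification import DialysisSession, UrineCollection

# single-expression re-implementations, kept deliberately separate from the package
ORACLE_DAILY_HD = lambda V, D, n, UE: (V * D * n) / 7 + UE
ORACLE_KTV = lambda R, t, UF, W: -math.log(R - 0.008 * t) + (4 - 3.5 * R) * UF / W
ORACLE_INTAKE_HD = lambda V, Du, n, UUE, BW, UPE: 6.25 * (
    0.028 * ((V * Du * n) / 7 + UUE) + 0.031 * BW
) + UPE
ORACLE_INTAKE_CTRL = lambda UUE, BW, UPE: 6.25 * (0.028 * UUE + 0.031 * BW) + UPE
ORACLE_CLEARANCE = lambda V, D, T, Ppre, Ppost: ((V * D) / T) / ((Ppre + Ppost) / 2) * (1000 / 60)


class TestDailyLosses:
    @pytest.mark.parametrize(
        "V, D, n, UE, expected",
        [
            (135, 20, 3, 100, 8100 / 7 + 100),   # 1257.14
            (135, 0, 3, 0, 0.0),
            (100, 50, 3, 0, 15000 / 7),          # anuric, 2142.86
        ],
    )
    def test_hd_examples(self, session_factory, urine_factory, V, D, n, UE, expected):
        session = session_factory(v_dialysate=V, n_per_week=n, dialysate_panel={"glycine": D})
        urine = urine_factory(volume=1.0, panel={"glycine": UE}) if UE else None
        assert q.daily_losses_hd(session, urine, "glycine") == pytest.approx(expected)

    @pytest.mark.parametrize(
        "vol, conc, expected", [(2.5, 100, 250.0), (2.5, 0, 0.0), (0.0, 100, 0.0)]
    )
    def test_control_examples(self, urine_factory, vol, conc, expected):
        urine = urine_factory(volume=vol, panel={"alanine": conc})
        assert q.daily_losses_control(urine, "alanine") == pytest.approx(expected)

    def test_single_session(self, session_factory):
        session = session_factory(v_dialysate=135, dialysate_panel={"valine": 20})
        assert q.single_session_losses(session, "valine") == pytest.approx(2700.0)
        assert q.single_session_losses(
            session_factory(dialysate_panel={"valine": 0}), "valine"
        ) == 0.0

    def test_weekly_identity_without_urine(self, session_factory):
        """daily_hd == single_session × n/7 when there is no urinary component."""
        session = session_factory(v_dialysate=120, n_per_week=2, dialysate_panel={"serine": 33.5})
        daily = q.daily_losses_hd(session, None, "serine")
        per_session = q.single_session_losses(session, "serine")
        assert daily == pytest.approx(per_session * session.n_per_week / 7, rel=1e-12)

    def test_missing_dialysate_concentration_is_an_error(self, session_factory):
        session = session_factory(dialysate_panel={})
        with pytest.raises(q.MissingAnalyteError):
            q.daily_losses_hd(session, None, "glycine")
        assert q.daily_losses_hd(session, None, "glycine", impute_zero=True) == 0.0

    def test_mass_conservation(self, session_factory, urine_factory):
        """Daily loss decomposes exactly into weekly-averaged dialytic + urinary parts."""
        session = session_factory(v_dialysate=141.3, n_per_week=3, dialysate_panel={"lysine": 17.2})
        urine = urine_factory(volume=0.8, panel={"lysine": 260.0})
        daily = q.daily_losses_hd(session, urine, "lysine")
        assert daily == pytest.approx(
            q.single_session_losses(session, "lysine") * 3 / 7
            + q.urinary_excretion(urine, "lysine"),
            rel=1e-12,
        )


class TestKtV:
    @pytest.mark.parametrize(
        "R, t, UF, W, expected",
        [
            (0.3, 4, 2.0, 78, -math.log(0.268) + 2.95 * 2 / 78),  # 1.392
            (1.0, 0, 0.0, 78, 0.0),
            (0.4, 4, 1.0, 70, -math.log(0.368) + 2.6 / 70),       # 1.037
        ],
    )
    def test_examples(self, R, t, UF, W, expected):
        assert q.ktv_daugirdas(R, t, UF, W) == pytest.approx(expected, rel=1e-9)

    def test_printed_precision(self):
        assert q.ktv_daugirdas(0.3, 4, 2.0, 78) == pytest.approx(1.392, abs=5e-4)
        assert q.ktv_daugirdas(0.4, 4, 1.0, 70) == pytest.approx(1.037, abs=5e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(R=0.03, t=4, UF=1, W=70), dict(R=0.5, t=4, UF=1, W=0), dict(R=1.2, t=1, UF=1, W=70)],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(q.DomainError):
            q.ktv_daugirdas(kwargs["R"], kwargs["t"], kwargs["UF"], kwargs["W"])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        R=st.floats(0.1, 0.95), dR=st.floats(0.01, 0.04),
        t=st.floats(2.0, 5.0), UF=st.floats(0.0, 4.0), dUF=st.floats(0.1, 1.0),
        W=st.floats(40.0, 120.0),
    )
    def test_monotonicity(self, R, dR, t, UF, dUF, W):
        """Kt/V strictly decreases in R and increases in UF on the valid domain."""
        assert q.ktv_daugirdas(R, t, UF, W) > q.ktv_daugirdas(R + dR, t, UF, W)
        assert q.ktv_daugirdas(R, t, UF + dUF, W) > q.ktv_daugirdas(R, t, UF, W)

    def test_inversion_round_trip(self):
        for ktv in (0.8, 1.4, 2.0):
            R = q.invert_daugirdas(ktv, 4.0, 1.9, 78.0)
            assert q.ktv_daugirdas(R, 4.0, 1.9, 78.0) == pytest.approx(ktv, abs=1e-6)


class TestProteinIntake:
    def test_hd_examples(self, session_factory, urine_factory):
        s = session_factory(v_dialysate=135, n_per_week=3, weight_post=78, dialysate_urea=10.0)
        intake, per_kg = q.protein_intake_hd(s, None)
        assert intake == pytest.approx(116.36, abs=0.005)
        assert per_kg == pytest.approx(intake / 78, rel=1e-12)
        urine = urine_factory(urea=100.0, protein=0.7)
        intake2, _ = q.protein_intake_hd(s, urine)
        assert intake2 == pytest.approx(134.56, abs=0.005)

    def test_control_examples(self, urine_factory):
        assert q.protein_intake_control(urine_factory(urea=400.0), 77.0)[0] == pytest.approx(
            84.92, abs=0.005
        )
        assert q.protein_intake_control(urine_factory(urea=400.0, protein=0.5), 77.0)[
            0
        ] == pytest.approx(85.42, abs=0.005)
        assert q.protein_intake_control(urine_factory(urea=0.0), 0.0)[0] == 0.0


class TestChangesAndClearances:
    @pytest.mark.parametrize(
        "pre, post, abs_exp, prop_exp",
        [(186, 148, -38, -38 / 186 * 100), (100, 100, 0, 0.0)],
    )
    def test_intradialytic_change(self, pre, post, abs_exp, prop_exp):
        absolute, proportional = q.intradialytic_change(pre, post)
        assert absolute == pytest.approx(abs_exp)
        assert proportional == pytest.approx(prop_exp)

    def test_histidine_printed_row(self):
        """Printed mean absolute change −15 on pre 69 rounds to −22%."""
        assert round(q.proportional_change(-15, 69)) == -22

    def test_zero_pre_flagged(self):
        _, prop = q.intradialytic_change(0.0, 5.0)
        assert prop is None

    @pytest.mark.parametrize(
        "V, D, T, Ppre, Ppost, expected",
        [(135, 100, 4, 300, 200, 225.0), (135, 0, 4, 300, 200, 0.0), (120, 50, 4, 100, 80, 1500 / 90 * 1000 / 60)],
    )
    def test_dialytic_clearance(self, session_factory, V, D, T, Ppre, Ppost, expected):
        s = session_factory(
            v_dialysate=V, duration_h=T,
            dialysate_panel={"leucine": D}, plasma_pre={"leucine": Ppre},
            plasma_post={"leucine": Ppost},
        )
        assert q.dialytic_clearance(s, "leucine") == pytest.approx(expected, rel=1e-9)

    def test_clearance_scale_invariance(self, session_factory):
        """Rescaling dialysate and both plasma levels together leaves clearance unchanged."""
        base = dict(v_dialysate=135, duration_h=4)
        s1 = session_factory(**base, dialysate_panel={"leucine": 80},
                             plasma_pre={"leucine": 300}, plasma_post={"leucine": 200})
        s2 = session_factory(**base, dialysate_panel={"leucine": 80 * 3.7},
                             plasma_pre={"leucine": 300 * 3.7}, plasma_post={"leucine": 200 * 3.7})
        assert q.dialytic_clearance(s1, "leucine") == pytest.approx(
            q.dialytic_clearance(s2, "leucine"), rel=1e-12
        )

    def test_zero_plasma_undefined(self, session_factory):
        s = session_factory(dialysate_panel={"leucine": 80},
                            plasma_pre={"leucine": 0.0}, plasma_post={"leucine": 0.0})
        assert q.dialytic_clearance(s, "leucine") is None

    @pytest.mark.parametrize("cl, cr, expected", [(20, 137, 20 / 137 * 100), (137, 137, 100.0), (0, 137, 0.0)])
    def test_fractional_clearance(self, cl, cr, expected):
        assert q.fractional_clearance(cl, cr) == pytest.approx(expected)
        with pytest.raises(q.DomainError):
            q.fractional_clearance(10, 0)


class TestGramsAndRatios:
    def test_losses_in_grams_glycine(self):
        grams, groups = q.losses_in_grams({"glycine": 1000.0})
        assert grams["glycine"] == pytest.approx(0.07507, rel=1e-6)
        assert groups["total"] == pytest.approx(0.07507, rel=1e-6)

    def test_additivity_and_empty(self):
        g1, _ = q.losses_in_grams({"leucine": 500.0})
        g2, _ = q.losses_in_grams({"taurine": 700.0})
        g12, groups = q.losses_in_grams({"leucine": 500.0, "taurine": 700.0})
        assert groups["total"] == pytest.approx(g1["leucine"] + g2["taurine"], rel=1e-12)
        assert q.losses_in_grams({})[1]["total"] == 0.0

    def test_group_sums_examples(self):
        sums = q.group_sums({"leucine": 1, "isoleucine": 2, "valine": 3})
        assert sums == {"bcaa": 6, "essential": 6, "non-essential": 0, "total": 6}
        assert q.group_sums({"taurine": 5})["non-essential"] == 5
        with pytest.raises(Exception):
            q.group_sums({"notanaa": 1.0})

    @pytest.mark.parametrize("loss, intake, expected", [(4.0, 60, 4 / 60 * 100), (0, 50, 0.0), (0.6, 84, 0.6 / 84 * 100)])
    def test_pct_of_intake(self, loss, intake, expected):
        assert q.pct_of_protein_intake(loss, intake) == pytest.approx(expected)
        with pytest.raises(q.DomainError):
            q.pct_of_protein_intake(1.0, 0.0)

    def test_hd_to_urine_ratio(self):
        assert q.hd_to_urine_ratio(1320, 10) == pytest.approx(132.0)
        assert q.hd_to_urine_ratio(5, 5) == pytest.approx(1.0)
        assert q.hd_to_urine_ratio(5, 0) is None


def test_formula_oracles_on_random_inputs():
    """All kinetic formulas match independent one-liners to 1e-9 relative."""
    rng = np.random.default_rng(2022)
    for _ in range(1000):
        V = rng.uniform(60, 220)
        D = rng.uniform(0, 400)
        n = int(rng.choice([2, 3]))
        UE = rng.uniform(0, 2000)
        T = rng.uniform(2, 5)
        W = rng.uniform(40, 130)
        UF = rng.uniform(0, 4)
        R = rng.uniform(0.1, 0.9)
        Du = rng.uniform(1, 40)
        UUE = rng.uniform(0, 400)
        UPE = rng.uniform(0, 3)
        Ppre, Ppost = rng.uniform(10, 600, 2)
        vol = rng.uniform(0.2, 3.0)

        session = DialysisSession(
            v_dialysate=V, duration_h=T, n_per_week=n, uf_volume=UF, weight_post=W,
            dialysate_panel={"leucine": D}, dialysate_urea=Du,
            plasma_pre={"leucine": Ppre}, plasma_post={"leucine": Ppost},
        )
        urine = UrineCollection(volume=vol, panel={"leucine": UE / vol}, urea=UUE, protein=UPE)

        assert q.daily_losses_hd(session, urine, "leucine") == pytest.approx(
            ORACLE_DAILY_HD(V, D, n, UE), rel=1e-9
        )
        assert q.ktv_daugirdas(R, T, UF, W) == pytest.approx(
            ORACLE_KTV(R, T, UF, W), rel=1e-9
        )
        assert q.protein_intake_hd(session, urine)[0] == pytest.approx(
            ORACLE_INTAKE_HD(V, Du, n, UUE, W, UPE), rel=1e-9
        )
        assert q.protein_intake_control(urine, W)[0] == pytest.approx(
            ORACLE_INTAKE_CTRL(UUE, W, UPE), rel=1e-9
        )
        assert q.dialytic_clearance(session, "leucine") == pytest.approx(
            ORACLE_CLEARANCE(V, D, T, Ppre, Ppost), rel=1e-9
        )
        assert q.fractional_clearance(10.0, 137.0) == pytest.approx(10 / 137 * 100, rel=1e-9)


class TestValidation:
    def test_session_invariants(self):
        with pytest.raises(q.DomainError):
            DialysisSession(v_dialysate=0, duration_h=4, n_per_week=3, uf_volume=1, weight_post=70)
        with pytest.raises(q.DomainError):
            DialysisSession(v_dialysate=100, duration_h=4, n_per_week=4, uf_volume=1, weight_post=70)
        with pytest.raises(q.DomainError):
            DialysisSession(v_dialysate=100, duration_h=4, n_per_week=3, uf_volume=1,
                            weight_post=70, dialysate_panel={"leucine": -1})

    def test_urine_invariants(self):
        with pytest.raises(q.DomainError):
            UrineCollection(volume=-0.1)
        with pytest.raises(q.DomainError):
            UrineCollection(volume=1.0, panel={"serine": -2.0})
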
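"""Cofactor ledger, cation model, export balancer and yield-ratio fit."""

import itertools
from fractions import Fraction

import pytest

from pelokit.energetics import (
    CationModel,
    CationYieldModel,
    CofactorLedger,
    Pathway,
    Reaction,
    UnbalancedLedgerError,
    export_cost,
    fit_cation_model,
    net_atp,
    yield_ratio,
)


def brute_force_export(nadh: Fraction, fd2e: Fraction, model: CationModel) -> Fraction:
    """Independent balancer: enumerate forward/reverse Rnf conversion
    counts on a half-integer grid and keep the best feasible plan.

    Feasibility: after conversions the NADH and Fd2e pools must be
    equal so that Nfn can pair everything for export via NADPH.
    """
    nadh, fd2e = Fraction(nadh), Fraction(fd2e)
    step = Fraction(1, 2)
    total = nadh + fd2e
    best = None
    k = 0
    while k * step <= total:
        for fwd, rev in ((k * step, Fraction(0)), (Fraction(0), k * step)):
            n_after = nadh - fwd + rev
            f_after = fd2e + fwd - rev
            if n_after < 0 or f_after < 0 or n_after != f_after:
                continue
            gain = (rev - fwd) * model.rnf_atp
            if best is None or gain > best:
                best = gain
        k += 1
    assert best is not None, "no feasible export plan found"
    return best


class TestLedger:
    def test_componentwise_addition_and_scaling(self):
        a = CofactorLedger(atp=1, nadh=Fraction(1, 2))
        b = CofactorLedger(nadh=Fraction(3, 2), fd2e=-1)
        s = a + b
        assert s.atp == 1 and s.nadh == 2 and s.fd2e == -1
        assert (a * 3).nadh == Fraction(3, 2)
        assert (Fraction(1, 2) * a).atp == Fraction(1, 2)

    def test_exact_rational_fields(self):
        led = CofactorLedger(atp="1/3")
        assert led.atp == Fraction(1, 3)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            Reaction("bad", {"nad": 1})

    def test_electron_pair_tally(self):
        led = CofactorLedger(nadh=2, fd2e=-1, h2_formate=3, nadph=Fraction(1, 2))
        assert led.electron_pairs() == Fraction(9, 2)


class TestCationModel:
    def test_atp_per_cation_identity(self):
        for c in range(10, 16):
            m = CationModel(c, 2)
            assert m.atp_per_cation * c == 3  # exact

    @pytest.mark.parametrize(
        "c,r,expected",
        [(12, 2, Fraction(2)), (15, 5, Fraction(1)), (10, 2, Fraction(5, 3))],
    )
    def test_yield_ratio(self, c, r, expected):
        assert yield_ratio(CationModel(c, r)) == expected

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CationModel(9, 2)
        with pytest.raises(ValueError):
            CationModel(16, 2)
        with pytest.raises(ValueError):
            CationModel(10, 0)


class TestExportCost:
    def test_two_nadh_cost(self):
        # one forward Rnf conversion at r*3/C plus free Nfn pairing
        assert export_cost(2, 0, CationModel(10, 2)) == Fraction(-3, 5)

    def test_perfect_nfn_pairing_is_free(self):
        assert export_cost(1, 1, CationModel(10, 2)) == 0

    def test_fd2e_surplus_gains(self):
        assert export_cost(0, 2, CationModel(10, 2)) == Fraction(3, 5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            export_cost(-1, 0, CationModel())
        with pytest.raises(ValueError):
            export_cost(0, -1, CationModel())

    def test_sign_symmetry(self):
        m = CationModel(13, 3)
        for a, b in [(3, 0), (2, 1), (5, 2), (0, 4)]:
            assert export_cost(a, b, m) == -export_cost(b, a, m)

    @pytest.mark.parametrize("c,r", [(10, 2), (12, 1), (15, 5), (11, 3)])
    def test_agrees_with_brute_force_balancer(self, c, r):
        m = CationModel(c, r)
        for nadh, fd2e in itertools.product(range(7), repeat=2):
            assert export_cost(nadh, fd2e, m) == brute_force_export(nadh, fd2e, m)

    def test_fractional_surplus(self):
        # half an NADH surplus per substrate: a quarter conversion
        m = CationModel(10, 2)
        assert export_cost(Fraction(1, 2), 0, m) == -(Fraction(1, 2) / 2) * m.rnf_atp


def _pathway(name, reactions, multiplicity=1, substrate="s"):
    return Pathway(
        name=name,
        substrate=substrate,
        substrate_multiplicity=multiplicity,
        reactions=tuple((Reaction(rn, d), Fraction(m)) for rn, d, m in reactions),
    )


class TestNetAtp:
    def test_ethanol_oxidation_net(self):
        pw = _pathway(
            "ethanol",
            [
                ("adh", {"nadh": 1}, 1),
                ("aldh", {"nadh": 1}, 1),
                ("ack", {"atp": 1}, 1),
            ],
        )
        assert net_atp(pw, CationModel(10, 2), mode="net") == Fraction(2, 5)
        assert net_atp(pw, mode="gross") == 1

    def test_no_residuals_means_net_equals_gross(self):
        pw = _pathway(
            "balanced",
            [("ox", {"nadh": 1, "atp": 1}, 1), ("red", {"nadh": -1}, 1)],
        )
        m = CationModel(14, 4)
        assert net_atp(pw, m, "net") == net_atp(pw, m, "gross") == 1

    def test_symport_debit(self):
        pw = _pathway(
            "asp-like",
            [
                ("symport", {"cations": -1}, 1),
                ("mdh", {"nadh": 1}, 1),
                ("ofor", {"fd2e": 1}, 1),
                ("ack", {"atp": 1}, 1),
            ],
        )
        assert net_atp(pw, CationModel(10, 2), "net") == Fraction(7, 10)

    def test_unbalanced_ledger_names_species(self):
        pw = _pathway("sink", [("consume", {"nadh": -1}, 1)])
        with pytest.raises(UnbalancedLedgerError, match="nadh"):
            net_atp(pw, CationModel(), "net")
        pw = _pathway("pep-leak", [("pts", {"pep": -1}, 1)])
        with pytest.raises(UnbalancedLedgerError, match="pep"):
            net_atp(pw, CationModel(), "net")

    def test_net_requires_model_and_valid_mode(self):
        pw = _pathway("x", [("ack", {"atp": 1}, 1)])
        with pytest.raises(ValueError):
            net_atp(pw, None, "net")
        with pytest.raises(ValueError):
            net_atp(pw, CationModel(), "brut")

    def test_gross_additive_under_concatenation(self):
        a = _pathway("a", [("ack", {"atp": 1}, 2)], multiplicity=2)
        b = _pathway("b", [("pk", {"atp": 3}, 1)], multiplicity=1)
        combined = a.concat(b)
        assert combined.total_ledger().atp == a.total_ledger().atp + b.total_ledger().atp
        assert combined.substrate_multiplicity == 3


class TestFit:
    def test_printed_ratios_select_ten_and_two(self):
        res = fit_cation_model([1.49, 1.83])
        assert res.best == (10, 2)
        assert res.predicted_ratio == Fraction(5, 3)

    def test_degenerate_minimum_reported_and_tie_broken_lexicographically(self):
        # (10,2) and (15,3) predict the same ratio 5/3
        res = fit_cation_model([Fraction(5, 3)])
        assert res.loss == 0
        assert res.best == (10, 2)
        assert (15, 3) in res.degenerate_minima

    @pytest.mark.parametrize("c0,r0", [(11, 1), (13, 4), (14, 5), (12, 2)])
    def test_exact_recovery_of_in_grid_ratio(self, c0, r0):
        ratio = Fraction(c0, 3) / r0
        res = fit_cation_model([ratio])
        assert res.loss == 0
        assert res.predicted_ratio == ratio

    def test_loss_zero_iff_all_ratios_exact(self):
        res = fit_cation_model([Fraction(5, 3), Fraction(5, 3)])
        assert res.loss == 0
        res = fit_cation_model([Fraction(5, 3), Fraction(17, 10)])
        assert res.loss > 0

    def test_empty_ratios_rejected(self):
        with pytest.raises(ValueError):
            CationYieldModel([])

    def test_grid_is_exhaustive(self):
        res = fit_cation_model([1.5])
        assert len(res.grid) == 6 * 5
        assert res.loss == min(res.grid["loss"])

    def test_results_object_surface(self):
        res = CationYieldModel([1.49, 1.83]).fit()
        assert res.cation_model.c_subunits == 10
        assert res.resid.shape == (2,)
        text = res.summary()
        assert "best c-ring size C    : 10" in text
        assert "best Rnf cations r    : 2" in text

    def test_from_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"ratio": [1.49, 1.83]})
        assert CationYieldModel.from_dataframe(df).fit().best == (10, 2)
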
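import math

import numpy as np
import pytest

from famba.mass_balance import (
    MassBalanceError,
    MassBalanceInput,
    N3_PATHWAY,
    Pathway,
    apparent_enzyme_flux,
    fa_moles,
    mass_balance,
    net_intake,
    partition_chain,
    treatment_summary,
)
from famba.reference import ALA_MASS_BALANCE_UMOL, FEED_PROFILES
from famba.synthetic import forward_flux

ALA, SDA, ETA, EPA, DPA, DHA = N3_PATHWAY.nodes


class TestPathway:
    def test_default_chain_order(self):
        assert N3_PATHWAY.head == "18:3n-3"
        assert N3_PATHWAY.terminal == "22:6n-3"
        assert len(N3_PATHWAY.nodes) == 6

    def test_rejects_mixed_series_and_cycles(self):
        with pytest.raises(ValueError):
            Pathway((("18:3n-3", "18:2n-6", "x"),))
        with pytest.raises(ValueError):
            Pathway((("18:3n-3", "18:4n-3", "x"), ("18:4n-3", "18:3n-3", "y")))


class TestMoleConversion:
    def test_feed_ala_moles(self):
        # 131.4 g as-fed TOFX feed: 131.4 x 0.902 x 0.2425 x 865.6 x 0.188 / 278.44 x 1000
        moles = fa_moles(FEED_PROFILES["TOFX"], 131.4)
        assert moles[ALA] == pytest.approx(1.68e4, rel=0.005)

    def test_zero_mass(self):
        moles = fa_moles(FEED_PROFILES["TOFX"], 0.0)
        assert all(v == 0.0 for v in moles.values())

    def test_single_fa_mass_closure(self):
        from famba.fatty_acids import FAProfile, molar_mass, parse_shorthand

        prof = FAProfile("pure", {"16:0": 100.0}, total_fa_content=1000.0,
                         lipid_content=1.0, dry_matter=1.0)
        umol = fa_moles(prof, 1.0)["16:0"]
        # 1 g of pure palmitic acid
        assert umol * molar_mass(parse_shorthand("16:0")) / 1e6 == pytest.approx(1.0, rel=1e-12)

    def test_net_intake(self):
        assert net_intake(100.0, 100.0) == 100.0
        assert net_intake(100.0, 0.0) == 0.0
        assert net_intake(16800.0, 93.7) == pytest.approx(15741.6, abs=0.1)
        with pytest.raises(ValueError):
            net_intake(10.0, 101.0)


class TestPartitionIdentities:
    """The backward attribution must reproduce the published whole-body
    ALA partition identities from the treatment means."""

    @pytest.mark.parametrize("diet", ["FO", "FOPO", "TOFX"])
    def test_published_closure(self, diet):
        v = ALA_MASS_BALANCE_UMOL[diet]
        res = partition_chain(
            {ALA: v["net_intake"]},
            {ALA: v["accumulated"], EPA: v["bioconverted"]},
        )
        row = res.components.loc[ALA]
        assert row["bioconverted"] == pytest.approx(v["bioconverted"], abs=0.05)
        assert row["disappeared"] == pytest.approx(v["disappeared"], abs=0.11)
        assert row["oxidized"] == pytest.approx(v["oxidized"], abs=0.11)

    def test_fo_oxidation_clamped_to_zero(self):
        v = ALA_MASS_BALANCE_UMOL["FO"]
        res = partition_chain(
            {ALA: v["net_intake"]}, {ALA: v["accumulated"], EPA: v["bioconverted"]}
        )
        assert res.components.loc[ALA, "oxidized"] == 0.0
        assert any(fa == ALA and comp == "oxidized" for fa, comp, _ in res.clamping_events)

    def test_head_excess_raises(self):
        with pytest.raises(MassBalanceError, match="cannot be synthesised"):
            partition_chain({ALA: 100.0}, {ALA: 150.0})

    def test_negative_net_intake_rejected(self):
        with pytest.raises(MassBalanceError):
            partition_chain({ALA: -1.0}, {ALA: 0.0})

    def test_terminal_deficit_folds_into_oxidation(self):
        res = partition_chain({ALA: 100.0, DHA: 50.0}, {ALA: 100.0, DHA: -10.0})
        assert res.components.loc[DHA, "oxidized"] == pytest.approx(60.0)
        assert res.components.loc[DHA, "bioconverted"] == 0.0


class TestRoundTrip:
    def test_worked_example(self):
        app, truth = forward_flux(
            {ALA: 1000.0},
            {ALA: (0.6, 0.3, 0.1), SDA: (0, 0, 1), ETA: (0, 0, 1), EPA: (1, 0, 0)},
        )
        res = partition_chain({ALA: 1000.0}, app)
        row = res.components.loc[ALA]
        assert (row["accumulated"], row["oxidized"], row["bioconverted"]) == (600.0, 300.0, 100.0)

    def test_two_hundred_random_draws_recover_exactly(self):
        """Seeded draws in the identifiable regime (no downstream
        oxidation): the balance must recover every prescribed partition
        without triggering a clamp."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            net = {fa: float(rng.uniform(0, 2000)) for fa in N3_PATHWAY.nodes}
            fractions = {}
            for fa in N3_PATHWAY.nodes[:-1]:
                if fa == N3_PATHWAY.head:
                    raw = rng.dirichlet([1.0, 1.0, 1.0])
                    fractions[fa] = tuple(raw)
                else:
                    conv = float(rng.uniform(0, 1))
                    fractions[fa] = (1.0 - conv, 0.0, conv)
            fractions[N3_PATHWAY.terminal] = (1.0, 0.0, 0.0)
            app, truth = forward_flux(net, fractions)
            res = partition_chain(net, app)
            assert not res.clamping_events
            got = res.components.loc[truth.index, ["accumulated", "oxidized", "bioconverted"]]
            want = truth[["accumulated", "oxidized", "bioconverted"]]
            assert np.allclose(got.to_numpy(), want.to_numpy(), rtol=1e-9, atol=1e-8)

    def test_closure_invariant(self):
        rng = np.random.default_rng(5)
        net = {fa: float(rng.uniform(10, 1000)) for fa in N3_PATHWAY.nodes}
        app = {fa: float(rng.uniform(0, net[fa])) for fa in N3_PATHWAY.nodes}
        res = partition_chain(net, app)
        c = res.components
        total_supply = c["net_intake"] + c["flux_in"]
        closure = c["accumulated"] + c["disappeared"]
        assert np.allclose(closure, total_supply, rtol=1e-9)
        assert (c[["accumulated", "disappeared", "oxidized", "bioconverted"]] >= 0).all().all()

    def test_chain_conservation(self):
        """Moles attributed to onward conversion from the head equal the
        summed net appearances of all downstream nodes when those have
        no intake of their own."""
        rng = np.random.default_rng(11)
        app = {fa: float(rng.uniform(0, 50)) for fa in N3_PATHWAY.nodes[1:]}
        downstream_sum = sum(app.values())
        app[ALA] = 400.0
        res = partition_chain({ALA: 1000.0}, app)
        assert res.components.loc[ALA, "bioconverted"] == pytest.approx(downstream_sum)

    def test_scaling_property(self):
        net = {ALA: 1000.0, EPA: 50.0}
        app = {ALA: 600.0, EPA: 120.0}
        r1 = partition_chain(net, app)
        r2 = partition_chain({k: 3 * v for k, v in net.items()},
                             {k: 3 * v for k, v in app.items()})
        cols = ["accumulated", "disappeared", "oxidized", "bioconverted"]
        assert np.allclose(3 * r1.components[cols], r2.components[cols])
        for fa in (ALA, EPA):
            for comp in cols:
                p1, p2 = (r.percent_of_net_intake(fa, comp) for r in (r1, r2))
                assert p1 == pytest.approx(p2)


class TestFullBalanceFromProfiles:
    def test_simulated_tank_recovers_flux_truth(self, noiseless_trial):
        ds = noiseless_trial
        t = ds.tanks[0]
        res = mass_balance(
            MassBalanceInput(
                feed=ds.config.feed_profiles[t.diet],
                fi_g=t.fi_g,
                ad=ds.fa_ad[t.diet],
                initial_weight_g=t.wi_g,
                initial_profile=ds.initial_carcass,
                final_weight_g=t.wf_g,
                final_profile=ds.final_carcass[t.tank_id],
                days=t.days,
            )
        )
        truth = ds.ground_truth["tanks"][t.tank_id]["flux"]
        got = res.components.loc[truth.index, ["accumulated", "oxidized", "bioconverted"]]
        assert np.allclose(got.to_numpy(), truth[["accumulated", "oxidized", "bioconverted"]].to_numpy(), atol=1e-6)


class TestEnzymeFlux:
    def test_normalised_rate(self):
        res = partition_chain({ALA: 15742.2}, {ALA: 9228.0, SDA: 112.6})
        rates = apparent_enzyme_flux(res, 107.0, 214.1, 89)
        assert rates[(ALA, SDA)] == pytest.approx(7.9, abs=0.05)

    def test_zero_flux_and_linearity(self):
        res = partition_chain({ALA: 100.0}, {ALA: 100.0})
        rates = apparent_enzyme_flux(res, 100.0, 200.0, 89)
        assert all(v == 0.0 for v in rates.values())
        res2 = partition_chain({ALA: 1000.0}, {ALA: 500.0, SDA: 100.0})
        r_89 = apparent_enzyme_flux(res2, 100.0, 200.0, 89)
        r_178 = apparent_enzyme_flux(res2, 100.0, 200.0, 178)
        assert r_89[(ALA, SDA)] == pytest.approx(2 * r_178[(ALA, SDA)])


def test_treatment_summary_modes():
    results = {}
    for i, (net, acc) in enumerate([(1000.0, 900.0), (1100.0, 950.0), (900.0, 850.0)]):
        results[f"t{i}"] = partition_chain({ALA: net}, {ALA: acc})
    mor = treatment_summary(results, ALA, mode="mean_of_ratios")
    rom = treatment_summary(results, ALA, mode="ratio_of_means")
    assert mor.loc["net_intake", "mean"] == pytest.approx(1000.0)
    # mean of per-tank percentages differs from ratio of means
    assert mor.loc["accumulated_pct", "mean"] != pytest.approx(rom.loc["accumulated_pct", "mean"], abs=1e-6)
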
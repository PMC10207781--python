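"""Cost ledger: cent-exact accounting identities per strategy."""

from decimal import Decimal

import pytest

from waitline.costs import (
    CostComponents,
    Strategy,
    Tariffs,
    build_ledger,
    cost_variation,
    daily_cost,
    daily_margin,
    daily_revenue,
    eur,
    read_ledger_csv,
    screening_cost_horizon,
    unit_screening_cost,
    write_ledger_csv,
)

COMPONENTS = CostComponents()
TARIFFS = Tariffs()


def make_strategy(name="current", teams_day=2, teams_afternoon=0, waiting=32, **overrides):
    return Strategy(
        name=name,
        teams_day=teams_day,
        teams_afternoon=teams_afternoon,
        mammographs=2,
        ultrasounds=3,
        reporting_stations=3,
        exams_per_day=20 * (teams_day + teams_afternoon),
        waiting_months=waiting,
        patients_3y=30000,
        overrides={k: eur(v) for k, v in overrides.items()},
    )


class TestDailyCost:
    def test_two_team_composition_close_to_accounts(self):
        # 2 x 608.28 + 128.59 + 92.65 + 30.82 = 1,468.62; the accounts
        # print 1,468.61 — composition agrees within 2 cents
        composed = daily_cost(make_strategy(), COMPONENTS)
        assert composed == Decimal("1468.62")
        assert abs(composed - Decimal("1468.61")) <= Decimal("0.02")

    def test_zero_teams_zero_shared_costs(self):
        empty = CostComponents(
            staff_daily_per_team=eur(0),
            goods_services_daily=eur(0),
            overheads_daily=eur(0),
            equipment_daily=eur(0),
        )
        assert daily_cost(make_strategy(teams_day=0), empty) == Decimal("0.00")

    def test_homogeneous_degree_one(self):
        doubled = CostComponents(
            staff_daily_per_team=COMPONENTS.staff_daily_per_team * 2,
            goods_services_daily=COMPONENTS.goods_services_daily * 2,
            overheads_daily=COMPONENTS.overheads_daily * 2,
            equipment_daily=COMPONENTS.equipment_daily * 2,
        )
        s = make_strategy()
        assert daily_cost(s, doubled) == 2 * daily_cost(s, COMPONENTS)

    def test_override_wins(self):
        assert daily_cost(make_strategy(), COMPONENTS, override=eur("2715.99")) == Decimal(
            "2715.99"
        )


class TestDailyRevenue:
    def test_blended_tariff_per_exam(self):
        # 87.00 + 0.35 x 36.15 = 99.6525 EUR per exam
        assert TARIFFS.blended_per_exam == Decimal("99.6525")

    @pytest.mark.parametrize(
        "teams_day, teams_afternoon, expected",
        [(2, 0, "3986.10"), (3, 0, "5979.15"), (0, 0, "0.00")],
    )
    def test_exact_daily_revenues(self, teams_day, teams_afternoon, expected):
        s = make_strategy(teams_day=teams_day, teams_afternoon=teams_afternoon)
        assert daily_revenue(s, TARIFFS) == Decimal(expected)

    def test_80_exam_revenue_requires_override(self):
        # the 80-exam accounts figure (7,936.05) undercuts the blend
        s = make_strategy(teams_day=2, teams_afternoon=2)
        assert daily_revenue(s, TARIFFS) == Decimal("7972.20")
        assert daily_revenue(s, TARIFFS, override=eur("7936.05")) == Decimal("7936.05")


class TestLedgerArithmetic:
    @pytest.mark.parametrize(
        "revenue, cost, expected",
        [
            ("3986.10", "1468.61", "2517.49"),
            ("5979.15", "2715.99", "3263.16"),
            ("7936.05", "2906.40", "5029.65"),
            ("123.45", "123.45", "0.00"),
        ],
    )
    def test_margin_exact_to_the_cent(self, revenue, cost, expected):
        assert daily_margin(eur(revenue), eur(cost)) == Decimal(expected)

    @pytest.mark.parametrize(
        "cost, exams, expected",
        [("2715.99", 60, "45.27"), ("2906.40", 80, "36.33"), ("0.00", 40, "0.00")],
    )
    def test_unit_screening_cost(self, cost, exams, expected):
        assert unit_screening_cost(eur(cost), exams) == Decimal(expected)

    def test_unit_cost_zero_exams_rejected(self):
        with pytest.raises(ZeroDivisionError):
            unit_screening_cost(eur("100.00"), 0)

    @pytest.mark.parametrize(
        "daily, total",
        [("2715.99", "1978238.64"), ("2906.40", "2116927.08")],
    )
    def test_three_year_projection_consistent_with_horizon(self, daily, total):
        projected = screening_cost_horizon(eur(daily), eur("728.37"))
        assert abs(projected - eur(total)) / eur(total) < Decimal("0.0002")

    def test_zero_daily_cost_projects_to_zero(self):
        assert screening_cost_horizon(eur("0"), eur("728.37")) == Decimal("0.00")

    @pytest.mark.parametrize(
        "cost, reference, expected",
        [
            ("1978238.64", "1069687.68", "908550.96"),
            ("2116927.08", "1069687.68", "1047239.40"),
            ("5.00", "5.00", "0.00"),
        ],
    )
    def test_cost_variation_exact(self, cost, reference, expected):
        assert cost_variation(eur(cost), eur(reference)) == Decimal(expected)


class TestBuildLedger:
    def test_ledger_identity_and_flags(self):
        s = make_strategy(daily_cost="1468.61", cost_3y="1069687.68", unit_cost="34.42")
        ledger = build_ledger(s, COMPONENTS, TARIFFS)
        assert ledger.daily_margin == ledger.daily_revenue - ledger.daily_cost
        # the computed unit cost (36.72) is reported, the printed 34.42 flagged
        assert ledger.unit_screening_cost == Decimal("36.72")
        assert any("34.42" in f for f in ledger.flags)

    def test_overrides_can_be_disabled(self):
        s = make_strategy(daily_cost="9999.99")
        ledger = build_ledger(s, COMPONENTS, TARIFFS, use_overrides=False)
        assert ledger.daily_cost == Decimal("1468.62")
        assert ledger.flags == ()

    def test_csv_round_trip_preserves_cents(self, tmp_path):
        ledgers = [
            build_ledger(make_strategy(), COMPONENTS, TARIFFS),
            build_ledger(
                make_strategy(name="22-month", teams_day=3, waiting=22, daily_cost="2715.99"),
                COMPONENTS,
                TARIFFS,
            ),
        ]
        path = tmp_path / "ledger.csv"
        write_ledger_csv(ledgers, path)
        back = read_ledger_csv(path)
        for a, b in zip(ledgers, back):
            assert (a.strategy, a.daily_revenue, a.daily_cost, a.daily_margin) == (
                b.strategy,
                b.daily_revenue,
                b.daily_cost,
                b.daily_margin,
            )
            assert a.screening_cost_3y == b.screening_cost_3y
            assert a.unit_screening_cost == b.unit_screening_cost


class TestStrategyInvariants:
    def test_capacity_follows_from_teams(self):
        s = Strategy(
            name="bad",
            teams_day=2,
            teams_afternoon=0,
            mammographs=2,
            ultrasounds=3,
            reporting_stations=3,
            exams_per_day=50,  # != 20 x 2
            waiting_months=32,
            patients_3y=30000,
        )
        assert any("exams_per_day" in issue for issue in s.issues())
        assert make_strategy().issues() == []
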
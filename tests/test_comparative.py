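"""Comparative database aggregation and the divergence correlation."""

import numpy as np
import pytest

from armrec.comparative import (
    DbRecord,
    DivergencePoint,
    GroupPoint,
    attach_divergence,
    clade_average,
    collapse_duplicate_species,
    db_record_rate,
    divergence_correlation,
    group_means,
    leave_one_out_sensitivity,
)
from armrec.cyto_rates import round_half_up
from armrec.simulate import DbSimParams, GroupSpec, simulate_db


def rec(species, rate=0.5, genome=2000.0, order="O", superorder="S", method="chiasmata"):
    return db_record_rate(
        DbRecord(
            species_id=species,
            order_label=order,
            superorder_label=superorder,
            method=method,
            genome_mbp=genome,
            crossover_count=rate * genome / 50.0,
        )
    )


class TestDbRecordRate:
    def test_round_number_chiasmata(self):
        r = db_record_rate(
            DbRecord("sp", "O", "S", "chiasmata", genome_mbp=2000.0, crossover_count=20.0)
        )
        assert r.map_cm == pytest.approx(1000.0)
        assert r.rate_cm_per_mb == pytest.approx(0.50)
        assert r.included

    def test_mlh1_armadillo_value(self):
        r = db_record_rate(
            DbRecord("Dhy", "Cingulata", "Xenarthra", "mlh1", genome_mbp=4782.0, crossover_count=39.2)
        )
        assert round_half_up(r.rate_cm_per_mb, 2) == 0.41

    def test_linkage_without_deep_coverage_excluded(self):
        r = db_record_rate(
            DbRecord("sp", "O", "S", "linkage", genome_mbp=3500.0, map_cm=1400.0)
        )
        assert r.rate_cm_per_mb == pytest.approx(0.40)
        assert not r.included
        deep = db_record_rate(
            DbRecord("sp", "O", "S", "linkage", genome_mbp=3500.0, map_cm=1400.0, deep_coverage=True)
        )
        assert deep.included

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError, match="method"):
            DbRecord("sp", "O", "S", "foci", genome_mbp=3000.0, crossover_count=20.0)
        with pytest.raises(ValueError, match="positive"):
            DbRecord("sp", "O", "S", "mlh1", genome_mbp=0.0, crossover_count=20.0)
        with pytest.raises(ValueError, match="neither"):
            db_record_rate(DbRecord("sp", "O", "S", "mlh1", genome_mbp=3000.0))


class TestGrouping:
    def test_single_record_group_is_identity(self):
        points = group_means([rec("a", rate=0.37)])
        assert len(points) == 1
        assert points[0].mean_rate_cm_per_mb == pytest.approx(0.37)
        assert points[0].n_species == 1

    def test_unweighted_mean_and_conservation(self):
        records = [rec(f"a{i}", rate=r, order="A") for i, r in enumerate([0.4, 0.6])]
        records += [rec(f"b{i}", rate=r, order="B") for i, r in enumerate([0.2, 0.3, 0.4])]
        points = group_means(records)
        by_label = {p.group_label: p for p in points}
        assert by_label["A"].mean_rate_cm_per_mb == pytest.approx(0.5)
        assert by_label["B"].mean_rate_cm_per_mb == pytest.approx(0.3)
        assert sum(p.n_species for p in points) == len(records)

    def test_excluded_records_do_not_count(self):
        shallow = db_record_rate(
            DbRecord("x", "A", "S", "linkage", genome_mbp=3000.0, map_cm=1200.0)
        )
        points = group_means([rec("a", rate=0.4, order="A"), shallow])
        assert points[0].n_species == 1
        assert points[0].mean_rate_cm_per_mb == pytest.approx(0.4)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        records = [rec(f"s{i}", rate=rng.uniform(0.2, 1.0), order=f"G{i % 4}") for i in range(12)]
        a = group_means(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        b = {p.group_label: p for p in group_means(shuffled)}
        for p in a:
            assert b[p.group_label].mean_rate_cm_per_mb == pytest.approx(p.mean_rate_cm_per_mb)
            assert b[p.group_label].n_species == p.n_species

    def test_duplicate_species_collapse(self):
        records = [rec("dup", rate=0.4), rec("dup", rate=0.6, method="mlh1"), rec("solo", rate=0.5)]
        merged = collapse_duplicate_species(records)
        assert len(merged) == 2
        dup = next(r for r in merged if r.species_id == "dup")
        assert dup.rate_cm_per_mb == pytest.approx(0.5)


def monotone_points(n=6, reverse=False):
    """Rates strictly increasing toward recency (younger clade, higher rate)."""
    pts = []
    for i in range(n):
        rate = 0.2 + 0.1 * (i if not reverse else n - 1 - i)
        pts.append(
            GroupPoint(
                group_label=f"g{i}",
                mean_rate_cm_per_mb=rate,
                mean_map_cm=rate * 3000.0,
                n_species=2,
                divergence_mya=200.0 - 20.0 * i,
            )
        )
    return pts


class TestDivergenceCorrelation:
    def test_monotone_construction_and_sign_convention(self):
        res = divergence_correlation(monotone_points())
        assert res.rho == pytest.approx(1.0)  # younger => higher rate => positive
        res_rev = divergence_correlation(monotone_points(reverse=True))
        assert res_rev.rho == pytest.approx(-1.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            divergence_correlation(monotone_points(2))
        with pytest.raises(ValueError, match="divergence"):
            divergence_correlation(
                [GroupPoint("g", 0.4, 1200.0, 1)] + monotone_points(3)
            )

    def test_rank_invariance_under_common_scaling(self):
        pts = monotone_points(7)
        scaled = [
            GroupPoint(p.group_label, p.mean_rate_cm_per_mb, 3.7 * p.mean_map_cm,
                       p.n_species, p.divergence_mya)
            for p in pts
        ]
        a = divergence_correlation(pts, "map_cm")
        b = divergence_correlation(scaled, "map_cm")
        assert b.rho == pytest.approx(a.rho)
        assert b.p_value == pytest.approx(a.p_value)

    def test_attach_divergence_requires_all_groups(self):
        points = group_means([rec("a", order="A")])
        with pytest.raises(ValueError, match="divergence"):
            attach_divergence(points, {"B": 50.0})
        attached = attach_divergence(points, [DivergencePoint("A", 80.0)])
        assert attached[0].divergence_mya == 80.0


class TestLeaveOneOut:
    def test_monotone_set_stays_perfect(self):
        df = leave_one_out_sensitivity(monotone_points(7))
        assert (df["rho"] >= 1.0 - 1e-12).all()
        assert not df["significance_changed"].any()

    def test_extreme_group_drives_trend(self):
        # six clades nearly uncorrelated with recency plus one old, very low
        # clade that anchors the full-set correlation
        rates = [0.30, 0.62, 0.55, 0.66, 0.58, 0.64, 0.60]
        mya = [200, 90, 85, 80, 75, 70, 65]
        pts = [
            GroupPoint(f"g{i}", r, r * 3000.0, 1, m)
            for i, (r, m) in enumerate(zip(rates, mya))
        ]
        full = divergence_correlation(pts)
        dropped = divergence_correlation(pts[1:])
        assert dropped.rho < full.rho
        df = leave_one_out_sensitivity(pts)
        assert df.loc[df["dropped_group"] == "g0", "rho"].iloc[0] == pytest.approx(dropped.rho)

    def test_constructed_fixture_flags_exactly_the_old_clades(self):
        """When the two oldest clades carry the lowest rates and the younger
        clades are jumbled, dropping either old clade breaks significance and
        dropping any younger one does not."""
        young = [0.58, 0.55, 0.62, 0.64, 0.68, 0.66, 0.60]
        groups = [GroupSpec("old0", 160.0, 0.28), GroupSpec("old1", 120.0, 0.33)]
        groups += [GroupSpec(f"y{i}", 90.0 - 5.0 * i, r) for i, r in enumerate(young)]
        records, div = simulate_db(
            DbSimParams(groups=tuple(groups), species_per_group=1, rate_noise_sd=0.0, seed=0)
        )
        pts = attach_divergence(group_means(records), div)
        df = leave_one_out_sensitivity(pts)
        flagged = set(df.loc[df["significance_changed"], "dropped_group"])
        assert flagged == {"old0", "old1"}

    def test_minimum_group_count(self):
        with pytest.raises(ValueError):
            leave_one_out_sensitivity(monotone_points(3))


class TestCladeAverage:
    def test_single_species_clade(self):
        assert clade_average([rec("a", rate=0.37, order="A")], "A") == pytest.approx(0.37)

    def test_generator_mean_recovery(self):
        rng = np.random.default_rng(9)
        true_mean = 0.62
        records = [rec(f"s{i}", rate=true_mean + rng.normal(0, 0.05), order="Euth") for i in range(200)]
        assert clade_average(records, "Euth") == pytest.approx(true_mean, abs=0.02)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            clade_average([rec("a", order="A")], "Nope")
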
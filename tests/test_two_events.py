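"""Two-event model algebra: catalogues, closed forms and the correspondence."""

import numpy as np
import pytest

from wgmfrac import (
    DupFirstParams,
    TripFirstParams,
    catalogue_expectations,
    constrained_correspondence,
    constrained_correspondence_inverse,
    constrained_reparam,
    constrained_reparam_inverse,
    constrained_trip_reparam,
    correspondence_solve,
    dup_first_expectations,
    dup_to_trip,
    enumerate_two_event_trees,
    trip_first_expectations,
    trip_first_expectations_xy,
    trip_to_dup,
    unpaired_difference_grid,
    unpaired_per_ancestral_gene,
    unpaired_ratio,
    valid_region_scan,
)


def random_dup_params(rng):
    u = rng.uniform(0.02, 0.6)
    v = rng.uniform(0.0, 1 - u - 0.02)
    w = rng.uniform(0.02, 0.98)
    return DupFirstParams(w=w, u=u, v=v)


def random_trip_params(rng):
    p3 = rng.uniform(0.02, 0.6)
    p2 = rng.uniform(0.0, 1 - p3 - 0.02)
    z = rng.uniform(0.02, 0.98)
    return TripFirstParams(z=z, p3=p3, p2=p2)


class TestExpectations:
    @pytest.mark.parametrize(
        "u, v, w, expected",
        [
            (1e-9, 0.0, 0.3, (0.3, 0.0, 0.7)),  # u,v -> 0: only the duplication acts
            (1 - 1e-9, 0.0, 0.3, (2.7, 3.9, 0.0)),  # u -> 1: (9w, 3w+3, 0)
        ],
    )
    def test_dup_first_limits(self, u, v, w, expected):
        got = dup_first_expectations(DupFirstParams(w=w, u=u, v=v))
        assert got == pytest.approx(expected, abs=1e-6)

    def test_trip_first_limits(self):
        got = trip_first_expectations(TripFirstParams(z=0.4, p3=1e-12, p2=0.0))
        assert got == pytest.approx((0.0, 0.4, 0.6), abs=1e-9)

    def test_validation_rejects_invalid_points(self):
        with pytest.raises(ValueError):
            DupFirstParams(w=0.5, u=0.7, v=0.4)
        with pytest.raises(ValueError):
            TripFirstParams(z=1.2, p3=0.1, p2=0.1)


class TestTreeCatalogue:
    def test_dup_catalogue_contains_two_w_v_u(self):
        recs = enumerate_two_event_trees("dup_first")
        target = [r for r in recs if str(r.monomial) == "2*u*v*w"]
        assert len(target) == 1
        assert target[0].multiplicity == 2

    def test_probabilities_sum_to_one_at_random_points(self, rng):
        for order, sampler in [
            ("dup_first", random_dup_params),
            ("trip_first", random_trip_params),
        ]:
            recs = enumerate_two_event_trees(order)
            for _ in range(100):
                params = sampler(rng)
                from wgmfrac.two_events import _factor_values

                total = sum(r.monomial.evaluate(_factor_values(order, params)) for r in recs)
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_closed_forms_match_catalogue(self, rng):
        for _ in range(100):
            dp = random_dup_params(rng)
            assert np.allclose(
                dup_first_expectations(dp), catalogue_expectations("dup_first", dp),
                atol=1e-12,
            )
            tp = random_trip_params(rng)
            assert np.allclose(
                trip_first_expectations(tp), catalogue_expectations("trip_first", tp),
                atol=1e-12,
            )

    def test_printed_symbol_mapping(self, rng):
        """The printed trip-first formulas hold with y = P(3 survive)."""
        for _ in range(50):
            tp = random_trip_params(rng)
            assert np.allclose(
                trip_first_expectations(tp),
                trip_first_expectations_xy(x=tp.p2, y=tp.p3, z=tp.z),
                atol=1e-15,
            )


class TestCorrespondence:
    def test_roots_have_tiny_residuals_and_match_triples(self, rng):
        found = 0
        for _ in range(200):
            dp = random_dup_params(rng)
            res = dup_to_trip(dp)
            for root in res.roots:
                if root.classification == "valid":
                    found += 1
                    assert root.residual < 1e-10
                    assert np.allclose(
                        trip_first_expectations(root.params),
                        dup_first_expectations(dp),
                        atol=1e-9,
                    )
        assert found > 0

    def test_reverse_direction_round_trip(self):
        dp = DupFirstParams(u=0.1, v=0.1, w=0.4)
        tp = dup_to_trip(dp).valid[0]
        back = trip_to_dup(tp).valid
        assert any(
            np.allclose((b.u, b.v, b.w), (dp.u, dp.v, dp.w), atol=1e-8) for b in back
        )

    def test_far_outside_volume_has_no_valid_root(self):
        res = dup_to_trip(DupFirstParams(w=0.95, u=0.9, v=0.05))
        assert res.valid == ()

    def test_dispatch(self):
        dp = DupFirstParams(u=0.1, v=0.1, w=0.4)
        assert correspondence_solve(dp).source is dp

    def test_region_scan_nonempty_and_strictly_smaller(self):
        scan = valid_region_scan(0.1)
        n_valid = int(scan.has_counterpart.sum())
        assert 0 < n_valid < len(scan.points)

    def test_scan_labels_stable_under_refinement(self):
        """Away from the region boundary, halving the step flips no label."""
        coarse = valid_region_scan(0.1)
        fine = valid_region_scan(0.05)
        fine_map = {tuple(np.round(p, 6)): l for p, l in zip(fine.points,
                                                            fine.has_counterpart)}
        neighbours = [
            (du, dv, dw)
            for du in (-0.1, 0, 0.1) for dv in (-0.1, 0, 0.1) for dw in (-0.1, 0, 0.1)
        ]
        for p, label in zip(coarse.points, coarse.has_counterpart):
            key = tuple(np.round(p, 6))
            if key not in fine_map:
                continue
            same = [
                fine_map.get(tuple(np.round(p + d, 6)))
                for d in neighbours
                if fine_map.get(tuple(np.round(p + d, 6))) is not None
            ]
            if all(s == label for s in same):  # interior point: all coarse
                assert fine_map[key] == label  # neighbours agree -> stable


class TestConstrainedModel:
    def test_reparam_examples(self):
        assert constrained_reparam(0.5) == pytest.approx((1 / 7, 3 / 7), abs=1e-15)
        u, v = constrained_reparam(1 - 1e-9)
        assert (u, v) == pytest.approx((1.0, 0.0), abs=1e-6)
        u, v = constrained_reparam(1e-9)
        assert (u, v) == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_reparam_inverse(self, rng):
        for s in rng.uniform(0.01, 0.99, size=20):
            u, v = constrained_reparam(s)
            assert constrained_reparam_inverse(u, v) == pytest.approx(s, abs=1e-12)

    def test_reparam_outside_domain(self):
        with pytest.raises(ValueError):
            constrained_reparam(1.5)

    def test_constrained_dup_triple_identity(self, rng):
        """Substituting the one-parameter law into the dup-first closed form
        gives E(t1 pairs) = 9w/(3-3s+s^2)^2 etc."""
        for _ in range(50):
            s = rng.uniform(0.02, 0.98)
            w = rng.uniform(0.02, 0.98)
            u, v = constrained_reparam(s)
            d = 3 * (1 - s) + s * s
            got = dup_first_expectations(DupFirstParams(w=w, u=u, v=v))
            assert got.t1_pairs == pytest.approx(9 * w / d**2, abs=1e-12)
            assert got.t2_pairs == pytest.approx(3 * s * (1 + w) / d, abs=1e-12)
            assert got.unpaired == pytest.approx(3 * (1 - w) * (1 - s) ** 2 / d, abs=1e-12)

    def test_constrained_trip_triple_identity(self, rng):
        for _ in range(50):
            h = rng.uniform(0.02, 0.98)
            z = rng.uniform(0.02, 0.98)
            p3, p2 = constrained_trip_reparam(h)
            d = 3 * (1 - h) + h * h
            got = trip_first_expectations(TripFirstParams(z=z, p3=p3, p2=p2))
            assert got.t1_pairs == pytest.approx(3 * h * (1 + z) ** 2 / d, abs=1e-12)
            assert got.t2_pairs == pytest.approx(3 * z / d, abs=1e-12)

    def test_round_trip_on_grid(self):
        for s in np.arange(0.1, 1.0, 0.2):
            for w in np.arange(0.1, 1.0, 0.2):
                m = constrained_correspondence(float(s), float(w))
                assert m.residual < 1e-10
                s2, w2 = constrained_correspondence_inverse(m.h, m.z)
                assert abs(s2 - s) < 1e-8 and abs(w2 - w) < 1e-8

    def test_matched_points_share_pair_expectations(self):
        m = constrained_correspondence(0.4, 0.5)
        u, v = constrained_reparam(m.s)
        p3, p2 = constrained_trip_reparam(m.h)
        dup = dup_first_expectations(DupFirstParams(w=m.w, u=u, v=v))
        trip = trip_first_expectations(TripFirstParams(z=m.z, p3=p3, p2=p2))
        assert dup.t1_pairs == pytest.approx(trip.t1_pairs, abs=1e-10)
        assert dup.t2_pairs == pytest.approx(trip.t2_pairs, abs=1e-10)
        # ... but generally disagree on unpaired genes: the discrimination lever
        assert abs(dup.unpaired - trip.unpaired) == pytest.approx(
            abs(m.unpaired_difference), abs=1e-12
        )
        assert m.unpaired_difference != 0.0

    def test_unpaired_difference_changes_sign(self):
        _, _, D = unpaired_difference_grid(0.05)
        assert D.min() < 0 < D.max()


class TestUnpairedDiagnostic:
    def test_expression_dispatch(self):
        dp = DupFirstParams(w=0.5, u=0.1, v=0.2)
        assert unpaired_per_ancestral_gene("dup_first", dp) == pytest.approx(
            0.5 * 0.7, abs=1e-15
        )

    def test_full_survival_leaves_none_unpaired(self):
        dp = DupFirstParams(w=1 - 1e-12, u=0.1, v=0.2)
        assert unpaired_per_ancestral_gene("dup_first", dp) == pytest.approx(0.0, abs=1e-9)

    def test_observed_ratios(self):
        assert round(unpaired_ratio(17751, 25000), 2) == 0.71
        assert round(unpaired_ratio(17751, 29000), 2) == 0.61
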
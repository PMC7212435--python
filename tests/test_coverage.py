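import datetime
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smokedays as sd
from smokedays.coverage import point_in_polygon, point_indicators

from conftest import UNIT_SQUARE, square_plume

DAY = datetime.date(2017, 10, 11)


# --- independent winding-number oracle (never shares code with the package)


def winding_number_inside(pt, ring):
    """Nonzero winding number test over one closed ring."""
    px, py = pt
    wn = 0
    n = len(ring) - 1 if ring[0] == ring[-1] else len(ring)
    for i in range(n):
        ax, ay = ring[i]
        bx, by = ring[(i + 1) % len(ring)] if ring[0] != ring[-1] else ring[i + 1]
        if ay <= py:
            if by > py and (bx - ax) * (py - ay) - (px - ax) * (by - ay) > 0:
                wn += 1
        elif by <= py and (bx - ax) * (py - ay) - (px - ax) * (by - ay) < 0:
            wn -= 1
    return wn != 0


@pytest.mark.parametrize(
    "pt, expected",
    [
        ((0.5, 0.5), True),   # interior
        ((2.0, 2.0), False),  # exterior
        ((1.0, 0.5), True),   # edge — boundary counts as inside
        ((0.0, 0.0), True),   # vertex
        ((0.5, 1.0), True),   # top edge
        ((-0.001, 0.5), False),
    ],
)
def test_unit_square_containment(pt, expected):
    assert point_in_polygon(pt, UNIT_SQUARE) is expected


def test_matches_winding_oracle_on_random_polygons():
    """Even-odd equals winding number for simple polygons, off the boundary."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        k = 12
        angles = np.sort(rng.uniform(0, 2 * math.pi, k))
        radii = rng.uniform(0.5, 2.0, k)  # star-shaped simple 12-gon
        ring = tuple(
            (float(r * math.cos(a)), float(r * math.sin(a)))
            for r, a in zip(radii, angles)
        )
        ring = ring + (ring[0],)
        pts = rng.uniform(-2.5, 2.5, size=(1000, 2))
        for px, py in pts:
            assert point_in_polygon((px, py), (ring,)) == winding_number_inside(
                (px, py), ring
            )


def test_self_intersecting_ring_uses_even_odd_rule():
    # bowtie: two triangles sharing the crossing point (0.5, 0.5)
    bowtie = (((0.0, 0.0), (1.0, 1.0), (1.0, 0.0), (0.0, 1.0), (0.0, 0.0)),)
    assert point_in_polygon((0.25, 0.5), bowtie)       # left lobe
    assert point_in_polygon((0.75, 0.5), bowtie)       # right lobe
    assert not point_in_polygon((0.5, 0.75), bowtie)   # outside by even-odd
    assert not point_in_polygon((0.5, 0.25), bowtie)


def test_nested_rings_even_odd_hole():
    outer = ((0.0, 0.0), (4.0, 0.0), (4.0, 4.0), (0.0, 4.0), (0.0, 0.0))
    inner = ((1.0, 1.0), (3.0, 1.0), (3.0, 3.0), (1.0, 3.0), (1.0, 1.0))
    poly = (outer, inner)
    assert point_in_polygon((0.5, 0.5), poly)        # in outer only
    assert not point_in_polygon((2.0, 2.0), poly)    # inside both -> hole
    assert point_in_polygon((1.0, 2.0), poly)        # on inner boundary


def test_flatten_partitions_by_density():
    plumes = [
        square_plume(sd.Density.LIGHT, 0, 2, DAY),
        square_plume(sd.Density.LIGHT, 1, 3, DAY),
        square_plume(sd.Density.HEAVY, 0, 1, DAY),
    ]
    cov = sd.flatten_day(plumes, DAY)
    assert len(cov.polygons(sd.Density.LIGHT)) == 2
    assert cov.polygons(sd.Density.MEDIUM) == ()  # present but empty
    assert len(cov.polygons(sd.Density.HEAVY)) == 1


def test_flatten_empty_day():
    cov = sd.flatten_day([], DAY)
    assert all(cov.polygons(d) == () for d in sd.Density)


def test_flatten_rejects_mismatched_date():
    plume = square_plume(sd.Density.LIGHT, 0, 1, DAY)
    with pytest.raises(ValueError, match="flatten"):
        sd.flatten_day([plume], DAY + datetime.timedelta(days=1))


def test_overlapping_same_density_is_still_one():
    cov = sd.flatten_day(
        [square_plume(sd.Density.LIGHT, 0, 2, DAY),
         square_plume(sd.Density.LIGHT, 1, 3, DAY)], DAY
    )
    ind = point_indicators((1.5, 1.5), cov)  # inside both light plumes
    assert ind == sd.SmokeIndicators(light=1, medium=0, heavy=0)


def test_densities_evaluated_independently():
    cov = sd.flatten_day(
        [square_plume(sd.Density.LIGHT, 0, 2, DAY),
         square_plume(sd.Density.HEAVY, 1, 3, DAY)], DAY
    )
    assert point_indicators((1.5, 1.5), cov) == sd.SmokeIndicators(1, 0, 1)
    assert point_indicators((10.0, 10.0), cov) == sd.SmokeIndicators(0, 0, 0)


@pytest.mark.parametrize(
    "ind, expected",
    [((1, 0, 1), 3), ((0, 0, 0), 0), ((1, 1, 0), 2), ((1, 0, 0), 1),
     ((0, 1, 1), 3), ((1, 1, 1), 3), ((0, 1, 0), 2), ((0, 0, 1), 3)],
)
def test_max_density_ordering(ind, expected):
    assert sd.max_density(sd.SmokeIndicators(*ind)) == expected


def _random_coverage(seed):
    spec = sd.PlumeDaySpec(
        counts={sd.Density.LIGHT: 3, sd.Density.MEDIUM: 2, sd.Density.HEAVY: 2},
        concave=seed % 2 == 1,
    )
    return sd.generate_plume_day(DAY, spec, seed)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_indicators_equal_per_plume_or_oracle(seed):
    """Flattened queries equal the brute-force per-plume OR."""
    plumes = _random_coverage(seed)
    cov = sd.flatten_day(plumes, DAY)
    rng = np.random.default_rng(seed + 1)
    pts = np.column_stack([
        rng.uniform(-126, -101, 100), rng.uniform(31, 50, 100)
    ])
    for px, py in pts:
        expected = {d: 0 for d in sd.Density}
        for p in plumes:
            if point_in_polygon((px, py), p.geometry):
                expected[p.density] = 1
        assert point_indicators((px, py), cov) == sd.SmokeIndicators(
            expected[sd.Density.LIGHT],
            expected[sd.Density.MEDIUM],
            expected[sd.Density.HEAVY],
        )


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_bbox_prefilter_is_observationally_identical(seed):
    cov = sd.flatten_day(_random_coverage(seed), DAY)
    rng = np.random.default_rng(seed)
    for _ in range(200):
        pt = (float(rng.uniform(-130, -95)), float(rng.uniform(28, 52)))
        assert point_indicators(pt, cov, use_bbox_prefilter=True) == \
            point_indicators(pt, cov, use_bbox_prefilter=False)


def test_flatten_idempotent_and_order_invariant():
    plumes = _random_coverage(5)
    cov = sd.flatten_day(plumes, DAY)
    again = sd.flatten_day(
        [sd.PlumeRecord(DAY, d, g, d.name.lower())
         for d in sd.Density for g in cov.polygons(d)], DAY
    )
    assert again.per_density == cov.per_density

    reversed_cov = sd.flatten_day(list(reversed(plumes)), DAY)
    rng = np.random.default_rng(0)
    for _ in range(100):
        pt = (float(rng.uniform(-126, -101)), float(rng.uniform(31, 50)))
        assert point_indicators(pt, cov) == point_indicators(pt, reversed_cov)


def test_adding_a_plume_is_monotone():
    base = [square_plume(sd.Density.LIGHT, 0, 2, DAY)]
    extra = base + [square_plume(sd.Density.MEDIUM, -1, 5, DAY)]
    cov0, cov1 = sd.flatten_day(base, DAY), sd.flatten_day(extra, DAY)
    for pt in [(1.0, 1.0), (3.0, 3.0), (9.0, 9.0), (0.0, 0.0)]:
        before, after = point_indicators(pt, cov0), point_indicators(pt, cov1)
        assert all(b <= a for b, a in zip(before, after))
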
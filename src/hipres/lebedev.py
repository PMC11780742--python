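"""Lebedev quadrature grids on the unit sphere.

Angular point sets with octahedral symmetry that integrate spherical
polynomials exactly up to a rule-specific degree.  They are the standard
discretization for atom-centered molecular surfaces: each grid point supplies
a surface direction and a quadrature weight (weights sum to 1, so a sphere of
radius r gets total area 4*pi*r^2).

The rules are built from symmetry orbits of the octahedral group; each rule is
a short table of orbit parameters and weights.  Every table shipped here is
verified by the test suite against the closed-form sphere averages of
monomials up to the rule's design degree.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["available_orders", "lebedev_grid", "RULE_DEGREE"]


def _orbit_points(code: int, a: float | None, b: float | None) -> np.ndarray:
    """Points of one octahedral symmetry orbit (unit vectors)."""
    pts: set[tuple[float, float, float]] = set()

    def add(x: float, y: float, z: float) -> None:
        for sx in (1.0, -1.0):
            for sy in (1.0, -1.0):
                for sz in (1.0, -1.0):
                    pts.add((round(sx * x, 15), round(sy * y, 15), round(sz * z, 15)))

    if code == 1:
        for perm in ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)):
            add(*perm)
    elif code == 2:
        c = 1.0 / math.sqrt(2.0)
        add(0.0, c, c); add(c, 0.0, c); add(c, c, 0.0)
    elif code == 3:
        c = 1.0 / math.sqrt(3.0)
        add(c, c, c)
    elif code == 4:
        assert a is not None
        bb = math.sqrt(max(0.0, 1.0 - 2.0 * a * a))
        add(a, a, bb); add(a, bb, a); add(bb, a, a)
    elif code == 5:
        assert a is not None
        bb = math.sqrt(max(0.0, 1.0 - a * a))
        add(a, bb, 0.0); add(bb, a, 0.0)
        add(a, 0.0, bb); add(bb, 0.0, a)
        add(0.0, a, bb); add(0.0, bb, a)
    elif code == 6:
        assert a is not None and b is not None
        c = math.sqrt(max(0.0, 1.0 - a * a - b * b))
        for perm in ((a, b, c), (a, c, b), (b, a, c), (b, c, a), (c, a, b), (c, b, a)):
            add(*perm)
    else:  # pragma: no cover - table integrity
        raise ValueError(f"unknown orbit code {code}")

    arr = np.array(sorted(pts), dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    return arr / norms[:, None]


# Rule tables: list of (code, a, b, weight).  Weights are per-point and sum to 1
# over the full rule.  Parameters are the published octahedral-orbit constants.
_RULES: dict[int, list[tuple[int, float | None, float | None, float]]] = {
    6: [(1, None, None, 0.1666666666666667)],
    14: [
        (1, None, None, 0.06666666666666667),
        (3, None, None, 0.07500000000000000),
    ],
    26: [
        (1, None, None, 0.04761904761904762),
        (2, None, None, 0.03809523809523810),
        (3, None, None, 0.03214285714285714),
    ],
    38: [
        (1, None, None, 0.009523809523809524),
        (3, None, None, 0.03214285714285714),
        (5, 0.4597008433809831, None, 0.02857142857142857),
    ],
    50: [
        (1, None, None, 0.01269841269841270),
        (2, None, None, 0.02257495590828924),
        (3, None, None, 0.02109375000000000),
        (4, 0.3015113445777636, None, 0.02017333553791887),
    ],
    86: [
        (1, None, None, 0.01154401154401154),
        (3, None, None, 0.01194390908585628),
        (4, 0.3696028464541502, None, 0.01111055571060340),
        (4, 0.6943540066026664, None, 0.01187650129453714),
        (5, 0.3742430390903412, None, 0.01181230374690448),
    ],
    110: [
        (1, None, None, 0.003828270494937162),
        (3, None, None, 0.009793737512487512),
        (4, 0.1851156353447362, None, 0.008211737283191111),
        (4, 0.6904210483822922, None, 0.009942814891178103),
        (4, 0.3956894730559419, None, 0.009595471336070963),
        (5, 0.4783690288121502, None, 0.009694996361663028),
    ],
    146: [
        (1, None, None, 0.0005996313688621381),
        (2, None, None, 0.007372999718620756),
        (3, None, None, 0.007210515360144488),
        (4, 0.6764410400114264, None, 0.007116355493117555),
        (4, 0.4174961227965453, None, 0.006753829486314477),
        (4, 0.1574676672039082, None, 0.007574394159054034),
        (6, 0.1403553811713183, 0.4493328323269557, 0.006991087353303262),
    ],
    194: [
        (1, None, None, 0.001782340447244611),
        (2, None, None, 0.005716905949977102),
        (3, None, None, 0.005573383178848738),
        (4, 0.6712973442695226, None, 0.005608704082587997),
        (4, 0.2892465627575439, None, 0.005158237711805383),
        (4, 0.4446933178717437, None, 0.005518771467273614),
        (4, 0.1299335447650067, None, 0.004106777028169394),
        (5, 0.3457702197611283, None, 0.005051846064614808),
        (6, 0.1590417105383530, 0.8360360154824589, 0.005530248916233094),
    ],
}

# Exact polynomial degree of each rule.
RULE_DEGREE = {6: 3, 14: 5, 26: 7, 38: 9, 50: 11, 86: 15, 110: 17,
               146: 19, 194: 23}


def available_orders() -> tuple[int, ...]:
    """Supported grid sizes (number of points per sphere)."""
    return tuple(sorted(_RULES))


def lebedev_grid(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(directions, weights)`` for the rule with `n_points` points.

    Directions are unit vectors of shape (n_points, 3); weights sum to 1.

    Raises
    ------
    ValueError
        If `n_points` is not one of :func:`available_orders`.
    """
    if n_points not in _RULES:
        raise ValueError(
            f"unsupported angular grid size {n_points}; "
            f"supported sizes: {available_orders()}"
        )
    dirs = []
    wts = []
    for code, a, b, v in _RULES[n_points]:
        pts = _orbit_points(code, a, b)
        dirs.append(pts)
        wts.append(np.full(len(pts), v))
    directions = np.vstack(dirs)
    weights = np.concatenate(wts)
    if len(directions) != n_points:  # pragma: no cover - table integrity
        raise AssertionError(f"rule {n_points} produced {len(directions)} points")
    return directions, weights
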
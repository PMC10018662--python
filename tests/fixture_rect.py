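"""Hand-checkable rectangle fixture for the landmark rules.

Every structure is an axis-aligned rectangle on a 1 mm grid whose pixel
centres sit at half-integers, so bounding boxes recover the printed integer
edges exactly.  The expected landmark coordinates below were derived by hand
from the documented placement rules; boundary-derived landmarks (C, D, E)
carry a 1-pixel tolerance because the expanded-brain contour is extracted
from the rasterized dilation.

Rectangles (umin, umax, vmin, vmax) in mm:

    external  ( 10, 110,   5, 130)
    brain     ( 30,  95,  70, 120)
    eyes      ( 84, 104,  54,  74)   (eye_L == eye_R: lateral superposition)
    lenses    ( 98, 106,  60,  68)
    C1        ( 20,  44,  30,  45)
    C2        ( 20,  44,  13,  28)

With brain_margin 15 and skin_flash 15 the expanded brain is the rounded
rectangle (15, 110) x (55, 135) with corner radius 15; the corner arc below
the back-of-lens line gives C = (98, 70 - sqrt(216)).
"""

import math

import numpy as np

from wbrt_aperture.projection import Grid2D, StructureSet2D

RECTS = {
    "external": (10, 110, 5, 130),
    "brain": (30, 95, 70, 120),
    "eye_L": (84, 104, 54, 74),
    "eye_R": (84, 104, 54, 74),
    "lens_L": (98, 106, 60, 68),
    "lens_R": (98, 106, 60, 68),
    "C1": (20, 44, 30, 45),
    "C2": (20, 44, 13, 28),
}

GRID = Grid2D(origin=(0.5, 0.5), spacing=(1.0, 1.0), shape=(130, 150))


def make_structures() -> StructureSet2D:
    u = GRID.u_coords()[:, None]
    v = GRID.v_coords()[None, :]
    masks = {
        name: (u > lo) & (u < hi) & (v > vlo) & (v < vhi)
        for name, (lo, hi, vlo, vhi) in RECTS.items()
    }
    return StructureSet2D(masks=masks, grid=GRID)


# Hand-derived geometry shared by all configurations (margin 15, flash 15,
# diagonal rise 10, vertebra anterior margin 5):
U_ANT = 125.0      # forehead anterior extreme 110 + flash
U_POST = -5.0      # posterior skin extreme 10 - flash
V_CRANIAL = 145.0  # skin top 130 + flash
V_B = 74.0         # eye-box top
U_E = 49.0         # vertebra box anterior 44 + 5
V_E = 55.0         # expanded-brain bottom edge 70 - 15
V_CAUDAL = {"C1": 30.0, "C2": 13.0}
U_B = {"lens": 98.0, "eye": 84.0, "mid": 91.0}
# Lower expanded-brain crossing of the vertical at u_B: flat bottom at 55 for
# u <= 95, corner circle centred (95, 70) radius 15 beyond.
V_C = {"lens": 70.0 - math.sqrt(15.0**2 - 3.0**2), "eye": 55.0, "mid": 55.0}
U_ORBITS = 125.0   # face anterior extreme 110 + flash


def expected_landmarks(ab_shape, bc_position, ce_shape, include_orbits, caudal="C1"):
    """Landmarks derived by hand from the placement rules."""
    v_caudal = V_CAUDAL[caudal]
    if include_orbits:
        p = (U_ORBITS, V_B)
        return {
            "I": (U_ORBITS, V_CRANIAL),
            "A": p, "B": p, "C": p, "D": p, "E": p,
            "F": (U_ORBITS, v_caudal),
            "G": (U_POST, v_caudal),
            "H": (U_POST, V_CRANIAL),
        }
    u_b = U_B[bc_position]
    v_c = V_C[bc_position]
    v_a = V_B if ab_shape == "horizontal" else V_B + 10.0
    if ce_shape == "straight":
        d = (0.5 * (u_b + U_E), 0.5 * (v_c + V_E))
    else:
        # Flat bottom stretch of the expanded brain spans u in [15+?, 95];
        # ties on minimal v resolve toward the midpoint of C and E in u.
        d = (0.5 * (u_b + U_E), 55.0)
    return {
        "I": (U_ANT, V_CRANIAL),
        "A": (U_ANT, v_a),
        "B": (u_b, V_B),
        "C": (u_b, v_c),
        "D": d,
        "E": (U_E, V_E),
        "F": (U_E, v_caudal),
        "G": (U_POST, v_caudal),
        "H": (U_POST, V_CRANIAL),
    }


#: exact for box-derived landmarks, 1 pixel for contour-derived ones
TOLERANCES = {
    "A": 1e-9, "B": 1e-9, "F": 1e-9, "G": 1e-9, "H": 1e-9, "I": 1e-9,
    "C": 1.0, "D": 1.5, "E": 1.0,
}


def check_landmarks(landmarks, expected, include_orbits=False):
    for name, (eu, ev) in expected.items():
        gu, gv = landmarks[name]
        tol = 1e-9 if include_orbits else TOLERANCES[name]
        assert abs(gu - eu) <= tol, f"{name}: u {gu} != {eu} (tol {tol})"
        assert abs(gv - ev) <= tol, f"{name}: v {gv} != {ev} (tol {tol})"
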
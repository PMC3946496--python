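"""Published point estimates for ten wild bird populations.

Posterior-mode G-matrix elements (mean-standardized, x100) and
directional selection gradients for seven species / ten long-term study
populations, usable as reference inputs for the constraint metrics and
as templates for the synthetic-data generator. Trait order everywhere:
wing, tarsus, mass, bill.
"""

from __future__ import annotations

import numpy as np

TRAITS = ("wing", "tarsus", "mass", "bill")

POPULATIONS = (
    "red_billed_gull",
    "great_reed_warbler",
    "barn_swallow_badajoz",
    "barn_swallow_kraghede",
    "blue_tit_muro",
    "blue_tit_pirio",
    "blue_tit_rouviere",
    "collared_flycatcher",
    "savannah_sparrow",
    "house_sparrow",
)

# (wing, tarsus, mass, bill diagonal), then (WT, WM, WB, TM, TB, MB), x100 scale
_G_ELEMENTS = {
    "red_billed_gull": ((0.032, 0.045, 0.109, 0.036), (0.015, 0.021, 0.010, 0.038, 0.015, 0.022)),
    "great_reed_warbler": ((0.019, 0.036, 0.077, 0.083), (0.001, 0.012, 0.004, 0.027, 0.013, 0.023)),
    "barn_swallow_badajoz": ((0.020, 0.031, 0.132, 0.073), (0.004, 0.024, 0.004, 0.022, 0.007, 0.030)),
    "barn_swallow_kraghede": ((0.030, 0.086, 0.178, 0.047), (0.025, 0.038, 0.000, 0.031, 0.006, 0.007)),
    "blue_tit_muro": ((0.018, 0.041, 0.075, 0.045), (0.010, 0.012, 0.008, 0.021, 0.019, 0.032)),
    "blue_tit_pirio": ((0.013, 0.043, 0.079, 0.028), (0.012, 0.012, 0.007, 0.029, 0.013, 0.017)),
    "blue_tit_rouviere": ((0.020, 0.043, 0.103, 0.050), (0.007, 0.017, 0.006, 0.020, 0.010, 0.029)),
    "collared_flycatcher": ((0.018, 0.037, 0.115, 0.045), (0.007, 0.015, 0.006, 0.028, 0.008, 0.015)),
    "savannah_sparrow": ((0.020, 0.036, 0.117, 0.087), (0.005, 0.015, 0.010, 0.020, 0.016, 0.036)),
    "house_sparrow": ((0.024, 0.090, 0.174, 0.090), (0.027, 0.036, 0.015, 0.086, 0.041, 0.053)),
}

# posterior-mode directional selection gradients (unitless, mean-standardized scale)
POINT_BETA = {
    "red_billed_gull": np.array([1.14, 1.86, -1.15, 1.86]),
    "great_reed_warbler": np.array([-0.09, 4.04, -1.78, 0.58]),
    "barn_swallow_badajoz": np.array([0.33, 0.12, 0.08, 0.15]),
    "barn_swallow_kraghede": np.array([-0.54, 0.70, -0.17, 0.32]),
    "blue_tit_muro": np.array([0.24, 0.48, -0.29, 0.63]),
    "blue_tit_pirio": np.array([0.46, 0.42, -0.82, 0.39]),
    "blue_tit_rouviere": np.array([0.23, 0.91, -0.22, 0.05]),
    "collared_flycatcher": np.array([0.74, 0.52, -0.39, -0.11]),
    "savannah_sparrow": np.array([0.94, -1.32, -0.73, 1.73]),
    "house_sparrow": np.array([-0.42, 1.16, 0.05, -0.87]),
}

# per-trait means (mm / g): wing, tarsus, mass, bill
TRAIT_MEANS = {
    "red_billed_gull": (278.13, 443.12, 288.99, 49.83),
    "great_reed_warbler": (98.33, 33.09, 33.37, 12.51),
    "barn_swallow_badajoz": (120.52, 11.15, 18.33, 7.53),
    "barn_swallow_kraghede": (125.68, 11.18, 19.28, 7.82),
    "blue_tit_muro": (61.83, 16.24, 9.71, 9.76),
    "blue_tit_pirio": (62.10, 16.04, 9.31, 9.74),
    "blue_tit_rouviere": (65.92, 16.70, 11.07, 9.86),
    "collared_flycatcher": (81.76, 19.37, 13.68, 13.36),
    "savannah_sparrow": (66.59, 21.07, 19.71, 8.09),
    "house_sparrow": (77.71, 18.55, 27.61, 13.29),
}


def point_G(population: str, scale: float = 1.0) -> np.ndarray:
    """Symmetric 4x4 point G for one population.

    ``scale=1.0`` keeps the published x100 scale; ``scale=0.01`` returns
    the raw mean-standardized scale.
    """
    diag, off = _G_ELEMENTS[population]
    G = np.diag(np.asarray(diag, dtype=float))
    (wt, wm, wb, tm, tb, mb) = off
    G[0, 1] = G[1, 0] = wt
    G[0, 2] = G[2, 0] = wm
    G[0, 3] = G[3, 0] = wb
    G[1, 2] = G[2, 1] = tm
    G[1, 3] = G[3, 1] = tb
    G[2, 3] = G[3, 2] = mb
    return G * scale
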
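"""Round-window grid frame conventions shared by the generator and the planner.

The 4x4 dynamic grid partitions the membrane's in-plane bounding box.  Rows
are labelled A-D from superior to inferior, columns 1-4 from anterior to
posterior.  "Superior" is the projection of the world +z direction (the
modiolar axis convention) onto the membrane plane; "anterior" is the in-plane
direction ``e_sup x n_out`` with ``n_out`` the outward membrane normal, which
makes (e_ant, e_sup, n_out) a right-handed frame.
"""

from __future__ import annotations

import numpy as np

ROW_LABELS = "ABCD"   # A = superior row
COL_LABELS = "1234"   # 1 = anterior column

CELL_LABELS = tuple(f"{r}{c}" for r in ROW_LABELS for c in COL_LABELS)

_SUPERIOR = np.array([0.0, 0.0, 1.0])


def normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize the zero vector")
    return v / n


def inplane_basis(n_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (e_sup, e_ant) for a membrane plane with outward normal ``n_out``.

    ``e_sup`` is the in-plane projection of the superior direction (+z); the
    plane must not be perpendicular to it.
    """
    n_out = normalize(n_out)
    sup = _SUPERIOR - np.dot(_SUPERIOR, n_out) * n_out
    if np.linalg.norm(sup) < 1e-6:
        raise ValueError("membrane plane is perpendicular to the superior axis; "
                         "in-plane superior direction undefined")
    e_sup = normalize(sup)
    e_ant = np.cross(e_sup, n_out)
    return e_sup, e_ant


def cell_centers(center: np.ndarray, n_out: np.ndarray,
                 ant_half: float, sup_half: float) -> dict[str, np.ndarray]:
    """3-D centers of the 16 grid cells for a membrane bounding box.

    ``ant_half``/``sup_half`` are the half-extents of the in-plane bounding
    box along the anterior and superior axes (mm).
    """
    center = np.asarray(center, dtype=float)
    e_sup, e_ant = inplane_basis(n_out)
    out = {}
    for i, row in enumerate(ROW_LABELS):
        s = sup_half - (i + 0.5) * (2.0 * sup_half / 4.0)
        for j, col in enumerate(COL_LABELS):
            a = ant_half - (j + 0.5) * (2.0 * ant_half / 4.0)
            out[f"{row}{col}"] = center + s * e_sup + a * e_ant
    return out
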
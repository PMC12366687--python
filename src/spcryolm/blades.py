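"""Rigid-body blade rotation scan on labeled coordinate sets.

The blade arm of each protomer can pivot about an "elbow" residue.  Given one
protomer's coordinates, a pivot site and a probe site (the labeled residue),
this module rotates the N-terminal sub-chain rigidly about the pivot -- either
in the membrane plane (about the vertical axis through the pivot) or out of
the plane (about the in-plane axis through the pivot perpendicular to the
blade direction) -- rebuilds the trimer by three-fold replication about the
central vertical axis, and reports the interblade distance between probe sites
on neighboring protomers for every angle on the grid (default 0-180 degrees in
5-degree steps).

Coordinates may come from a PDB/mmCIF file (loaded in angstroms and converted
to nanometers) or from any labeled point set, e.g. a synthetic straight-arm
toy model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

DEFAULT_ANGLE_GRID = np.arange(0.0, 181.0, 5.0)

_AXES = ("in-plane", "out-of-plane")


@dataclass
class BladeModel:
    """One protomer as labeled 3D points with a pivot and a probe site.

    ``coords`` is (n, 3); ``labels`` identifies each point (e.g. residue
    numbers); the mobile sub-chain runs from the N terminus (index 0) up to and
    including the pivot.  Units must be declared; nanometers are canonical.
    """

    coords: np.ndarray
    pivot_index: int
    probe_index: int
    labels: np.ndarray | None = None
    unit: str = "nm"
    mobile_indices: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        n = len(self.coords)
        if not (0 <= self.pivot_index < n):
            raise IndexError("pivot index outside the coordinate set")
        if not (0 <= self.probe_index < n):
            raise IndexError("probe index outside the coordinate set")
        if self.unit not in ("nm", "angstrom"):
            raise ValueError("unit must be 'nm' or 'angstrom'")
        if self.unit == "angstrom":
            self.coords = self.coords / 10.0
            self.unit = "nm"
        if self.mobile_indices is None:
            self.mobile_indices = np.arange(self.pivot_index + 1)
        else:
            self.mobile_indices = np.asarray(self.mobile_indices, dtype=int)


def load_chain_ca(path: str, chain: str | None = None) -> BladeModel | pd.DataFrame:
    """Load C-alpha coordinates of one chain from a PDB/mmCIF file.

    Returns a DataFrame with residue numbers and (x, y, z) in nm; build a
    BladeModel from it by choosing pivot and probe residues."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    rows = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is not None:
                rows.append(
                    (ch.name, res.seqid.num, ca.pos.x / 10.0, ca.pos.y / 10.0, ca.pos.z / 10.0)
                )
    if not rows:
        raise ValueError(f"no C-alpha atoms found in {path!r}")
    return pd.DataFrame(rows, columns=["chain", "residue", "x_nm", "y_nm", "z_nm"])


def rotate_mobile(
    model: BladeModel, angle_deg: float, axis: str = "in-plane"
) -> np.ndarray:
    """Rotate the mobile sub-chain rigidly about the pivot; returns new coords.

    "in-plane" rotates about the vertical (z) axis through the pivot;
    "out-of-plane" rotates about the in-plane axis through the pivot that is
    perpendicular to the blade direction (pivot -> probe, projected in-plane).
    The pivot point itself is fixed exactly.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}")
    pivot = model.coords[model.pivot_index]
    if axis == "in-plane":
        axis_vec = np.array([0.0, 0.0, 1.0])
    else:
        blade = model.coords[model.probe_index] - pivot
        blade[2] = 0.0
        norm = np.linalg.norm(blade)
        if norm == 0:
            raise ValueError("probe coincides with pivot in-plane; axis undefined")
        u = blade / norm
        axis_vec = np.array([-u[1], u[0], 0.0])
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis_vec)
    out = model.coords.copy()
    mob = model.mobile_indices
    out[mob] = rot.apply(out[mob] - pivot) + pivot
    return out


def trimer_probe_positions(coords: np.ndarray, probe_index: int) -> np.ndarray:
    """Probe positions of the three protomers after C3 replication about z."""
    probe = coords[probe_index]
    angles = [0.0, 120.0, 240.0]
    return np.stack(
        [Rotation.from_euler("z", a, degrees=True).apply(probe) for a in angles]
    )


def rigid_body_scan(
    model: BladeModel,
    angles=DEFAULT_ANGLE_GRID,
    axis: str = "in-plane",
) -> pd.DataFrame:
    """Interblade distance between neighboring probe sites for each angle.

    For every grid angle the mobile sub-chain is rotated rigidly about the
    pivot, the trimer is rebuilt by 120-degree replication about the central
    vertical axis, and the distance between probe sites of adjacent protomers
    is measured.  Returns a DataFrame (angle_deg, interblade_nm)."""
    records = []
    for a in np.asarray(angles, dtype=float):
        coords = rotate_mobile(model, a, axis=axis)
        probes = trimer_probe_positions(coords, model.probe_index)
        d = float(np.linalg.norm(probes[0] - probes[1]))
        records.append((a, d))
    return pd.DataFrame(records, columns=["angle_deg", "interblade_nm"])
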
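"""Reduced CA1 morphology: compartment geometry and an optional SWC reader.

The default model is a three-section cable: one somatic compartment, the
first 200 um of the apical trunk split into equal cylinders, and an
electrical-only axonal compartment for spike initiation.  The expanded
calcium/cascade chemistry lives in the soma and trunk only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import MorphologyParams, SectionParams
from .units import MS_PER_CM2_TO_NS_PER_UM2, UF_PER_CM2_TO_PF_PER_UM2


@dataclass
class CompartmentGeometry:
    """One cylindrical compartment with cytosol/ER sub-volumes."""

    length: float                 # um
    diameter: float               # um
    position: float               # path distance of centre from soma centre, um
    cytosol_fraction: float = 0.9
    er_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be positive")
        if not (0 < self.cytosol_fraction < 1 and 0 < self.er_fraction < 1):
            raise ValueError("volume fractions must lie in (0, 1)")
        if abs(self.cytosol_fraction + self.er_fraction - 1.0) > 1e-12:
            raise ValueError("cytosol_fraction + er_fraction must equal 1")

    @property
    def area(self) -> float:
        """Lateral membrane area, um^2."""
        return np.pi * self.diameter * self.length

    @property
    def volume(self) -> float:
        """Total intracellular volume, um^3."""
        return np.pi * (self.diameter / 2.0) ** 2 * self.length

    @property
    def volume_cyt(self) -> float:
        return self.volume * self.cytosol_fraction

    @property
    def volume_er(self) -> float:
        return self.volume * self.er_fraction

    @property
    def sv_ratio(self) -> float:
        """Membrane area per cytosolic volume, 1/um."""
        return self.area / self.volume_cyt


@dataclass
class Morphology:
    """Compiled compartment arrays for the electrical cable and chemistry.

    Compartment order: soma (0), trunk (1..n_trunk), axon (last).  Chemistry
    compartments are the soma+trunk prefix (indices 0..n_trunk).
    """

    compartments: list[CompartmentGeometry]
    section_of: list[str]
    channel_density: dict[str, np.ndarray]   # channel -> nS/um^2 per compartment
    params: MorphologyParams
    chem_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.chem_mask = np.array([s != "axon" for s in self.section_of])

    @property
    def n_elec(self) -> int:
        return len(self.compartments)

    @property
    def n_chem(self) -> int:
        return int(self.chem_mask.sum())

    @property
    def chem_indices(self) -> np.ndarray:
        return np.flatnonzero(self.chem_mask)

    def arrays(self) -> dict[str, np.ndarray]:
        c = self.compartments
        return {
            "area": np.array([x.area for x in c]),
            "volume_cyt": np.array([x.volume_cyt for x in c]),
            "volume_er": np.array([x.volume_er for x in c]),
            "length": np.array([x.length for x in c]),
            "diameter": np.array([x.diameter for x in c]),
            "position": np.array([x.position for x in c]),
            "sv_ratio": np.array([x.sv_ratio for x in c]),
        }

    def capacitance(self) -> np.ndarray:
        """pF per compartment."""
        return self.params.cm * UF_PER_CM2_TO_PF_PER_UM2 * self.arrays()["area"]

    def axial_conductance(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, g_nS) for each connected compartment pair.

        Series resistance of the two half-cylinders, Ra in ohm*cm.
        """
        c = self.compartments
        ra = self.params.ra
        # axial resistance of half a compartment in megaohm:
        # R = Ra[ohm*cm] * (L/2)[cm] / A[cm^2] ; um -> cm : 1e-4
        def half_r(x: CompartmentGeometry) -> float:
            area_cross = np.pi * (x.diameter / 2.0) ** 2 * 1e-8  # cm^2
            return ra * (x.length / 2.0) * 1e-4 / area_cross * 1e-6  # Mohm

        ii, jj, gg = [], [], []
        # chain: soma(0) - trunk(1..k) ; axon attaches to soma
        order = [i for i, s in enumerate(self.section_of) if s != "axon"]
        for a, b in zip(order[:-1], order[1:]):
            r = half_r(c[a]) + half_r(c[b])
            ii.append(a); jj.append(b); gg.append(1e3 / r)  # nS = 1e3 / Mohm
        axon = [i for i, s in enumerate(self.section_of) if s == "axon"]
        for b in axon:
            r = half_r(c[0]) + half_r(c[b])
            ii.append(0); jj.append(b); gg.append(1e3 / r)
        return np.array(ii), np.array(jj), np.array(gg)


def _section_compartments(sec: SectionParams, name: str, start_pos: float,
                          frac_cyt: float, frac_er: float) -> list[CompartmentGeometry]:
    dl = sec.length / sec.n_compartments
    out = []
    for k in range(sec.n_compartments):
        out.append(CompartmentGeometry(
            length=dl, diameter=sec.diameter,
            position=start_pos + (k + 0.5) * dl,
            cytosol_fraction=frac_cyt, er_fraction=frac_er))
    return out


def build_reduced_morphology(params: MorphologyParams) -> Morphology:
    """Soma + trunk + axon compartments with per-compartment densities."""
    for sec, name in ((params.soma, "soma"), (params.trunk, "trunk"),
                      (params.axon, "axon")):
        if sec.length <= 0:
            raise ValueError(f"zero-length section {name!r}")
    for mandatory in ("na", "kdr", "leak"):
        if mandatory not in params.soma.channels:
            raise ValueError(f"missing mandatory channel {mandatory!r} on soma")

    comps: list[CompartmentGeometry] = []
    section_of: list[str] = []
    fc, fe = params.cytosol_fraction, params.er_fraction

    comps += _section_compartments(params.soma, "soma", -params.soma.length / 2, fc, fe)
    section_of += ["soma"] * params.soma.n_compartments
    comps += _section_compartments(params.trunk, "trunk", params.soma.length / 2, fc, fe)
    section_of += ["trunk"] * params.trunk.n_compartments
    comps += _section_compartments(params.axon, "axon", params.soma.length / 2, fc, fe)
    section_of += ["axon"] * params.axon.n_compartments

    all_channels = sorted(set(params.soma.channels) | set(params.trunk.channels)
                          | set(params.axon.channels))
    density = {}
    sec_by_name = {"soma": params.soma, "trunk": params.trunk, "axon": params.axon}
    for ch in all_channels:
        density[ch] = np.array([
            sec_by_name[s].channels.get(ch, 0.0) * MS_PER_CM2_TO_NS_PER_UM2
            for s in section_of])
    return Morphology(comps, section_of, density, params)


def read_swc(path: str) -> list[tuple[int, int, float, float, float, float, int]]:
    """Parse an SWC reconstruction: (id, type, x, y, z, radius, parent)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append((int(parts[0]), int(parts[1]), float(parts[2]),
                         float(parts[3]), float(parts[4]), float(parts[5]),
                         int(parts[6])))
    if not rows:
        raise ValueError("empty SWC file")
    return rows


def morphology_from_swc(path: str, params: MorphologyParams,
                        max_trunk_length: float = 200.0) -> Morphology:
    """Build the reduced model from an SWC file.

    The soma is collapsed to an equivalent cylinder and the apical path
    (SWC type 4) is followed from the soma and truncated at
    ``max_trunk_length``; the chemistry is restricted to that prefix exactly
    as in the built-in morphology.
    """
    rows = read_swc(path)
    by_id = {r[0]: r for r in rows}
    soma_pts = [r for r in rows if r[1] == 1]
    if not soma_pts:
        raise ValueError("SWC file lacks soma points (type 1)")
    soma_radius = float(np.mean([r[5] for r in soma_pts]))
    soma_ids = {r[0] for r in soma_pts}

    # follow the apical dendrite (type 4) rooted at the soma
    children: dict[int, list] = {}
    for r in rows:
        children.setdefault(r[6], []).append(r)
    path_pts = []
    frontier = [r for r in rows if r[1] == 4 and r[6] in soma_ids]
    if not frontier:
        raise ValueError("SWC file lacks an apical path (type 4) from the soma")
    node = frontier[0]
    dist = 0.0
    prev_xyz = np.array(node[2:5])
    while node is not None and dist < max_trunk_length:
        xyz = np.array(node[2:5])
        dist += float(np.linalg.norm(xyz - prev_xyz))
        prev_xyz = xyz
        path_pts.append((dist, node[5]))
        nxt = [c for c in children.get(node[0], []) if c[1] == 4]
        node = nxt[0] if nxt else None

    trunk_len = min(max_trunk_length, path_pts[-1][0]) if path_pts else 0.0
    if trunk_len <= 0:
        raise ValueError("apical path has zero length")
    mean_diam = 2.0 * float(np.mean([r for _, r in path_pts]))

    p = params.copy() if hasattr(params, "copy") else params
    import copy as _copy
    p = _copy.deepcopy(params)
    p.soma.length = 2.0 * soma_radius
    p.soma.diameter = 2.0 * soma_radius
    p.trunk.length = trunk_len
    p.trunk.diameter = mean_diam
    return build_reduced_morphology(p)
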
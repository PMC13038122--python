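"""Branched neuron morphologies and their compartmental discretization.

A :class:`Morphology` is a tree of straight :class:`Section` polylines with a
soma-relative depth axis (z', positive from the soma toward the dendrites).
:func:`compartmentalize` breaks sections into cylindrical compartments that
serve as the computational units of the cable solver.  Morphologies can be
read from / written to standard 7-column SWC files or generated synthetically
(:func:`generate_synthetic`) as stand-ins for reconstructed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "SectionKind",
    "Section",
    "Morphology",
    "Compartment",
    "CompartmentModel",
    "SyntheticMorphSpec",
    "read_swc",
    "write_swc",
    "generate_synthetic",
    "rotate_azimuthal",
    "compartmentalize",
]


class SectionKind(str, Enum):
    SOMA = "soma"
    AXON = "axon"
    BASAL_DENDRITE = "basal_dendrite"
    APICAL_DENDRITE = "apical_dendrite"

    @property
    def is_dendrite(self) -> bool:
        return self in (SectionKind.BASAL_DENDRITE, SectionKind.APICAL_DENDRITE)


#: SWC structure-identifier codes <-> section kinds.
_SWC_TYPE_TO_KIND = {
    1: SectionKind.SOMA,
    2: SectionKind.AXON,
    3: SectionKind.BASAL_DENDRITE,
    4: SectionKind.APICAL_DENDRITE,
}
_KIND_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_KIND.items()}


class SWCParseError(ValueError):
    """Malformed SWC content (reports the offending line number)."""


class StructureError(ValueError):
    """Topologically invalid morphology (orphan parents, cycles, ...)."""


@dataclass
class Section:
    """A straight run of cable: an ordered 3D polyline with per-point diameters."""

    id: int
    parent_id: int | None
    kind: SectionKind
    points: np.ndarray      # (n, 3) um
    diameters: np.ndarray   # (n,) um

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if self.kind is not SectionKind.SOMA and len(self.points) < 2:
            raise ValueError("non-soma sections need >= 2 points")
        if len(self.diameters) != len(self.points):
            raise ValueError("diameters must match points")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")

    @property
    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class Morphology:
    """A tree of sections with an explicit somatodendritic (z') axis."""

    sections: list[Section]
    soma_center: np.ndarray
    somatodendritic_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        axis = np.asarray(self.somatodendritic_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("somatodendritic axis must be nonzero")
        self.somatodendritic_axis = axis / norm
        self._validate_tree()

    def _validate_tree(self) -> None:
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise StructureError("duplicate section ids")
        by_id = {s.id: s for s in self.sections}
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1 or roots[0].kind is not SectionKind.SOMA:
            raise StructureError("exactly one root section (the soma) required")
        for s in self.sections:
            if s.parent_id is not None and s.parent_id not in by_id:
                raise StructureError(f"section {s.id} references missing parent {s.parent_id}")
        # acyclicity / connectedness: every section must reach the root
        for s in self.sections:
            seen, cur = set(), s
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise StructureError("cycle in section tree")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent_id is None)

    def z_prime(self, points: np.ndarray) -> np.ndarray:
        """Soma-relative depth (um) of 3D points along the somatodendritic axis."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.soma_center) @ self.somatodendritic_axis

    def total_cable_length(self) -> float:
        return sum(s.arc_length for s in self.sections)


@dataclass(frozen=True)
class Compartment:
    """A cylindrical computational unit.

    Two distinct area fields are kept because the membrane equations use the
    lateral (membrane) area pi*d*L while the axial-current expression uses the
    cross-section pi*d^2/4.
    """

    id: int
    section_id: int
    midpoint: np.ndarray
    direction: np.ndarray
    length: float
    diameter: float
    kind: SectionKind
    axial_resistivity: float = 100.0  # Ohm*cm

    @property
    def membrane_area(self) -> float:
        """Lateral surface pi*d*L (um^2)."""
        return float(np.pi * self.diameter * self.length)

    @property
    def cross_section_area(self) -> float:
        """Cross-section pi*d^2/4 (um^2)."""
        return float(np.pi * self.diameter**2 / 4.0)


class CompartmentModel:
    """Discretized morphology: compartments, tree adjacency, terminals, z'.

    ``parent[i]`` is the parent compartment index (-1 for the root soma
    compartment); ``terminal_ids`` are axonal leaf compartments (axonal
    compartments with no axonal child) where synaptic boutons are assumed.
    """

    def __init__(
        self,
        morphology: Morphology,
        compartments: list[Compartment],
        parent: np.ndarray,
    ) -> None:
        self.morphology = morphology
        self.compartments = compartments
        self.parent = np.asarray(parent, dtype=int)
        n = len(compartments)
        if self.parent.shape != (n,):
            raise ValueError("parent index array must match compartment count")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.kinds = np.array([c.kind for c in compartments], dtype=object)
        mids = np.array([c.midpoint for c in compartments])
        self.z_prime = morphology.z_prime(mids)
        axon = np.array([c.kind is SectionKind.AXON for c in compartments])
        self.terminal_ids = np.array(
            [
                i
                for i in range(n)
                if axon[i] and not any(axon[c] for c in self.children[i])
            ],
            dtype=int,
        )

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([c.midpoint for c in self.compartments])

    @property
    def directions(self) -> np.ndarray:
        return np.array([c.direction for c in self.compartments])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.compartments])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.compartments])

    @property
    def membrane_areas(self) -> np.ndarray:
        return np.array([c.membrane_area for c in self.compartments])

    def dendrite_mask(self) -> np.ndarray:
        return np.array([c.kind.is_dendrite for c in self.compartments])

    def axial_conductances(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edge list (child, parent) and axial conductance g (uS) per edge.

        Each interface carries two half-compartment series resistances
        r = 4*Ra*(L/2)/(pi*d^2) (Ohm, after unit conversion) on either side.
        """
        child, par, g = [], [], []
        for i, p in enumerate(self.parent):
            if p < 0:
                continue
            r = _half_resistance(self.compartments[i]) + _half_resistance(
                self.compartments[p]
            )
            child.append(i)
            par.append(p)
            g.append(1.0 / (r * 1e-6))  # Ohm -> uS
        return np.asarray(child, int), np.asarray(par, int), np.asarray(g, float)


def _half_resistance(c: Compartment) -> float:
    """Series resistance (Ohm) of half a compartment: 4*Ra*(L/2)/(pi*d^2)."""
    ra_ohm_um = c.axial_resistivity * 1e4  # Ohm*cm -> Ohm*um
    return 4.0 * ra_ohm_um * (c.length / 2.0) / (np.pi * c.diameter**2)


# ---------------------------------------------------------------------------
# SWC input / output
# ---------------------------------------------------------------------------

def read_swc(path: str | Path, axis: np.ndarray | None = None) -> Morphology:
    """Read a standard 7-column SWC file.

    Radii are doubled to diameters on import.  The somatodendritic axis
    defaults to +y (the common SWC convention of apical dendrites growing
    along +y); pass ``axis`` to override.
    """
    path = Path(path)
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            typ = int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            radius = float(parts[5])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(f"{path.name}:{lineno}: {exc}") from exc
        nodes[nid] = (typ, xyz, radius, parent)

    for nid, (_, _, _, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise StructureError(f"node {nid} references missing parent {parent}")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    roots = []
    for nid, (_, _, _, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            children[parent].append(nid)
    if len(roots) != 1:
        raise StructureError(f"expected exactly one root node, found {len(roots)}")
    root = roots[0]
    if nodes[root][0] != 1:
        raise StructureError("root node must be soma (type 1)")

    soma_ids = [nid for nid, (typ, _, _, _) in nodes.items() if typ == 1]
    soma_pts = np.array([nodes[nid][1] for nid in soma_ids])
    soma_radii = np.array([nodes[nid][2] for nid in soma_ids])
    soma_center = soma_pts.mean(axis=0)
    sections: list[Section] = [
        Section(
            id=0,
            parent_id=None,
            kind=SectionKind.SOMA,
            points=soma_pts,
            diameters=2.0 * soma_radii,
        )
    ]

    # split neurites into unbranched sections at branch points / kind changes
    soma_set = set(soma_ids)
    next_id = 1
    section_of_node: dict[int, int] = {nid: 0 for nid in soma_ids}

    def walk(start: int, parent_section: int) -> None:
        nonlocal next_id
        typ = nodes[start][0]
        kind = _SWC_TYPE_TO_KIND.get(typ, SectionKind.BASAL_DENDRITE)
        parent_node = nodes[start][3]
        pts = [nodes[parent_node][1], nodes[start][1]]
        dia = [2.0 * nodes[start][2], 2.0 * nodes[start][2]]
        cur = start
        while True:
            kids = [k for k in children[cur] if nodes[k][0] == typ]
            other = [k for k in children[cur] if nodes[k][0] != typ]
            if len(kids) == 1 and not other:
                cur = kids[0]
                pts.append(nodes[cur][1])
                dia.append(2.0 * nodes[cur][2])
            else:
                break
        sec = Section(
            id=next_id,
            parent_id=parent_section,
            kind=kind,
            points=np.array(pts),
            diameters=np.array(dia),
        )
        sections.append(sec)
        sid = next_id
        next_id += 1
        section_of_node[cur] = sid
        for k in children[cur]:
            walk(k, sid)

    for nid in soma_ids:
        for k in children[nid]:
            if k not in soma_set:
                walk(k, 0)

    morph = Morphology(
        sections=sections,
        soma_center=soma_center,
        somatodendritic_axis=np.array([0.0, 1.0, 0.0]) if axis is None else axis,
    )
    return morph


def write_swc(morphology: Morphology, path: str | Path) -> None:
    """Write a morphology as 7-column SWC (diameters halved back to radii)."""
    path = Path(path)
    lines = ["# generated by tmscouple"]
    nid = 0
    # map section id -> swc id of its last node; swc id -> coordinates
    tail: dict[int, int] = {}
    node_xyz: dict[int, tuple] = {}
    root = morphology.root
    root_first = None
    for p, d in zip(root.points, root.diameters):
        nid += 1
        parent = -1 if root_first is None else nid - 1
        if root_first is None:
            root_first = nid
        lines.append(
            f"{nid} 1 {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {d / 2.0:.9g} {parent}"
        )
        node_xyz[nid] = tuple(p)
    tail[root.id] = nid

    ordered = [s for s in morphology.sections if s.parent_id is not None]
    done = {root.id}
    while ordered:
        progressed = False
        for s in list(ordered):
            if s.parent_id in done:
                ordered.remove(s)
                done.add(s.id)
                progressed = True
                typ = _KIND_TO_SWC_TYPE[s.kind]
                parent_swc = tail[s.parent_id]
                # skip the first point only when it duplicates the parent's
                # tail node; mid-section attachments keep their coordinate
                pts, dias = s.points, s.diameters
                tail_xyz = np.array(node_xyz[parent_swc])
                if np.allclose(pts[0], tail_xyz, atol=1e-9):
                    pts, dias = pts[1:], dias[1:]
                for p, d in zip(pts, dias):
                    nid += 1
                    lines.append(
                        f"{nid} {typ} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g} "
                        f"{d / 2.0:.9g} {parent_swc}"
                    )
                    node_xyz[nid] = tuple(p)
                    parent_swc = nid
                tail[s.id] = parent_swc
        if not progressed:
            raise StructureError("section tree is not connected")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic morphologies
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMorphSpec:
    """Recipe for a synthetic branched cell (stand-in for reconstructions).

    Axon terminals are distributed over soma-relative depth z' by a truncated
    normal; each terminal is reached by a branch leaving a vertical axonal
    trunk, giving a branched arbor with controllable terminal count.  The
    dendritic tree mirrors the construction on the opposite side of the soma.
    """

    n_axon_terminals: int = 20
    terminal_depth_mean: float = -600.0   # um, z'
    terminal_depth_sd: float = 350.0      # um
    terminal_depth_range: tuple[float, float] = (-2000.0, -50.0)
    n_dendrite_terminals: int = 8
    dendrite_depth_mean: float = 250.0
    dendrite_depth_sd: float = 120.0
    dendrite_depth_range: tuple[float, float] = (50.0, 500.0)
    lateral_spread: float = 150.0         # um, horizontal reach of branches
    soma_diameter: float = 15.0           # um
    axon_diameter: float = 1.0            # um
    dendrite_diameter: float = 2.0        # um
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axon_terminals < 1 or self.n_dendrite_terminals < 1:
            raise ValueError("terminal counts must be >= 1")
        lo, hi = self.terminal_depth_range
        if not (-2000.0 <= lo < hi <= 500.0):
            raise ValueError("terminal depth range must lie within z' in [-2000, 500] um")


def _truncated_normal(rng, mean, sd, lo, hi, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_synthetic(spec: SyntheticMorphSpec) -> Morphology:
    """Generate a branched synthetic cell; deterministic for a fixed seed.

    The somatodendritic axis is +z, so a point's z coordinate (relative to
    the soma) is its z' depth.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sections: list[Section] = []
    soma_center = np.zeros(3)
    # single-cylinder soma of equal length and diameter, along the axis
    half = spec.soma_diameter / 2.0
    sections.append(
        Section(
            id=0,
            parent_id=None,
            kind=SectionKind.SOMA,
            points=np.array([[0.0, 0.0, -half], [0.0, 0.0, half]]),
            diameters=np.array([spec.soma_diameter, spec.soma_diameter]),
        )
    )
    next_id = 1

    def build_tree(kind, n_term, mean, sd, rng_range, diameter, sign):
        """Vertical trunk + one branch per terminal, attached at trunk nodes."""
        nonlocal next_id
        depths = _truncated_normal(rng, mean, sd, rng_range[0], rng_range[1], n_term)
        deepest = depths.min() if sign < 0 else depths.max()
        trunk_end = abs(deepest) * 0.7 * sign
        start = half * sign
        trunk_pts = np.array(
            [[0.0, 0.0, start], [0.0, 0.0, sign * max(abs(trunk_end), half + 20.0)]]
        )
        trunk = Section(
            id=next_id,
            parent_id=0,
            kind=kind,
            points=trunk_pts,
            diameters=np.full(2, diameter * 1.5),
        )
        sections.append(trunk)
        trunk_id = next_id
        next_id += 1
        z0, z1 = trunk_pts[0, 2], trunk_pts[1, 2]
        deepest_idx = int(np.argmin(depths) if sign < 0 else np.argmax(depths))
        for b, depth in enumerate(depths):
            # branch leaves the trunk at a random height and descends/ascends
            # laterally to its terminal point; the extreme terminal extends
            # from the trunk tip so the trunk itself never ends blind
            frac = 1.0 if b == deepest_idx else rng.uniform(0.1, 0.9)
            attach = np.array([0.0, 0.0, z0 + frac * (z1 - z0)])
            angle = rng.uniform(0.0, 2.0 * np.pi)
            radial = rng.uniform(0.3, 1.0) * spec.lateral_spread
            end = np.array([radial * np.cos(angle), radial * np.sin(angle), depth])
            mid = 0.5 * (attach + end) + np.array([0.0, 0.0, 0.0])
            sections.append(
                Section(
                    id=next_id,
                    parent_id=trunk_id,
                    kind=kind,
                    points=np.array([attach, mid, end]),
                    diameters=np.full(3, diameter),
                )
            )
            next_id += 1

    build_tree(
        SectionKind.AXON,
        spec.n_axon_terminals,
        spec.terminal_depth_mean,
        spec.terminal_depth_sd,
        spec.terminal_depth_range,
        spec.axon_diameter,
        sign=-1,
    )
    build_tree(
        SectionKind.APICAL_DENDRITE,
        spec.n_dendrite_terminals,
        spec.dendrite_depth_mean,
        spec.dendrite_depth_sd,
        spec.dendrite_depth_range,
        spec.dendrite_diameter,
        sign=+1,
    )
    return Morphology(
        sections=sections,
        soma_center=soma_center,
        somatodendritic_axis=np.array([0.0, 0.0, 1.0]),
    )


def rotate_azimuthal(morphology: Morphology, phi_deg: float) -> Morphology:
    """Rigidly rotate the cell about its somatodendritic axis by phi.

    z' of every point is invariant (rotation about the z' axis through the
    soma center).
    """
    axis = morphology.somatodendritic_axis
    phi = np.deg2rad(phi_deg)
    # Rodrigues rotation matrix about `axis`
    kx, ky, kz = axis
    k_cross = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    rot = np.eye(3) + np.sin(phi) * k_cross + (1 - np.cos(phi)) * (k_cross @ k_cross)
    center = morphology.soma_center
    new_sections = [
        replace(s, points=(s.points - center) @ rot.T + center)
        for s in morphology.sections
    ]
    return Morphology(
        sections=new_sections,
        soma_center=center.copy(),
        somatodendritic_axis=axis.copy(),
    )


def compartmentalize(
    morphology: Morphology,
    max_compartment_length: float = 20.0,
    axial_resistivity: float = 100.0,
) -> CompartmentModel:
    """Discretize each section into compartments of length <= max.

    The soma becomes a single compartment regardless of max length (single-
    compartment soma convention).  Per-section compartment lengths sum to the
    section arc length; connectivity across branch points is preserved.
    """
    if max_compartment_length <= 0:
        raise ValueError("max_compartment_length must be > 0")
    compartments: list[Compartment] = []
    parent: list[int] = []
    last_comp_of_section: dict[int, int] = {}
    comps_of_section: dict[int, list[int]] = {}

    by_id = {s.id: s for s in morphology.sections}
    ordered: list[Section] = []
    done: set[int] = set()
    pending = list(morphology.sections)
    while pending:
        for s in list(pending):
            if s.parent_id is None or s.parent_id in done:
                ordered.append(s)
                done.add(s.id)
                pending.remove(s)

    for sec in ordered:
        if sec.kind is SectionKind.SOMA:
            p0, p1 = sec.points[0], sec.points[-1]
            vec = p1 - p0
            length = float(np.linalg.norm(vec))
            if length == 0:
                vec = morphology.somatodendritic_axis
                length = float(np.mean(sec.diameters))
                p0 = morphology.soma_center - 0.5 * length * vec
                p1 = morphology.soma_center + 0.5 * length * vec
            direction = vec / np.linalg.norm(vec) if np.linalg.norm(vec) else vec
            compartments.append(
                Compartment(
                    id=len(compartments),
                    section_id=sec.id,
                    midpoint=0.5 * (p0 + p1),
                    direction=direction,
                    length=length,
                    diameter=float(np.mean(sec.diameters)),
                    kind=sec.kind,
                    axial_resistivity=axial_resistivity,
                )
            )
            parent.append(-1)
            last_comp_of_section[sec.id] = len(compartments) - 1
            comps_of_section[sec.id] = [len(compartments) - 1]
            continue

        arc = sec.arc_length
        n_comp = max(1, int(np.ceil(arc / max_compartment_length - 1e-12)))
        # arc-length positions of compartment boundaries
        seg_len = np.linalg.norm(np.diff(sec.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        bounds = np.linspace(0.0, arc, n_comp + 1)

        def point_at(s_arc: float) -> tuple[np.ndarray, float]:
            idx = int(np.searchsorted(cum, s_arc, side="right") - 1)
            idx = min(idx, len(seg_len) - 1)
            frac = 0.0 if seg_len[idx] == 0 else (s_arc - cum[idx]) / seg_len[idx]
            pt = sec.points[idx] + frac * (sec.points[idx + 1] - sec.points[idx])
            dia = sec.diameters[idx] + frac * (sec.diameters[idx + 1] - sec.diameters[idx])
            return pt, float(dia)

        # attach to the parent-section compartment nearest the section start
        cand = comps_of_section[sec.parent_id]
        start_pt = sec.points[0]
        prev = min(
            cand,
            key=lambda i: float(
                np.linalg.norm(compartments[i].midpoint - start_pt)
            ),
        )
        own: list[int] = []
        for k in range(n_comp):
            a, da = point_at(bounds[k])
            b, db = point_at(bounds[k + 1])
            vec = b - a
            norm = np.linalg.norm(vec)
            compartments.append(
                Compartment(
                    id=len(compartments),
                    section_id=sec.id,
                    midpoint=0.5 * (a + b),
                    direction=vec / norm if norm else vec,
                    length=float(bounds[k + 1] - bounds[k]),
                    diameter=0.5 * (da + db),
                    kind=sec.kind,
                    axial_resistivity=axial_resistivity,
                )
            )
            parent.append(prev)
            prev = len(compartments) - 1
            own.append(prev)
        last_comp_of_section[sec.id] = prev
        comps_of_section[sec.id] = own

    return CompartmentModel(morphology, compartments, np.asarray(parent))
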
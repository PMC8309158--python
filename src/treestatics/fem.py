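"""Linear static 3D space-frame finite-element solver.

Each tapered span of the tree is subdivided into prismatic Euler–Bernoulli
sub-elements whose section properties (A, Iy, Iz, J) are taken at the
sub-element midpoint from the tapered-span interpolation.  Every node has
six degrees of freedom (three translations, three rotations); the single
support node is fully fixed.  Distributed loads become consistent nodal
forces; stresses are recovered at sub-element end stations from
σ = N/A + My·z/Iy − Mz·y/Iz evaluated over the section's extreme fibers,
with tension positive.

Local frames: local x along the element axis; the auxiliary reference is
global z crossed with the axis, falling back to global x when the element
is within 1° of vertical, so stress axes are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .loads import LoadCase, LoadCombination
from .model import TreeModel

_VERTICAL_COS = math.cos(math.radians(1.0))


class SolverError(RuntimeError):
    pass


def _local_frame(axis: np.ndarray) -> np.ndarray:
    """Rows = local x, y, z axes in global coordinates."""
    x = axis / np.linalg.norm(axis)
    if abs(x[2]) >= _VERTICAL_COS:           # near-vertical member
        ref = np.array([1.0, 0.0, 0.0])      # fall back to global x
    else:
        ref = np.array([0.0, 0.0, 1.0])
    y = np.cross(ref, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.vstack([x, y, z])


def _beam_stiffness(E: float, G: float, A: float, Iy: float, Iz: float,
                    J: float, L: float) -> np.ndarray:
    """12×12 Euler–Bernoulli space-frame stiffness matrix, local frame."""
    k = np.zeros((12, 12))
    a, t = E * A / L, G * J / L
    k[0, 0] = k[6, 6] = a
    k[0, 6] = -a
    k[3, 3] = k[9, 9] = t
    k[3, 9] = -t
    # bending about local z (deflection in local y), Iz
    c = E * Iz
    k[1, 1] = k[7, 7] = 12 * c / L**3
    k[1, 7] = -12 * c / L**3
    k[1, 5] = k[1, 11] = 6 * c / L**2
    k[5, 7] = k[7, 11] = -6 * c / L**2
    k[5, 5] = k[11, 11] = 4 * c / L
    k[5, 11] = 2 * c / L
    # bending about local y (deflection in local z), Iy
    c = E * Iy
    k[2, 2] = k[8, 8] = 12 * c / L**3
    k[2, 8] = -12 * c / L**3
    k[2, 4] = k[2, 10] = -6 * c / L**2
    k[4, 8] = k[8, 10] = 6 * c / L**2
    k[4, 4] = k[10, 10] = 4 * c / L
    k[4, 10] = 2 * c / L
    return k + np.triu(k, 1).T


def _uniform_load_vector(w_local: np.ndarray, L: float) -> np.ndarray:
    """Consistent nodal forces for a uniform line load (local frame)."""
    wx, wy, wz = w_local
    f = np.zeros(12)
    f[0] = f[6] = wx * L / 2
    f[1] = f[7] = wy * L / 2
    f[5] = wy * L**2 / 12
    f[11] = -wy * L**2 / 12
    f[2] = f[8] = wz * L / 2
    f[4] = -wz * L**2 / 12
    f[10] = wz * L**2 / 12
    return f


@dataclass(frozen=True)
class SubElement:
    beam_id: str
    span_index: int
    sub_index: int
    node_i: int           # mesh node indices
    node_j: int
    s0: float             # span fractions covered by this sub-element
    s1: float
    length: float
    rotation: np.ndarray  # 3×3 local frame (rows = local axes)
    A: float
    Iy: float
    Iz: float
    J: float


@dataclass(frozen=True)
class ElementMesh:
    model: TreeModel
    coords: np.ndarray                       # (n_nodes, 3)
    node_ids: tuple[str, ...]                # mesh-node labels
    model_node_index: dict[str, int]         # model node id → mesh index
    elements: tuple[SubElement, ...]
    span_elements: dict[tuple[str, int], tuple[int, ...]]  # (beam, span) → element idx
    subdivisions: int

    @property
    def n_dof(self) -> int:
        return 6 * len(self.node_ids)

    def total_length(self) -> float:
        return sum(e.length for e in self.elements)


def discretize(model: TreeModel, subdivisions: int = 8) -> ElementMesh:
    """Split every span into ``subdivisions`` prismatic sub-elements."""
    if subdivisions < 1:
        raise SolverError("need at least one sub-element per span")
    node_ids: list[str] = list(model.nodes)
    coords = [model.nodes[n].pos() for n in node_ids]
    index = {n: i for i, n in enumerate(node_ids)}
    elements: list[SubElement] = []
    span_map: dict[tuple[str, int], tuple[int, ...]] = {}

    for beam in model.beams:
        for si, span in enumerate(beam.spans):
            p0 = model.nodes[span.start].pos()
            p1 = model.nodes[span.end].pos()
            axis = p1 - p0
            length = float(np.linalg.norm(axis))
            rot = _local_frame(axis)
            sub_len = length / subdivisions
            if sub_len <= 0:
                raise SolverError(
                    f"zero-length sub-element on {beam.id} span {si}")
            chain = [index[span.start]]
            for k in range(1, subdivisions):
                label = f"{beam.id}.{si}.{k}"
                node_ids.append(label)
                coords.append(p0 + axis * (k / subdivisions))
                chain.append(len(node_ids) - 1)
            chain.append(index[span.end])
            ids = []
            for k in range(subdivisions):
                s0, s1 = k / subdivisions, (k + 1) / subdivisions
                props = span.properties_at((s0 + s1) / 2)
                elements.append(SubElement(
                    beam_id=beam.id, span_index=si, sub_index=k,
                    node_i=chain[k], node_j=chain[k + 1],
                    s0=s0, s1=s1, length=sub_len, rotation=rot,
                    A=props.area, Iy=props.Iy, Iz=props.Iz, J=props.J))
                ids.append(len(elements) - 1)
            span_map[(beam.id, si)] = tuple(ids)

    return ElementMesh(model=model, coords=np.asarray(coords),
                       node_ids=tuple(node_ids), model_node_index=index,
                       elements=tuple(elements), span_elements=span_map,
                       subdivisions=subdivisions)


# ---------------------------------------------------------------------------
# Assembly and solve
# ---------------------------------------------------------------------------

def _element_dofs(e: SubElement) -> np.ndarray:
    return np.concatenate([6 * e.node_i + np.arange(6), 6 * e.node_j + np.arange(6)])


def _assemble_stiffness(mesh: ElementMesh) -> sp.csr_matrix:
    E, G = mesh.model.material.E, mesh.model.material.G
    rows, cols, vals = [], [], []
    for e in mesh.elements:
        k_loc = _beam_stiffness(E, G, e.A, e.Iy, e.Iz, e.J, e.length)
        T = np.kron(np.eye(4), e.rotation)
        k_glob = T.T @ k_loc @ T
        dofs = _element_dofs(e)
        rows.append(np.repeat(dofs, 12))
        cols.append(np.tile(dofs, 12))
        vals.append(k_glob.ravel())
    K = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(mesh.n_dof, mesh.n_dof))
    asym = abs(K - K.T).max()
    scale = abs(K).max()
    if scale > 0 and asym / scale > 1e-10:
        raise SolverError(f"asymmetric stiffness matrix ({asym/scale:.2e})")
    return K


def _case_load_vector(mesh: ElementMesh, case: LoadCase) -> np.ndarray:
    """Consistent global nodal forces for one load case."""
    f = np.zeros(mesh.n_dof)
    spans = {(b.id, i): s for b in mesh.model.beams for i, s in enumerate(b.spans)}
    for dl in case.loads:
        key = (dl.beam_id, dl.span_index)
        if key not in mesh.span_elements:
            raise SolverError(f"load targets unknown span {key}")
        span = spans[key]
        for ei in mesh.span_elements[key]:
            e = mesh.elements[ei]
            w = dl.mean_intensity(span, e.s0, e.s1)
            w_glob = w * np.asarray(dl.direction)
            w_loc = e.rotation @ w_glob
            f_loc = _uniform_load_vector(w_loc, e.length)
            T = np.kron(np.eye(4), e.rotation)
            f[_element_dofs(e)] += T.T @ f_loc
    for nl in case.nodal:
        if nl.node_id not in mesh.model_node_index:
            raise SolverError(f"nodal load targets unknown node {nl.node_id!r}")
        base = 6 * mesh.model_node_index[nl.node_id]
        f[base:base + 3] += np.asarray(nl.force, float)
        f[base + 3:base + 6] += np.asarray(nl.moment, float)
    return f


def _combo_load_vector(mesh: ElementMesh, combo) -> np.ndarray:
    if isinstance(combo, LoadCase):
        return _case_load_vector(mesh, combo)
    f = np.zeros(mesh.n_dof)
    for factor, case in zip(combo.factors, combo.cases):
        f += factor * _case_load_vector(mesh, case)
    return f


@dataclass(frozen=True)
class StationStress:
    beam_id: str
    span_index: int
    s: float                # fraction along span
    sigma_tension: float    # Pa, max over fibers (tension positive)
    sigma_compression: float  # Pa, min over fibers (negative in compression)
    N: float
    My: float
    Mz: float


@dataclass(frozen=True)
class SolveResult:
    """Displacements, end forces, fiber stresses and reactions of one combo."""

    mesh: ElementMesh
    name: str
    displacements: np.ndarray          # (n_nodes, 6): ux uy uz rx ry rz (m, rad)
    end_forces: tuple                  # per element: (f_local_12,) local frame
    stations: tuple[StationStress, ...]
    reactions: np.ndarray              # 6-vector at support (forces N, moments N·m)
    applied_total: np.ndarray          # resultant applied force+moment about support
    equilibrium_residual: float

    def node_displacement(self, node_id: str) -> np.ndarray:
        return self.displacements[self.mesh.model_node_index[node_id]]

    def max_horizontal_displacement(self) -> tuple[str, float]:
        """(model node id, magnitude in m) of the largest in-plane movement."""
        best, best_id = -1.0, None
        for nid, idx in self.mesh.model_node_index.items():
            d = float(np.hypot(*self.displacements[idx, :2]))
            if d > best:
                best, best_id = d, nid
        return best_id, best

    def stress_extremes(self, exclusions: set | None = None):
        """(max tensile, max compressive StationStress) over non-excluded beams."""
        exclusions = exclusions or set()
        stations = [st for st in self.stations if st.beam_id not in exclusions]
        if not stations:
            raise SolverError("all stations excluded")
        return (max(stations, key=lambda s: s.sigma_tension),
                min(stations, key=lambda s: s.sigma_compression))


def _fiber_stress_extremes(N, My, Mz, A, Iy, Iz, fibers) -> tuple[float, float]:
    ax = N / A
    if Iy > 0 and Iz > 0 and abs(Iy - Iz) <= 1e-9 * Iy and fibers:
        c = max(math.hypot(y, z) for y, z in fibers)
        b = math.hypot(My, Mz) * c / Iy
        return ax + b, ax - b
    fib = np.asarray(fibers)
    sig = ax + My * fib[:, 1] / Iy - Mz * fib[:, 0] / Iz
    return float(sig.max()), float(sig.min())


def assemble_and_solve(mesh: ElementMesh, combo) -> SolveResult:
    """Solve K·u = f for a load case or combination, fixed support."""
    model = mesh.model
    K = _assemble_stiffness(mesh)
    f = _combo_load_vector(mesh, combo)

    # detect nodes with no attached element (mechanism) up front
    attached = np.zeros(len(mesh.node_ids), bool)
    for e in mesh.elements:
        attached[[e.node_i, e.node_j]] = True
    if not attached.all():
        free = mesh.node_ids[int(np.argmin(attached))]
        raise SolverError(f"disconnected node {free!r}: singular stiffness")

    support_idx = mesh.model_node_index[model.support]
    fixed = 6 * support_idx + np.arange(6)
    free = np.setdiff1d(np.arange(mesh.n_dof), fixed)

    K_ff = K[free][:, free].tocsc()
    u = np.zeros(mesh.n_dof)
    try:
        u[free] = spla.spsolve(K_ff, f[free])
    except Exception as exc:  # pragma: no cover - pathological input
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise SolverError("singular stiffness matrix (non-finite solution)")

    reactions = (K @ u - f)[fixed]

    # resultant of the applied loads about the support point (for equilibrium)
    support_pos = mesh.coords[support_idx]
    f_nodes = f.reshape(-1, 6)
    forces = f_nodes[:, :3]
    moments = f_nodes[:, 3:].sum(axis=0) + np.cross(
        mesh.coords - support_pos, forces).sum(axis=0)
    applied = np.concatenate([forces.sum(axis=0), moments])

    react_force = reactions[:3]
    react_moment = reactions[3:]
    total = np.concatenate([applied[:3] + react_force,
                            applied[3:] + react_moment])
    scale = max(np.linalg.norm(applied), 1.0)
    residual = float(np.linalg.norm(total) / scale)

    # end-force recovery and fiber stresses at element end stations
    E, G = model.material.E, model.material.G
    spans = {(b.id, i): s for b in model.beams for i, s in enumerate(b.spans)}
    end_forces = []
    stations: list[StationStress] = []
    f_eq_cache = _equivalent_local_loads(mesh, combo, spans)
    for ei, e in enumerate(mesh.elements):
        k_loc = _beam_stiffness(E, G, e.A, e.Iy, e.Iz, e.J, e.length)
        T = np.kron(np.eye(4), e.rotation)
        u_loc = T @ u[_element_dofs(e)]
        f_int = k_loc @ u_loc - f_eq_cache[ei]
        end_forces.append(f_int)
        span = spans[(e.beam_id, e.span_index)]
        for s_frac, sgn, base in ((e.s0, -1.0, 0), (e.s1, 1.0, 6)):
            props = span.properties_at(s_frac)
            N = sgn * f_int[base + 0]
            My = sgn * f_int[base + 4]
            Mz = sgn * f_int[base + 5]
            st, sc = _fiber_stress_extremes(
                N, My, Mz, props.area, props.Iy, props.Iz, props.fibers)
            stations.append(StationStress(
                beam_id=e.beam_id, span_index=e.span_index, s=s_frac,
                sigma_tension=st, sigma_compression=sc, N=N, My=My, Mz=Mz))

    name = getattr(combo, "name", "case")
    return SolveResult(mesh=mesh, name=name, displacements=u.reshape(-1, 6),
                       end_forces=tuple(end_forces), stations=tuple(stations),
                       reactions=reactions, applied_total=applied,
                       equilibrium_residual=residual)


def _equivalent_local_loads(mesh: ElementMesh, combo, spans) -> list[np.ndarray]:
    """Per-element consistent load vectors in the local frame."""
    out = [np.zeros(12) for _ in mesh.elements]
    if isinstance(combo, LoadCase):
        members = [(1.0, combo)]
    else:
        members = list(zip(combo.factors, combo.cases))
    for factor, case in members:
        for dl in case.loads:
            key = (dl.beam_id, dl.span_index)
            span = spans[key]
            for ei in mesh.span_elements[key]:
                e = mesh.elements[ei]
                w = dl.mean_intensity(span, e.s0, e.s1)
                w_loc = e.rotation @ (w * np.asarray(dl.direction))
                out[ei] += factor * _uniform_load_vector(w_loc, e.length)
    return out


def fiber_stress(result: SolveResult, beam_id: str, span_index: int,
                 s: float) -> tuple[float, float]:
    """(σ_tension_max, σ_compression_max) at a span station, Pa.

    The station must coincide with a sub-element end (the solver's stress
    recovery points).
    """
    candidates = [st for st in result.stations
                  if st.beam_id == beam_id and st.span_index == span_index
                  and abs(st.s - s) < 1e-9]
    if not candidates:
        raise SolverError(
            f"station s={s} of {beam_id} span {span_index} is not a "
            "recovery point (use k/subdivisions fractions)")
    st = max(candidates, key=lambda c: c.sigma_tension)
    sc = min(candidates, key=lambda c: c.sigma_compression)
    return st.sigma_tension, sc.sigma_compression


def summarize(result: SolveResult, exclusions: list[str] | None = None) -> dict:
    """Headline extremes of one solved combination (mm / MPa units)."""
    excl = set(exclusions or ())
    node_id, d_h = result.max_horizontal_displacement()
    disp = {nid: result.displacements[i] for nid, i in
            result.mesh.model_node_index.items()}
    max_node = max(disp, key=lambda n: np.linalg.norm(disp[n][:3]))
    st, sc = result.stress_extremes(excl)
    return {
        "combination": result.name,
        "max_displacement_node": max_node,
        "max_displacement_mm": float(np.linalg.norm(disp[max_node][:3]) * 1e3),
        "max_horizontal_node": node_id,
        "max_horizontal_mm": d_h * 1e3,
        "max_tension_MPa": st.sigma_tension / 1e6,
        "max_tension_location": (st.beam_id, st.span_index, st.s),
        "max_compression_MPa": sc.sigma_compression / 1e6,
        "max_compression_location": (sc.beam_id, sc.span_index, sc.s),
        "equilibrium_residual": result.equilibrium_residual,
        "excluded_beams": sorted(excl),
    }
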
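"""Wilson loops, spin gauges and the symmetry-restoring manifold.

The core criterion: associate to each oriented bond ``(i -> j)`` the SU(2)
rotation of its polar decomposition; for a closed path the ordered product of
the link rotations is the Wilson loop ``W(C)``.  Spin polarization is
forbidden when every elementary loop is trivial (proportional to the
identity) — equivalently, when a site-local spin gauge exists that removes
all spin dependence from the Hamiltonian — and becomes symmetry-allowed as
soon as one elementary loop is nontrivial.

Electronic loops live on the bond graph (triangular plaquettes for NN
hopping + NNN SOC, one traversal loop for a ring).  Peierls coupling opens
*vibronic* loops in the joint electron-vibration space: the minimal plaquette
``|1,0> -> |2,1> -> |1,1> -> |2,0> -> |1,0>`` carries the SU(2) phase of the
operator sequence ``G T0^-1 G T0^-1``, trivial exactly on the manifold
``g/t = chi/lam`` (equivalently ``g*lam - chi*t = 0``) where every bond
operator is proportional to the same SU(2) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import expm

from .model_builder import (
    ChainSpec,
    CompositeSpace,
    HamiltonianOperator,
    ModeSpec,
    _ladder,
    _mode_operator,
)
from .spin_algebra import (
    ID2,
    SpinRotation,
    axis_angle_from_su2,
    decompose_bond,
    is_trivial,
    pauli_dot,
)

__all__ = [
    "OrientedPath",
    "LoopReport",
    "GaugeMap",
    "SymmetryCheckReport",
    "extract_links",
    "loop_product",
    "enumerate_elementary_loops",
    "plaquette_loop",
    "vibronic_wilson_loop",
    "dimer_phases",
    "interference_term",
    "build_site_gauge",
    "apply_gauge",
    "check_gauge_condition",
    "effective_dimer_soc",
    "lang_firsov",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class OrientedPath:
    """An ordered vertex sequence; vertices are site indices (electronic
    loops) or ``(site, boson occupation)`` pairs (vibronic loops)."""

    vertices: tuple

    @property
    def closed(self) -> bool:
        return len(self.vertices) >= 2 and self.vertices[0] == self.vertices[-1]

    def reversed(self) -> "OrientedPath":
        return OrientedPath(tuple(reversed(self.vertices)))

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class LoopReport:
    """A closed path with its ordered SU(2) product.

    ``phase`` and ``axis`` satisfy ``loop_matrix ~ exp(+i*phase*(axis.sigma))``
    (up to the stripped real scalar for vibronic loops); electronic loops
    report ``phase in [0, pi]``, vibronic loops a signed ``phase in (-pi, pi]``
    about the fixed SOC axis.
    """

    path: OrientedPath
    loop_matrix: np.ndarray
    trace: complex
    phase: float
    axis: np.ndarray
    trivial: bool
    deviation: float
    tol: float


@dataclass(frozen=True)
class GaugeMap:
    """Per-site SU(2) rotations ``W_j`` (anchored at ``W_1 = I``)."""

    rotations: np.ndarray  # (n_sites, 2, 2)

    def __post_init__(self):
        if np.max(np.abs(self.rotations[0] - ID2)) > 1e-12:
            raise ValueError("gauge must be anchored at W_1 = identity")


@dataclass(frozen=True)
class SymmetryCheckReport:
    """Residuals ``|g*lam - chi*t|`` per (bond, mode) of the
    symmetry-restoring condition ``g/t = chi/lam`` on every bond and mode."""

    entries: tuple  # (bond key, mode index, residual eV^2, ok)
    on_manifold: bool
    rel_tol: float


# ---------------------------------------------------------------------------
# links and loop products


def extract_links(chain: ChainSpec) -> dict[tuple[int, int], SpinRotation]:
    """SU(2) link rotations for every oriented bond of an electronic model;
    the reverse orientation carries the inverse matrix.  Bonds with
    ``t = lam = 0`` would be absent, but ChainSpec already forbids storing
    them only implicitly — they are simply skipped here."""
    links: dict[tuple[int, int], SpinRotation] = {}
    for b in chain.bonds:
        if b.t == 0.0 and b.lam * np.linalg.norm(b.axis) == 0.0:
            continue
        u = decompose_bond(b.t, b.lam, b.axis).rotation
        links[(b.i, b.j)] = u
        links[(b.j, b.i)] = u.inverse
    return links


def _su2_report(path: OrientedPath, m: np.ndarray, tol: float) -> LoopReport:
    trace = complex(np.trace(m))
    angle, axis = axis_angle_from_su2(m, tol=1e-9)
    # report W = exp(+i*phase*(axis.sigma)): flip the e^{-i} convention
    phase, axis = angle, (-axis if angle > 0 else axis)
    trivial, dev = is_trivial(m, tol)
    return LoopReport(path, m, trace, phase, axis, trivial, dev, tol)


def loop_product(
    path: OrientedPath | Sequence[int],
    links: Mapping[tuple[int, int], SpinRotation],
    tol: float = 1e-10,
) -> LoopReport:
    """Ordered left-to-right product of link rotations along a closed path."""
    if not isinstance(path, OrientedPath):
        path = OrientedPath(tuple(path))
    if not path.closed:
        raise ValueError("Wilson loops are defined on closed paths only")
    m = ID2.copy()
    for a, b in zip(path.vertices[:-1], path.vertices[1:]):
        if (a, b) not in links:
            raise KeyError(f"no link for step {a} -> {b}")
        m = m @ links[(a, b)].matrix
    return _su2_report(path, m, tol)


def enumerate_elementary_loops(chain: ChainSpec) -> list[OrientedPath]:
    """The elementary loop set generating all Wilson loops of the model.

    An open single-channel chain has no cycles (back-and-forth paths are
    trivially the identity) — the list is empty.  NN+NNN connectivity yields
    one triangle ``(j, j+1, j+2, j)`` per interior site; a ring adds the full
    traversal.  Any remaining connectivity falls back to a minimum cycle
    basis of the bond graph.
    """
    loops: list[OrientedPath] = []
    covered: set[frozenset] = set()

    for j in range(1, chain.n_sites - 1):
        if chain.has_bond(j, j + 1) and chain.has_bond(j + 1, j + 2) and chain.has_bond(j, j + 2):
            loops.append(OrientedPath((j, j + 1, j + 2, j)))
            covered.add(frozenset({j, j + 1, j + 2}))
    if chain.topology == "ring":
        loops.append(OrientedPath(tuple(range(1, chain.n_sites + 1)) + (1,)))
        covered.add(frozenset(range(1, chain.n_sites + 1)))

    g = nx.Graph((b.i, b.j) for b in chain.bonds)
    for cyc in nx.minimum_cycle_basis(g):
        key = frozenset(cyc)
        if key in covered:
            continue
        ordered = _order_cycle(g, cyc)
        if ordered is not None:
            loops.append(OrientedPath(tuple(ordered) + (ordered[0],)))
            covered.add(key)
    return loops


def _order_cycle(g: nx.Graph, nodes: list[int]) -> list[int] | None:
    """Recover a cyclic vertex order for a cycle-basis node set by walking
    the induced subgraph (best effort; None when ambiguous)."""
    sub = g.subgraph(nodes)
    if any(d < 2 for _, d in sub.degree):
        return None
    start = min(nodes)
    order = [start]
    prev = None
    while True:
        nxt = [x for x in sub.neighbors(order[-1]) if x != prev]
        if not nxt:
            return None
        prev, cur = order[-1], min(nxt)
        if cur == start:
            return order if len(order) == len(nodes) else None
        if cur in order:
            return None
        order.append(cur)


def plaquette_loop(
    j: int, chain: ChainSpec, links: Mapping | None = None, tol: float = 1e-10
) -> LoopReport:
    """Triangular plaquette ``W_j = U_{j,j+1} U_{j+1,j+2} U_{j,j+2}^{-1}``
    of a NN+NNN model; for uniform ``t`` and ``lam*(v.sigma)`` this equals
    ``exp(i*(pi/2)*(n.sigma))`` with vanishing trace."""
    for pair in ((j, j + 1), (j + 1, j + 2), (j, j + 2)):
        if not chain.has_bond(*pair):
            raise KeyError(f"plaquette at site {j} needs bond {pair}")
    if links is None:
        links = extract_links(chain)
    m = (
        links[(j, j + 1)].matrix
        @ links[(j + 1, j + 2)].matrix
        @ links[(j, j + 2)].matrix.conj().T
    )
    return _su2_report(OrientedPath((j, j + 1, j + 2, j)), m, tol)


# ---------------------------------------------------------------------------
# vibronic loops (Peierls dimer)


def vibronic_wilson_loop(
    t: float,
    lam: float,
    v: np.ndarray,
    g: float,
    chi: float,
    tol: float = 1e-10,
) -> LoopReport:
    """SU(2) phase of the minimal vibronic plaquette of a Peierls dimer.

    The plaquette ``|1,0> -> |2,1> -> |1,1> -> |2,0> -> |1,0>`` is generated
    by the operator sequence ``G T0^-1 G T0^-1`` with ``T0 = -t*I +
    i*lam*(v.sigma)`` and ``G = -g*I + i*chi*(v.sigma)``.  The product is a
    positive scalar times an SU(2) matrix; the scalar is stripped by
    ``sqrt(det)`` and the signed rotation angle ``Phi_vib in (-pi, pi]``
    about the SOC axis is reported.  Trivial iff ``Phi_vib = 0 mod 2*pi``,
    which happens exactly on the manifold ``g/t = chi/lam``.
    """
    v = np.asarray(v, dtype=float)
    vnorm = np.linalg.norm(v)
    if np.hypot(t, lam * vnorm) < 1e-300:
        raise ValueError("T0 is singular: t and lam*|v| both vanish")
    if np.hypot(g, chi * vnorm) < 1e-300:
        raise ValueError("no phonon-assisted path: g and chi both vanish (G = 0)")
    t0 = -t * ID2 + 1j * lam * pauli_dot(v)
    gg = -g * ID2 + 1j * chi * pauli_dot(v)
    t0_inv = np.linalg.inv(t0)
    a = gg @ t0_inv @ gg @ t0_inv
    det = np.linalg.det(a)
    w = a / np.sqrt(det)
    n = v / vnorm if vnorm > 0 else _Z
    # W = cos(Phi) I + i sin(Phi) (n.sigma)
    cos_phi = float(np.real(np.trace(w)) / 2.0)
    sin_phi = float(np.imag(np.trace(w @ pauli_dot(n)) / 2.0))
    phi = float(np.arctan2(sin_phi, cos_phi))
    trivial = abs(phi) < tol
    path = OrientedPath(((1, 0), (2, 1), (1, 1), (2, 0), (1, 0)))
    return LoopReport(path, w, complex(np.trace(w)), phi, n, trivial, abs(phi), tol)


def dimer_phases(t: float, lam: float, v: np.ndarray, g: float, chi: float):
    """Closed-form phases of the two-path vibronic interferometer.

    ``phi_dir = arctan(lam*|v|/t)`` is the direct-hop rotation angle and
    ``phi_bos = phi_dir - 2*phi_G`` (with ``tan(phi_G) = chi*|v|/g``) the
    phase of the phonon-assisted amplitude ``G T0^-1 G``, each factor
    decomposed as ``-R exp(-i*phi*(n.sigma))``.  Their sum equals the
    vibronic loop phase modulo 2*pi.
    """
    vnorm = float(np.linalg.norm(np.asarray(v, dtype=float)))
    phi_dir = float(np.arctan2(lam * vnorm, t))
    phi_g = float(np.arctan2(chi * vnorm, g))
    return phi_dir, phi_dir - 2.0 * phi_g


def interference_term(t: float, lam: float, v: np.ndarray, g: float, chi: float) -> float:
    """Spin-averaged two-path interference factor ``cos(Phi_vib)`` — equal
    to ``cos(phi_dir + phi_bos)`` and to 1 exactly on the trivial manifold."""
    report = vibronic_wilson_loop(t, lam, v, g, chi)
    return float(np.cos(report.phase))


# ---------------------------------------------------------------------------
# gauges


def build_site_gauge(chain: ChainSpec) -> GaugeMap:
    """Cumulative site rotations ``W_1 = I``, ``W_{j+1} = U_j^{-1} W_j``
    that render an open single-channel chain spin-independent.  Rejected for
    multichannel or ring models, where no such gauge exists in general."""
    if not chain.is_single_channel:
        raise ValueError("site-local gauge exists only for single-channel chains")
    if chain.topology != "open":
        raise ValueError("ring models generally admit no spin-removing gauge")
    links = extract_links(chain)
    rots = np.zeros((chain.n_sites, 2, 2), dtype=complex)
    rots[0] = ID2
    for j in range(1, chain.n_sites):
        u = links.get((j, j + 1))
        u_mat = u.matrix if u is not None else ID2
        rots[j] = u_mat.conj().T @ rots[j - 1]
    return GaugeMap(rots)


def apply_gauge(h: HamiltonianOperator, gauge: GaugeMap) -> HamiltonianOperator:
    """Conjugate ``H -> V^dag H V`` with ``V = diag_j(W_j) (x) I_boson``.

    The spectrum is preserved exactly; with the gauge of
    :func:`build_site_gauge` every transformed NN block becomes ``-R_j*I``
    and the Hamiltonian commutes with all global spin components.
    """
    n = h.space.n_sites
    if gauge.rotations.shape[0] != n:
        raise ValueError("gauge must define one rotation per site")
    bdim = h.space.boson_dim
    blocks = [np.kron(gauge.rotations[j], np.eye(bdim, dtype=complex)) for j in range(n)]
    v = np.zeros_like(h.matrix)
    blk = 2 * bdim
    for j in range(n):
        v[j * blk: (j + 1) * blk, j * blk: (j + 1) * blk] = blocks[j]
    ht = v.conj().T @ h.matrix @ v
    return HamiltonianOperator(ht, h.space, h.chain, h.modes, h.provenance + "+gauge")


def check_gauge_condition(
    chain: ChainSpec, modes: Sequence[ModeSpec], rel_tol: float = 1e-9
) -> SymmetryCheckReport:
    """Symmetry-restoring manifold test ``g_{j,mu}/t_j = chi_{j,mu}/lam_j``
    for every Peierls-coupled bond and mode, evaluated in the singularity-free
    product form ``|g*lam - chi*t| <= rel_tol * max(|g*lam|, |chi*t|)``.

    A single-channel model with no Peierls couplings is trivially
    on-manifold (empty entry list).
    """
    entries = []
    ok_all = True
    for mu, mode in enumerate(modes):
        for p in mode.peierls:
            bond = chain.bond(*p.bond)
            lhs, rhs = p.g * bond.lam, p.chi * bond.t
            residual = abs(lhs - rhs)
            scale = max(abs(lhs), abs(rhs))
            ok = residual <= rel_tol * scale if scale > 0 else True
            ok_all &= ok
            entries.append((p.bond, mu, residual, ok))
    return SymmetryCheckReport(tuple(entries), ok_all, rel_tol)


def effective_dimer_soc(
    t: float, lam: float, g: float, chi: float, v: np.ndarray
) -> np.ndarray:
    """Phonon-dressed effective SOC vector ``(lam*g - chi*t) * v`` of the
    Peierls dimer (proportionality constant 1 by convention); vanishes
    component-wise iff ``g/t = chi/lam``."""
    return (lam * g - chi * t) * np.asarray(v, dtype=float)


# ---------------------------------------------------------------------------
# Lang-Firsov


def lang_firsov(h: HamiltonianOperator) -> HamiltonianOperator:
    """Polaron transformation ``H -> e^S H e^{-S}`` of a Holstein model,
    with ``S = sum_{j,mu} (g_j/omega0) (a^dag - a) n_j``, evaluated by exact
    matrix exponentials on the truncated space.

    On-site energies shift by ``-g_j^2/omega0`` per mode while hoppings
    acquire an exponential phonon dressing; the spectrum is preserved up to
    truncation error.  Models with Peierls couplings are rejected — the
    transformation in this form applies to diagonal coupling only.
    """
    if not h.modes:
        raise ValueError("lang_firsov needs a vibronic Hamiltonian")
    if any(mode.peierls for mode in h.modes):
        raise ValueError("Lang-Firsov as implemented applies to Holstein-only models")
    n = h.space.n_sites
    truncs = h.space.truncations
    s = np.zeros_like(h.matrix)
    for mu, mode in enumerate(h.modes):
        if not mode.holstein_g:
            continue
        a = _ladder(truncs[mu])
        adiff = _mode_operator(a.conj().T - a, mu, truncs)
        for j, g in enumerate(mode.holstein_g, start=1):
            if g == 0.0:
                continue
            proj = np.zeros((2 * n, 2 * n), dtype=complex)
            proj[2 * (j - 1): 2 * j, 2 * (j - 1): 2 * j] = ID2
            s += (g / mode.omega0) * np.kron(proj, adiff)
    es = expm(s)
    ht = es @ h.matrix @ expm(-s)
    ht = 0.5 * (ht + ht.conj().T)  # symmetrize rounding noise
    return HamiltonianOperator(ht, h.space, h.chain, h.modes, h.provenance + "+lang_firsov")
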
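"""Hamiltonian assembly for chiral tight-binding chains with vibrations.

Builds single-electron Hamiltonians on the composite site (x) spin
((x) boson) space for every model variant the Wilson-loop analysis
addresses:

* single-channel chains where hopping ``t_j`` and SOC ``lam_j v_j.sigma``
  act on the same nearest-neighbour (NN) bonds,
* multichannel chains with NN hopping plus next-nearest-neighbour (NNN) SOC,
* Holstein coupling (vibrations modulating on-site energies),
* Peierls coupling (vibrations modulating bond hopping and/or SOC),
* donor-bridge-acceptor extensions for open-system electron transfer.

Every bond contributes the block ``T = -t*I + i*lam*(v.sigma)`` in its
oriented ``(i -> j)`` position plus the Hermitian conjugate.  Basis ordering
is site-major, then spin (up first), then boson occupations (one mixed-radix
factor per mode); sites are 1-based at every user surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spin_algebra import ID2, pauli_dot

__all__ = [
    "Bond",
    "PeierlsCoupling",
    "ChainSpec",
    "ModeSpec",
    "CompositeSpace",
    "HamiltonianOperator",
    "OpenModel",
    "single_channel_chain",
    "multichannel_chain",
    "build_electronic",
    "build_vibronic",
    "truncation_shift",
    "attach_donor_acceptor",
    "generate_random_model",
    "helix_soc_axes",
    "peierls_scan_mode",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class Bond:
    """One oriented bond ``(i -> j)`` with hopping ``t`` (eV), SOC strength
    ``lam`` (eV) and SOC axis ``v`` (dimensionless 3-vector)."""

    i: int
    j: int
    t: float
    lam: float
    v: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.v, dtype=float)

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class PeierlsCoupling:
    """Linear Peierls modulation of one bond by one mode: the bond block
    acquires ``-g*X*I + i*chi*X*(v.sigma)`` with ``X = (a^dag + a)/2``."""

    bond: tuple[int, int]
    g: float
    chi: float


@dataclass(frozen=True)
class ChainSpec:
    """Electronic lattice: sites, on-site energies (eV) and bonds.

    ``topology`` is ``"open"`` or ``"ring"``; a ring carries exactly one
    wrap-around bond ``(n_sites, 1)`` closing the chain.
    """

    n_sites: int
    onsite: tuple[float, ...]
    bonds: tuple[Bond, ...]
    topology: str = "open"

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("a chain needs at least 2 sites")
        if self.topology not in ("open", "ring"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if len(self.onsite) != self.n_sites:
            raise ValueError("onsite energies must match n_sites")
        seen = set()
        n_wrap = 0
        for b in self.bonds:
            if not (1 <= b.i <= self.n_sites and 1 <= b.j <= self.n_sites):
                raise ValueError(f"bond ({b.i}, {b.j}) has endpoints outside 1..{self.n_sites}")
            if b.i == b.j:
                raise ValueError(f"bond ({b.i}, {b.j}) is a self-loop")
            if (b.i, b.j) == (self.n_sites, 1):
                n_wrap += 1
            elif b.i > b.j:
                raise ValueError(f"bond ({b.i}, {b.j}) must be ordered i < j")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond ({b.i}, {b.j})")
            seen.add(key)
            if not np.all(np.isfinite(b.axis)) or b.axis.shape != (3,):
                raise ValueError(f"bond ({b.i}, {b.j}) has an invalid SOC axis")
        if self.topology == "ring" and n_wrap != 1:
            raise ValueError("ring topology requires exactly the wrap bond (n_sites, 1)")
        if self.topology == "open" and n_wrap:
            raise ValueError("open topology must not contain the wrap bond")

    @property
    def is_single_channel(self) -> bool:
        """True when every bond is nearest-neighbour (no NNN / longer bonds)."""
        return all(
            b.j - b.i == 1 or (b.i, b.j) == (self.n_sites, 1) for b in self.bonds
        )

    def bond(self, i: int, j: int) -> Bond:
        for b in self.bonds:
            if (b.i, b.j) == (i, j):
                return b
        raise KeyError(f"no bond ({i}, {j}) in chain")

    def has_bond(self, i: int, j: int) -> bool:
        return any((b.i, b.j) == (i, j) for b in self.bonds)


@dataclass(frozen=True)
class ModeSpec:
    """One vibrational mode: energy quantum ``omega0`` (eV, meaning
    hbar*omega0), per-site Holstein couplings ``holstein_g`` (eV) and
    per-bond Peierls couplings."""

    omega0: float
    holstein_g: tuple[float, ...] = ()
    peierls: tuple[PeierlsCoupling, ...] = ()

    def __post_init__(self):
        if not (self.omega0 > 0 and math.isfinite(self.omega0)):
            raise ValueError("mode frequency must be positive and finite")
        if not all(math.isfinite(g) for g in self.holstein_g):
            raise ValueError("Holstein couplings must be finite")
        for p in self.peierls:
            if not (math.isfinite(p.g) and math.isfinite(p.chi)):
                raise ValueError("Peierls couplings must be finite")


@dataclass(frozen=True)
class CompositeSpace:
    """Index bookkeeping for the site (x) spin (x) boson product space.

    ``truncations`` holds the highest retained occupation ``N_b`` per mode
    (levels ``0..N_b``).  Flat index = ``((site-1)*2 + spin) * B + occ`` with
    ``occ`` the mixed-radix boson index (first mode most significant).
    """

    n_sites: int
    truncations: tuple[int, ...] = ()

    @property
    def boson_dim(self) -> int:
        out = 1
        for nb in self.truncations:
            out *= nb + 1
        return out

    @property
    def dim(self) -> int:
        return self.n_sites * 2 * self.boson_dim

    def flat_index(self, site: int, spin: int, occs: Sequence[int] = ()) -> int:
        if not 1 <= site <= self.n_sites:
            raise ValueError(f"site {site} out of range")
        if spin not in (0, 1):
            raise ValueError("spin must be 0 (up) or 1 (down)")
        occs = tuple(occs)
        if len(occs) != len(self.truncations):
            raise ValueError("one occupation per mode required")
        b = 0
        for occ, nb in zip(occs, self.truncations):
            if not 0 <= occ <= nb:
                raise ValueError(f"occupation {occ} exceeds truncation {nb}")
            b = b * (nb + 1) + occ
        return ((site - 1) * 2 + spin) * self.boson_dim + b


@dataclass(frozen=True)
class HamiltonianOperator:
    """A Hermitian matrix on a :class:`CompositeSpace` with provenance."""

    matrix: np.ndarray
    space: CompositeSpace
    chain: ChainSpec
    modes: tuple[ModeSpec, ...] = ()
    provenance: str = ""

    def __post_init__(self):
        m = self.matrix
        scale = max(np.linalg.norm(m), 1.0)
        if np.max(np.abs(m - m.conj().T)) > 1e-12 * scale:
            raise ValueError("assembled Hamiltonian is not Hermitian")


@dataclass(frozen=True)
class OpenModel:
    """Donor-bridge-acceptor model: total Hamiltonian plus the
    spin-conserving transfer operators ``X_D`` (donor -> bridge site 1) and
    ``X_A`` (bridge site N -> acceptor).  Site ordering: donor = 1, bridge =
    2..N+1, acceptor = N+2."""

    h: HamiltonianOperator
    x_d: np.ndarray
    x_a: np.ndarray
    bridge: HamiltonianOperator

    @property
    def space(self) -> CompositeSpace:
        return self.h.space

    @property
    def donor_site(self) -> int:
        return 1

    @property
    def acceptor_site(self) -> int:
        return self.space.n_sites

    @property
    def bridge_sites(self) -> tuple[int, ...]:
        return tuple(range(2, self.space.n_sites))


# ---------------------------------------------------------------------------
# chain constructors


def single_channel_chain(
    n_sites: int,
    t: float | Sequence[float],
    lam: float | Sequence[float],
    axes: np.ndarray | Sequence[Sequence[float]] | None = None,
    onsite: float | Sequence[float] = 0.0,
    topology: str = "open",
) -> ChainSpec:
    """NN chain where hopping and SOC act on the same bonds (the
    single-channel geometry; degenerate on-site energies default to 0 eV)."""
    n_bonds = n_sites if topology == "ring" else n_sites - 1
    t = np.broadcast_to(np.asarray(t, dtype=float), (n_bonds,))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (n_bonds,))
    if axes is None:
        axes = np.tile(_Z, (n_bonds, 1))
    axes = np.asarray(axes, dtype=float)
    if axes.shape == (3,):
        axes = np.tile(axes, (n_bonds, 1))
    onsite = np.broadcast_to(np.asarray(onsite, dtype=float), (n_sites,))
    bonds = [
        Bond(j, j + 1, float(t[j - 1]), float(lam[j - 1]), tuple(axes[j - 1]))
        for j in range(1, n_sites)
    ]
    if topology == "ring":
        bonds.append(Bond(n_sites, 1, float(t[-1]), float(lam[-1]), tuple(axes[-1])))
    return ChainSpec(n_sites, tuple(onsite), tuple(bonds), topology)


def multichannel_chain(
    n_sites: int,
    t: float | Sequence[float],
    lam: float | Sequence[float],
    axes: np.ndarray | Sequence[Sequence[float]] | None = None,
    onsite: float | Sequence[float] = 0.0,
) -> ChainSpec:
    """Open chain with NN spin-independent hopping and NNN SOC (the minimal
    multichannel geometry hosting triangular plaquettes)."""
    t = np.broadcast_to(np.asarray(t, dtype=float), (n_sites - 1,))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (max(n_sites - 2, 0),))
    if axes is None:
        axes = np.tile(_Z, (max(n_sites - 2, 0), 1))
    axes = np.asarray(axes, dtype=float)
    if axes.shape == (3,):
        axes = np.tile(axes, (max(n_sites - 2, 0), 1))
    onsite = np.broadcast_to(np.asarray(onsite, dtype=float), (n_sites,))
    bonds = [Bond(j, j + 1, float(t[j - 1]), 0.0, tuple(_Z)) for j in range(1, n_sites)]
    bonds += [
        Bond(j, j + 2, 0.0, float(lam[j - 1]), tuple(axes[j - 1]))
        for j in range(1, n_sites - 1)
    ]
    return ChainSpec(n_sites, tuple(onsite), tuple(bonds), "open")


# ---------------------------------------------------------------------------
# Hamiltonian assembly


def bond_block(bond: Bond) -> np.ndarray:
    """The 2x2 spin block ``-t*I + i*lam*(v.sigma)`` of one oriented bond."""
    return -bond.t * ID2 + 1j * bond.lam * pauli_dot(bond.axis)


def build_electronic(chain: ChainSpec) -> HamiltonianOperator:
    """Single-electron Hamiltonian on the 2*n_sites site (x) spin space."""
    n = chain.n_sites
    h = np.zeros((2 * n, 2 * n), dtype=complex)
    for j, eps in enumerate(chain.onsite, start=1):
        sl = slice(2 * (j - 1), 2 * j)
        h[sl, sl] += eps * ID2
    for b in chain.bonds:
        blk = bond_block(b)
        ri, rj = slice(2 * (b.i - 1), 2 * b.i), slice(2 * (b.j - 1), 2 * b.j)
        h[ri, rj] += blk
        h[rj, ri] += blk.conj().T
    space = CompositeSpace(n)
    return HamiltonianOperator(h, space, chain, (), "electronic")


def _ladder(nb: int) -> np.ndarray:
    a = np.zeros((nb + 1, nb + 1), dtype=complex)
    for m in range(nb):
        a[m, m + 1] = np.sqrt(m + 1.0)
    return a


def _mode_operator(op: np.ndarray, mu: int, truncations: Sequence[int]) -> np.ndarray:
    """Embed a single-mode operator into the full boson factor."""
    out = np.array([[1.0 + 0.0j]])
    for k, nb in enumerate(truncations):
        out = np.kron(out, op if k == mu else np.eye(nb + 1, dtype=complex))
    return out


def build_vibronic(
    chain: ChainSpec,
    modes: Sequence[ModeSpec],
    truncation: int | Sequence[int],
    check_convergence: bool = False,
) -> HamiltonianOperator:
    """Vibronic Hamiltonian: electronic part, oscillator energies
    ``omega0*(a^dag a + 1/2)``, Holstein terms ``g_j*(a^dag+a)*n_j`` and
    Peierls bond modulations ``[-g*I + i*chi*(v.sigma)]*X`` with
    ``X = (a^dag + a)/2``.

    ``truncation`` gives the highest boson level ``N_b`` per mode (>= 1).
    With ``check_convergence`` the lowest eigenvalues are compared against a
    ``N_b + 10`` build and a warning is emitted above 1e-8 eV shift.
    """
    modes = tuple(modes)
    if not modes:
        raise ValueError("at least one vibrational mode is required")
    if np.isscalar(truncation):
        truncations = tuple(int(truncation) for _ in modes)
    else:
        truncations = tuple(int(x) for x in truncation)
    if len(truncations) != len(modes) or any(nb < 1 for nb in truncations):
        raise ValueError("one truncation >= 1 per mode is required")

    n = chain.n_sites
    space = CompositeSpace(n, truncations)
    bdim = space.boson_dim
    el = build_electronic(chain).matrix
    h = np.kron(el, np.eye(bdim, dtype=complex))

    ident_el = np.eye(2 * n, dtype=complex)
    for mu, (mode, nb) in enumerate(zip(modes, truncations)):
        a = _ladder(nb)
        num = a.conj().T @ a
        h += np.kron(ident_el, _mode_operator(mode.omega0 * (num + 0.5 * np.eye(nb + 1)), mu, truncations))
        disp = _mode_operator(a + a.conj().T, mu, truncations)
        if mode.holstein_g:
            if len(mode.holstein_g) != n:
                raise ValueError("holstein_g must have one entry per site")
            for j, g in enumerate(mode.holstein_g, start=1):
                if g == 0.0:
                    continue
                proj = np.zeros((2 * n, 2 * n), dtype=complex)
                proj[2 * (j - 1): 2 * j, 2 * (j - 1): 2 * j] = ID2
                h += g * np.kron(proj, disp)
        for p in mode.peierls:
            bond = chain.bond(*p.bond)  # raises if the bond does not exist
            mod = -p.g * ID2 + 1j * p.chi * pauli_dot(bond.axis)
            hop = np.zeros((2 * n, 2 * n), dtype=complex)
            hop[2 * (bond.i - 1): 2 * bond.i, 2 * (bond.j - 1): 2 * bond.j] = mod
            term = np.kron(hop, 0.5 * disp)
            h += term + term.conj().T

    op = HamiltonianOperator(h, space, chain, modes, "vibronic")
    if check_convergence:
        shift = truncation_shift(chain, modes, truncations)
        if shift > 1e-8:
            warnings.warn(
                f"boson truncation not converged: lowest eigenvalues shift by {shift:.2e} eV "
                "when N_b -> N_b + 10",
                stacklevel=2,
            )
    return op


def truncation_shift(
    chain: ChainSpec,
    modes: Sequence[ModeSpec],
    truncations: Sequence[int],
    k: int = 4,
    extra: int = 10,
) -> float:
    """Max shift of the lowest ``k`` eigenvalues when every ``N_b`` grows by
    ``extra`` — the operational truncation-convergence measure."""
    lo = build_vibronic(chain, modes, tuple(truncations))
    hi = build_vibronic(chain, modes, tuple(nb + extra for nb in truncations))
    ev_lo = np.linalg.eigvalsh(lo.matrix)[:k]
    ev_hi = np.linalg.eigvalsh(hi.matrix)[:k]
    return float(np.max(np.abs(ev_lo - ev_hi)))


def attach_donor_acceptor(
    bridge: HamiltonianOperator, eps_d: float, eps_a: float
) -> OpenModel:
    """Extend a bridge Hamiltonian with spin-degenerate donor and acceptor
    sites (no boson coupling) and build the spin-conserving transfer
    operators ``X_D`` and ``X_A``."""
    nb_sites = bridge.space.n_sites
    bdim = bridge.space.boson_dim
    n_tot = nb_sites + 2
    space = CompositeSpace(n_tot, bridge.space.truncations)
    dim = space.dim
    blk = 2 * bdim  # states per site

    h = np.zeros((dim, dim), dtype=complex)
    h[blk: blk * (nb_sites + 1), blk: blk * (nb_sites + 1)] = bridge.matrix
    # boson energy acts regardless of where the electron sits
    bos = np.zeros((bdim, bdim), dtype=complex)
    for mu, (mode, nb) in enumerate(zip(bridge.modes, bridge.space.truncations)):
        a = _ladder(nb)
        bos += _mode_operator(
            mode.omega0 * (a.conj().T @ a + 0.5 * np.eye(nb + 1)), mu, bridge.space.truncations
        )
    donor = slice(0, blk)
    acceptor = slice(blk * (nb_sites + 1), dim)
    h[donor, donor] = eps_d * np.eye(blk) + np.kron(ID2, bos)
    h[acceptor, acceptor] = eps_a * np.eye(blk) + np.kron(ID2, bos)

    x_d = np.zeros((dim, dim), dtype=complex)
    x_d[blk: 2 * blk, 0: blk] = np.eye(blk)  # |B1, s, b> <D, s, b|
    x_a = np.zeros((dim, dim), dtype=complex)
    x_a[blk * (nb_sites + 1):, blk * nb_sites: blk * (nb_sites + 1)] = np.eye(blk)

    chain = bridge.chain
    ext_onsite = (eps_d,) + tuple(chain.onsite) + (eps_a,)
    ext_bonds = tuple(
        Bond(b.i + 1, b.j + 1, b.t, b.lam, b.v) for b in chain.bonds
    )
    ext_chain = ChainSpec(n_tot, ext_onsite, ext_bonds, "open")
    h_op = HamiltonianOperator(h, space, ext_chain, bridge.modes, bridge.provenance + "+DA")
    return OpenModel(h_op, x_d, x_a, bridge)


# ---------------------------------------------------------------------------
# synthetic models and geometry helpers


def generate_random_model(
    seed: int,
    n_sites: int = 8,
    multichannel: bool = False,
    holstein: bool = False,
    peierls: bool = False,
) -> tuple[ChainSpec, tuple[ModeSpec, ...]]:
    """Seeded random chain for property tests.

    Ranges: ``t in [0.05, 0.2]`` eV, ``lam in [1e-4, 1e-2]`` eV, random unit
    SOC axes, ``omega0 in [0.025, 0.1]`` eV, Holstein ``g in [0, 0.04]`` eV,
    Peierls ``g in [0, 0.04]`` / ``chi in [0, 0.02]`` eV (the coupling window
    scanned in the benchmark maps).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)

    def unit_axes(k):
        x = rng.normal(size=(k, 3))
        return x / np.linalg.norm(x, axis=1, keepdims=True)

    t = rng.uniform(0.05, 0.2, size=n_sites - 1)
    lam = rng.uniform(1e-4, 1e-2, size=n_sites - 1)
    if multichannel:
        nnn = max(n_sites - 2, 0)
        axes = unit_axes(nnn)
        bonds = [Bond(j, j + 1, float(t[j - 1]), 0.0, tuple(_Z)) for j in range(1, n_sites)]
        bonds += [
            Bond(j, j + 2, 0.0, float(lam[j - 1]), tuple(axes[j - 1]))
            for j in range(1, n_sites - 1)
        ]
        chain = ChainSpec(n_sites, (0.0,) * n_sites, tuple(bonds), "open")
    else:
        axes = unit_axes(n_sites - 1)
        chain = single_channel_chain(n_sites, t, lam, axes)

    modes: list[ModeSpec] = []
    if holstein or peierls:
        omega0 = float(rng.uniform(0.025, 0.1))
        hol = tuple(rng.uniform(0.0, 0.04, size=n_sites)) if holstein else ()
        pe = ()
        if peierls:
            pe = tuple(
                PeierlsCoupling(
                    b.key, float(rng.uniform(0.0, 0.04)), float(rng.uniform(0.0, 0.02))
                )
                for b in chain.bonds
            )
        modes.append(ModeSpec(omega0, hol, pe))
    return chain, tuple(modes)


def helix_soc_axes(
    n_sites: int,
    radius: float,
    pitch: float,
    sites_per_turn: float = 4.0,
    handedness: int = 1,
) -> np.ndarray:
    """SOC axes from the geometry of a helical chain.

    Sites sit on a helix of given ``radius`` and ``pitch`` (rise per turn);
    axis ``v_j`` is the normalized cross product of consecutive inter-site
    displacements ``d_j x d_{j+1}``, the standard stand-in for the
    chirality-encoding SOC direction of the NNN bond ``j -> j+2``.  Returns
    ``n_sites - 2`` unit vectors.

    ``handedness = -1`` mirrors the helix through the xz-plane (theta ->
    -theta).  The axes are pseudovectors, so the mirror flips their radial
    and axial components (``v -> (-vx, vy, -vz)``); in the planar limit
    ``pitch = 0`` this is a full sign flip.
    """
    if radius <= 0 or sites_per_turn <= 0:
        raise ValueError("geometric parameters must be positive")
    if handedness not in (1, -1):
        raise ValueError("handedness must be +1 or -1")
    theta = handedness * 2.0 * np.pi * np.arange(n_sites) / sites_per_turn
    z = pitch * np.arange(n_sites) / sites_per_turn
    pos = np.stack([radius * np.cos(theta), radius * np.sin(theta), z], axis=1)
    d = np.diff(pos, axis=0)
    axes = np.cross(d[:-1], d[1:])
    norms = np.linalg.norm(axes, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate geometry: consecutive bonds are collinear")
    return axes / norms[:, None]


def peierls_scan_mode(chain: ChainSpec, omega0: float, g: float, chi: float) -> ModeSpec:
    """One Peierls mode modulating hopping (coupling ``g``) on every bond
    carrying hopping and SOC (coupling ``chi``) on every bond carrying SOC —
    the pattern scanned in the benchmark polarization maps."""
    couplings = tuple(
        PeierlsCoupling(
            b.key, g if b.t != 0.0 else 0.0, chi if b.lam != 0.0 else 0.0
        )
        for b in chain.bonds
    )
    return ModeSpec(omega0, (), couplings)
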
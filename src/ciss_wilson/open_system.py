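"""Donor-bridge-acceptor Redfield dynamics and acceptor spin polarization.

The reduced density matrix evolves as

    hbar drho/dt = -i [H_tot, rho]
                   + Gamma * sum_{xi=D,A} (Y_xi rho X_xi^dag - X_xi^dag Y_xi rho + h.c.)
                   + Gamma_d * sum_{n, mu} (L rho L^dag - 1/2 {L^dag L, rho})

with spin-independent transfer operators ``X_D`` (donor -> bridge site 1)
and ``X_A`` (bridge site N -> acceptor), energy-filtered counterparts
``Y_xi`` and site-local spin-dephasing operators ``L_{n,mu} = P_n sigma_mu``
on every bridge site and axis.

The ``Y_xi`` filter implements the wide-band, low-temperature limit: ``X``
is expanded in the eigenbasis of ``H_tot`` and only energy-non-increasing
matrix elements are kept (ties below 1e-12 eV count as allowed), so transfer
is downhill from a donor placed above the bridge band to an acceptor below
it.  The construction is isolated in :func:`energy_filter` so it can be
swapped for a different environment model.

Propagation exponentiates the vectorized generator once per run and steps
the density matrix across a uniform grid — exact for the fixed truncation,
stiffness-free (the transfer rate is orders of magnitude below the bond
energies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .model_builder import OpenModel
from .spin_algebra import PAULI
from .units import HBAR_EV_FS

__all__ = [
    "OpenConfig",
    "DensityTrajectory",
    "Generator",
    "energy_filter",
    "build_generator",
    "donor_mixed_state",
    "propagate_density",
    "acceptor_polarization",
]


@dataclass(frozen=True)
class OpenConfig:
    """Transfer rate ``gamma`` (eV), spin-dephasing rate ``gamma_d`` (eV)
    and the simulated time window (fs).  Defaults follow the benchmark:
    Gamma = 5e-5 eV, Gamma_d in {0, 1e-6} eV."""

    gamma: float = 5e-5
    gamma_d: float = 0.0
    t_max: float = 20000.0
    n_steps: int = 400

    def __post_init__(self):
        if self.gamma < 0 or self.gamma_d < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class DensityTrajectory:
    """Observables along a density-matrix trajectory: site populations,
    site spin expectations, trace and Hermiticity deviation per time."""

    times: np.ndarray
    populations: np.ndarray  # (n_t, n_sites)
    spins: np.ndarray  # (n_t, n_sites, 3)
    traces: np.ndarray
    herm_dev: np.ndarray
    rhos: np.ndarray | None = None  # (n_t, dim, dim) when stored


@dataclass(frozen=True)
class Generator:
    """Vectorized Liouvillian (column-stacking convention) with its pieces."""

    superop: np.ndarray  # (dim^2, dim^2), units 1/fs
    model: OpenModel
    config: OpenConfig


def _sop(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Superoperator of ``rho -> a @ rho @ b`` under column-stacked vec."""
    return np.kron(b.T, a)


def energy_filter(x: np.ndarray, h: np.ndarray, tie_tol: float = 1e-12) -> np.ndarray:
    """Energy-lowering part of a transfer operator in the eigenbasis of
    ``h``: keep ``<a|X|b>`` only for ``E_a <= E_b + tie_tol``."""
    w, v = np.linalg.eigh(h)
    xe = v.conj().T @ x @ v
    allowed = w[:, None] <= w[None, :] + tie_tol
    return v @ (xe * allowed) @ v.conj().T


def build_generator(model: OpenModel, cfg: OpenConfig) -> Generator:
    """Assemble the full Liouvillian superoperator (1/fs units)."""
    h = model.h.matrix
    dim = h.shape[0]
    ident = np.eye(dim, dtype=complex)
    lv = (-1j / HBAR_EV_FS) * (_sop(h, ident) - _sop(ident, h))

    if cfg.gamma > 0:
        for x in (model.x_d, model.x_a):
            y = energy_filter(x, h)
            xd = x.conj().T
            term = _sop(y, xd) - _sop(xd @ y, ident)
            # h.c. of the map rho -> Y rho X^dag - X^dag Y rho
            term += _sop(x, y.conj().T) - _sop(ident, y.conj().T @ x)
            lv += (cfg.gamma / HBAR_EV_FS) * term

    if cfg.gamma_d > 0:
        bdim = model.space.boson_dim
        n = model.space.n_sites
        for site in model.bridge_sites:
            for sigma in PAULI:
                l = np.zeros((dim, dim), dtype=complex)
                sl = slice((site - 1) * 2 * bdim, site * 2 * bdim)
                l[sl, sl] = np.kron(sigma, np.eye(bdim, dtype=complex))
                ld_l = l.conj().T @ l
                lv += (cfg.gamma_d / HBAR_EV_FS) * (
                    _sop(l, l.conj().T)
                    - 0.5 * _sop(ld_l, ident)
                    - 0.5 * _sop(ident, ld_l)
                )
    return Generator(lv, model, cfg)


def donor_mixed_state(model: OpenModel) -> np.ndarray:
    """Electron on the donor as an even spin mixture, boson vacuum."""
    space = model.space
    rho = np.zeros((space.dim, space.dim), dtype=complex)
    occs = (0,) * len(space.truncations)
    for spin in (0, 1):
        idx = space.flat_index(model.donor_site, spin, occs)
        rho[idx, idx] = 0.5
    return rho


def propagate_density(
    generator: Generator,
    rho0: np.ndarray,
    t_max: float | None = None,
    n_steps: int | None = None,
    store_states: bool = False,
) -> DensityTrajectory:
    """Step a density matrix across a uniform grid with the one-shot
    propagator ``exp(L * dt)``.

    ``rho0`` must be Hermitian, unit-trace and positive semidefinite within
    1e-10.  Trace and Hermiticity are monitored along the trajectory.
    """
    cfg = generator.config
    t_max = cfg.t_max if t_max is None else t_max
    n_steps = cfg.n_steps if n_steps is None else n_steps
    model = generator.model
    dim = model.space.dim
    rho0 = np.asarray(rho0, dtype=complex)
    if rho0.shape != (dim, dim):
        raise ValueError("density matrix does not match the model space")
    if np.max(np.abs(rho0 - rho0.conj().T)) > 1e-10:
        raise ValueError("initial state is not Hermitian")
    if abs(np.trace(rho0) - 1.0) > 1e-10:
        raise ValueError("initial state is not normalized")
    if np.min(np.linalg.eigvalsh(0.5 * (rho0 + rho0.conj().T))) < -1e-10:
        raise ValueError("initial state is not positive semidefinite")

    times = np.linspace(0.0, t_max, n_steps)
    dt = times[1] - times[0] if n_steps > 1 else 0.0
    prop = expm(generator.superop * dt)

    n, bdim = model.space.n_sites, model.space.boson_dim
    pops = np.zeros((n_steps, n))
    spins = np.zeros((n_steps, n, 3))
    traces = np.zeros(n_steps)
    herm = np.zeros(n_steps)
    rhos = np.zeros((n_steps, dim, dim), dtype=complex) if store_states else None

    vec = rho0.flatten(order="F")
    for it in range(n_steps):
        rho = vec.reshape(dim, dim, order="F")
        if store_states:
            rhos[it] = rho
        traces[it] = float(np.real(np.trace(rho)))
        herm[it] = float(np.max(np.abs(rho - rho.conj().T)))
        blocks = rho.reshape(n, 2, bdim, n, 2, bdim)
        # trace over bosons of the on-site 2x2 spin blocks
        site_blocks = np.einsum("isbjtb->isjt", blocks)
        for k in range(n):
            m = site_blocks[k, :, k, :]
            pops[it, k] = float(np.real(m[0, 0] + m[1, 1]))
            spins[it, k, 0] = float(np.real(m[1, 0] + m[0, 1])) / 2.0
            spins[it, k, 1] = float(np.imag(m[1, 0] - m[0, 1])) / 2.0
            spins[it, k, 2] = float(np.real(m[0, 0] - m[1, 1])) / 2.0
        if it < n_steps - 1:
            vec = prop @ vec
    return DensityTrajectory(times, pops, spins, traces, herm, rhos)


def acceptor_polarization(traj: DensityTrajectory, model: OpenModel) -> np.ndarray:
    """``P_A(t) = <n_{A,up} - n_{A,down}> = 2 <S_{z,A}(t)>``."""
    return 2.0 * traj.spins[:, model.acceptor_site - 1, 2]
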
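# Methods

## Model class

The package treats single-electron tight-binding chains of `N` sites with
spin-1/2, the minimal setting for chirality-induced spin selectivity (CISS)
in organic chains.  Each bond `(i, j)` carries a spin-independent hopping
`t_j` (eV) and a spin-orbit term `i lam_j (v_j . sigma)` (eV) with a fixed
SOC axis `v_j`; the bond block of the Hamiltonian is

    T_j = -t_j I + i lam_j (v_j . sigma)  =  -R_j U_j,

with `R_j = sqrt(t_j^2 + (lam_j |v_j|)^2)` and `U_j = exp(-i phi_j n_j .
sigma)`, `phi_j = arctan(lam_j |v_j| / t_j)`, `n_j = v_j/|v_j|`.  The SU(2)
rotations `U_j` are the link variables of the analysis.  Vibrations enter in
two flavours:

* **Holstein** — a mode of energy `hbar omega_0` couples to on-site
  occupation, `g_j (a^dag + a) n_j` (diagonal coupling);
* **Peierls** — the mode modulates a bond linearly, the block becoming
  `-(t + g X) I + i (lam + chi X)(v.sigma)` with `X = (a^dag + a)/2`
  (off-diagonal coupling).

Boson spaces are truncated at `N_b` quanta per mode; multiple modes tensor
together (mixed-radix index, site-major / spin / boson ordering, 1-based
site labels at every user surface).  Energies are in eV, times in fs,
`hbar = 0.6582119569 eV fs`.

## The Wilson-loop criterion

For any closed oriented path the ordered product of link rotations is the
Wilson loop `W(C)`; it is *trivial* when proportional to the identity (both
signs count).  The criterion: spin polarization from an unpolarized initial
state is forbidden iff every elementary loop is trivial, which is equivalent
to the existence of a site-local spin gauge (one SU(2) rotation per site)
that removes all spin dependence.  Concretely:

* **Open single-channel chains** have no cycles, all loops reduce to
  back-and-forth products `U U^-1 = I`, and the cumulative gauge
  `W_1 = I`, `W_{j+1} = U_j^{-1} W_j` maps `H` onto a spin-independent
  chain with hoppings `R_j`.  This is verified constructively on seeded
  random chains (commutators with all global spin components below 1e-10).
* **NN hopping + NNN SOC** opens one triangular plaquette per interior
  site, `W_j = U_{j,j+1} U_{j+1,j+2} U_{j,j+2}^{-1}`.  For uniform
  parameters `W_j = exp(i (pi/2) n.sigma)` and `Tr W_j = 0`: the two paths
  from `j` to `j+2` produce orthogonal spin rotations and maximal
  spin-dependent interference.
* **Rings** add one full-traversal loop, generically nontrivial; its
  triviality is reported numerically rather than from a closed-form `t/lam`
  condition.
* **Peierls coupling** opens *vibronic* plaquettes.  For a dimer the
  minimal loop `|1,0> -> |2,1> -> |1,1> -> |2,0> -> |1,0>` carries the
  SU(2) phase of `G T0^{-1} G T0^{-1}`, `G = -g I + i chi (v.sigma)`.  The
  product equals a positive scalar times an SU(2) matrix; the scalar is
  stripped by `sqrt(det)` and the signed angle `Phi_vib in (-pi, pi]` about
  the SOC axis reported.  `Phi_vib = 0 (mod 2 pi)` iff `g/t = chi/lam`
  (equivalently `g lam - chi t = 0`), where every bond operator is
  `f(X) T0` with real `f` and the spin and vibrational sectors factorize.
  For `N` sites and several modes the manifold condition applies bond-by-bond
  and mode-by-mode; it is checked in the product form `|g lam - chi t|`
  against a relative tolerance (1e-9), which avoids the division-by-zero of
  the ratio form.

Two bookkeeping conventions matter and are fixed package-wide:

* Rotation angles are *full* exponent angles, `U = exp(-i angle (axis .
  sigma))`, reduced to `[0, pi]` with the axis sign absorbing the branch.
  This is the convention under which `phi = arctan(Lambda/t)` reconstructs
  the bond matrix entrywise and a quarter-turn (`t = 0`) gives `U = -i
  n.sigma`.
* The phase of a composite amplitude is defined compositionally — each
  factor decomposed as `-R exp(-i phi n.sigma)` with `R > 0` and the phases
  summed.  Under this convention the phonon-assisted amplitude
  `A_bos = G T0^{-1} G` carries `phi_bos = phi_dir - 2 phi_G`
  (`tan phi_G = chi|v|/g`) and the two-path interference identity
  `cos(Phi_vib) = cos(phi_dir + phi_bos)` holds to 1e-10, which the tests
  verify against the independent matrix-product route.  Extracting
  `phi_bos` with a positive-scalar convention instead would flip the sign
  of the cosine: the scalar prefactor of `A_bos` is negative.

A note on the factorized-manifold identity: a string of `k` on-manifold
bond operators equals `(prod_i f(X_i)) T0^k` — a scalar times the *k-th
power* of the common rotation, i.e. all trajectories with the same hop
count share one SU(2) rotation.  The tests assert that form; the looser
"scalar times T0" phrasing is dimensionally inconsistent for `k >= 2`.

## Holstein models and Lang-Firsov

The polaron transformation `H -> e^S H e^{-S}` with `S = sum_j (g_j /
hbar omega_0)(a^dag - a) n_j` is evaluated by exact matrix exponentials on
the truncated space rather than through the normal-ordered closed form;
this is truncation-safe and lets the expected consequences be *checked*
rather than assumed: on-site energies shift by `-g_j^2 / hbar omega_0`
(verified on a near-decoupled site to 1e-10) and the spectrum is preserved
(1e-8 at `N_b = 30`).  Because the dressing renormalizes hopping and SOC by
the same bosonic factor, Holstein coupling never breaks the spin gauge —
the zero-polarization dynamics tests confirm this for one and two
independent modes.

## Unitary dynamics

Propagation uses the full spectral decomposition of `H` (spaces up to ~600
states in the benchmarks), exact for fixed truncation; an independent
high-order ODE integration of the Schrodinger equation serves as the test
oracle (agreement below 1e-8).  The default preparation is an electron on
site 1, boson vacuum, and *unpolarized* spin, implemented as the average of
the two opposite pure preparations (exactly the maximally mixed spin
state).  CISS is polarization emerging from unpolarized input, so no pure
default direction is silently chosen; Fig-4-style pure-state traces require
an explicit direction.

Observables are `<S_{mu,k}(t)>` (site-projected `sigma_mu/2`, traced over
bosons) and the peak polarization

    P^max_{z,k} = 2 max_{t in [0, 1 ps]} |<S_{z,k}(t)>|

on a 2000-point uniform grid (a 10x finer grid moves the value by < 1e-3).

The benchmark map scans one Peierls mode (`hbar omega_0 = 50 meV`) over
`g in [0, 0.04] eV` (hopping-carrying bonds) and `chi in [0, 0.02] eV`
(SOC-carrying bonds) for the 6-site chain with NN `t = 0.1 eV` and NNN
`lam = 1e-3 eV` along z.  At `N_b = 50` (the benchmark truncation; 20, 35
and 50 agree to 1e-6 here) the 5x5 grid maximum of `P^max_{z,6}` is
0.1844, against ~0.2-0.25 quoted for the regime; the residual gap traces
to the convention choice that the map couplings multiply `X = (a^dag+a)/2`
— reading them as coefficients of `(a^dag+a)` doubles the modulation and
yields ~0.25.  The printed-equation convention is kept throughout.

## Open-system dynamics

Donor-bridge-acceptor transfer uses the master equation

    hbar d rho/dt = -i [H, rho]
        + Gamma sum_{xi=D,A} (Y_xi rho X_xi^dag - X_xi^dag Y_xi rho + h.c.)
        + Gamma_d sum_{n,mu} (L rho L^dag - (1/2){L^dag L, rho}),

with spin-conserving transfer operators `X_D` (donor to bridge site 1) and
`X_A` (bridge site N to acceptor), spin dephasing `L_{n,mu} = P_n sigma_mu`
on every bridge site, and `Y_xi` the wide-band low-temperature energy
filter: `X` in the eigenbasis of `H` keeping only energy-non-increasing
elements (ties within 1e-12 eV allowed, so symmetric models behave
deterministically).  The filter is isolated in one function
(`energy_filter`) so a different environment model can be substituted.
Defaults: `Gamma = 5e-5 eV`, `Gamma_d in {0, 1e-6} eV`, 4 bridge sites,
donor at +0.3 eV and acceptor at -0.3 eV — bracketing the bridge band
(half-width `2t = 0.2 eV`) so both transfer steps are downhill.

The vectorized generator (column-stacking convention) is exponentiated once
per run and the density matrix stepped over a uniform grid — stiffness-free
despite `Gamma` being four orders below the bond energies, and
trace/Hermiticity-preserving to 1e-8/1e-10 along every trajectory (checked,
not assumed; the closed-system limit `Gamma = Gamma_d = 0` reproduces the
unitary observables to 1e-12).

Bridge parameters for the five open-system scenarios (NN-only, +Holstein,
+Peierls, symmetry-restored Peierls with `g_i = t_i/10` and `chi_i =
lam_i/10`, NNN SOC) are package defaults chosen to match the unitary
benchmark: `t = 0.1 eV`, `lam = 1e-3 eV`, `v || z`, `omega_0 = 50 meV`,
generic Peierls `g = 0.02 / chi = 0.01 eV` (the midpoint of the scanned
coupling window).  The qualitative contract — `P_A(t)` identically zero
iff all loops trivial, decoherence damping bridge oscillations while
stabilizing the acceptor signal — is what the tests assert; specific
trajectory shapes depend on these choices.

## Problem sizes and numerical choices

* Boson truncations: `N_b = 50` for the benchmark map (convergence margin
  1e-8 eV on low eigenvalues when `N_b -> N_b + 10`); `N_b = 2-3` for
  open-system runs, where the zero-polarization statements are symmetry
  identities valid at any truncation and the nonzero/damping statements are
  qualitative — the superoperator dimension grows as `(12 (N_b+1))^2` and
  this keeps single runs at seconds.
* Redfield windows: 15-20 ps with 150-400 steps; one `expm` of the
  generator per run, then matrix-vector stepping.
* Triviality tolerance 1e-10 absolute (all link algebra is exact to machine
  precision; loose tolerances would mask bugs); manifold residual tolerance
  1e-9 relative.
* Degenerate eigenvalue ties in the energy filter: treated as allowed
  transitions (1e-12 eV window).
* The synthetic-model generator draws `t in [0.05, 0.2] eV`, `lam in
  [1e-4, 1e-2] eV`, uniform random unit SOC axes, `omega_0 in [0.025, 0.1]
  eV`, Holstein/Peierls couplings inside the scanned benchmark windows
  (`g <= 0.04`, `chi <= 0.02 eV`) — the parameter regime of the printed
  benchmarks, which real molecular chains (DNA-like stacks, helical
  oligomers) motivate.  It emulates parameter diversity, not molecular
  structure: axes are i.i.d. rather than helix-correlated (the
  `helix_soc_axes` helper provides geometry-derived axes as a documented
  stand-in for a microscopic construction), on-site energies are
  degenerate, and no disorder correlations are included.  Tests passing on
  these draws establish the symmetry dichotomy, not quantitative transport
  for any specific molecule.

## Known limitations

* Single electron only; no electron-electron interaction, no external
  fields, no electrode self-energies.
* Vacuum initial boson state; no finite-temperature phonon occupations.
* The SOC axes are inputs; their microscopic derivation from molecular
  geometry is out of scope beyond the helix cross-product helper.  For
  that helper, mirror symmetry flips the axial and radial pseudovector
  components (full sign flip only in the planar limit).
* Ring-traversal loop triviality is reported numerically; no closed-form
  condition is hard-coded.
* The open-system energy filter is one standard reading of the wide-band,
  low-temperature limit; quantitative rates near resonances would need the
  full environment spectral density.
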
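"""Open-system electron transfer: the Wilson-loop verdict survives dissipation.

A 4-site bridge is connected incoherently to a donor (0.3 eV above the
band) and an acceptor (0.3 eV below) with transfer rate Gamma = 5e-5 eV,
plus optional spin dephasing Gamma_d on the bridge.  Starting from an
unpolarized electron on the donor, the acceptor polarization
P_A(t) = <n_up - n_down> stays numerically zero for every bridge whose
Wilson loops are all trivial (NN-only, Holstein, symmetry-restored Peierls)
and becomes finite when a loop is nontrivial (generic Peierls, NNN SOC) —
with or without decoherence.
"""

import numpy as np

import ciss_wilson as cw

nn = cw.single_channel_chain(4, t=0.1, lam=1e-3)
nnn = cw.multichannel_chain(4, t=0.1, lam=1e-3)

holstein = cw.ModeSpec(0.05, (0.02, 0.015, 0.01, 0.02))
peierls = cw.ModeSpec(0.05, (), tuple(cw.PeierlsCoupling(b.key, 0.02, 0.01) for b in nn.bonds))
restored = cw.ModeSpec(0.05, (), tuple(cw.PeierlsCoupling(b.key, b.t / 10, b.lam / 10) for b in nn.bonds))

scenarios = [
    ("NN only (trivial)", nn, None),
    ("NN + Holstein (trivial)", nn, holstein),
    ("NN + Peierls (nontrivial)", nn, peierls),
    ("NN + restored Peierls (trivial)", nn, restored),
    ("NNN SOC (nontrivial)", nnn, None),
]

for gamma_d in (0.0, 1e-6):
    print(f"\nGamma_d = {gamma_d:g} eV:")
    for label, chain, mode in scenarios:
        h = cw.build_vibronic(chain, [mode], 2) if mode else cw.build_electronic(chain)
        model = cw.attach_donor_acceptor(h, eps_d=0.3, eps_a=-0.3)
        gen = cw.build_generator(model, cw.OpenConfig(5e-5, gamma_d, t_max=15000.0, n_steps=150))
        traj = cw.propagate_density(gen, cw.donor_mixed_state(model))
        pa = cw.acceptor_polarization(traj, model)
        print(
            f"  {label:32} max|P_A| = {np.max(np.abs(pa)):9.2e}   "
            f"acceptor population(15 ps) = {traj.populations[-1, -1]:.3f}"
        )
print(
    "\ntrivial-loop bridges stay at machine-zero polarization; nontrivial"
    "\nones transfer a finite spin imbalance to the acceptor."
)
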
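# 6-site benchmark chain: NN hopping 0.1 eV, NNN SOC 1e-3 eV along z,
# one 50 meV Peierls-active mode scanned by the `ciss map` subcommand.
model:
  n_sites: 6
  topology: open
  bonds:
    - {i: 1, j: 2, t: 0.1}
    - {i: 2, j: 3, t: 0.1}
    - {i: 3, j: 4, t: 0.1}
    - {i: 4, j: 5, t: 0.1}
    - {i: 5, j: 6, t: 0.1}
    - {i: 1, j: 3, lam: 1.0e-3, v: [0.0, 0.0, 1.0]}
    - {i: 2, j: 4, lam: 1.0e-3, v: [0.0, 0.0, 1.0]}
    - {i: 3, j: 5, lam: 1.0e-3, v: [0.0, 0.0, 1.0]}
    - {i: 4, j: 6, lam: 1.0e-3, v: [0.0, 0.0, 1.0]}
  truncation: 12
map:
  omega0: 0.05
  n_g: 3
  n_chi: 3
  sites: [6]
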
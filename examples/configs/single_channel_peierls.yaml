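# 4-site single-channel bridge with a generic (off-manifold) Peierls mode;
# used by `ciss wilson|dynamics|open`.
model:
  n_sites: 4
  topology: open
  bonds:
    - {i: 1, j: 2, t: 0.1, lam: 1.0e-3, v: [0.0, 0.0, 1.0]}
    - {i: 2, j: 3, t: 0.1, lam: 1.0e-3, v: [0.0, 0.0, 1.0]}
    - {i: 3, j: 4, t: 0.1, lam: 1.0e-3, v: [0.0, 0.0, 1.0]}
  modes:
    - omega0: 0.05
      peierls:
        - {bond: [1, 2], g: 0.02, chi: 0.01}
        - {bond: [2, 3], g: 0.02, chi: 0.01}
        - {bond: [3, 4], g: 0.02, chi: 0.01}
  truncation: 6
dynamics:
  t_max: 1000.0
  n_steps: 1000
open_system:
  gamma: 5.0e-5
  gamma_d: 1.0e-6
  t_max: 15000.0
  n_steps: 150
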
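"""Unit conventions used throughout the package.

Energies are in eV, times in fs, spin expectations in units of hbar.
"""

#: Reduced Planck constant in eV*fs.
HBAR_EV_FS = 0.6582119569
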
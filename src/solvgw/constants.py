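"""Physical constants and unit conversions (atomic units internally)."""

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

#: 1 Hartree in eV
HARTREE_EV = 27.211386

#: Coulomb constant scaling the QM <-> polarizable-MM coupling (a.u.).
#: Enters linearly in the response right-hand side and quadratically in dv_res.
DEFAULT_KC = 0.7853
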
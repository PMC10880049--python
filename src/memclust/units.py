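"""Physical constants and unit conversions.

Internal convention: all user-facing lengths are nm, times are ns, and
diffusion coefficients are nm^2/ns.  Hydrodynamic model evaluation happens
in SI internally; the conversion constants live here and nowhere else.
"""

#: Boltzmann constant, J/K (2019 SI definition).
KB = 1.380649e-23

#: Metres per nanometre.
M_PER_NM = 1e-9

#: 1 nm^2/ns expressed in m^2/s  (1e-18 m^2 / 1e-9 s).
M2_PER_S_PER_NM2_PER_NS = 1e-9

#: 1 m^2/s expressed in nm^2/ns.
NM2_PER_NS_PER_M2_PER_S = 1.0 / M2_PER_S_PER_NM2_PER_NS


def d_si_to_nm2_ns(d_m2_s: float) -> float:
    """Convert a diffusion coefficient from m^2/s to nm^2/ns."""
    return d_m2_s * NM2_PER_NS_PER_M2_PER_S


def d_nm2_ns_to_si(d_nm2_ns: float) -> float:
    """Convert a diffusion coefficient from nm^2/ns to m^2/s."""
    return d_nm2_ns * M2_PER_S_PER_NM2_PER_NS
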
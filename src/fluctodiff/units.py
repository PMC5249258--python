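"""Unit conventions and conversions.

Internal units are nm for length and ns for time. Diffusion coefficients are
exposed in μm²/s, the unit conventional for membrane diffusion:

    1 nm²/ns = 1e-6 μm² / 1e-9 s = 1e3 μm²/s
"""

UM2_PER_S_PER_NM2_PER_NS = 1.0e3
NM2_PER_NS_PER_UM2_PER_S = 1.0e-3

NS_PER_US = 1.0e3
NM_PER_ANGSTROM = 0.1


def d_nm2ns_to_um2s(d: float) -> float:
    """Convert a diffusion coefficient from nm²/ns to μm²/s."""
    return d * UM2_PER_S_PER_NM2_PER_NS


def d_um2s_to_nm2ns(d: float) -> float:
    """Convert a diffusion coefficient from μm²/s to nm²/ns."""
    return d * NM2_PER_NS_PER_UM2_PER_S
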
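"""Unit conversions for the RTI diffusion pipeline.

All internal computation is done in cm / s / mol·cm⁻³ / A: the diffusion
literature reports D in cm²/s and mixing unit systems is the dominant
failure mode in this kind of analysis.  User-facing interfaces accept
micrometres and millimolar and convert explicitly through these helpers.
"""

#: Faraday constant, C/mol.
FARADAY = 96485.33212


def um_to_cm(x_um: float) -> float:
    """Micrometres → centimetres."""
    return x_um * 1e-4


def cm_to_um(x_cm: float) -> float:
    """Centimetres → micrometres."""
    return x_cm * 1e4


def mM_to_mol_per_cm3(c_mM: float) -> float:
    """Millimolar (mmol/L) → mol/cm³.  1 mM = 1e-6 mol/cm³."""
    return c_mM * 1e-6


def mol_per_cm3_to_mM(c: float) -> float:
    """mol/cm³ → millimolar."""
    return c * 1e6
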
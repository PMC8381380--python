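"""Fixed physico-chemical and physiological conversion constants.

The defaults encode the conversion factors used throughout the analysis:
an *E. coli*-like cell volume of 1 fL, an OD-specific plating density of
1e9 CFU mL^-1 OD^-1, the slow nitrogenase turnover number (~5 N2 s^-1,
two N atoms fixed per turnover), and the translation-capacity parameters
of a slowly growing, N-limited cell (7.6e7 polymerised residues per cell,
~8000 active ribosomes elongating at <=5 residues s^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

#: Monoisotopic proton mass (Da).
PROTON_MASS = 1.007276
#: Monoisotopic mass of water (Da).
WATER_MASS = 18.010565
#: Avogadro's number (mol^-1).
AVOGADRO = 6.022e23
#: Heavy-label mass shift for [13C6,15N2]-Lys/Arg: 6*1.003355 + 2*0.997035 Da.
HEAVY_SHIFT_KR = 8.0142
#: Monoisotopic mass of a uridine-5'-monophosphate adduct (uridylylation, Da).
UMP_MASS = 306.0253


@dataclass(frozen=True)
class PhysiologyConstants:
    """Conversion constants for per-cell and rate calculations.

    All attributes must be positive; every value can be overridden at
    construction for sensitivity analyses.
    """

    cell_volume_l: float = 1e-15
    cells_per_od_ml: float = 1e9
    avogadro: float = AVOGADRO
    nitrogenase_kcat: float = 5.0        # N2 reduced per enzyme per second
    n_atoms_per_turnover: float = 2.0    # N atoms fixed per N2 turnover
    total_proteome_aa: float = 7.6e7     # polymerised residues per cell
    active_ribosomes: float = 8000.0     # per cell
    elongation_rate: float = 5.0         # residues s^-1 per ribosome

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name!r} must be > 0")


DEFAULT_CONSTANTS = PhysiologyConstants()
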
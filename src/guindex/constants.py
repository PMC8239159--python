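"""Physical constants: monoisotopic masses and isotope abundance tables.

Values are IUPAC/CODATA monoisotopic masses (Da) and representative
terrestrial isotopic abundances, embedded as constants so the chemistry
layer never performs a runtime lookup.
"""

from __future__ import annotations

# (mass Da, abundance) per isotope, ordered by increasing nucleon number.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.0030740048, 0.99636), (15.0001088989, 0.00364)),
    "O": ((15.9949146196, 0.99757), (16.9991317565, 0.00038), (17.9991596129, 0.00205)),
    "S": (
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ),
    "Na": ((22.9897692820, 1.0),),
}

#: Monoisotopic (lightest-isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: Proton mass, Da (electron mass is neglected throughout: < 0.0006 Da,
#: far below the working ppm tolerances).
PROTON_MASS = 1.00727646677

#: Na+ cation mass, Da (atomic Na minus one electron).
SODIUM_CATION_MASS = 22.98922192

ADDUCT_MASS: dict[str, float] = {
    "proton": PROTON_MASS,
    "sodium": SODIUM_CATION_MASS,
}

#: 13C - 12C mass difference, Da: spacing of aggregated isotope peaks.
NEUTRON_SPACING = 1.00335483507
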
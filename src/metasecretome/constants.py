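"""Physical constants used throughout the pipeline.

Monoisotopic residue masses follow the standard amino-acid residue mass
table (IUPAC atomic masses; identical to the values shipped with common
proteomics toolkits, frozen here so that search results do not silently
change when a dependency updates its tables).
"""

# Monoisotopic residue (i.e. water-free) masses in Da.
MONO_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294986,
}

CANONICAL_RESIDUES = frozenset(MONO_RESIDUE_MASS)

WATER_MONO = 18.0105646863
PROTON_MASS = 1.00727646688

# Modification deltas (Da, monoisotopic).
CARBAMIDOMETHYL = 57.021464   # fixed on every Cys
OXIDATION = 15.994915         # variable on Met
DEAMIDATION = 0.984016        # variable on Asn/Gln

VARIABLE_MODS: dict[str, tuple[str, float]] = {
    # residue -> (modification name, delta)
    "M": ("Oxidation", OXIDATION),
    "N": ("Deamidation", DEAMIDATION),
    "Q": ("Deamidation", DEAMIDATION),
}

# IUPAC nucleotide alphabet accepted in contigs.
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
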
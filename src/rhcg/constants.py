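"""Physical constants and ideal-geometry parameters used across the package.

All lengths are in Angstrom, angles in degrees, couplings in Hz unless
stated otherwise.
"""

# CODATA physical constants (SI)
MU_0 = 1.25663706212e-06        # vacuum permeability, N A^-2
HBAR = 1.054571817e-34          # reduced Planck constant, J s
GAMMA_1H = 2.6752218744e8       # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_15N = -2.7116e7           # 15N gyromagnetic ratio, rad s^-1 T^-1
K_B_KJ_MOL = 8.31446261815324e-3  # Boltzmann constant x Avogadro, kJ mol^-1 K^-1

#: Idealized amide bond length used for the dipolar prefactor and for
#: geometric reconstruction of amide hydrogens.
AMIDE_NH_LENGTH = 1.04

#: Default temperature (K) for free-energy conversions S_KL * k_B * T.
DEFAULT_TEMPERATURE = 298.15

#: 3J(HN,HA) Karplus coefficients (Hz) of the Voegeli parameterization.
KARPLUS_HNHA = (8.4, -1.36, 0.33)

# Ideal backbone geometry (Engh-Huber-like values).
BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.521,
    ("C", "CH3"): 1.505,   # acetyl / N-methyl cap carbon
    ("N", "CH3"): 1.455,
}

BOND_ANGLES = {
    ("C", "N", "CA"): 121.7,
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,
    ("CA", "C", "O"): 120.8,
    ("C", "CA", "CB"): 110.6,
    ("CA", "N", "CH3"): 121.7,
    ("CH3", "C", "N"): 116.2,
    ("CH3", "C", "O"): 121.0,
}

#: Improper dihedral N-C-CA-CB placing CB for an L-amino acid.
CB_IMPROPER_DIHEDRAL = 122.686

#: Conventional Ramachandran basin centers (phi, psi) in degrees.
DEFAULT_BASINS = {
    "alpha": (-63.0, -43.0),
    "beta": (-120.0, 130.0),
    "ppii": (-75.0, 150.0),
}
DEFAULT_BASIN_SPREAD = 15.0
OMEGA_TRANS = 180.0
OMEGA_SPREAD = 3.0

#: Default clash cutoff between heavy atoms of merged parts (Angstrom).
DEFAULT_CLASH_CUTOFF = 2.0

#: Default confidence parameters mirroring the published tau K18 protocol.
DEFAULT_THETA = 5.0
DEFAULT_THETA_F = 10.0
DEFAULT_POOL_SIZE = 10000
DEFAULT_N_CHAINS = 50000

#: Forward-model error defaults added in quadrature to experimental errors.
FORWARD_ERROR_DEFAULTS = {
    "ca_shift": 1.0,   # ppm
    "j3_hnha": 0.9,    # Hz
}

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}

#: Tau K18 sequence, residues 244-372 of 2N4R tau numbering (129 residues).
TAU_K18_SEQUENCE = (
    "QTAPVPMPDLKNVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKCGSKDNIKHVPGGG"
    "SVQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITHVPGGG"
    "NKKIE"
)
#: One pad residue (L243) precedes K18 during growth and is removed after
#: assembly, so the grown construct is 130 residues long.
TAU_K18_PAD_SEQUENCE = "L" + TAU_K18_SEQUENCE
TAU_K18_FIRST_RESID = 244
TAU_K18_PAD_FIRST_RESID = 243
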
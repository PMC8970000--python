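"""Synthetic fragment-conformer libraries and observables with known truth.

The published workflow samples each fragment in explicit-solvent replica
exchange MD.  For desk-scale work and testing, this module emulates those
libraries with ideal-geometry backbones whose (phi, psi) angles are drawn
from mixtures of Ramachandran basins (alpha, beta, polyproline II), with
trans peptide bonds and acetyl / N-methyl caps.  The generator is seeded
and reproducible, and ground truth (basin occupancies, true ensemble
weights) is recorded so that recovery can be scored exactly.

What this emulates: local backbone preferences, their residue-to-residue
variability, and cap effects on fragment termini.  What it does not: side
chains beyond C-beta, solvent effects, and the force-field-specific
Ramachandran statistics of real amino acids — passing tests show that the
machinery is correct, not that any particular protein's ensemble is.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .fragments import FragmentConformer, FragmentDef, FragmentLibrary
from .geometry import dihedral, place_atom
from .reweight import ObservableSet
from .struct import Structure

__all__ = [
    "BasinModel",
    "build_backbone",
    "sample_library",
    "make_synthetic_observations",
    "SyntheticShiftPredictor",
    "backbone_dihedrals",
]


@dataclass
class BasinModel:
    """Per-residue mixture of Ramachandran basins.

    ``basins`` maps basin name -> (phi, psi) center in degrees.
    ``occupancies`` maps a residue index (or the string ``"default"``) to a
    dict of basin probabilities summing to 1.  ``spread`` is the Gaussian
    angular width (degrees) applied to both phi and psi; glycine gets
    1.5x the spread, proline's phi is clamped near -65 degrees.
    """

    basins: dict = field(default_factory=lambda: dict(K.DEFAULT_BASINS))
    occupancies: dict = field(default_factory=dict)
    spread: float = K.DEFAULT_BASIN_SPREAD
    omega: float = K.OMEGA_TRANS
    omega_spread: float = K.OMEGA_SPREAD

    def __post_init__(self) -> None:
        if self.spread <= 0 or self.omega_spread <= 0:
            raise ValueError("angular spreads must be positive")
        if "default" not in self.occupancies:
            n = len(self.basins)
            self.occupancies["default"] = {b: 1.0 / n for b in self.basins}
        for res, occ in self.occupancies.items():
            total = sum(occ.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"occupancies for {res!r} sum to {total}, not 1")

    def occupancy(self, residue: int) -> dict:
        return self.occupancies.get(residue, self.occupancies["default"])

    def with_occupancy(self, residue: int, occ: dict) -> "BasinModel":
        new = dict(self.occupancies)
        new[residue] = dict(occ)
        return BasinModel(dict(self.basins), new, self.spread, self.omega, self.omega_spread)


def build_backbone(
    sequence: str,
    dihedrals,
    first_resid: int = 1,
    caps: bool = True,
) -> Structure:
    """Build an ideal-geometry backbone (N, CA, C, O, CB except Gly) from
    per-residue (phi, psi, omega) dihedrals in degrees.

    With ``caps`` the chain is blocked by an acetyl (ACE) group before the
    first residue and an N-methyl (NME) group after the last, which makes
    every phi/psi/omega well defined.  Residue ids start at
    ``first_resid``; caps get ids ``first_resid - 1`` and ``last + 1``.
    """
    dihedrals = [tuple(map(float, d)) for d in dihedrals]
    if len(dihedrals) != len(sequence):
        raise ValueError(
            f"got {len(dihedrals)} dihedral triples for {len(sequence)} residues"
        )
    if not caps:
        raise NotImplementedError("uncapped building is not supported; caps "
                                  "are stripped at assembly time instead")
    bl, ba = K.BOND_LENGTHS, K.BOND_ANGLES

    rows: list[tuple[int, str, str, str, np.ndarray]] = []

    # seed: acetyl cap CH3-C(=O)- in the xy plane
    ch3 = np.zeros(3)
    c_prev = np.array([bl[("C", "CH3")], 0.0, 0.0])
    ang = np.radians(ba[("CH3", "C", "N")])
    n_cur = c_prev + bl[("C", "N")] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    cap_id = first_resid - 1
    rows.append((cap_id, "ACE", "CH3", "C", ch3))
    rows.append((cap_id, "ACE", "C", "C", c_prev))
    o_cap = place_atom(n_cur, ch3, c_prev, bl[("C", "O")], ba[("CH3", "C", "O")], 180.0)
    rows.append((cap_id, "ACE", "O", "O", o_cap))

    ca_prev = ch3  # plays the role of CA(i-1) in the omega dihedral
    for i, (aa, (phi, psi, omega)) in enumerate(zip(sequence, dihedrals)):
        res = first_resid + i
        res3 = K.AA3[aa]
        ca = place_atom(ca_prev, c_prev, n_cur, bl[("N", "CA")], ba[("C", "N", "CA")], omega)
        c = place_atom(c_prev, n_cur, ca, bl[("CA", "C")], ba[("N", "CA", "C")], phi)
        n_next = place_atom(n_cur, ca, c, bl[("C", "N")], ba[("CA", "C", "N")], psi)
        o = place_atom(n_cur, ca, c, bl[("C", "O")], ba[("CA", "C", "O")], psi + 180.0)
        rows.append((res, res3, "N", "N", n_cur))
        rows.append((res, res3, "CA", "C", ca))
        rows.append((res, res3, "C", "C", c))
        rows.append((res, res3, "O", "O", o))
        if aa != "G":
            cb = place_atom(
                n_cur, c, ca, bl[("CA", "CB")], ba[("C", "CA", "CB")],
                K.CB_IMPROPER_DIHEDRAL,
            )
            rows.append((res, res3, "CB", "C", cb))
        ca_prev, c_prev, n_cur = ca, c, n_next

    nme_id = first_resid + len(sequence)
    rows.append((nme_id, "NME", "N", "N", n_cur))
    ch3_nme = place_atom(
        ca_prev, c_prev, n_cur, bl[("N", "CH3")], ba[("C", "N", "CA")], 180.0
    )
    rows.append((nme_id, "NME", "CH3", "C", ch3_nme))

    return Structure(
        np.array([r[0] for r in rows]),
        np.array([r[1] for r in rows]),
        np.array([r[2] for r in rows]),
        np.array([r[3] for r in rows]),
        np.array([r[4] for r in rows]),
    )


def backbone_dihedrals(structure: Structure, residue: int) -> tuple[float, float, float]:
    """(phi, psi, omega) in degrees for one residue, using cap atoms where
    needed; the inverse of :func:`build_backbone` for checking round trips."""
    s = structure
    res_prev, res_next = residue - 1, residue + 1
    c_prev = s.atom_coord(res_prev, "C")
    ca_prev_name = "CA" if "CA" in s.atom_name[s.res_id == res_prev] else "CH3"
    ca_prev = s.atom_coord(res_prev, ca_prev_name)
    n = s.atom_coord(residue, "N")
    ca = s.atom_coord(residue, "CA")
    c = s.atom_coord(residue, "C")
    n_next = s.atom_coord(res_next, "N")
    phi = float(dihedral(c_prev, n, ca, c))
    psi = float(dihedral(n, ca, c, n_next))
    omega = float(dihedral(ca_prev, c_prev, n, ca))
    return phi, psi, omega


def _wrap(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


def sample_library(
    fragment_def: FragmentDef,
    basin_model: BasinModel,
    n_conformers: int,
    seed: int,
) -> FragmentLibrary:
    """Draw a seeded fragment library from the basin mixture model."""
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(basin_model.basins)
    conformers = []
    first = fragment_def.residue_span[0]
    for i in range(n_conformers):
        dihedrals = []
        for j, aa in enumerate(fragment_def.sequence):
            occ = basin_model.occupancy(first + j)
            probs = np.array([occ.get(b, 0.0) for b in names])
            basin = names[int(rng.choice(len(names), p=probs / probs.sum()))]
            phi0, psi0 = basin_model.basins[basin]
            spread = basin_model.spread * (1.5 if aa == "G" else 1.0)
            phi = rng.normal(phi0, spread)
            psi = rng.normal(psi0, spread)
            if aa == "P":
                phi = rng.normal(-65.0, 5.0)
            omega = rng.normal(basin_model.omega, basin_model.omega_spread)
            dihedrals.append((_wrap(phi), _wrap(psi), _wrap(omega)))
        structure = build_backbone(fragment_def.sequence, dihedrals, first_resid=first)
        conformers.append(
            FragmentConformer(structure, source=f"synthetic seed={seed} conformer={i}")
        )
    return FragmentLibrary(fragment_def, conformers)


@dataclass
class SyntheticShiftPredictor:
    """Toy chemical-shift predictor: coil baseline plus a basin offset.

    Assigns each residue's (phi, psi) to the nearest basin center (great-
    circle distance on the torus) and returns ``coil + offset[basin]``.
    Exists to exercise the fragment-reweighting machinery end to end; it is
    not a physical shift model.
    """

    basins: dict = field(default_factory=lambda: dict(K.DEFAULT_BASINS))
    offsets: dict = field(
        default_factory=lambda: {"alpha": 2.0, "beta": -1.5, "ppii": -0.8}
    )
    coil: float = 55.0

    def basin_of(self, phi: float, psi: float) -> str:
        best, best_d = None, np.inf
        for name, (p0, s0) in self.basins.items():
            d = _wrap(phi - p0) ** 2 + _wrap(psi - s0) ** 2
            if d < best_d:
                best, best_d = name, d
        return best

    def __call__(self, structure: Structure, residue: int, observable: str = "ca_shift") -> float:
        phi, psi, _ = backbone_dihedrals(structure, residue)
        return self.coil + self.offsets.get(self.basin_of(phi, psi), 0.0)


def make_synthetic_observations(
    ensemble,
    true_weights: np.ndarray,
    forward_models: dict,
    noise_sigmas: dict,
    seed: int,
) -> tuple[ObservableSet, dict]:
    """Emit synthetic "experimental" observations from a known truth.

    ``forward_models`` maps observable id -> callable(Structure) -> float;
    ``noise_sigmas`` maps the same ids to Gaussian noise levels (also used
    as the reported sigma; a zero noise level reports sigma = 1 so chi2
    stays finite).  Returns the observable set plus a ground-truth record.
    """
    w = np.asarray(true_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("true weights must lie on the simplex")
    rng = np.random.default_rng(seed)
    ids = list(forward_models)
    forward = np.empty((len(ids), len(ensemble)))
    for c, chain in enumerate(ensemble.structures()):
        for i, key in enumerate(ids):
            forward[i, c] = forward_models[key](chain)
    truth = forward @ w
    sig = np.array([noise_sigmas[k] for k in ids], dtype=float)
    noise = rng.normal(0.0, 1.0, len(ids)) * sig
    values = truth + noise
    reported = np.where(sig > 0, sig, 1.0)
    obs = ObservableSet(values, reported, forward, ids)
    ground_truth = {
        "true_weights": w,
        "true_averages": truth,
        "noise": noise,
    }
    return obs, ground_truth
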
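"""Forward models from conformers and ensembles to experimental observables.

Implements scalar couplings (Karplus 3J(HN,HA)), residual dipolar couplings
under a shape-based steric-alignment approximation, SAXS profiles by Debye
summation with the two-regime scale/background/aggregation fit, radii of
gyration and empirical hydrodynamic radii, self-avoiding-walk (SAW-nu)
distance distributions with Foerster transfer efficiencies, and secondary
chemical-shift bookkeeping behind a pluggable shift-predictor interface.

Every ensemble-level observable is linear in the chain weights: the
ensemble value is the w_c-weighted mean of per-chain values (root-mean-
square for R_G, harmonic mean for R_h, as each experiment averages).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import gamma as gamma_fn

from . import constants as K
from .geometry import dihedral
from .struct import Structure

__all__ = [
    "RdcProfile",
    "ScatteringProfile",
    "DistanceModel",
    "karplus_j3",
    "phi_angles",
    "j3_profile",
    "dmax_hn",
    "alignment_tensor",
    "amide_h_vectors",
    "rdc_profile",
    "saxs_debye",
    "fit_saxs",
    "radius_of_gyration",
    "ensemble_rg",
    "hydrodynamic_radius",
    "saw_nu_distribution",
    "fret_efficiency",
    "secondary_shifts",
]


@dataclass
class RdcProfile:
    residues: np.ndarray
    values: np.ndarray              # ensemble-averaged D_HN per residue, Hz
    per_chain: np.ndarray | None = None   # (C, R) optional


@dataclass
class ScatteringProfile:
    q: np.ndarray                   # 1/Angstrom, strictly increasing
    intensity: np.ndarray
    fit_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class DistanceModel:
    """SAW-nu end-to-end distance density p(r) on r > 0 (Angstrom)."""

    nu: float
    scale: float        # length scale b of the reduced density
    mean_distance: float
    r0_forster: float | None = None

    _GAMMA_FLORY = 1.1615   # universal SAW entropic exponent

    @property
    def _g(self) -> float:
        return (self._GAMMA_FLORY - 1.0) / self.nu

    @property
    def _delta(self) -> float:
        return 1.0 / (1.0 - self.nu)

    def _moment(self, k: int) -> float:
        """Integral of x^(k+2+g) exp(-x^delta) over x > 0 (analytic)."""
        d, g = self._delta, self._g
        return gamma_fn((k + 3.0 + g) / d) / d

    def pdf(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        x = r / self.scale
        norm = self.scale * self._moment(0)
        out = np.where(
            r > 0, x ** (2.0 + self._g) * np.exp(-np.clip(x, 0, 700) ** self._delta), 0.0
        )
        return out / norm

    def mean(self) -> float:
        return self.scale * self._moment(1) / self._moment(0)


# ---------------------------------------------------------------------------
# scalar couplings

def karplus_j3(phi, params: tuple[float, float, float] = K.KARPLUS_HNHA):
    """3J(HN,HA) from the backbone phi dihedral (degrees):
    A cos^2(phi - 60) + B cos(phi - 60) + C, in Hz."""
    a, b, c = params
    x = np.cos(np.radians(np.asarray(phi, dtype=float) - 60.0))
    return a * x**2 + b * x + c


def phi_angles(structure: Structure, residues) -> np.ndarray:
    """Backbone phi dihedrals (degrees) for the given residues."""
    s = structure
    out = np.empty(len(residues))
    for i, r in enumerate(residues):
        out[i] = dihedral(
            s.atom_coord(r - 1, "C"),
            s.atom_coord(r, "N"),
            s.atom_coord(r, "CA"),
            s.atom_coord(r, "C"),
        )
    return out


def j3_profile(ensemble, residues, weights=None, params=K.KARPLUS_HNHA) -> np.ndarray:
    """Weighted ensemble mean of per-chain 3J(HN,HA) couplings (Hz)."""
    w = _weights(ensemble, weights)
    vals = np.stack(
        [karplus_j3(phi_angles(s, residues), params) for s in ensemble.structures()]
    )
    return w @ vals


# ---------------------------------------------------------------------------
# residual dipolar couplings

def dmax_hn(bond_length: float = K.AMIDE_NH_LENGTH) -> float:
    """Static 1H-15N dipolar prefactor in kHz for a given N-H length (A).

    D_max = (mu0 / 4 pi) * gammaH * |gammaN| * hbar / (pi r^3); 21.7 kHz at
    the idealized 1.04 A amide bond, scaling as 1/r^3.
    """
    if bond_length <= 0:
        raise ValueError("bond length must be positive")
    r = bond_length * 1e-10
    d_hz = (K.MU_0 / (4 * np.pi)) * K.GAMMA_1H * abs(K.GAMMA_15N) * K.HBAR / (np.pi * r**3)
    return d_hz / 1e3


def alignment_tensor(structure: Structure, order_scale: float = 1e-3) -> np.ndarray:
    """Shape-based Saupe-like order tensor from the gyration tensor.

    The molecule's principal axes define the steric-alignment frame and the
    anisotropy of the gyration eigenvalues sets the order parameters:
    S = order_scale * (3/2) (T - tr(T)/3 I) / tr(T).  Traceless and
    symmetric by construction; zero for a perfectly spherical shape, and
    axially symmetric with S_zz = -2 S_xx for an ideal rod.  This captures
    the shape dependence of steric alignment; the absolute scale of an
    obstruction-medium simulation is folded into ``order_scale``.
    """
    heavy = structure.coords[structure.heavy_mask]
    if len(heavy) < 4:
        raise ValueError("need at least 4 heavy atoms")
    centered = heavy - heavy.mean(axis=0)
    t = centered.T @ centered / len(centered)
    tr = np.trace(t)
    if tr <= 0 or np.linalg.matrix_rank(t, tol=1e-10 * max(tr, 1.0)) < 2:
        raise ValueError("degenerate (collinear) geometry")
    return order_scale * 1.5 * (t - tr / 3.0 * np.eye(3)) / tr


def amide_h_vectors(structure: Structure, residues) -> np.ndarray:
    """Unit N->H bond vectors, reconstructing H geometrically when absent.

    H is placed opposite the bisector of the N-CA and N-C(prev) bonds at
    the idealized 1.04 A amide length (prolines have no amide H and raise).
    """
    s = structure
    out = np.empty((len(residues), 3))
    missing = []
    for i, r in enumerate(residues):
        names = s.atom_name[s.res_id == r]
        resname = s.res_name[s.res_id == r][0]
        if resname == "PRO":
            missing.append(int(r))
            continue
        n = s.atom_coord(r, "N")
        if "H" in names:
            h = s.atom_coord(r, "H")
        else:
            try:
                ca = s.atom_coord(r, "CA")
                c_prev = s.atom_coord(r - 1, "C")
            except KeyError:
                missing.append(int(r))
                continue
            u = -(_unit(ca - n) + _unit(c_prev - n))
            h = n + K.AMIDE_NH_LENGTH * _unit(u)
        out[i] = _unit(h - n)
    if missing:
        raise ValueError(f"no amide H and none reconstructible for residues {missing}")
    return out


def rdc_profile(
    ensemble,
    residues,
    weights=None,
    order_scale: float = 1e-3,
    tensor_backend=None,
    dmax_khz: float | None = None,
) -> RdcProfile:
    """Per-residue 1H-15N RDCs, weight-averaged over the ensemble.

    Per chain, D_r = D_HN^max * v_r^T S v_r with v_r the amide bond unit
    vector and S the chain's alignment tensor (for traceless S this equals
    D_max <P2(cos theta)> over the alignment-biased orientations).
    ``tensor_backend(Structure) -> 3x3`` can inject externally computed
    alignment tensors (e.g. from an obstruction-surface simulation).
    """
    residues = np.asarray(list(residues), dtype=int)
    dmax_hz = (dmax_hn() if dmax_khz is None else dmax_khz) * 1e3
    w = _weights(ensemble, weights)
    per_chain = np.empty((len(w), len(residues)))
    for c, s in enumerate(ensemble.structures()):
        tensor = (
            tensor_backend(s) if tensor_backend is not None
            else alignment_tensor(s, order_scale)
        )
        v = amide_h_vectors(s, residues)
        per_chain[c] = dmax_hz * np.einsum("ri,ij,rj->r", v, tensor, v)
    return RdcProfile(residues, w @ per_chain, per_chain)


# ---------------------------------------------------------------------------
# SAXS

def saxs_debye(
    target,
    q_grid,
    form_factors=None,
    weights=None,
) -> ScatteringProfile:
    """Debye-sum scattering profile I(q) = sum_ij f_i f_j sinc(q d_ij).

    ``target`` is a Structure or an ensemble; ensemble profiles are the
    weighted mean of per-chain profiles.  ``form_factors`` maps element ->
    reduced per-atom constant (default: effective electron counts for
    heavy atoms); q in 1/Angstrom.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q grid must be nonnegative")
    if isinstance(target, Structure):
        return ScatteringProfile(q, _debye_single(target, q, form_factors))
    w = _weights(target, weights)
    intensity = np.zeros_like(q)
    for c, s in enumerate(target.structures()):
        intensity += w[c] * _debye_single(s, q, form_factors)
    return ScatteringProfile(q, intensity)


_DEFAULT_FORM_FACTORS = {"C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0, "H": 1.0}


def _debye_single(structure: Structure, q: np.ndarray, form_factors) -> np.ndarray:
    ff_map = _DEFAULT_FORM_FACTORS if form_factors is None else form_factors
    mask = structure.heavy_mask
    xyz = structure.coords[mask]
    if len(xyz) == 0:
        raise ValueError("empty chain")
    f = np.array([ff_map.get(e, 6.0) for e in structure.element[mask]])
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    ff = f[:, None] * f[None, :]
    qd = q[:, None, None] * d[None, :, :]
    kernel = np.ones_like(qd)
    nz = qd != 0
    kernel[nz] = np.sin(qd[nz]) / qd[nz]
    return np.einsum("qij,ij->q", kernel, ff)


def fit_saxs(
    profile: ScatteringProfile,
    q_exp,
    i_exp,
    q_split: float = 0.012,
) -> dict:
    """Two-stage fit of a simulated profile to an experimental curve.

    Stage 1 (q > q_split): linear least squares for scale a and constant
    background b in I_exp ~ a I_sim + b.  Stage 2 (q < q_split), with
    (a, b) held fixed: aggregate amplitude c and size R_a in
    I_exp ~ a I_sim + b + c exp(-q^2 R_a^2 / 3), accounting for possible
    mild aggregation at low q.  Returns {a, b, c, R_a}.
    """
    q_exp = np.asarray(q_exp, dtype=float)
    i_exp = np.asarray(i_exp, dtype=float)
    i_sim = np.interp(q_exp, profile.q, profile.intensity)
    hi = q_exp > q_split
    lo = q_exp < q_split
    if hi.sum() < 2:
        raise ValueError(f"need >= 2 experimental points above q_split={q_split}")
    design = np.column_stack([i_sim[hi], np.ones(hi.sum())])
    (a, b), *_ = np.linalg.lstsq(design, i_exp[hi], rcond=None)
    out = {"a": float(a), "b": float(b), "c": 0.0, "R_a": np.nan}
    if lo.sum() >= 2:
        resid_lo = i_exp[lo] - (a * i_sim[lo] + b)
        q_lo = q_exp[lo]

        def model(p):
            c, ra = p
            return c * np.exp(-(q_lo**2) * ra**2 / 3.0) - resid_lo

        c0 = max(float(resid_lo.max()), 1e-12)
        fit = least_squares(model, x0=[c0, 100.0], bounds=([0, 1.0], [np.inf, 1e4]))
        out["c"], out["R_a"] = float(fit.x[0]), float(fit.x[1])
    elif lo.sum() > 0:
        raise ValueError(f"need >= 2 experimental points below q_split={q_split}")
    return out


# ---------------------------------------------------------------------------
# chain dimensions

def radius_of_gyration(structure: Structure, mode: str = "geometric") -> float:
    """R_G in Angstrom; geometric mode weights all heavy atoms equally."""
    mask = structure.heavy_mask
    xyz = structure.coords[mask]
    if len(xyz) == 0:
        raise ValueError("empty structure")
    if mode == "geometric":
        m = np.ones(len(xyz))
    elif mode == "mass_weighted":
        masses = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
        m = np.array([masses.get(e, 12.0) for e in structure.element[mask]])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    com = (m[:, None] * xyz).sum(0) / m.sum()
    return float(np.sqrt((m * ((xyz - com) ** 2).sum(-1)).sum() / m.sum()))


def ensemble_rg(ensemble, weights=None, mode: str = "geometric") -> float:
    """Root-mean-square R_G over the weighted ensemble."""
    w = _weights(ensemble, weights)
    rg2 = np.array([radius_of_gyration(s, mode) ** 2 for s in ensemble.structures()])
    return float(np.sqrt(w @ rg2))


_NYGAARD = (0.216, 4.06, 0.821)


def hydrodynamic_radius(
    target,
    weights=None,
    parameterization: str = "length_corrected",
    n_residues: int | None = None,
) -> float:
    """Empirical hydrodynamic radius R_h (Angstrom) of a chain or ensemble.

    ``length_corrected`` (default): the IDP-calibrated mapping
    R_G/R_h = a1 (R_G - a2 N^(1/3)) / (N^0.6 - N^(1/3)) + a3 applied per
    chain.  ``kirkwood``: R_h = 1 / <1/r_ij> over distinct heavy-atom
    pairs.  Ensemble values combine per-chain radii harmonically, as a
    diffusion measurement averages 1/R_h.
    """
    if isinstance(target, Structure):
        return _rh_single(target, parameterization, n_residues)
    w = _weights(target, weights)
    inv = np.array(
        [1.0 / _rh_single(s, parameterization, n_residues) for s in target.structures()]
    )
    return float(1.0 / (w @ inv))


def _rh_single(structure: Structure, parameterization: str, n_residues) -> float:
    if parameterization == "kirkwood":
        xyz = structure.coords[structure.heavy_mask]
        diff = xyz[:, None, :] - xyz[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(len(xyz), k=1)
        return float(1.0 / np.mean(1.0 / d[iu]))
    if parameterization != "length_corrected":
        raise ValueError(f"unknown parameterization {parameterization!r}")
    n = len(structure.residue_ids) if n_residues is None else int(n_residues)
    rg = radius_of_gyration(structure)
    return rg_to_rh(rg, n)


def rg_to_rh(rg: float, n_residues: int) -> float:
    """Length-corrected empirical R_G -> R_h mapping for disordered chains."""
    a1, a2, a3 = _NYGAARD
    ratio = a1 * (rg - a2 * n_residues ** (1.0 / 3)) / (
        n_residues**0.6 - n_residues ** (1.0 / 3)
    ) + a3
    if ratio <= 0:
        raise ValueError("mapping outside its calibrated range")
    return float(rg / ratio)


def rh_to_rg(rh: float, n_residues: int) -> float:
    """Numerical inverse of :func:`rg_to_rh`."""
    return float(
        brentq(lambda rg: rg_to_rh(rg, n_residues) - rh, 1e-3, 1e4, xtol=1e-10)
    )


# ---------------------------------------------------------------------------
# FRET / SAW-nu

def saw_nu_distribution(
    nu: float, mean_distance: float, r0_forster: float | None = None
) -> DistanceModel:
    """Self-avoiding-walk end-to-end distance density for scaling exponent
    nu, scaled so the mean distance matches ``mean_distance`` (Angstrom).

    p(r) propto r^(2+g) exp(-(r/b)^delta) with g = (gamma - 1)/nu and
    delta = 1/(1 - nu); the length scale b follows analytically from the
    requested mean via Gamma-function moments.
    """
    if not (0.33 < nu < 0.7):
        raise ValueError("nu outside the sanity band (0.33, 0.7)")
    if mean_distance <= 0:
        raise ValueError("mean distance must be positive")
    model = DistanceModel(nu=nu, scale=1.0, mean_distance=mean_distance,
                          r0_forster=r0_forster)
    unit_mean = model._moment(1) / model._moment(0)
    model.scale = mean_distance / unit_mean
    return model


def fret_efficiency(target, r0: float, weights=None) -> float:
    """Mean Foerster efficiency E = <1 / (1 + (r/R0)^6)>.

    ``target`` may be a DistanceModel (integrated by quadrature), an array
    of distances, or ``(distances, weights)`` via the ``weights`` argument.
    """
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    if isinstance(target, DistanceModel):
        from scipy.integrate import quad

        val, _ = quad(
            lambda r: target.pdf(r) / (1.0 + (r / r0) ** 6),
            0.0,
            np.inf,
            epsabs=1e-10,
            epsrel=1e-10,
            limit=200,
        )
        return float(val)
    r = np.asarray(target, dtype=float)
    e = 1.0 / (1.0 + (r / r0) ** 6)
    if weights is None:
        return float(e.mean())
    w = np.asarray(weights, dtype=float)
    return float((w @ e) / w.sum())


# ---------------------------------------------------------------------------
# chemical shifts

def secondary_shifts(predicted: dict, random_coil: dict) -> dict:
    """Delta-C per residue: predicted minus random-coil shift.

    Both are residue -> value maps over the same residues; the predicted
    values for an ensemble are the weight-averaged per-chain predictions
    from the pluggable predictor.
    """
    if set(predicted) != set(random_coil):
        extra = set(predicted) ^ set(random_coil)
        raise ValueError(f"residue mismatch between tables: {sorted(extra)}")
    return {r: predicted[r] - random_coil[r] for r in predicted}


def ensemble_predicted_shifts(ensemble, residues, predictor, weights=None,
                              observable: str = "ca_shift") -> dict:
    """Weight-averaged per-residue shifts from a per-chain predictor."""
    w = _weights(ensemble, weights)
    out = {int(r): 0.0 for r in residues}
    for c, s in enumerate(ensemble.structures()):
        for r in residues:
            out[int(r)] += w[c] * predictor(s, int(r), observable)
    return out


# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _weights(ensemble, weights) -> np.ndarray:
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    else:
        w = ensemble.weights_or_uniform()
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("ensemble weights must be normalized")
    return w
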
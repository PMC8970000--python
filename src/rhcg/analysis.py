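"""Structural statistics on weighted ensembles.

Superposition RMSD to reference motifs (e.g. the aggregation-prone
hexapeptides VQIINK and VQIVYK in their fibril conformations, or the
microtubule-binding-competent VPGGG turn) with random-segment null
distributions, beta-turn populations from backbone O(i)-N(i+3) distances,
pairwise ensemble diversity, and label-site distance distributions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import superposed_rmsd
from .struct import Structure

__all__ = [
    "MotifReference",
    "motif_population",
    "random_segment_null",
    "turn_population",
    "turn_count_structures",
    "pairwise_diversity",
    "label_distance_distribution",
    "weighted_cdf",
]


@dataclass
class MotifReference:
    """A reference motif: residue span in construct coordinates plus one or
    more reference conformations of the selected atoms."""

    name: str
    residue_span: tuple[int, int]
    reference_coords: np.ndarray        # (n_models, n_atoms, 3) or (n_atoms, 3)
    atom_selection: str = "CA"

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.reference_coords.ndim == 2:
            self.reference_coords = self.reference_coords[None]
        if self.reference_coords.shape[1] == 0:
            raise ValueError("empty atom selection in reference")
        if self.residue_span[1] < self.residue_span[0]:
            raise ValueError("invalid residue span")

    @classmethod
    def from_structures(
        cls, name, residue_span, structures: list[Structure], atom_selection="CA"
    ) -> "MotifReference":
        coords = np.stack(
            [
                _selected_coords(s, range(residue_span[0], residue_span[1] + 1), atom_selection)
                for s in structures
            ]
        )
        return cls(name, tuple(residue_span), coords, atom_selection)

    @property
    def n_models(self) -> int:
        return self.reference_coords.shape[0]


def _selected_coords(structure: Structure, residues, selection: str) -> np.ndarray:
    names = ("CA",) if selection == "CA" else ("N", "CA", "C", "O")
    idx = [structure.atom_index(r, a) for r in residues for a in names]
    return structure.coords[idx]


def _min_rmsd_to_reference(coords: np.ndarray, reference: np.ndarray) -> float:
    """Minimum superposed RMSD over reference models (multi-model refs use
    the closest representative)."""
    return float(
        min(superposed_rmsd(coords, reference[m]) for m in range(reference.shape[0]))
    )


def weighted_cdf(values: np.ndarray, weights: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Weighted empirical CDF evaluated on ``grid``; nondecreasing, 0 -> 1."""
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w)
    cum /= cum[-1]
    return np.interp(grid, v, cum, left=0.0, right=1.0)


def motif_population(
    ensemble,
    motif: MotifReference,
    cutoff: float = 1.0,
    weights=None,
    rmsd_grid: np.ndarray | None = None,
) -> dict:
    """Weighted fraction of chains whose motif segment superposes onto the
    reference within ``cutoff`` (Angstrom), plus the cumulative RMSD curve.
    """
    first, last = motif.residue_span
    ids = ensemble.template.residue_ids
    if first < ids.min() or last > ids.max():
        raise ValueError(f"motif span {motif.residue_span} outside construct")
    w = _weights(ensemble, weights)
    rmsds = np.array(
        [
            _min_rmsd_to_reference(
                _selected_coords(s, range(first, last + 1), motif.atom_selection),
                motif.reference_coords,
            )
            for s in ensemble.structures()
        ]
    )
    fraction = float(w[rmsds < cutoff].sum())
    if rmsd_grid is None:
        hi = rmsds.max() * 1.05
        if np.isfinite(cutoff):
            hi = max(hi, cutoff * 1.05)
        rmsd_grid = np.linspace(0.0, hi, 200)
    return {
        "fraction": fraction,
        "rmsd": rmsds,
        "grid": rmsd_grid,
        "cdf": weighted_cdf(rmsds, w, rmsd_grid),
    }


def random_segment_null(
    ensemble,
    reference: MotifReference,
    segment_length: int,
    n_samples: int,
    seed: int,
    weights=None,
    rmsd_grid: np.ndarray | None = None,
) -> dict:
    """Null RMSD distribution from randomly chosen same-length segments.

    Samples (chain, start) pairs — chains with probability w_c, start
    positions uniformly — and superposes each random segment onto the
    reference, giving the background against which a motif enrichment is
    judged.
    """
    ids = ensemble.template.residue_ids
    if segment_length > len(ids):
        raise ValueError("segment longer than construct")
    rng = np.random.default_rng(seed)
    w = _weights(ensemble, weights)
    chain_idx = rng.choice(len(w), size=n_samples, p=w)
    starts = rng.integers(0, len(ids) - segment_length + 1, size=n_samples)
    rmsds = np.empty(n_samples)
    cache = {}
    for k in range(n_samples):
        c = int(chain_idx[k])
        if c not in cache:
            cache[c] = ensemble.template.with_coords(ensemble.coords[c])
        residues = ids[starts[k] : starts[k] + segment_length]
        coords = _selected_coords(cache[c], residues, reference.atom_selection)
        rmsds[k] = _min_rmsd_to_reference(coords, reference.reference_coords)
    if rmsd_grid is None:
        rmsd_grid = np.linspace(0.0, rmsds.max() * 1.05, 200)
    return {
        "rmsd": rmsds,
        "grid": rmsd_grid,
        "cdf": weighted_cdf(rmsds, np.full(n_samples, 1.0 / n_samples), rmsd_grid),
    }


def turn_population(
    ensemble,
    donor_residue: int,
    acceptor_residue: int | None = None,
    cutoff: float = 4.0,
    weights=None,
    grid: np.ndarray | None = None,
) -> dict:
    """Weighted fraction of chains with backbone O(i)-N(i+3) distance below
    ``cutoff`` — the signature of a beta-turn, e.g. at V300-G303 of tau —
    plus the distance CDF.
    """
    i = int(donor_residue)
    j = i + 3 if acceptor_residue is None else int(acceptor_residue)
    w = _weights(ensemble, weights)
    try:
        oi = ensemble.template.atom_index(i, "O")
        nj = ensemble.template.atom_index(j, "N")
    except KeyError as err:
        raise ValueError(f"missing backbone atom for turn {i}->{j}: {err}") from err
    d = np.linalg.norm(ensemble.coords[:, oi] - ensemble.coords[:, nj], axis=1)
    if grid is None:
        grid = np.linspace(0.0, max(d.max() * 1.05, cutoff), 200)
    return {
        "fraction": float(w[d < cutoff].sum()),
        "distances": d,
        "grid": grid,
        "cdf": weighted_cdf(d, w, grid),
    }


def turn_count_structures(structures: list[Structure], donor_residue: int,
                          acceptor_residue: int | None = None,
                          cutoff: float = 4.0) -> int:
    """Count models of a structure list with O(i)-N(i+3) below cutoff
    (convenience for NMR-ensemble PDB files)."""
    i = int(donor_residue)
    j = i + 3 if acceptor_residue is None else int(acceptor_residue)
    n = 0
    for s in structures:
        d = np.linalg.norm(s.atom_coord(i, "O") - s.atom_coord(j, "N"))
        n += bool(d < cutoff)
    return n


def pairwise_diversity(ensemble, n_pairs: int, seed: int, selection: str = "CA") -> dict:
    """C-alpha RMSD between randomly drawn chain pairs: sample, median, IQR."""
    if len(ensemble) < 2:
        raise ValueError("need at least two chains")
    rng = np.random.default_rng(seed)
    ids = ensemble.template.residue_ids
    sel_idx = [ensemble.template.atom_index(r, "CA") for r in ids] if selection == "CA" \
        else list(range(ensemble.template.n_atoms))
    a = rng.integers(0, len(ensemble), n_pairs)
    b = (a + 1 + rng.integers(0, len(ensemble) - 1, n_pairs)) % len(ensemble)
    rmsds = np.array(
        [
            superposed_rmsd(ensemble.coords[i][sel_idx], ensemble.coords[j][sel_idx])
            for i, j in zip(a, b)
        ]
    )
    q1, med, q3 = np.percentile(rmsds, [25, 50, 75])
    return {"rmsd": rmsds, "median": float(med), "iqr": (float(q1), float(q3))}


def label_distance_distribution(
    ensemble, site_a: int, site_b: int, weights=None, bins=None
) -> dict:
    """Weighted C-alpha--C-alpha distance distribution between two label
    sites (e.g. the natural cysteines C291/C322 used for FRET dyes) and the
    root-mean-square distance.

    Histogram bins default to Freedman-Diaconis on the weighted sample.
    """
    w = _weights(ensemble, weights)
    ia = ensemble.template.atom_index(int(site_a), "CA")
    ib = ensemble.template.atom_index(int(site_b), "CA")
    d = np.linalg.norm(ensemble.coords[:, ia] - ensemble.coords[:, ib], axis=1)
    rms = float(np.sqrt(w @ d**2))
    if bins is None:
        q1, q3 = _weighted_quantile(d, w, [0.25, 0.75])
        width = 2 * (q3 - q1) / max(len(d), 1) ** (1 / 3)
        if width <= 0:
            bins = 10
        else:
            bins = max(int(np.ceil((d.max() - d.min()) / width)), 1)
    hist, edges = np.histogram(d, bins=bins, weights=w, density=True)
    return {"distances": d, "rms": rms, "hist": hist, "edges": edges}


def _weighted_quantile(values, weights, qs):
    order = np.argsort(values)
    v, w = np.asarray(values)[order], np.asarray(weights)[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return np.interp(qs, cum, v)


def _weights(ensemble, weights) -> np.ndarray:
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    else:
        w = ensemble.weights_or_uniform()
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be normalized")
    return w
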
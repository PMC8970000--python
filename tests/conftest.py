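"""Shared fixtures: a small enumerable toy system and independent oracles."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from rhcg import fragments, growth, synthetic

TOY_SEQUENCE = "AKVLSDGKAMQ"   # 11 residues -> pentamers (1-5), (4-8), (7-11)


@pytest.fixture(scope="session")
def toy_defs():
    return fragments.tile_sequence(TOY_SEQUENCE, 5, 2)


@pytest.fixture(scope="session")
def toy_libraries(toy_defs):
    basin = synthetic.BasinModel()
    return [
        synthetic.sample_library(fd, basin, 4, seed=10 + i)
        for i, fd in enumerate(toy_defs)
    ]


@pytest.fixture(scope="session")
def toy_ensemble(toy_libraries):
    ens = growth.grow(toy_libraries, n_chains=400, pool_size=800, seed=5)
    return growth.reference_weights(ens)


def tree_assemble(structures, clash_cutoff=2.0):
    """Left-packed binary-tree assembly of explicit fragment conformers,
    mirroring the growth hierarchy; returns the merged Structure or None
    on any clash rejection."""
    nodes = list(structures)
    while len(nodes) > 1:
        nxt = []
        for k in range(0, len(nodes) - 1, 2):
            merged, _ = growth.assemble_pair(nodes[k], nodes[k + 1], clash_cutoff)
            if isinstance(merged, growth.ClashRejection):
                return None
            nxt.append(merged)
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0]


def enumerate_combinations(libraries, clash_cutoff=2.0):
    """Exhaustive enumeration oracle: every fragment combination and its
    assembled chain (None where rejected)."""
    out = {}
    sizes = [lib.size for lib in libraries]
    for combo in itertools.product(*(range(s) for s in sizes)):
        structs = [
            lib.conformers[f].structure for lib, f in zip(libraries, combo)
        ]
        out[combo] = tree_assemble(structs, clash_cutoff)
    return out


def quaternion_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent superposition oracle (Horn's quaternion method)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * lam) / len(a)
    return float(np.sqrt(max(msd, 0.0)))


def weighted_se(values: np.ndarray, weights: np.ndarray) -> float:
    """Standard error of a self-normalized weighted mean."""
    w = weights / weights.sum()
    mean = w @ values
    return float(np.sqrt(np.sum(w**2 * (values - mean) ** 2)))


def end_to_end(structure) -> float:
    ids = structure.residue_ids
    return float(
        np.linalg.norm(
            structure.atom_coord(ids[0], "CA") - structure.atom_coord(ids[-1], "CA")
        )
    )
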
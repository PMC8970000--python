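"""Hierarchical chain growth with clash rejection and bias bookkeeping.

Full-length chains are assembled pairwise along an (unbalanced, left-packed)
binary tree over fragment positions.  At each internal node a pool of
clash-free merged subchains is built by sampling members of the child
nodes — fragments are drawn according to their library weights w_n^f,
pool members uniformly — superposing the downstream part onto the upstream
part over the shared junction residues, and discarding merges with steric
clashes.  Each emitted chain records its selection probability
p[f^c] = prod_n w_n^{f_n^c} (kept in log space), from which the
bias-correcting reference weights w0_c  propto  exp(-beta G_c) / p[f^c]
are computed; with the default clash-indicator energy this reduces to
w0_c propto 1 / p[f^c], and for uniform libraries to w0_c = 1/C.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DEFAULT_CLASH_CUTOFF
from .fragments import FragmentLibrary
from .geometry import superpose
from .struct import Structure, concat


__all__ = [
    "ChainModel",
    "Ensemble",
    "ClashRejection",
    "GrowthError",
    "assemble_pair",
    "grow",
    "reference_weights",
]


class GrowthError(RuntimeError):
    """Raised when a node cannot produce a clash-free merge in time."""


class ClashRejection:
    """Sentinel signalling that a merge was rejected for steric clashes."""

    def __init__(self, min_distance: float):
        self.min_distance = float(min_distance)

    def __repr__(self) -> str:
        return f"ClashRejection(min_distance={self.min_distance:.3f})"


@dataclass
class ChainModel:
    """One assembled conformer with its growth bookkeeping."""

    structure: Structure
    fragment_indices: np.ndarray
    log_p_bias: float
    log_energy_weight: float = 0.0

    @property
    def bias_probability(self) -> float:
        return float(np.exp(self.log_p_bias))

    @property
    def energy_weight(self) -> float:
        return float(np.exp(self.log_energy_weight))


@dataclass
class Ensemble:
    """A grown ensemble: shared atom table, stacked coordinates and weights."""

    template: Structure
    coords: np.ndarray                  # (C, n_atoms, 3)
    fragment_indices: np.ndarray        # (C, N)
    log_p_bias: np.ndarray              # (C,)
    log_energy_weight: np.ndarray = None
    w0: np.ndarray = None
    w: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.log_p_bias = np.asarray(self.log_p_bias, dtype=float)
        if self.log_energy_weight is None:
            self.log_energy_weight = np.zeros(len(self))
        for name in ("w0", "w"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if abs(v.sum() - 1.0) > 1e-6 or len(v) != len(self):
                    raise ValueError(f"{name} must be normalized, one per chain")
                setattr(self, name, v)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_chains(self) -> int:
        return len(self)

    def chain(self, c: int) -> ChainModel:
        return ChainModel(
            self.template.with_coords(self.coords[c]),
            self.fragment_indices[c],
            float(self.log_p_bias[c]),
            float(self.log_energy_weight[c]),
        )

    def structures(self):
        for c in range(len(self)):
            yield self.template.with_coords(self.coords[c])

    def weights_or_uniform(self) -> np.ndarray:
        if self.w is not None:
            return self.w
        if self.w0 is not None:
            return self.w0
        return np.full(len(self), 1.0 / len(self))


# ---------------------------------------------------------------------------
# pairwise merge

def _overlap_residues(up: Structure, down: Structure) -> np.ndarray:
    shared = np.intersect1d(up.residue_ids, down.residue_ids)
    if len(shared) == 0:
        raise ValueError("subchains share no residues to superpose on")
    if np.any(np.diff(shared) != 1):
        raise ValueError("junction overlap residues are not contiguous")
    return shared


def assemble_pair(
    upstream: Structure,
    downstream: Structure,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
):
    """Merge two subchains over their shared residues.

    The downstream part is rigid-body superposed (least-squares, backbone
    N/CA/C/O of the shared residues) onto the upstream part.  The merged
    chain keeps upstream coordinates up to and including the first overlap
    residue and downstream coordinates beyond it.  Returns ``(merged,
    fit_rmsd)`` or ``(ClashRejection, fit_rmsd)`` when any inter-part
    heavy-atom pair outside the junction residues comes closer than
    ``clash_cutoff``.
    """
    up, down = upstream.without_caps(), downstream.without_caps()
    if up.residue_ids[0] > down.residue_ids[0]:
        up, down = down, up
    shared = _overlap_residues(up, down)
    for r in shared:
        a = up.res_name[up.res_id == r][0]
        b = down.res_name[down.res_id == r][0]
        if a != b:
            raise ValueError(f"overlap residue {r}: sequence mismatch {a} vs {b}")
    fit_up = up.coords[up.backbone_indices(shared)]
    fit_down = down.coords[down.backbone_indices(shared)]
    moved, rmsd = superpose(fit_down, fit_up, down.coords)

    up_clash = up.heavy_mask & (up.res_id < shared[0])
    down_clash = down.heavy_mask & (down.res_id > shared[-1])
    if up_clash.any() and down_clash.any():
        diff = up.coords[up_clash][:, None, :] - moved[down_clash][None, :, :]
        dmin = float(np.sqrt((diff**2).sum(-1)).min())
        if dmin < clash_cutoff:
            return ClashRejection(dmin), float(rmsd)

    keep_up = up.res_id <= shared[0]
    keep_down = down.res_id > shared[0]
    merged = concat([up.select(keep_up), down.with_coords(moved).select(keep_down)])
    return merged, float(rmsd)


# ---------------------------------------------------------------------------
# hierarchical growth

@dataclass
class _Pool:
    """Internal node: template + stacked member coordinates + bookkeeping."""

    template: Structure
    coords: np.ndarray            # (n, A, 3)
    log_p: np.ndarray             # (n,)
    frag: np.ndarray              # (n, k) fragment indices
    positions: list               # fragment position indices covered
    sample_weights: np.ndarray | None = None   # None = uniform


def _weighted_draw(rng: np.random.Generator, n: int, size: int, weights) -> np.ndarray:
    """Inverse-CDF sampling; an explicit uniform vector and ``None`` consume
    the stream identically, so uniform-weight RHCG reproduces HCG exactly."""
    u = rng.random(size)
    if weights is None:
        return np.minimum((u * n).astype(int), n - 1)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    return np.searchsorted(cdf, u, side="right").clip(0, n - 1)


def _leaf_pool(library: FragmentLibrary) -> _Pool:
    template, stack = library.coords_stack(without_caps=True)
    with np.errstate(divide="ignore"):
        log_w = np.log(library.weights)
    return _Pool(
        template=template,
        coords=stack,
        log_p=log_w,
        frag=np.arange(library.size)[:, None],
        positions=[library.definition.position_index],
        sample_weights=None if library.is_uniform else library.weights,
    )


def _merge_pools(
    left: _Pool,
    right: _Pool,
    n_out: int,
    rng: np.random.Generator,
    clash_cutoff: float,
    max_attempts: int,
    stats: dict,
) -> _Pool:
    up, down = left, right
    if up.template.residue_ids[0] > down.template.residue_ids[0]:
        up, down = down, up
    shared = _overlap_residues(up.template, down.template)
    fit_up_idx = up.template.backbone_indices(shared)
    fit_down_idx = down.template.backbone_indices(shared)
    up_clash = up.template.heavy_mask & (up.template.res_id < shared[0])
    down_clash = down.template.heavy_mask & (down.template.res_id > shared[-1])
    keep_up = up.template.res_id <= shared[0]
    keep_down = down.template.res_id > shared[0]
    template = concat([up.template.select(keep_up), down.template.select(keep_down)])

    n_pairs = up_clash.sum() * down_clash.sum()
    batch_max = max(64, min(8192, int(2e7 / max(n_pairs, 1))))

    out_coords, out_logp, out_frag = [], [], []
    n_done, attempts = 0, 0
    node_label = f"positions {up.positions[0]}..{down.positions[-1]}"
    while n_done < n_out:
        if attempts > max_attempts * max(n_out, 1):
            raise GrowthError(
                f"node {node_label}: no clash-free merge after {attempts} "
                f"attempts ({n_done}/{n_out} filled)"
            )
        batch = min(batch_max, 2 * (n_out - n_done) + 16)
        # upstream always drawn before downstream for a reproducible stream
        i_up = _weighted_draw(rng, len(up.log_p), batch, up.sample_weights)
        i_down = _weighted_draw(rng, len(down.log_p), batch, down.sample_weights)
        attempts += batch
        fit_u = up.coords[i_up][:, fit_up_idx]
        fit_d = down.coords[i_down][:, fit_down_idx]
        moved, _ = superpose(fit_d, fit_u, down.coords[i_down])
        if n_pairs > 0:
            diff = up.coords[i_up][:, up_clash, None, :] - moved[:, None, down_clash, :]
            dmin = np.sqrt((diff**2).sum(-1)).min(axis=(1, 2))
            ok = dmin >= clash_cutoff
        else:
            ok = np.ones(batch, dtype=bool)
        if not ok.any():
            continue
        merged = np.concatenate(
            [up.coords[i_up[ok]][:, keep_up], moved[ok][:, keep_down]], axis=1
        )
        out_coords.append(merged)
        out_logp.append(up.log_p[i_up[ok]] + down.log_p[i_down[ok]])
        out_frag.append(np.hstack([up.frag[i_up[ok]], down.frag[i_down[ok]]]))
        n_done += int(ok.sum())

    coords = np.concatenate(out_coords)[:n_out]
    stats.setdefault("nodes", []).append(
        {"node": node_label, "attempted": attempts, "accepted": n_done}
    )
    return _Pool(
        template=template,
        coords=coords,
        log_p=np.concatenate(out_logp)[:n_out],
        frag=np.concatenate(out_frag)[:n_out],
        positions=up.positions + down.positions,
        sample_weights=None,
    )


def grow(
    libraries: list[FragmentLibrary],
    n_chains: int,
    pool_size: int = 10000,
    seed: int = 0,
    max_attempts: int = 10000,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    n_pad_residues: int = 0,
    direction: str = "n2c",
) -> Ensemble:
    """Grow an ensemble of full-length chains from fragment libraries.

    With all libraries uniform this is plain HCG; with weighted libraries
    it is RHCG and each chain's log p[f^c] records the product of its
    fragments' selection weights.  ``pool_size`` clash-free subchains are
    kept at every internal tree level below the root; the root draws
    ``n_chains`` full constructs.  ``n_pad_residues`` N-terminal residues
    (growth scaffolding, e.g. the single pad residue preceding tau K18)
    are removed from the finished chains.  ``direction="c2n"`` mirrors the
    assembly tree; the resulting ensemble is statistically equivalent.
    """
    if not libraries:
        raise ValueError("no fragment libraries given")
    if pool_size < 1 or n_chains < 1:
        raise ValueError("pool_size and n_chains must be >= 1")
    if direction not in ("n2c", "c2n"):
        raise ValueError("direction must be 'n2c' or 'c2n'")
    spans = [lib.definition.residue_span for lib in libraries]
    if sorted(spans) != spans:
        raise ValueError("libraries must be ordered by residue span")

    ss = np.random.SeedSequence(seed)
    stats: dict = {"nodes": []}
    nodes = [_leaf_pool(lib) for lib in libraries]
    if direction == "c2n":
        nodes = nodes[::-1]

    if len(nodes) == 1:
        rng = np.random.default_rng(ss.spawn(1)[0])
        lib = libraries[0]
        idx = _weighted_draw(rng, lib.size, n_chains, nodes[0].sample_weights)
        pool = _Pool(
            nodes[0].template,
            nodes[0].coords[idx],
            nodes[0].log_p[idx],
            nodes[0].frag[idx],
            nodes[0].positions,
        )
    else:
        while len(nodes) > 1:
            n_out = n_chains if len(nodes) == 2 else pool_size
            streams = ss.spawn(len(nodes) // 2)
            nxt = []
            for k in range(0, len(nodes) - 1, 2):
                rng = np.random.default_rng(streams[k // 2])
                nxt.append(
                    _merge_pools(
                        nodes[k], nodes[k + 1], n_out, rng,
                        clash_cutoff, max_attempts, stats,
                    )
                )
            if len(nodes) % 2:
                nxt.append(nodes[-1])
            nodes = nxt
        pool = nodes[0]

    template, coords = pool.template, pool.coords
    if n_pad_residues:
        pad = template.residue_ids[:n_pad_residues]
        keep = ~np.isin(template.res_id, pad)
        template = template.select(keep)
        coords = coords[:, keep]

    order = np.argsort(pool.positions)
    frag = pool.frag[:, order]
    return Ensemble(
        template=template,
        coords=coords,
        fragment_indices=frag,
        log_p_bias=pool.log_p,
        provenance={
            "seed": seed,
            "pool_size": pool_size,
            "clash_cutoff": clash_cutoff,
            "direction": direction,
            "rejection_stats": stats,
        },
    )


def reference_weights(ensemble: Ensemble, energy_model=None) -> Ensemble:
    """Attach bias-corrected reference weights w0 to an ensemble.

    w0_c propto exp(-beta G_c) / p[f^c]; the default (no energy model)
    is the pure clash-indicator case w0_c propto 1 / p[f^c].  For an
    ensemble grown from uniform libraries this gives w0_c = 1/C exactly.
    ``energy_model(ChainModel) -> beta*G`` supplies interfragment free
    energies in units of k_B T.
    """
    log_p = ensemble.log_p_bias
    if np.any(~np.isfinite(log_p)):
        raise ValueError("a chain records p[f^c] = 0; cannot form 1/p weights")
    log_e = ensemble.log_energy_weight.copy()
    if energy_model is not None:
        log_e = np.array(
            [-float(energy_model(ensemble.chain(c))) for c in range(len(ensemble))]
        )
    logw = log_e - log_p
    logw -= logw.max()
    w0 = np.exp(logw)
    w0 /= w0.sum()
    return replace(ensemble, w0=w0, log_energy_weight=log_e)
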
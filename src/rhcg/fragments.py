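"""Fragment tiling, conformer libraries and local (per-fragment) reweighting.

A construct sequence is tiled into short overlapping fragments (pentamers
with two-residue overlap by default).  Each fragment position carries a
library of conformers with normalized selection weights w_n^f; uniform
weights reproduce plain hierarchical chain growth, while weights obtained
by local BioEn reweighting against per-residue data (e.g. C-alpha chemical
shifts) bias the growth toward data-consistent local structure.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reweight
from .struct import BACKBONE_ATOMS, Structure, read_models, write_models

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentDef",
    "FragmentConformer",
    "FragmentLibrary",
    "tile_sequence",
    "load_library",
    "write_library",
    "build_local_observables",
    "weight_fragments",
    "substitute_variant",
]


@dataclass(frozen=True)
class FragmentDef:
    """One fragment position in the tiling of a construct sequence."""

    position_index: int          # 1-based position n
    residue_span: tuple[int, int]  # (first, last), 1-based inclusive
    sequence: str
    capped: bool = True

    @property
    def residues(self) -> range:
        return range(self.residue_span[0], self.residue_span[1] + 1)

    @property
    def nonterminal_residues(self) -> range:
        """Span residues except the first and last (cap/join-perturbed)."""
        return range(self.residue_span[0] + 1, self.residue_span[1])

    def __len__(self) -> int:
        return self.residue_span[1] - self.residue_span[0] + 1


@dataclass
class FragmentConformer:
    """A single conformer of a fragment, with provenance tag."""

    structure: Structure
    source: str = ""


@dataclass
class FragmentLibrary:
    """Conformers of one fragment position with selection weights w_n^f."""

    definition: FragmentDef
    conformers: list[FragmentConformer]
    weights: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("fragment library needs at least one conformer")
        if self.weights is None:
            self.weights = np.full(self.size, 1.0 / self.size)
        self.weights = np.asarray(self.weights, dtype=float)
        self._validate_weights()

    def _validate_weights(self) -> None:
        if self.weights.shape != (self.size,):
            raise ValueError("one weight per conformer required")
        if np.any(self.weights < 0):
            raise ValueError("fragment weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("fragment weights must sum to 1")

    @property
    def size(self) -> int:
        return len(self.conformers)

    @property
    def is_uniform(self) -> bool:
        return bool(np.allclose(self.weights, 1.0 / self.size, atol=1e-12))

    def with_weights(self, weights: np.ndarray) -> "FragmentLibrary":
        return FragmentLibrary(self.definition, self.conformers, weights)

    def coords_stack(self, without_caps: bool = True) -> tuple[Structure, np.ndarray]:
        """Shared atom table plus an (F, n_atoms, 3) coordinate stack."""
        first = self.conformers[0].structure
        template = first.without_caps() if without_caps else first
        mask = ~first.is_cap if without_caps else np.ones(first.n_atoms, bool)
        stack = np.stack([c.structure.coords[mask] for c in self.conformers])
        return template, stack


def tile_sequence(
    sequence: str, fragment_length: int = 5, overlap_length: int = 2
) -> list[FragmentDef]:
    """Tile a construct sequence into overlapping fragment definitions.

    Fragments advance by ``fragment_length - overlap_length``; the final
    fragment is anchored to the C terminus so the tiling covers the
    sequence exactly (it may overlap its predecessor by more than
    ``overlap_length``).
    """
    if overlap_length < 1:
        raise ValueError("overlap_length must be >= 1")
    if fragment_length <= overlap_length:
        raise ValueError("fragment_length must exceed overlap_length")
    length = len(sequence)
    if length < fragment_length:
        raise ValueError(
            f"sequence of {length} residues is shorter than one fragment "
            f"(minimum {fragment_length})"
        )
    step = fragment_length - overlap_length
    n_frag = math.ceil((length - fragment_length) / step) + 1
    defs = []
    for i in range(n_frag):
        if i == n_frag - 1:
            first = length - fragment_length + 1
        else:
            first = 1 + i * step
        last = first + fragment_length - 1
        defs.append(
            FragmentDef(
                position_index=i + 1,
                residue_span=(first, last),
                sequence=sequence[first - 1 : last],
            )
        )
    return defs


def load_library(fragment_def: FragmentDef, conformer_file) -> FragmentLibrary:
    """Load a multi-model PDB of fragment conformers into a library.

    Each MODEL becomes one conformer; caps (ACE/NME residues) are retained
    but flagged.  Initial weights are uniform 1/F.
    """
    models = read_models(conformer_file)
    if not models:
        raise ValueError(f"{conformer_file}: no models found")
    span = set(fragment_def.residues)
    conformers = []
    for i, s in enumerate(models, start=1):
        present = set(s.residue_ids.tolist())
        if not span <= present:
            missing = sorted(span - present)
            raise ValueError(
                f"{conformer_file} model {i}: missing residues {missing}"
            )
        for r in fragment_def.residues:
            for name in BACKBONE_ATOMS:
                hits = np.sum((s.res_id == r) & (s.atom_name == name))
                if hits != 1:
                    raise ValueError(
                        f"{conformer_file} model {i}: backbone atom {name} "
                        f"of residue {r} missing or duplicated"
                    )
        if not np.all(np.isfinite(s.coords)):
            raise ValueError(f"{conformer_file} model {i}: non-finite coordinates")
        conformers.append(FragmentConformer(s, source=f"model {i}"))
    return FragmentLibrary(fragment_def, conformers)


def write_library(library: FragmentLibrary, path) -> None:
    write_models(path, [c.structure for c in library.conformers])


def build_local_observables(
    library: FragmentLibrary,
    data: pd.DataFrame,
    predictor,
    forward_error: float = 0.0,
) -> reweight.ObservableSet | None:
    """Restrict a per-residue data table to this fragment and build the
    forward matrix with a pluggable predictor.

    ``data`` has columns ``residue_index, observable_name, value, sigma``;
    only rows for the fragment's nonterminal residues are used (terminal
    residues are perturbed by caps and junctions).  ``predictor(structure,
    residue_index, observable_name) -> float`` supplies per-conformer
    forward values.  Returns None when no local data applies.
    """
    nonterm = set(library.definition.nonterminal_residues)
    local = data[data["residue_index"].isin(nonterm)]
    if local.empty:
        return None
    forward = np.empty((len(local), library.size))
    for j, conf in enumerate(library.conformers):
        for i, row in enumerate(local.itertuples()):
            forward[i, j] = predictor(
                conf.structure, int(row.residue_index), str(row.observable_name)
            )
    sigmas = np.sqrt(local["sigma"].to_numpy() ** 2 + forward_error**2)
    ids = [
        f"{row.observable_name}:{int(row.residue_index)}" for row in local.itertuples()
    ]
    return reweight.ObservableSet(local["value"].to_numpy(), sigmas, forward, ids)


def weight_fragments(
    library: FragmentLibrary,
    local_data: reweight.ObservableSet | None,
    theta_f: float,
) -> FragmentLibrary:
    """Locally reweight a fragment library against its own data (BioEn).

    Minimizes theta_f * S_KL(w | uniform) + chi2/2 over the library
    weights; a large theta_f keeps the bias gentle.  An empty data set
    returns the library unchanged with a warning.
    """
    if theta_f <= 0:
        raise ValueError("theta_f must be positive")
    if local_data is None or local_data.n_observables == 0:
        logger.warning(
            "fragment %d: no local data, weights left unchanged",
            library.definition.position_index,
        )
        return library
    uniform = np.full(library.size, 1.0 / library.size)
    result = reweight.optimize(local_data, uniform, theta_f)
    return library.with_weights(result.weights)


def substitute_variant(
    libraries: list[FragmentLibrary],
    position: int,
    variant_libraries: dict[int, FragmentLibrary],
    variant_residue: str | None = None,
) -> list[FragmentLibrary]:
    """Swap in variant fragment libraries at every fragment containing a
    mutated residue.

    ``variant_libraries`` maps fragment position_index to the replacement
    library.  Fragments not containing ``position`` are returned unchanged
    (same objects).  The variant sequence must differ from the original
    only at the stated position.
    """
    out = []
    for lib in libraries:
        if position not in lib.definition.residues:
            out.append(lib)
            continue
        n = lib.definition.position_index
        if n not in variant_libraries:
            raise ValueError(
                f"fragment {n} contains residue {position} but no variant "
                "library was supplied for it"
            )
        var = variant_libraries[n]
        if var.definition.residue_span != lib.definition.residue_span:
            raise ValueError(f"variant fragment {n}: residue span mismatch")
        offset = lib.definition.residue_span[0]
        for k, (old, new) in enumerate(
            zip(lib.definition.sequence, var.definition.sequence)
        ):
            res = offset + k
            if old != new and res != position:
                raise ValueError(
                    f"variant fragment {n} differs at residue {res}, "
                    f"not the stated position {position}"
                )
            if res == position and variant_residue is not None and new != variant_residue:
                raise ValueError(
                    f"variant fragment {n} has {new} at {position}, "
                    f"expected {variant_residue}"
                )
        out.append(var)
    return out
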
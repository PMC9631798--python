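"""Structure-derived termini distance and Gly-Ser linker reach feasibility.

A single-chain immunocytokine tethers the cytokine's C terminus to the
antibody light chain's N terminus with a flexible (Gly4Ser)n linker. Whether
the fused cytokine can fold back and engage its own antibody intramolecularly
depends on the linker's maximal reach versus the distance between the two
termini in the assembled cytokine/antibody complex. This module measures that
distance from a PDB-format structure (Cα of the first/last resolved residue
per chain) and checks linker-length feasibility against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi

__all__ = [
    "TerminiSelection",
    "LinkerSpec",
    "LinkerReach",
    "SelectionError",
    "termini_distance",
    "linker_reach",
]

#: default per-residue extension of a near-extended Gly-Ser chain, Å/residue
DEFAULT_EXTENSION_A = 3.5


class SelectionError(KeyError):
    """A requested chain, terminus or Cα atom is absent from the structure."""


@dataclass(frozen=True)
class TerminiSelection:
    """Two chain termini in a PDB-format structure.

    ``terminus`` is ``"N"`` (first resolved residue) or ``"C"`` (last).
    The measured atom is the Cα of that residue.
    """

    path: str | Path
    chain_a: str
    terminus_a: str
    chain_b: str
    terminus_b: str

    def __post_init__(self) -> None:
        for term in (self.terminus_a, self.terminus_b):
            if term not in ("N", "C"):
                raise ValueError(f"terminus must be 'N' or 'C', got {term!r}")


def _terminal_ca(structure: gemmi.Structure, chain_id: str, terminus: str) -> gemmi.Position:
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [ch.name for ch in model]
        raise SelectionError(
            f"chain {chain_id!r} not found (available: {available})"
        )
    residues = list(chain)
    ordered = residues if terminus == "N" else reversed(residues)
    for res in ordered:
        atom = res.find_atom("CA", "*")
        if atom is not None:
            return atom.pos
    raise SelectionError(
        f"no Cα atom resolved in chain {chain_id!r} from the {terminus} terminus"
    )


def termini_distance(sel: TerminiSelection) -> float:
    """Euclidean distance (Å) between the Cα atoms of two chain termini."""
    structure = gemmi.read_structure(str(sel.path))
    if len(structure) == 0:
        raise SelectionError(f"no models in structure {sel.path}")
    a = _terminal_ca(structure, sel.chain_a, sel.terminus_a)
    b = _terminal_ca(structure, sel.chain_b, sel.terminus_b)
    return a.dist(b)


@dataclass(frozen=True)
class LinkerSpec:
    """A Gly-Ser repeat linker: unit sequence, repeat count, Å per residue."""

    repeat_unit: str = "GGGGS"
    repeats: int = 3
    per_residue_A: float = DEFAULT_EXTENSION_A

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise ValueError("repeats must be >= 0")
        if not self.per_residue_A > 0:
            raise ValueError("per-residue length must be > 0")

    @property
    def n_residues(self) -> int:
        return len(self.repeat_unit) * self.repeats


@dataclass(frozen=True)
class LinkerReach:
    n_residues: int
    max_span_A: float
    required_span_A: float
    feasible: bool


def linker_reach(spec: LinkerSpec, required_span: float) -> LinkerReach:
    """Maximal linker span vs a required termini distance.

    ``max_span = n_residues × per-residue extension``; the linker is feasible
    for intramolecular assembly when that reach meets or exceeds the required
    span. This is an upper-bound geometric check — an entropically relaxed
    linker spans less, so feasibility is necessary, not sufficient.
    """
    if required_span < 0:
        raise ValueError("required_span must be >= 0")
    n = spec.n_residues
    span = n * spec.per_residue_A
    return LinkerReach(
        n_residues=n,
        max_span_A=span,
        required_span_A=required_span,
        feasible=span >= required_span,
    )
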
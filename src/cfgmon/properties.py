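"""Per-molecule descriptors and windowed distribution envelopes.

Three cheap structural descriptors track how a generator's output
drifts over a run: molecular weight, conjugate length and aromatic ring
count. Conjugate length — the size of the contiguous pi-conjugated
system — correlates with absorption wavelength for organic
chromophores, which is why a wavelength-maximising generator tends to
grow it.

"Conjugate length" is defined here as the number of atoms in the
largest connected component of the subgraph induced by conjugated bonds
(RDKit's conjugation perception). An alternative definition — the
longest simple path through that subgraph, in atoms — is available via
``method="path"``. The component definition is the default because it
is deterministic, cheap, and monotone as the pi system is extended.

Windowed envelopes summarise a property over the same sliding windows
used for enrichment: per-window mean plus percentile bands, by default
the (5, 95) and (15, 75) percentile pairs. Percentiles use linear
interpolation between order statistics (numpy's default convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .catalog import MoleculeRecord

__all__ = [
    "PropertyEnvelope",
    "molecular_weight",
    "aromatic_ring_count",
    "conjugate_length",
    "compute_properties",
    "property_envelope",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((5.0, 95.0), (15.0, 75.0))


def _require_mol(molecule: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    if isinstance(molecule, MoleculeRecord):
        if not molecule.valid or molecule.mol is None:
            raise ValueError(f"invalid molecule at index {molecule.index}")
        return molecule.mol
    return molecule


def molecular_weight(molecule: MoleculeRecord | Chem.Mol) -> float:
    """Average molecular weight in g/mol, implicit hydrogens included."""
    return Descriptors.MolWt(_require_mol(molecule))


def aromatic_ring_count(molecule: MoleculeRecord | Chem.Mol) -> int:
    """Number of SSSR rings whose atoms are all aromatic."""
    return rdMolDescriptors.CalcNumAromaticRings(_require_mol(molecule))


def conjugate_length(molecule: MoleculeRecord | Chem.Mol, method: str = "component") -> int:
    """Size of the largest conjugated system, in atoms.

    ``method="component"`` (default): atom count of the largest connected
    component of the conjugated-bond subgraph. ``method="path"``: atom
    count of the longest simple path within that subgraph. A molecule
    with no conjugated bonds has conjugate length 0 under both.
    """
    mol = _require_mol(molecule)
    adjacency: dict[int, list[int]] = {}
    for bond in mol.GetBonds():
        if bond.GetIsConjugated():
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            adjacency.setdefault(a, []).append(b)
            adjacency.setdefault(b, []).append(a)
    if not adjacency:
        return 0
    if method == "component":
        return _largest_component(adjacency)
    if method == "path":
        return _longest_path(adjacency)
    raise ValueError(f"unknown conjugate_length method {method!r}")


def _largest_component(adjacency: dict[int, list[int]]) -> int:
    seen: set[int] = set()
    best = 0
    for start in adjacency:
        if start in seen:
            continue
        stack, size = [start], 0
        seen.add(start)
        while stack:
            node = stack.pop()
            size += 1
            for nxt in adjacency[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        best = max(best, size)
    return best


def _longest_path(adjacency: dict[int, list[int]]) -> int:
    # Exhaustive DFS; fine for molecule-sized graphs.
    best = 0

    def dfs(node: int, visited: set[int]) -> int:
        length = 1
        for nxt in adjacency[node]:
            if nxt not in visited:
                visited.add(nxt)
                length = max(length, 1 + dfs(nxt, visited))
                visited.remove(nxt)
        return length

    for start in adjacency:
        best = max(best, dfs(start, {start}))
    return best


def compute_properties(
    record: MoleculeRecord, conjugation_method: str = "component"
) -> MoleculeRecord:
    """Attach the standard descriptor set to a valid record (in place)."""
    if not record.valid:
        return record
    record.properties = dict(record.properties or {})
    record.properties.update(
        molecular_weight=molecular_weight(record),
        conjugate_length=float(conjugate_length(record, conjugation_method)),
        aromatic_rings=float(aromatic_ring_count(record)),
    )
    return record


@dataclass
class PropertyEnvelope:
    """Windowed mean and percentile bands of one property."""

    property_name: str
    window_ends: list[int]
    mean: list[float]
    bands: dict[tuple[float, float], tuple[list[float], list[float]]]

    def to_frame(self) -> pd.DataFrame:
        """Wide export: window_end, property, mean, then pXX columns."""
        data: dict[str, object] = {
            "window_end": self.window_ends,
            "property": self.property_name,
            "mean": self.mean,
        }
        for (lo, hi), (lower, upper) in self.bands.items():
            data[f"p{lo:02.0f}"] = lower
            data[f"p{hi:02.0f}"] = upper
        return pd.DataFrame(data)


def property_envelope(
    stream: Sequence[MoleculeRecord],
    property_name: str,
    window_length: int = 100,
    stride: int = 1,
    band_pairs: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> PropertyEnvelope:
    """Sliding-window mean and percentile bands of a per-record property.

    Windows follow the enrichment convention: ``(end - L, end]`` over the
    0-based stream, advanced by ``stride``; statistics are over valid
    records carrying the property.
    """
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    n = len(stream)
    if n < window_length:
        raise ValueError(f"stream of length {n} shorter than window {window_length}")
    values = np.full(n, np.nan)
    for i, rec in enumerate(stream):
        if rec.valid and rec.properties and property_name in rec.properties:
            values[i] = rec.properties[property_name]

    window_ends: list[int] = []
    means: list[float] = []
    bands: dict[tuple[float, float], tuple[list[float], list[float]]] = {
        tuple(pair): ([], []) for pair in band_pairs
    }
    for end in range(window_length - 1, n, stride):
        window = values[end - window_length + 1 : end + 1]
        window = window[~np.isnan(window)]
        if window.size == 0:
            raise ValueError(
                f"window ending at {end} has no valid molecules with "
                f"property {property_name!r}"
            )
        window_ends.append(end)
        means.append(float(window.mean()))
        for (lo, hi), (lower, upper) in bands.items():
            qlo, qhi = np.percentile(window, [lo, hi])
            lower.append(float(qlo))
            upper.append(float(qhi))
    return PropertyEnvelope(
        property_name=property_name, window_ends=window_ends, mean=means, bands=bands
    )
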
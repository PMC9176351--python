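"""Functional-group catalogs and SMARTS substructure annotation.

A catalog is an ordered set of named SMARTS patterns. Each molecule in a
generation stream is annotated with a boolean presence flag per group
(at least one substructure match — match *presence*, not match count),
and those flags feed the windowed enrichment statistics.

The built-in default catalog monitors eight chromophore-relevant groups:
ketone, alpha-diketone, aniline, azo, the ortho- and para-quinone ring
motifs, and the two naphthoquinone cores. The shipped SMARTS nest as
chemistry dictates: every 1,2-naphthoquinone is also a 1,2-quinone, an
alpha-diketone and a ketone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem, RDLogger

__all__ = [
    "FunctionalGroup",
    "FunctionalGroupCatalog",
    "MoleculeRecord",
    "CatalogError",
    "load_catalog",
    "default_catalog",
    "parse_smiles",
    "make_record",
    "match_group",
    "annotate_stream",
]

# SMILES parse failures are reported through MoleculeRecord.valid, not stderr.
RDLogger.DisableLog("rdApp.error")


class CatalogError(ValueError):
    """A catalog file or entry is malformed."""


@dataclass(frozen=True)
class FunctionalGroup:
    """A named SMARTS substructure query.

    Parameters
    ----------
    name:
        Short unique identifier (e.g. ``"1,4-quinone"``).
    smarts:
        Substructure pattern; compiled eagerly, so construction fails
        on malformed SMARTS.
    description:
        Free-text note on what the pattern is meant to capture.
    """

    name: str
    smarts: str
    description: str = ""
    _pattern: Chem.Mol = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pattern = Chem.MolFromSmarts(self.smarts)
        if pattern is None:
            raise CatalogError(
                f"functional group {self.name!r}: invalid SMARTS {self.smarts!r}"
            )
        object.__setattr__(self, "_pattern", pattern)

    @property
    def pattern(self) -> Chem.Mol:
        """Compiled RDKit query molecule."""
        return self._pattern


class FunctionalGroupCatalog:
    """An ordered, non-empty collection of uniquely named groups."""

    def __init__(self, groups: Iterable[FunctionalGroup]):
        groups = list(groups)
        if not groups:
            raise CatalogError("empty catalog")
        seen: set[str] = set()
        for g in groups:
            if g.name in seen:
                raise CatalogError(f"duplicate group name {g.name!r}")
            seen.add(g.name)
        self._groups = groups
        self._by_name = {g.name: g for g in groups}

    @property
    def names(self) -> list[str]:
        return [g.name for g in self._groups]

    def __iter__(self) -> Iterator[FunctionalGroup]:
        return iter(self._groups)

    def __len__(self) -> int:
        return len(self._groups)

    def __getitem__(self, name: str) -> FunctionalGroup:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __repr__(self) -> str:
        return f"FunctionalGroupCatalog({self.names!r})"


@dataclass
class MoleculeRecord:
    """One molecule in a training set or generation stream.

    ``group_flags`` and ``properties`` are populated only for valid
    (parsable and sanitizable) molecules; invalid records are retained
    for index bookkeeping but excluded from every fraction.
    """

    index: int
    smiles: str
    valid: bool
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)
    group_flags: dict[str, bool] | None = None
    properties: dict[str, float] | None = None
    reward_components: dict[str, float] | None = None


def parse_smiles(smiles: str) -> Chem.Mol | None:
    """Parse and sanitize a SMILES string; ``None`` on failure."""
    return Chem.MolFromSmiles(smiles)


def make_record(index: int, smiles: str) -> MoleculeRecord:
    """Build a record; unparsable or empty (zero-atom) SMILES are invalid."""
    mol = parse_smiles(smiles)
    valid = mol is not None and mol.GetNumAtoms() > 0
    return MoleculeRecord(index=index, smiles=smiles, valid=valid, mol=mol if valid else None)


def _entries_from_json(text: str) -> list[dict]:
    data = json.loads(text)
    if isinstance(data, Mapping):  # {name: {smarts, description}} form
        return [
            {"name": name, **(value if isinstance(value, Mapping) else {"smarts": value})}
            for name, value in data.items()
        ]
    return list(data)


def _entries_from_tsv(text: str) -> list[dict]:
    rows = [line.split("\t") for line in text.splitlines() if line.strip()]
    if not rows:
        return []
    header = [h.strip().lower() for h in rows[0]]
    if "name" not in header or "smarts" not in header:
        raise CatalogError("TSV catalog needs 'name' and 'smarts' columns")
    entries = []
    for row in rows[1:]:
        entry = dict(zip(header, (cell.strip() for cell in row)))
        entries.append(entry)
    return entries


def load_catalog(path: str | Path) -> FunctionalGroupCatalog:
    """Load a functional-group catalog from a JSON or TSV file.

    JSON may be a list of ``{name, smarts, description}`` objects or a
    ``name -> {smarts, description}`` mapping; TSV needs ``name`` and
    ``smarts`` columns (``description`` optional).
    """
    text = Path(path).read_text()
    if not text.strip():
        raise CatalogError(f"empty catalog: {path}")
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        entries = _entries_from_json(text)
    else:
        entries = _entries_from_tsv(text)
    if not entries:
        raise CatalogError(f"empty catalog: {path}")
    groups = []
    for entry in entries:
        if "name" not in entry or "smarts" not in entry:
            raise CatalogError(f"catalog entry missing name/smarts: {entry!r}")
        groups.append(
            FunctionalGroup(
                name=entry["name"],
                smarts=entry["smarts"],
                description=entry.get("description", ""),
            )
        )
    return FunctionalGroupCatalog(groups)


def default_catalog() -> FunctionalGroupCatalog:
    """The built-in eight-group chromophore catalog."""
    text = resources.files("cfgmon.data").joinpath("default_catalog.json").read_text()
    return FunctionalGroupCatalog(
        FunctionalGroup(e["name"], e["smarts"], e.get("description", ""))
        for e in json.loads(text)
    )


def match_group(molecule: MoleculeRecord | Chem.Mol, group: FunctionalGroup) -> bool:
    """True iff the molecule contains at least one match of the group.

    Presence is boolean: a molecule with three ketones counts once.
    Raises ``ValueError`` for invalid records — callers must filter.
    """
    if isinstance(molecule, MoleculeRecord):
        if not molecule.valid or molecule.mol is None:
            raise ValueError(
                f"cannot match invalid molecule at index {molecule.index}: "
                f"{molecule.smiles!r}"
            )
        mol = molecule.mol
    else:
        mol = molecule
    return mol.HasSubstructMatch(group.pattern)


def annotate_stream(
    stream: Sequence[MoleculeRecord] | Iterable[str],
    catalog: FunctionalGroupCatalog,
) -> list[MoleculeRecord]:
    """Annotate every valid record with per-group presence flags.

    Accepts either existing records or raw SMILES strings (which are
    parsed first). Invalid records pass through unchanged; order is
    preserved and the operation is idempotent.
    """
    records: list[MoleculeRecord] = []
    for i, item in enumerate(stream):
        rec = item if isinstance(item, MoleculeRecord) else make_record(i, item)
        if rec.valid:
            if rec.mol is None:  # records loaded from CSV carry no Mol
                rec.mol = parse_smiles(rec.smiles)
            rec.group_flags = {
                g.name: rec.mol.HasSubstructMatch(g.pattern) for g in catalog
            }
        records.append(rec)
    return records
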
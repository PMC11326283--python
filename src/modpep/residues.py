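"""Residue library: monomer definitions the peptide builder assembles into molecules.

Each entry is a free amino-acid monomer written as an atom-mapped SMILES string.
The atom maps identify the handles the assembly chemistry needs:

====  ==========================================
map   meaning
====  ==========================================
1     backbone amine nitrogen
2     backbone acyl (carboxyl) carbon
3     side-chain thiol sulfur
4     side-chain primary amine nitrogen
5     side-chain carboxyl carbon
====  ==========================================

The packaged default library holds the 20 proteinogenic amino acids plus a
panel of unnatural monomers in the style of the SwissSidechain collection
(ornithine-series amines, homo/nor side chains, achiral disubstituted
residues, thiol variants).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from rdkit import Chem

__all__ = [
    "ResidueEntry",
    "ResidueLibrary",
    "LibraryError",
    "load_residue_library",
    "default_library",
]

#: reactive-group tags a residue may carry
REACTIVE_GROUPS = frozenset({"thiol", "sidechain_amine", "sidechain_carboxyl"})

# atom-map conventions used in monomer SMILES
MAP_BACKBONE_N = 1
MAP_ACYL_C = 2
MAP_THIOL_S = 3
MAP_SC_AMINE_N = 4
MAP_SC_CARBOXYL_C = 5


class LibraryError(ValueError):
    """Malformed or inconsistent residue-library input."""


@dataclass(frozen=True)
class ResidueEntry:
    """One monomer: code, atom-mapped structure and chemistry metadata."""

    code: str
    monomer: str
    natural: bool
    reactive_groups: frozenset[str] = field(default_factory=frozenset)
    has_alpha_stereocenter: bool = True
    #: backbone N is a secondary ring amine (proline-like) and cannot be N-methylated
    proline_like: bool = False

    @property
    def mol(self) -> Chem.Mol:
        return _monomer_mol(self.monomer)


def _parse_monomer(smiles: str) -> Chem.Mol:
    """Parse an atom-mapped monomer, relaxing the H counts SMILES brackets freeze.

    Bracket atoms carry an explicit hydrogen count; mapped handle atoms must
    instead pick up implicit hydrogens so that bond formation at build time
    adjusts their valence automatically.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise LibraryError(f"monomer SMILES does not parse: {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum():
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise LibraryError(f"monomer is not valid chemistry: {smiles!r} ({exc})") from None
    return mol


_MONOMER_CACHE: dict[str, Chem.Mol] = {}


def _monomer_mol(smiles: str) -> Chem.Mol:
    if smiles not in _MONOMER_CACHE:
        _MONOMER_CACHE[smiles] = _parse_monomer(smiles)
    return _MONOMER_CACHE[smiles]


def _find_map(mol: Chem.Mol, map_num: int) -> int | None:
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() == map_num:
            return atom.GetIdx()
    return None


def _alpha_carbon(mol: Chem.Mol) -> int:
    """The carbon bonded to both the backbone N and the acyl C."""
    n_idx = _find_map(mol, MAP_BACKBONE_N)
    c_idx = _find_map(mol, MAP_ACYL_C)
    if n_idx is None or c_idx is None:
        raise LibraryError("monomer lacks backbone atom maps 1 and 2")
    n_nbrs = {a.GetIdx() for a in mol.GetAtomWithIdx(n_idx).GetNeighbors()}
    c_nbrs = {a.GetIdx() for a in mol.GetAtomWithIdx(c_idx).GetNeighbors()}
    shared = [i for i in n_nbrs & c_nbrs if mol.GetAtomWithIdx(i).GetAtomicNum() == 6]
    if len(shared) != 1:
        raise LibraryError("monomer has no unique alpha carbon between maps 1 and 2")
    return shared[0]


def _entry_from_fields(code: str, monomer: str, natural: bool, tags: frozenset[str]) -> ResidueEntry:
    mol = _parse_monomer(monomer)
    for tag, map_num in (
        ("thiol", MAP_THIOL_S),
        ("sidechain_amine", MAP_SC_AMINE_N),
        ("sidechain_carboxyl", MAP_SC_CARBOXYL_C),
    ):
        has_handle = _find_map(mol, map_num) is not None
        if (tag in tags) != has_handle:
            raise LibraryError(
                f"residue {code!r}: reactive tag {tag!r} inconsistent with atom map {map_num}"
            )
    alpha = mol.GetAtomWithIdx(_alpha_carbon(mol))
    n_atom = mol.GetAtomWithIdx(_find_map(mol, MAP_BACKBONE_N))
    return ResidueEntry(
        code=code,
        monomer=monomer,
        natural=natural,
        reactive_groups=tags,
        has_alpha_stereocenter=alpha.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED,
        proline_like=n_atom.IsInRing(),
    )


class ResidueLibrary:
    """Ordered, code-indexed collection of :class:`ResidueEntry`."""

    def __init__(self, entries: list[ResidueEntry]):
        self._entries: dict[str, ResidueEntry] = {}
        for entry in entries:
            if entry.code in self._entries:
                raise LibraryError(f"duplicate residue code {entry.code!r}")
            self._entries[entry.code] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> ResidueEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None

    @property
    def codes(self) -> list[str]:
        return list(self._entries)

    @property
    def natural_codes(self) -> list[str]:
        return [e.code for e in self if e.natural]

    @property
    def unnatural_codes(self) -> list[str]:
        return [e.code for e in self if not e.natural]


def load_residue_library(path) -> ResidueLibrary:
    """Read a tab-separated residue library file.

    One entry per line: ``code<TAB>monomer SMILES<TAB>natural(1/0)<TAB>tags``,
    with ``#`` comments and blank lines ignored. ``tags`` is a comma-separated
    subset of ``{thiol, sidechain_amine, sidechain_carboxyl}`` or ``-``.
    """
    entries: list[ResidueEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise LibraryError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}")
            code, monomer, natural_s, tags_s = (f.strip() for f in fields)
            if natural_s not in {"0", "1"}:
                raise LibraryError(f"{path}:{lineno}: natural flag must be 0 or 1, got {natural_s!r}")
            tags = frozenset() if tags_s == "-" else frozenset(tags_s.split(","))
            if not tags <= REACTIVE_GROUPS:
                raise LibraryError(f"{path}:{lineno}: unknown reactive tags {sorted(tags - REACTIVE_GROUPS)}")
            if code in seen:
                raise LibraryError(f"{path}:{lineno}: duplicate residue code {code!r}")
            seen.add(code)
            try:
                entries.append(_entry_from_fields(code, monomer, natural_s == "1", tags))
            except LibraryError as exc:
                raise LibraryError(f"{path}:{lineno}: {exc}") from None
    return ResidueLibrary(entries)


def default_library() -> ResidueLibrary:
    """The packaged 20-natural + unnatural-panel library."""
    ref = importlib.resources.files("modpep") / "data" / "residues.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_residue_library(path)
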
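"""Realize a :class:`~modpep.specs.PeptideSpec` as an RDKit molecule / SMILES.

Monomers are condensed head-to-tail into amides (losing one water per bond),
then the requested ring closure, backbone N-methylations and PEG chain are
applied by graph editing before a single final sanitization. Alpha carbons
are tagged with a ``residx`` atom property so downstream code can verify
residue conservation on the built molecule.
"""

from __future__ import annotations

from rdkit import Chem

from .residues import (
    MAP_ACYL_C,
    MAP_BACKBONE_N,
    MAP_SC_AMINE_N,
    MAP_SC_CARBOXYL_C,
    MAP_THIOL_S,
    ResidueLibrary,
)
from .specs import PeptideSpec

__all__ = ["BuildError", "build_molecule", "build_smiles", "alpha_carbon_count", "canonical"]

#: one match per residue in this library's chemistry: N - alpha C - acyl C(=O)
ALPHA_SMARTS = Chem.MolFromSmarts("[NX3][CX4][CX3](=O)")


class BuildError(RuntimeError):
    """A spec could not be realized as valid chemistry; carries the spec."""

    def __init__(self, message: str, spec: PeptideSpec | None = None):
        super().__init__(message)
        self.spec = spec


class _ResidueHandles:
    __slots__ = ("n", "acyl", "alpha", "thiol", "sc_amine", "sc_carboxyl")

    def __init__(self):
        self.n = self.acyl = self.alpha = None
        self.thiol = self.sc_amine = self.sc_carboxyl = None


_MAP_SLOTS = {
    MAP_BACKBONE_N: "n",
    MAP_ACYL_C: "acyl",
    MAP_THIOL_S: "thiol",
    MAP_SC_AMINE_N: "sc_amine",
    MAP_SC_CARBOXYL_C: "sc_carboxyl",
}


def _invert_alpha(mol: Chem.RWMol, alpha_idx: int, spec: PeptideSpec) -> None:
    atom = mol.GetAtomWithIdx(alpha_idx)
    if atom.GetChiralTag() == Chem.ChiralType.CHI_UNSPECIFIED:
        raise BuildError("dextro flag on a residue without an alpha stereocenter", spec)
    atom.InvertChirality()


def build_molecule(spec: PeptideSpec, library: ResidueLibrary) -> Chem.Mol:
    """Assemble the molecule for a fully specified peptide."""
    rw = Chem.RWMol()
    handles: list[_ResidueHandles] = []

    for pos, res in enumerate(spec.residues):
        entry = library[res.code]
        monomer = Chem.Mol(entry.mol)  # copy; the library caches parsed monomers
        offset = rw.GetNumAtoms()
        rw.InsertMol(monomer)
        h = _ResidueHandles()
        for idx in range(offset, rw.GetNumAtoms()):
            atom = rw.GetAtomWithIdx(idx)
            slot = _MAP_SLOTS.get(atom.GetAtomMapNum())
            if slot is not None:
                setattr(h, slot, idx)
            atom.SetAtomMapNum(0)
        if h.n is None or h.acyl is None:
            raise BuildError(f"residue {res.code!r} lacks backbone handles", spec)
        n_nbrs = {a.GetIdx() for a in rw.GetAtomWithIdx(h.n).GetNeighbors()}
        c_nbrs = {a.GetIdx() for a in rw.GetAtomWithIdx(h.acyl).GetNeighbors()}
        (h.alpha,) = [i for i in n_nbrs & c_nbrs if rw.GetAtomWithIdx(i).GetAtomicNum() == 6]
        rw.GetAtomWithIdx(h.alpha).SetIntProp("residx", pos)
        if res.stereo == "D":
            _invert_alpha(rw, h.alpha, spec)
        handles.append(h)

    to_remove: set[int] = set()

    def condense(acyl_idx: int, n_idx: int) -> None:
        """Turn a carboxyl + amine pair into an amide (drop the hydroxyl O)."""
        acyl = rw.GetAtomWithIdx(acyl_idx)
        hydroxyl = None
        for bond in acyl.GetBonds():
            other = bond.GetOtherAtom(acyl)
            if (
                bond.GetBondType() == Chem.BondType.SINGLE
                and other.GetAtomicNum() == 8
                and other.GetDegree() == 1
                and other.GetIdx() not in to_remove
            ):
                hydroxyl = other.GetIdx()
                break
        if hydroxyl is None:
            raise BuildError("acyl carbon has no free hydroxyl to condense", spec)
        n_atom = rw.GetAtomWithIdx(n_idx)
        if n_atom.GetDegree() >= 3:
            raise BuildError("amine nitrogen already fully substituted", spec)
        to_remove.add(hydroxyl)
        rw.AddBond(acyl_idx, n_idx, Chem.BondType.SINGLE)

    # backbone amide bonds
    for i in range(len(handles) - 1):
        condense(handles[i].acyl, handles[i + 1].n)

    # ring closure
    cyc = spec.cyclization
    if cyc.kind == "head_to_tail":
        condense(handles[-1].acyl, handles[0].n)
    elif cyc.kind == "disulfide":
        i, j = cyc.sites
        if handles[i].thiol is None or handles[j].thiol is None:
            raise BuildError("disulfide sites lack thiols", spec)
        rw.AddBond(handles[i].thiol, handles[j].thiol, Chem.BondType.SINGLE)
    elif cyc.kind == "sidechain_to_sidechain":
        i, j = cyc.sites
        if handles[i].sc_carboxyl is None or handles[j].sc_amine is None:
            raise BuildError("sidechain-to-sidechain sites lack reactive groups", spec)
        condense(handles[i].sc_carboxyl, handles[j].sc_amine)
    elif cyc.kind == "sidechain_to_head":
        (i,) = cyc.sites
        if handles[i].sc_carboxyl is None:
            raise BuildError("sidechain-to-head donor lacks a carboxyl", spec)
        condense(handles[i].sc_carboxyl, handles[0].n)
    elif cyc.kind == "sidechain_to_tail":
        (j,) = cyc.sites
        if handles[j].sc_amine is None:
            raise BuildError("sidechain-to-tail donor lacks an amine", spec)
        condense(handles[-1].acyl, handles[j].sc_amine)

    # backbone N-methylation
    for pos in sorted(spec.n_methyl_sites):
        n_idx = handles[pos].n
        if rw.GetAtomWithIdx(n_idx).GetDegree() >= 3:
            raise BuildError(f"backbone N of residue {pos} cannot take a methyl", spec)
        methyl = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(n_idx, methyl, Chem.BondType.SINGLE)

    # PEG chain: N-(CH2CH2O)n-CH3, methyl-capped
    if spec.peg is not None:
        kind, pos = spec.peg.site
        n_idx = handles[0].n if kind == "nterm" else handles[pos].sc_amine
        if n_idx is None:
            raise BuildError("PEG site residue has no side-chain amine", spec)
        if rw.GetAtomWithIdx(n_idx).GetDegree() >= 3:
            raise BuildError("PEG attachment amine is fully substituted", spec)
        prev = n_idx
        for _ in range(spec.peg.monomers):
            for atomic_num in (6, 6, 8):
                nxt = rw.AddAtom(Chem.Atom(atomic_num))
                rw.AddBond(prev, nxt, Chem.BondType.SINGLE)
                prev = nxt
        cap = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(prev, cap, Chem.BondType.SINGLE)

    for idx in sorted(to_remove, reverse=True):
        rw.RemoveAtom(idx)

    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - guarded by spec-level feasibility rules
        raise BuildError(f"sanitization failed: {exc}", spec) from exc
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def build_smiles(spec: PeptideSpec, library: ResidueLibrary) -> str:
    """Canonical SMILES of the realized peptide."""
    return Chem.MolToSmiles(build_molecule(spec, library))


def alpha_carbon_count(mol_or_smiles) -> int:
    """Count backbone alpha carbons (N-CA-C(=O) units) in a molecule."""
    mol = mol_or_smiles
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"SMILES does not parse: {mol_or_smiles!r}")
    return len(mol.GetSubstructMatches(ALPHA_SMARTS))


def canonical(smiles: str) -> str | None:
    """Canonical form of a SMILES string, or None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)
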
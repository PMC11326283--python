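"""Symbolic peptide specifications: the residue-level description of a peptide
(sequence, stereochemistry, cyclization, backbone N-methylation, PEGylation)
prior to its realization as a molecule."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CYCLIZATION_TYPES",
    "Residue",
    "Cyclization",
    "PEG",
    "PeptideSpec",
    "LINEAR",
]

#: the five supported ring-closure chemistries
CYCLIZATION_TYPES = (
    "head_to_tail",
    "sidechain_to_sidechain",
    "sidechain_to_head",
    "sidechain_to_tail",
    "disulfide",
)


@dataclass(frozen=True)
class Residue:
    """One position in the chain: residue code and alpha-carbon configuration."""

    code: str
    stereo: str = "L"  # "L", "D", or "none" for achiral alpha carbons

    def __post_init__(self):
        if self.stereo not in {"L", "D", "none"}:
            raise ValueError(f"stereo must be L, D or none, got {self.stereo!r}")


@dataclass(frozen=True)
class Cyclization:
    """A ring closure: its chemistry and the residue indices it joins.

    ``sites`` semantics by kind: ``head_to_tail`` — empty (termini implied);
    ``disulfide`` — the two thiol residues; ``sidechain_to_sidechain`` —
    (carboxyl residue, amine residue); ``sidechain_to_head`` — the carboxyl
    donor; ``sidechain_to_tail`` — the amine donor.
    """

    kind: str = "linear"
    sites: tuple[int, ...] = ()

    def __post_init__(self):
        if self.kind != "linear" and self.kind not in CYCLIZATION_TYPES:
            raise ValueError(f"unknown cyclization kind {self.kind!r}")

    @property
    def is_cyclic(self) -> bool:
        return self.kind != "linear"

    @property
    def consumes_nterm(self) -> bool:
        return self.kind in {"head_to_tail", "sidechain_to_head"}

    @property
    def consumes_cterm(self) -> bool:
        return self.kind in {"head_to_tail", "sidechain_to_tail"}


LINEAR = Cyclization()


@dataclass(frozen=True)
class PEG(object):
    """A polyethylene-glycol chain attached to a free amine.

    ``site`` is ``("nterm", 0)`` for the N-terminal alpha amine or
    ``("sidechain", i)`` for residue *i*'s side-chain amine; ``monomers`` is
    the number of ethylene-oxide units.
    """

    site: tuple[str, int]
    monomers: int

    def __post_init__(self):
        kind, idx = self.site
        if kind not in {"nterm", "sidechain"}:
            raise ValueError(f"PEG site kind must be nterm or sidechain, got {kind!r}")
        if self.monomers < 1:
            raise ValueError("PEG chain needs at least one monomer")


@dataclass(frozen=True)
class PeptideSpec:
    """Complete symbolic description of one generated peptide."""

    residues: tuple[Residue, ...]
    cyclization: Cyclization = LINEAR
    n_methyl_sites: frozenset[int] = field(default_factory=frozenset)
    peg: PEG | None = None

    def __post_init__(self):
        n = len(self.residues)
        if n < 1:
            raise ValueError("a peptide needs at least one residue")
        for idx in self.cyclization.sites:
            if not 0 <= idx < n:
                raise ValueError(f"cyclization site {idx} out of range for length {n}")
        for idx in self.n_methyl_sites:
            # position 0 carries the alpha amine, not a backbone amide
            if not 1 <= idx < n:
                raise ValueError(f"N-methyl site {idx} is not a backbone amide position")
        if self.peg is not None:
            kind, idx = self.peg.site
            if not 0 <= idx < n:
                raise ValueError(f"PEG site {idx} out of range")
            if kind == "nterm" and idx != 0:
                raise ValueError("N-terminal PEG site must be residue 0")

    def __len__(self) -> int:
        return len(self.residues)

    def with_cyclization(self, cyc: Cyclization) -> "PeptideSpec":
        return replace(self, cyclization=cyc)

    def with_n_methyl(self, sites: frozenset[int]) -> "PeptideSpec":
        return replace(self, n_methyl_sites=frozenset(sites))

    def with_peg(self, peg: PEG | None) -> "PeptideSpec":
        return replace(self, peg=peg)
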
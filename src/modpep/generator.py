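"""Stochastic generation of chemically modified, optionally cyclic peptides.

The sampling scheme mirrors how modified therapeutic peptides are enumerated
for pretraining corpora: uniform-length chains drawn from a residue library
(90% natural / 10% unnatural by default), dextro inversion at 10% of alpha
stereocenters, a uniformly drawn cyclization chemistry that degrades to a
linear peptide when infeasible, backbone N-methylation on 20% of amide NH
positions within 20% of peptides, and PEGylation of 20% of peptides at a
free amine with 1-4 ethylene-oxide monomers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .chem import build_smiles
from .residues import ResidueLibrary
from .specs import CYCLIZATION_TYPES, PEG, Cyclization, PeptideSpec, Residue

__all__ = [
    "GeneratorConfig",
    "GeneratedRecord",
    "GenerationSummary",
    "sample_peptide_spec",
    "assign_cyclization",
    "apply_n_methylation",
    "apply_pegylation",
    "sample_modified_spec",
    "generate_specs",
    "generate_record",
    "generate_corpus",
    "summarize_specs",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling rates and limits for peptide generation."""

    max_length: int = 100
    unnatural_fraction: float = 0.10
    d_fraction: float = 0.10
    nmeth_peptide_fraction: float = 0.20
    nmeth_amine_fraction: float = 0.20
    peg_fraction: float = 0.20
    peg_monomers: tuple[int, int] = (1, 4)
    cyclization_types: tuple[str, ...] = CYCLIZATION_TYPES
    seed: int = 0

    def __post_init__(self):
        for name in (
            "unnatural_fraction",
            "d_fraction",
            "nmeth_peptide_fraction",
            "nmeth_amine_fraction",
            "peg_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.max_length < 1:
            raise ValueError("max_length must be at least 1")
        lo, hi = self.peg_monomers
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid peg_monomers range {self.peg_monomers}")
        unknown = set(self.cyclization_types) - set(CYCLIZATION_TYPES)
        if unknown:
            raise ValueError(f"unknown cyclization types {sorted(unknown)}")


@dataclass(frozen=True)
class GeneratedRecord:
    """A realized peptide with the provenance needed to regenerate it."""

    spec: PeptideSpec
    smiles: str
    seed_path: tuple[int, int]  # (run seed, record index)


def sample_peptide_spec(
    library: ResidueLibrary, config: GeneratorConfig, rng: np.random.Generator
) -> PeptideSpec:
    """Draw an unmodified linear peptide: length, residues and stereochemistry."""
    naturals = library.natural_codes
    unnaturals = library.unnatural_codes
    if not naturals:
        raise ValueError("residue library has no natural residues")
    if config.unnatural_fraction > 0 and not unnaturals:
        raise ValueError("unnatural_fraction > 0 but the library has no unnatural residues")

    length = int(rng.integers(1, config.max_length + 1))
    residues = []
    for _ in range(length):
        if config.unnatural_fraction > 0 and rng.random() < config.unnatural_fraction:
            code = unnaturals[int(rng.integers(len(unnaturals)))]
        else:
            code = naturals[int(rng.integers(len(naturals)))]
        entry = library[code]
        if not entry.has_alpha_stereocenter:
            stereo = "none"
        elif rng.random() < config.d_fraction:
            stereo = "D"
        else:
            stereo = "L"
        residues.append(Residue(code, stereo))
    return PeptideSpec(tuple(residues))


def _cyclization_candidates(
    spec: PeptideSpec, library: ResidueLibrary, kind: str
) -> list[tuple[int, ...]]:
    """All feasible attachment-site tuples for a cyclization chemistry."""
    n = len(spec)
    groups = [library[r.code].reactive_groups for r in spec.residues]
    thiols = [i for i, g in enumerate(groups) if "thiol" in g]
    amines = [i for i, g in enumerate(groups) if "sidechain_amine" in g]
    carboxyls = [i for i, g in enumerate(groups) if "sidechain_carboxyl" in g]

    if kind == "head_to_tail":
        return [()] if n >= 2 else []
    if kind == "disulfide":
        return [(i, j) for k, i in enumerate(thiols) for j in thiols[k + 1 :]]
    if kind == "sidechain_to_sidechain":
        return [(i, j) for i in carboxyls for j in amines if i != j]
    if kind == "sidechain_to_head":
        # residue 0 may not lactamize onto its own backbone amine
        return [(i,) for i in carboxyls if i >= 1]
    if kind == "sidechain_to_tail":
        return [(j,) for j in amines if j <= n - 2]
    raise ValueError(f"unknown cyclization kind {kind!r}")


def assign_cyclization(
    spec: PeptideSpec,
    library: ResidueLibrary,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> PeptideSpec:
    """Draw a cyclization chemistry uniformly; fall back to linear if infeasible."""
    if spec.cyclization.is_cyclic or spec.n_methyl_sites or spec.peg is not None:
        raise ValueError("cyclization must be assigned to an unmodified linear spec")
    if not config.cyclization_types:
        return spec
    kind = config.cyclization_types[int(rng.integers(len(config.cyclization_types)))]
    candidates = _cyclization_candidates(spec, library, kind)
    if not candidates:
        return spec  # infeasible draw leaves the peptide linear
    sites = candidates[int(rng.integers(len(candidates)))]
    return spec.with_cyclization(Cyclization(kind, sites))


def methylatable_positions(spec: PeptideSpec, library: ResidueLibrary) -> list[int]:
    """Backbone amide NH positions: every position after the first whose
    nitrogen is not already tertiary (proline-like rings are excluded)."""
    return [
        i for i in range(1, len(spec)) if not library[spec.residues[i].code].proline_like
    ]


def apply_n_methylation(
    spec: PeptideSpec,
    library: ResidueLibrary,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> PeptideSpec:
    """Two-level draw: select the peptide, then methylate each amide NH independently."""
    if rng.random() >= config.nmeth_peptide_fraction:
        return spec
    sites = {
        i
        for i in methylatable_positions(spec, library)
        if rng.random() < config.nmeth_amine_fraction
    }
    return spec.with_n_methyl(frozenset(sites)) if sites else spec


def free_amine_sites(spec: PeptideSpec, library: ResidueLibrary) -> list[tuple[str, int]]:
    """Amines still free after cyclization: the N-terminal alpha amine plus
    unconsumed side-chain amines."""
    sites: list[tuple[str, int]] = []
    cyc = spec.cyclization
    if not cyc.consumes_nterm:
        sites.append(("nterm", 0))
    consumed = set()
    if cyc.kind == "sidechain_to_sidechain":
        consumed.add(cyc.sites[1])
    elif cyc.kind == "sidechain_to_tail":
        consumed.add(cyc.sites[0])
    for i, res in enumerate(spec.residues):
        if "sidechain_amine" in library[res.code].reactive_groups and i not in consumed:
            sites.append(("sidechain", i))
    return sites


def apply_pegylation(
    spec: PeptideSpec,
    library: ResidueLibrary,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> PeptideSpec:
    """Attach a 1-4 monomer PEG chain at a uniformly chosen free amine."""
    if rng.random() >= config.peg_fraction:
        return spec
    sites = free_amine_sites(spec, library)
    if not sites:
        return spec
    site = sites[int(rng.integers(len(sites)))]
    lo, hi = config.peg_monomers
    monomers = int(rng.integers(lo, hi + 1))
    return spec.with_peg(PEG(site, monomers))


def sample_modified_spec(
    library: ResidueLibrary, config: GeneratorConfig, rng: np.random.Generator
) -> PeptideSpec:
    """One fully assigned peptide: sequence, cyclization, N-methylation, PEG."""
    spec = sample_peptide_spec(library, config, rng)
    spec = assign_cyclization(spec, library, config, rng)
    spec = apply_n_methylation(spec, library, config, rng)
    spec = apply_pegylation(spec, library, config, rng)
    return spec


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_record(
    library: ResidueLibrary, config: GeneratorConfig, index: int
) -> GeneratedRecord:
    """Generate record ``index`` of the run; reproducible from (seed, index)."""
    rng = _record_rng(config.seed, index)
    spec = sample_modified_spec(library, config, rng)
    return GeneratedRecord(spec, build_smiles(spec, library), (config.seed, index))


def generate_specs(
    n: int, library: ResidueLibrary, config: GeneratorConfig
) -> list[PeptideSpec]:
    """n fully assigned specs, one independent substream per record."""
    return [
        sample_modified_spec(library, config, _record_rng(config.seed, i)) for i in range(n)
    ]


@dataclass
class GenerationSummary:
    """Empirical modification counts over a batch of generated peptides."""

    n: int = 0
    residues_total: int = 0
    unnatural_residues: int = 0
    stereocenter_residues: int = 0
    d_residues: int = 0
    amide_nh_total: int = 0
    methylated_amides: int = 0
    free_amine_peptides: int = 0
    pegylated_peptides: int = 0
    peg_monomer_counts: Counter = field(default_factory=Counter)
    cyclization_counts: Counter = field(default_factory=Counter)

    @property
    def unnatural_fraction(self) -> float:
        return self.unnatural_residues / max(self.residues_total, 1)

    @property
    def d_fraction(self) -> float:
        return self.d_residues / max(self.stereocenter_residues, 1)

    @property
    def methylated_amide_fraction(self) -> float:
        return self.methylated_amides / max(self.amide_nh_total, 1)

    @property
    def pegylated_fraction(self) -> float:
        """PEGylated share among peptides that had a free amine to modify."""
        return self.pegylated_peptides / max(self.free_amine_peptides, 1)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "unnatural_fraction": self.unnatural_fraction,
            "d_fraction": self.d_fraction,
            "methylated_amide_fraction": self.methylated_amide_fraction,
            "pegylated_fraction": self.pegylated_fraction,
            "peg_monomer_counts": dict(sorted(self.peg_monomer_counts.items())),
            "cyclization_counts": dict(sorted(self.cyclization_counts.items())),
        }


def summarize_specs(specs, library: ResidueLibrary) -> GenerationSummary:
    s = GenerationSummary()
    for spec in specs:
        s.n += 1
        s.residues_total += len(spec)
        for res in spec.residues:
            entry = library[res.code]
            if not entry.natural:
                s.unnatural_residues += 1
            if entry.has_alpha_stereocenter:
                s.stereocenter_residues += 1
                if res.stereo == "D":
                    s.d_residues += 1
        s.amide_nh_total += len(methylatable_positions(spec, library))
        s.methylated_amides += len(spec.n_methyl_sites)
        # a peptide counts as PEG-eligible if, post-cyclization, a free amine exists
        if spec.peg is not None or free_amine_sites(spec, library):
            s.free_amine_peptides += 1
        if spec.peg is not None:
            s.pegylated_peptides += 1
            s.peg_monomer_counts[spec.peg.monomers] += 1
        s.cyclization_counts[spec.cyclization.kind] += 1
    return s


def generate_corpus(
    n: int, library: ResidueLibrary, config: GeneratorConfig, output
) -> GenerationSummary:
    """Write ``n`` generated SMILES, one per line, and return the batch summary."""
    if n < 0:
        raise ValueError("n must be non-negative")
    specs = []
    with open(output, "w", encoding="utf-8", newline="\n") as fh:
        for i in range(n):
            record = generate_record(library, config, i)
            specs.append(record.spec)
            fh.write(record.smiles + "\n")
    return summarize_specs(specs, library)
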
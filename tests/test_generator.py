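import math

import numpy as np
import pytest
from rdkit import Chem

from modpep.chem import BuildError, alpha_carbon_count, build_smiles, canonical
from modpep.generator import (
    GeneratorConfig,
    apply_n_methylation,
    apply_pegylation,
    assign_cyclization,
    free_amine_sites,
    generate_corpus,
    generate_record,
    generate_specs,
    methylatable_positions,
    sample_peptide_spec,
    summarize_specs,
)
from modpep.specs import CYCLIZATION_TYPES, PEG, Cyclization, PeptideSpec, Residue


def three_se(p, n):
    return 3.0 * math.sqrt(p * (1.0 - p) / n)


class TestSampling:
    def test_unnatural_and_dextro_rates(self, library):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(max_length=30)
        specs = [sample_peptide_spec(library, cfg, rng) for _ in range(4000)]
        s = summarize_specs(specs, library)
        assert abs(s.unnatural_fraction - 0.10) < three_se(0.10, s.residues_total)
        assert abs(s.d_fraction - 0.10) < three_se(0.10, s.stereocenter_residues)

    def test_glycine_never_dextro(self, library):
        rng = np.random.default_rng(1)
        cfg = GeneratorConfig(max_length=20, d_fraction=1.0)
        for _ in range(200):
            spec = sample_peptide_spec(library, cfg, rng)
            for res in spec.residues:
                if not library[res.code].has_alpha_stereocenter:
                    assert res.stereo == "none"
                else:
                    assert res.stereo == "D"

    def test_unnatural_fraction_zero(self, library):
        rng = np.random.default_rng(2)
        cfg = GeneratorConfig(max_length=20, unnatural_fraction=0.0)
        spec = sample_peptide_spec(library, cfg, rng)
        assert all(library[r.code].natural for r in spec.residues)

    def test_lengths_span_range(self, library):
        rng = np.random.default_rng(3)
        cfg = GeneratorConfig(max_length=5)
        lengths = {len(sample_peptide_spec(library, cfg, rng)) for _ in range(300)}
        assert lengths == {1, 2, 3, 4, 5}


class TestCyclization:
    def test_draw_uniform_over_feasible_types(self, library):
        # every chemistry is feasible for this sequence
        spec = PeptideSpec(
            tuple(Residue(c) for c in ("Cys", "Lys", "Gly", "Asp", "Cys", "Ala"))
        )
        spec = PeptideSpec(
            tuple(
                Residue(c, "none" if not library[c].has_alpha_stereocenter else "L")
                for c in ("Cys", "Lys", "Gly", "Asp", "Cys", "Ala")
            )
        )
        rng = np.random.default_rng(4)
        cfg = GeneratorConfig()
        counts = {k: 0 for k in CYCLIZATION_TYPES}
        n = 10_000
        for _ in range(n):
            out = assign_cyclization(spec, library, cfg, rng)
            assert out.cyclization.is_cyclic
            counts[out.cyclization.kind] += 1
        for kind, count in counts.items():
            assert abs(count / n - 0.2) < three_se(0.2, n), kind

    def test_infeasible_draw_leaves_linear(self, library):
        rng = np.random.default_rng(5)
        cfg = GeneratorConfig(cyclization_types=("disulfide",))
        spec = PeptideSpec((Residue("Ala"), Residue("Gly", "none")))
        out = assign_cyclization(spec, library, cfg, rng)
        assert not out.cyclization.is_cyclic

    def test_single_residue_never_head_to_tail(self, library):
        rng = np.random.default_rng(6)
        cfg = GeneratorConfig(cyclization_types=("head_to_tail",))
        spec = PeptideSpec((Residue("Ala"),))
        for _ in range(20):
            assert not assign_cyclization(spec, library, cfg, rng).cyclization.is_cyclic


class TestNMethylation:
    def test_selected_peptide_binomial_expectation(self, library):
        # 11 residues -> 10 backbone amides; q = 0.2 -> expected 2 methyls
        spec = PeptideSpec(tuple(Residue("Ala") for _ in range(11)))
        cfg = GeneratorConfig(nmeth_peptide_fraction=1.0)
        rng = np.random.default_rng(7)
        counts = [
            len(apply_n_methylation(spec, library, cfg, rng).n_methyl_sites)
            for _ in range(10_000)
        ]
        se = math.sqrt(10 * 0.2 * 0.8 / len(counts))
        assert abs(np.mean(counts) - 2.0) < 3 * se

    def test_disabled_methylation(self, library):
        spec = PeptideSpec(tuple(Residue("Ala") for _ in range(5)))
        cfg = GeneratorConfig(nmeth_peptide_fraction=0.0)
        rng = np.random.default_rng(8)
        assert not apply_n_methylation(spec, library, cfg, rng).n_methyl_sites

    def test_proline_excluded(self, library):
        spec = PeptideSpec((Residue("Ala"), Residue("Pro"), Residue("Ala")))
        assert methylatable_positions(spec, library) == [2]


class TestPegylation:
    def test_no_free_amine_leaves_unmodified(self, library):
        spec = PeptideSpec(
            (Residue("Ala"), Residue("Ala")), cyclization=Cyclization("head_to_tail")
        )
        cfg = GeneratorConfig(peg_fraction=1.0)
        rng = np.random.default_rng(9)
        assert apply_pegylation(spec, library, cfg, rng).peg is None

    def test_monomer_counts_uniform(self, library):
        spec = PeptideSpec(tuple(Residue("Ala") for _ in range(4)))
        cfg = GeneratorConfig(peg_fraction=1.0)
        rng = np.random.default_rng(10)
        counts = np.zeros(5)
        n = 10_000
        for _ in range(n):
            peg = apply_pegylation(spec, library, cfg, rng).peg
            counts[peg.monomers] += 1
        assert counts[0] == 0 and counts.argmax() <= 4
        for m in range(1, 5):
            assert abs(counts[m] / n - 0.25) < three_se(0.25, n)

    def test_consumed_sidechain_amine_not_free(self, library):
        spec = PeptideSpec(
            (Residue("Asp"), Residue("Ala"), Residue("Lys")),
            cyclization=Cyclization("sidechain_to_sidechain", (0, 2)),
        )
        assert free_amine_sites(spec, library) == [("nterm", 0)]


class TestBuild:
    def test_single_glycine(self, library):
        spec = PeptideSpec((Residue("Gly", "none"),))
        assert build_smiles(spec, library) == canonical("NCC(=O)O")

    def test_gly_gly(self, library):
        spec = PeptideSpec((Residue("Gly", "none"), Residue("Gly", "none")))
        assert build_smiles(spec, library) == canonical("NCC(=O)NCC(=O)O")

    def test_all_five_modifications_present_in_structure(self, library):
        """A tetrapeptide carrying an unnatural residue, a dextro flag, a ring
        closure, an N-methyl and a PEG chain realizes all five motifs."""
        spec = PeptideSpec(
            (Residue("Dea", "none"), Residue("Lys"), Residue("Leu", "D"), Residue("Gly", "none")),
            cyclization=Cyclization("sidechain_to_tail", (1,)),
            n_methyl_sites=frozenset({2}),
            peg=PEG(("nterm", 0), 2),
        )
        smiles = build_smiles(spec, library)
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None
        assert alpha_carbon_count(mol) == 4
        assert mol.GetSubstructMatches(Chem.MolFromSmarts("[CH3][NX3][CX3]=O"))  # N-methyl
        assert mol.GetSubstructMatches(Chem.MolFromSmarts("[NX3]CCOC"))  # PEG ether
        assert any(b.IsInRing() for b in mol.GetBonds())  # macrolactam
        assert "@" in smiles  # stereo annotation survives

    def test_dextro_inverts_alpha_configuration(self, library):
        l_form = build_smiles(PeptideSpec((Residue("Ala", "L"),)), library)
        d_form = build_smiles(PeptideSpec((Residue("Ala", "D"),)), library)
        assert l_form != d_form
        assert canonical(d_form) == canonical("C[C@@H](N)C(=O)O")

    def test_methylating_proline_fails(self, library):
        spec = PeptideSpec(
            (Residue("Ala"), Residue("Pro")), n_methyl_sites=frozenset({1})
        )
        with pytest.raises(BuildError):
            build_smiles(spec, library)


class TestCorpus:
    def test_deterministic_output(self, library, tmp_path):
        cfg = GeneratorConfig(seed=42, max_length=8)
        a, b = tmp_path / "a.txt", tmp_path / "b.txt"
        generate_corpus(50, library, cfg, a)
        generate_corpus(50, library, cfg, b)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_corpus(self, library, tmp_path):
        path = tmp_path / "empty.txt"
        summary = generate_corpus(0, library, GeneratorConfig(), path)
        assert path.read_text() == ""
        assert summary.n == 0

    def test_record_reproducible_from_seed_path(self, library):
        cfg = GeneratorConfig(seed=3, max_length=15)
        first = generate_record(library, cfg, 5)
        again = generate_record(library, cfg, 5)
        assert first.smiles == again.smiles
        assert first.seed_path == (3, 5)

    def test_validity_and_residue_conservation(self, library):
        cfg = GeneratorConfig(seed=11, max_length=25)
        for i in range(60):
            record = generate_record(library, cfg, i)
            assert canonical(record.smiles) == record.smiles  # idempotent canonicalization
            assert alpha_carbon_count(record.smiles) == len(record.spec)

    def test_cyclic_iff_feasible_draw(self, library):
        specs = generate_specs(300, library, GeneratorConfig(seed=13, max_length=12))
        summary = summarize_specs(specs, library)
        assert summary.cyclization_counts["linear"] > 0
        assert sum(summary.cyclization_counts.values()) == 300


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"unnatural_fraction": 1.5},
            {"max_length": 0},
            {"peg_monomers": (0, 4)},
            {"cyclization_types": ("macro",)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_unnatural_required_when_fraction_positive(self, library, tmp_path):
        from modpep.residues import load_residue_library

        path = tmp_path / "nat.tsv"
        path.write_text("Ala\t[N:1][C@@H](C)[C:2](=O)O\t1\t-\n")
        natural_only = load_residue_library(path)
        with pytest.raises(ValueError):
            sample_peptide_spec(natural_only, GeneratorConfig(), np.random.default_rng(0))
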
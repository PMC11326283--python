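# Packaged residue library: 20 proteinogenic amino acids plus a SwissSidechain-style
# panel of unnatural monomers. Columns (tab-separated):
#   code    monomer SMILES (atom-mapped)    natural (1/0)    reactive tags (comma list or '-')
# Atom maps: 1 = backbone amine N, 2 = backbone acyl C, 3 = thiol S,
#            4 = side-chain primary amine N, 5 = side-chain carboxyl C.
# Monomers are drawn in the L configuration; dextro residues are produced by
# inverting the alpha carbon at build time.
Ala	[N:1][C@@H](C)[C:2](=O)O	1	-
Arg	[N:1][C@@H](CCCNC(=N)N)[C:2](=O)O	1	-
Asn	[N:1][C@@H](CC(N)=O)[C:2](=O)O	1	-
Asp	[N:1][C@@H](C[C:5](=O)O)[C:2](=O)O	1	sidechain_carboxyl
Cys	[N:1][C@@H](C[S:3])[C:2](=O)O	1	thiol
Gln	[N:1][C@@H](CCC(N)=O)[C:2](=O)O	1	-
Glu	[N:1][C@@H](CC[C:5](=O)O)[C:2](=O)O	1	sidechain_carboxyl
Gly	[N:1]C[C:2](=O)O	1	-
His	[N:1][C@@H](Cc1c[nH]cn1)[C:2](=O)O	1	-
Ile	[N:1][C@@H]([C@@H](C)CC)[C:2](=O)O	1	-
Leu	[N:1][C@@H](CC(C)C)[C:2](=O)O	1	-
Lys	[N:1][C@@H](CCCC[N:4])[C:2](=O)O	1	sidechain_amine
Met	[N:1][C@@H](CCSC)[C:2](=O)O	1	-
Phe	[N:1][C@@H](Cc1ccccc1)[C:2](=O)O	1	-
Pro	[N:1]1CCC[C@H]1[C:2](=O)O	1	-
Ser	[N:1][C@@H](CO)[C:2](=O)O	1	-
Thr	[N:1][C@@H]([C@@H](O)C)[C:2](=O)O	1	-
Trp	[N:1][C@@H](Cc1c[nH]c2ccccc12)[C:2](=O)O	1	-
Tyr	[N:1][C@@H](Cc1ccc(O)cc1)[C:2](=O)O	1	-
Val	[N:1][C@@H](C(C)C)[C:2](=O)O	1	-
Orn	[N:1][C@@H](CCC[N:4])[C:2](=O)O	0	sidechain_amine
Dab	[N:1][C@@H](CC[N:4])[C:2](=O)O	0	sidechain_amine
Dap	[N:1][C@@H](C[N:4])[C:2](=O)O	0	sidechain_amine
Hcy	[N:1][C@@H](CC[S:3])[C:2](=O)O	0	thiol
Pen	[N:1][C@@H](C(C)(C)[S:3])[C:2](=O)O	0	thiol
Aib	[N:1]C(C)(C)[C:2](=O)O	0	-
Dea	[N:1]C(CC)(CC)[C:2](=O)O	0	-
Nle	[N:1][C@@H](CCCC)[C:2](=O)O	0	-
Nva	[N:1][C@@H](CCC)[C:2](=O)O	0	-
Abu	[N:1][C@@H](CC)[C:2](=O)O	0	-
Phg	[N:1][C@@H](c1ccccc1)[C:2](=O)O	0	-
Cha	[N:1][C@@H](CC1CCCCC1)[C:2](=O)O	0	-
Nal	[N:1][C@@H](Cc1ccc2ccccc2c1)[C:2](=O)O	0	-
Hse	[N:1][C@@H](CCO)[C:2](=O)O	0	-
Aad	[N:1][C@@H](CCC[C:5](=O)O)[C:2](=O)O	0	sidechain_carboxyl
Hle	[N:1][C@@H](CCC(C)C)[C:2](=O)O	0	-
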
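# Deposited coordinate files

Place the deposited PDB entries here (lower-case file names) to enable the
acceptance tests that reproduce published structural values:

    1ubq.pdb   ubiquitin crystal structure (reference)
    6gf1.pdb   FAT10 N-domain crystal structure (3 chains / asymmetric unit)
    6gf2.pdb   FAT10 C-domain NMR ensemble

With network access:

    for id in 1ubq 6gf1 6gf2; do
      curl -o data/deposited/$id.pdb https://files.rcsb.org/download/${id^^}.pdb
    done

These files are not redistributed with the package. `.cif` / `.ent`
extensions are also recognised.
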
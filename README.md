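# ublsurf

Quantitative structural comparison of ubiquitin-like (UBL) domains, built
around the analyses used to characterise FAT10 (ubiquitin D) -- the
mammalian UBL modifier whose two β-grasp domains target substrates directly
for proteasomal degradation. The package is for structural biologists and
bioinformaticians who want reproducible, scriptable versions of the usual
desk analyses around such a structure determination:

- **Superposition / r.m.s.d.** — Kabsch least-squares superposition
  (reflections excluded), pairwise backbone r.m.s.d. over a residue
  correspondence, NMR-ensemble precision (mean ± sd of per-model r.m.s.d.
  to an iteratively refined mean structure), and an iterative
  structure-based sequence alignment (superpose on CA, re-pair by monotone
  nearest-neighbour matching within 4.5 Å, repeat to convergence).
- **Solvent accessibility** — Shrake–Rupley SASA on a deterministic
  golden-spiral lattice (bit-identical across runs), relative accessibility
  against Gly-X-Gly maxima, and exposed/buried calls (threshold 0.25).
- **Interface scoring** — per-residue buried SASA in binary complexes
  (ΔSASA between the isolated chain and the assembly) and a 0–1
  interface-occurrence score across a panel of complexes: the fraction of
  complexes in which a residue buries > 10 % of its accessible surface.
- **Sequence conservation** — global BLOSUM62 identity (gap open 10 /
  extend 0.5), per-column MSA conservation (modal frequency or normalised
  Shannon entropy), and mapping of column scores onto structure B-factors
  for surface colouring.
- **NMR observables** — chemical shift perturbations
  Δδ = √(Δδ_H² + (0.154·Δδ_N)²) from assigned HSQC peak lists, and
  steady-state {¹H}-¹⁵N NOE ratios with replicate statistics; residues with
  NOE < 0.2 are flagged as undergoing fast backbone motion.
- **Stability & dynamics** — melting temperatures from the first-derivative
  maximum of smoothed nanoDSF-style melt curves, residue-wise RMSF,
  GROMOS-style RMSD clustering of trajectory frames, and centroid-distance
  time series.
- **Synthetic data** — seeded generators for every input class (ideal-geometry
  backbones, self-certified interface plants, MSAs with exact planted
  conservation, sigmoid melt curves, jittered ensembles), each returning the
  planted ground truth.

## Worked example

The bundled reference sequences (human FAT10, human ubiquitin) reproduce the
domain-level sequence relationships directly:

```python
>>> from ublsurf import refseqs
>>> from ublsurf.seqcons import pairwise_identity, sequence_correspondence
>>> from ublsurf.interface import surface_patch_compare
>>> seq_n, _ = refseqs.fat10_domain("N")
>>> seq_c, start_c = refseqs.fat10_domain("C")
>>> round(pairwise_identity(seq_n, refseqs.UBIQUITIN_HUMAN))
27
>>> round(pairwise_identity(seq_c, refseqs.UBIQUITIN_HUMAN))
35
>>> round(pairwise_identity(seq_n, seq_c))
18
>>> corr = sequence_correspondence(refseqs.UBIQUITIN_HUMAN, seq_c, start_b=start_c)
>>> [(r.position_b, r.name_b) for r in surface_patch_compare([8, 44, 70], corr)]
[(95, 'S'), (133, 'T'), (159, 'A')]
```

The FAT10 domains are only ~27 % and ~35 % identical to ubiquitin (and 18 %
to each other), and ubiquitin's hydrophobic patch L8/I44/V70 — the surface
used by most ubiquitin–protein interactions — maps onto the polar C-domain
triad S95/T133/A159, i.e. the patch is not conserved.

From the shell, the same machinery runs on files:

```sh
ublsurf info structure.pdb
ublsurf rmsd n_domain.pdb ubiquitin.pdb --range 8-81
ublsurf ensemble-rmsd ensemble.pdb --range 87-160
ublsurf sasa structure.pdb --per-residue sasa.tsv
ublsurf binding-score --complexes manifest.tsv --out scores.tsv
ublsurf tm melt.csv
ublsurf fat10-report --n-domain n.pdb --c-domain c.pdb --reference ub.pdb --out report/
```

`ublsurf sasa` on an isolated carbon atom reproduces the analytic sphere
area 4π(1.70 + 1.40)² = 120.76 Å² to better than 0.5 %.

## Deposited coordinates

Tests that reproduce published numbers for the deposited FAT10/ubiquitin
entries (backbone r.m.s.d. 0.764 / 0.964 Å vs ubiquitin, ensemble precision
0.27 Å, three-chain cross-superposition 0.66 Å, and the N-domain patch triad
E15/L51/K79) need the coordinate files, which are not redistributed with the
package. With network access, fetch them once into `data/deposited/`:

```sh
for id in 1ubq 6gf1 6gf2; do
  curl -o data/deposited/$id.pdb https://files.rcsb.org/download/${id^^}.pdb
done
```

Without these files the corresponding acceptance tests fail with an explicit
"deposited entry not available" message; everything else is download-free.

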
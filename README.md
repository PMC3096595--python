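# netfootprint

Phylogenetic network footprinting of transcription-factor (TF) interaction
networks: classify TFs by DNA-binding-domain content, transfer experimentally
observed TF–TF interactions across species through orthology, and compare the
resulting per-species networks to find what evolution kept and what it
changed.

## The problem and who this is for

Combinatorial TF–TF interactions are mapped experimentally in only a handful
of model organisms. For everything else — corals, sea urchins, most marine
invertebrates — the practical route to a first regulatory network is
comparative: if proteins A and B interact in an assayed species, their
orthologs A′ and B′ in another species are assumed to interact too (an
**interolog**, here called *interlog*). This package implements that pipeline
for systems biologists working on non-model organisms, end to end and with a
ground-truthed simulator so every stage is testable without external
databases.

## The method

1. **TF census.** A protein is a TF iff it carries ≥ 1 domain from a curated
   catalog of sequence-specific DNA-binding domains (DBDs), scanned from
   InterProScan-style Pfam annotations. For transcriptome contigs, ORFs are
   found in all six frames and one CDS per contig is selected (best database
   hit, else longest peptide). Predictions are scored against a known TF set
   by positive predictive value, PPV = 100·TP/(TP+FP).
2. **Interlog inference.** For a source interaction (A, B) in species *s* and
   every target species *i*, all orthologs A\_i1…A\_iP of A and B\_i1…B\_iQ
   of B are taken from Inparanoid-style ortholog groups (seed orthologs plus
   post-speciation inparalogs) and **all P×Q pairs** are inferred as
   interlogs; candidates whose endpoints are not both catalog-positive TFs
   are discarded. One-to-many ortholog relations therefore expand one source
   edge into several interlogs (*network expansion*); homodimer sources
   expand in either `full` (all paralog pairs) or `diagonal` (per-paralog
   homodimer) convention.
3. **Cross-species alignment.** Because each inferred edge carries the id of
   its source interaction, alignment is exact: an *interaction class* is one
   source edge plus its interlog sets in every species. Classes present in
   all species are **conserved interactions**; classes whose presence pattern
   is a proper subset are **Taxonomically Restricted Interactions (TRIs)**,
   with the cause per missing species diagnosed as ortholog loss or DBD loss.
4. **Repertoire structure.** Domain-composition profiles (fraction of TFs
   carrying each domain) are variance-stabilized with the arcsine–square-root
   transform asin(√p), compared across species with Fisher contingency tests
   (exact 2×2; Monte-Carlo Freeman–Halton for larger tables), and clustered
   into a UPGMA/NJ tree. Degree distributions are fitted with the discrete
   maximum-likelihood power-law estimator (Hurwitz-zeta likelihood,
   KS-minimizing xmin).
5. **Synthetic data.** A seeded generator produces five species on a known
   tree with duplication-driven ortholog expansions, DBD-bearing domain
   architectures, a scale-free source network, and planted interaction
   losses — with brute-force ground truth for every downstream stage.

## Worked example

`examples/interolog_transfer.py` transfers one human interaction to coral
(AM), where endpoint A has two coral co-orthologs:

```
heterodimer (A,B) with orth(A)={a1,a2}, orth(B)={b1}:
  AM interlog a1--b1  (from HS:A--B)
  AM interlog a2--b1  (from HS:A--B)
  -> one source edge, two interlogs: a lineage-specific expansion

homodimer (A,A), full mode: [('a1', 'a1'), ('a1', 'a2'), ('a2', 'a2')]
homodimer (A,A), diagonal mode: [('a1', 'a1'), ('a2', 'a2')]
```

`examples/simulate_and_run_pipeline.py` runs the whole pipeline on a
synthetic dataset with 10 % planted interaction losses:

```
TFs per species: {'HS': 43, 'MM': 41, 'SP': 43, 'DM': 38, 'AM': 43}
interaction totals: {'AM': 271, 'DM': 204, 'HS': 212, 'MM': 209, 'SP': 258}
classes=200 conserved=173 TRIs=27 expansions=288
planted TRI classes: 27; detected TRI classes: 27
```

All 200 source edges come back as interaction classes; the 27 detected TRIs
are exactly the planted ones. `examples/tf_census_validation.py` reproduces
the published census validation: with 1,443 known and 1,405 predicted TFs
sharing 1,226 ids, PPV = 87.26 % and 217 known TFs lack a catalog DBD.
Other examples cover ORF finding/CDS selection, the domain-composition tree
and the power-law fit.

A thin CLI mirrors the library (`netfootprint simulate|run|classify-tf|
validate-tf|interlogs|dom-tree|stats|find-orfs`); `netfootprint run
--config run.yaml` executes the full pipeline and writes per-species TF
lists, interaction tables, conserved-interaction tables, TRI/expansion
tables, a Newick tree and a manifest with input checksums and per-stage
counts.

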
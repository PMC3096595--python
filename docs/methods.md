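# Methods

This note documents the models, conventions and numerical choices behind
`netfootprint`, and what the synthetic-data tests do and do not demonstrate
about real data.

## TF classification and census validation

A protein is classified as a transcription factor iff its Pfam annotation set
intersects a curated catalog of sequence-specific DNA-binding domains (DBDs).
The catalog is an input (one accession per line); classification is strict by
default (annotations naming unknown proteins raise) with a lenient mode that
warns instead. Validation against a known TF set reports TP/FP/FN and
PPV = 100·TP/(TP+FP), rounded half-up to two decimals; an empty prediction
set leaves PPV undefined rather than zero.

ORF finding supports two conventions, because "default parameters" of ORF
tools are not reproducible across versions: `atg_to_stop` (default, minimum
30 aa) takes the first ATG after the previous stop to the next stop;
`stop_to_stop` takes the whole inter-stop stretch. Translation uses the
standard nuclear code; any codon containing N yields X; the stop codon is
excluded from coordinates, which are 1-based inclusive on the forward strand
(frame −f reads the reverse complement from offset f−1). CDS selection takes
the ORF with the best database hit (bitscore, then e-value, then peptide
length, then 5′-most start — the tie-break order is this package's
convention), else the longest peptide (then smallest start, then lowest
frame). One CDS per contig.

## Interlog inference

For source edge (A, B) in species *s* and target *i*: candidates are all
unordered pairs from orth\_i(A) × orth\_i(B), de-duplicated after
canonicalization. Design choices:

- **DBD filter (`both`, default).** A candidate is kept only when *both*
  endpoints are catalog-positive TFs in the target species. An `either` mode
  exists for sensitivity analysis. Rationale: the census excludes proteins
  without sequence-specific DBDs from the TF universe, so an interaction with
  a non-TF endpoint is outside the network being reconstructed.
- **Homodimer expansion (`full`, default).** A homodimeric source (A, A) with
  target orthologs {a1…ak} expands to all unordered pairs including the
  diagonal — the literal "all possible pairs" reading. `diagonal` mode keeps
  only per-paralog homodimers (the reading in which a duplicated homodimer
  yields two independent homodimers); both modes are tested.
- **Direct transfer only.** Interlogs are inferred from source species to
  each target; no chaining through intermediate species.
- Inparalog confidences are carried through but never thresholded.

Edges are unordered, canonicalized lexicographically; an edge that is both
experimentally sourced and inferred keeps provenance `source` with the
inferred origins appended. Per-species totals count the union.

The bundled ortholog caller is a simplified Inparanoid-style procedure for
testing: mutual best hits seed groups; a same-species protein joins as an
inparalog iff its score to the seed is at least the seed–seed score;
confidence uses Inparanoid's interpolation when self-scores are available,
else 1.0. Real analyses should ingest Inparanoid `sqltable` output directly.

## Conservation, TRIs, expansions

Conservation is defined at the class (source-edge) level: one surviving
interlog per species suffices, regardless of paralog count. The default
required set is all analyzed species (configurable). A TRI is a class whose
presence pattern is a proper non-empty subset of the analyzed species —
a class present only in its source species counts, with |pattern| = 1. Every
class is therefore exactly one of conserved / TRI when the required set is
the full species set. The cause per missing species is diagnosed from the
inputs: no ortholog of an endpoint → `ortholog_loss`; orthologs present but
none a TF → `dbd_loss`; otherwise `unknown`. Expansions are class/species
pairs with multiplicity ≥ 2 (threshold configurable). Conserved subnetworks
are connected components of the reference-species graph induced by conserved
classes, projected into every species, with orthology links drawn between
adjacent species of a display order.

## Domain-composition phylogeny

Profiles count domain **presence per TF** (a TF with k copies of a domain
contributes 1), matching a census of domain *types*; a copy-count mode exists
behind a flag and normalizes by total hits so proportions stay in [0, 1].
Proportions are transformed with asin(√p), which stabilizes binomial
variance near 1/(4n). Species are compared with a Fisher test over the
union of top-k domains (k = 10 default): exact two-sided for 2×2; for larger
tables the Freeman–Halton exact test is estimated by Monte Carlo (default
10⁵ tables with the observed margins, Patefield sampler, add-one corrected,
standard error reported) because exact enumeration is exponential in the
table size; a chi-square fallback is available. Trees are built from
Euclidean distances between transformed vectors: UPGMA (default; implemented
in-package so ties break deterministically by lexicographic cluster name,
heights are cluster-average distances/2, output is ultrametric) or
neighbor-joining (scikit-bio). Branch lengths are written with six
significant digits for reproducible diffs. Which linkage or distance the
original figure used is not stated anywhere; Euclidean-on-transformed with
UPGMA is this package's documented default, with NJ as the alternative.

## Degree structure

Degrees default to `partner_count` (number of distinct interaction partners;
a self-loop contributes 1 — the biological quantity is partner diversity),
with `graph_degree` (loop counts 2) available; the handshake law is tested
under the latter. Power-law fits use the discrete MLE:
P(k) = k^(−α)/ζ(α, xmin), α by bounded likelihood maximization
(α ∈ (1, 8]), xmin by KS minimization over candidate cutoffs with ≥ 10 tail
observations. A log–log OLS fit is provided for comparison and flagged as
biased. Degree-0 nodes are excluded from fits, included in summaries.
All-equal degree sequences are rejected as degenerate.

## Synthetic data: what it emulates and what it does not

The generator draws `n_families` ancestral families; per lineage a family
survives with probability 1 − `loss_rate` and has 1 + Poisson(`duplication_rate`)
members (pure post-speciation inparalogs — outparalogs are out of scope). A
family carries a DBD with probability `dbd_fraction`, drawn rank-weighted
from a 147-accession synthetic catalog so a few DBD types dominate, plus 0–2
auxiliary domains. The source network grows by preferential attachment over
the assayed species' TF proteins (growth-based; at attachment exponent 1
this is the Barabási–Albert regime, giving MLE exponents ≈ 2.6–3.0; once all
nodes have entered, remaining edges are internal and degree-weighted), with
a configurable homodimer fraction. Planted TRIs remove a lineage's family
members (`ortholog_loss`) or strip their DBD annotations (`dbd_loss`), only
in non-assayed lineages so the source species stays present in every class.
Ground truth (ortholog groups, per-edge interlog sets, presence patterns,
TRIs with causes, expansion multiplicities) is recomputed by an independent
brute-force application of the cross-product rule. One integer seed drives a
single generator stream; outputs are byte-identical across reruns.

Defaults mirror the study regime where magnitudes are known: five species on
the ((((HS,MM),SP),DM),AM) topology; `dbd_fraction` 0.1 (≈ the fraction of a
mammalian proteome that is a TF); two assayed species. Counts default to a
scaled-down problem (1,000 families, 500 source edges) chosen so a full
pipeline run completes in seconds; all rates are configurable.

Protein sequences are random placeholders — only the domain annotations
matter downstream of classification. Consequently, passing tests show that
the *pipeline logic* is exact (inference equals brute-force enumeration;
planted signals are recovered perfectly), not that real ortholog calls,
domain scans or interaction screens are error-free: real Inparanoid output,
InterProScan annotations and two-hybrid data carry noise the generator does
not model (mis-assigned orthologs, missed domains, false-positive
interactions), and real conservation/TRI calls inherit those errors.

## Tree-recovery test regime

For the domain-tree recovery test, transformed proportions evolve by
Brownian motion (per-unit-branch σ = 0.03, clipped to (0.05, π/2 − 0.05))
along an ultrametric version of the species tree with depth-doubling heights
(1, 2, 4, 8) and 150 domains, then re-quantized to counts out of 1,000 TFs.
The relative spread of squared Brownian distances is ≈ √(2/n_domains)
regardless of σ, so recovery reliability is set by the number of domains and
the contrast between successive tree levels; the chosen regime recovered the
generating topology in 100/100 seeded trials for both UPGMA and NJ.

## Problem sizes

Tests and the acceptance script use scaled-down problem sizes as the
package's own defaults: 200–500 families and 100–200 source edges per
synthetic run, 10 seeded replicates for TRI recovery, 10,000 observations
for exponent recovery, 200 randomized instances for oracle equivalence. The
published dataset-scale figures (TF counts per species, interlog totals)
depend on external proteomes, domain databases and interaction screens and
are deliberately not reproduced; the package validates the *procedures*
against ground truth instead.

## Known limitations

- No outparalog simulation; ortholog groups are family-exact in synthetic
  data, so one-to-many relations are always true inparalogs.
- The Monte-Carlo Fisher p-value has sampling error ≈ √(p(1−p)/n_draws);
  raise `n_draws` for small p.
- Nonlinear preferential attachment (exponent ≠ 1) does not produce a power
  law; the exponent knob exists for sensitivity checks only.
- The OLS power-law fit is included for comparison with historical practice
  and should not be used for inference.
- SIF output drops provenance; TSV is the round-trip format.
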
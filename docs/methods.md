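# Methods

`photorep` reconstructs the genomic repertoire of the two light-transducing
protein families of molluscs and other animals — opsins (retinal-binding
GPCRs) and the cryptochrome/photolyase (CRY-PL) superfamily — from genome
scaffolds, and characterises how those families evolve: which clades stay
near single copy ("static", retinochrome-like) and which expand repeatedly
by lineage-specific duplication ("dynamic", xenopsin-like).  This note
records the models, the defaults and why they are set where they are, and
what the synthetic data can and cannot show.

## Pipeline overview

1. **Screening** (`photorep.screening`) curates candidate proteins with
   three criteria: seven transmembrane (TM) segments, the
   chromophore-binding lysine at the position homologous to K296 of bovine
   rhodopsin, and a complete open reading frame; plus a family domain
   profile score (the stand-in for a Pfam domain screen).  Opsins and
   CRY-PLs are two `FamilyConfig` settings of one screen: the CRY-PL
   configuration requires its own domain profiles but no TM segments and
   no anchor lysine.
2. **Gene prediction** (`photorep.genescan`) finds gene models on
   scaffolds by homology: seeded Smith–Waterman of reference proteins
   against six-frame translations, exon chaining by dynamic programming,
   GT..AG splice refinement, and ORF completion.
3. **Classification** (`photorep.classify`) places each screened candidate
   into a named clade by joint phylogeny with a labeled reference panel
   (neighbor joining + site-resampling bootstrap, rooted on the outgroup).
4. **Reconciliation** (`photorep.reconcile`) maps each family's gene tree
   onto the species tree under duplication–loss parsimony and tabulates
   speciation (S), duplication (D) and loss (L) events per family and per
   species branch.
5. **Repertoire** (`photorep.repertoire`) aggregates placements into the
   species × clade copy-number matrix, joins ecological metadata, and
   flags complete losses (all-opsin zero; CRY-II-only; all-photopigment
   zero).
6. **Motifs** (`photorep.motifs`) reads out functional residues at
   bovine-rhodopsin-anchored sites (K296; E/DRY at 134–136; NPxxY at
   302–306; an extracellular-loop tripeptide, default 280–282; counterions
   113 and 181) and tabulates per-clade allele frequencies and ranked
   residue abundances.

A synthetic-data module (`photorep.simulate`) generates genomes with known
truth so every stage is testable end to end without downloads.

## Models and conventions

**Duplication–loss parsimony.**  Every gene-tree node *g* is mapped to
M(*g*), the last common ancestor in the species tree of the species under
*g*.  An internal node is a duplication iff it maps to the same species
node as one of its children; otherwise a speciation.  Losses are counted
per gene-tree edge as the number of species-tree edges skipped between the
parent's and the child's mapping, minus one below a speciation; no losses
are counted above M(root) ("no stem losses").  LCA mapping simultaneously
minimises duplications and losses over all valid embeddings; the package
carries an independent brute-force enumerator and verifies the equality
exhaustively over all rooted gene trees with ≤ 6 leaves against all
species-tree shapes with ≤ 4 leaves (≈ 21 000 cases).  Trees must be
binary; non-binary nodes are refused rather than silently resolved,
because resolution changes event counts.  Unrooted gene trees are rooted
at the branch minimising D+L (ties: fewest D, then the lexicographically
smallest leaf-set bipartition).

Family summaries report S, L, D, their non-loss total S+D, and the
fractions S/(S+D) and D/(S+D) rounded half-up to two decimals.

**Phylogenetic placement.**  Queries are merged into the panel's fixed
master-alignment columns by global affine-gap alignment (BLOSUM62, 11/1,
free end gaps) to the column-majority consensus; query-specific insertions
are discarded and columns with > 60 % gaps are removed before tree
building.  Distances are Poisson-corrected normalised mismatches
(d = −ln(1−p), pairwise gap deletion, capped at 5).  Neighbor joining is
implemented on numpy matrices so that 100 bootstrap replicates on a few
hundred sequences stay fast; joins tie-break on the lexicographically
smallest cluster-name pair for determinism.  The tree is rooted on the
smallest clade containing the outgroup (placopsin/melatonin-receptor-like
panel entries for opsins).

A query is assigned by walking rootward while the enclosing clade's
reference labels stay uniform.  Placement support is the fraction of
bootstrap replicates whose own walk lands on the same label (default
threshold 0.7): a query solidly inside a family clade keeps full support
even when its exact insertion point wobbles between near-identical
references, while a between-clade chimera splits its replicate walks and
stays unclassified.  Classical per-node bipartition supports are still
computed and written with the tree.  A query whose labeled neighborhood is
exclusively outgroup — or whose nearest labeled reference is an outgroup
member when the walk ends mixed — is flagged as a contaminant if it came
from a scaffold shorter than the contaminant threshold (default 5 kb),
mirroring the removal of bacterial-like sequences found on short
scaffolds.

**TM detection.**  Kyte–Doolittle hydropathy in a 19-residue sliding
window, threshold 1.6; each maximal run of at least 13 above-threshold
windows counts as one segment.  Thirteen is the run length that a
21-residue all-hydrophobic segment flanked by charged loops yields at
window 19 — the operational definition of a minimal TM segment here — and
is exposed in config along with the window and threshold.

**Domain profiles.**  A position-specific log2-odds matrix over the family
master alignment (pseudocount 1, background from the alignment's own
residue frequencies), scored as the best ungapped placement along the
query (partial overlaps down to half the shorter length).  Two
calibrations are provided: a null floor (mean + 5 sd of seeded random
sequences, optionally composition-matched) and a gathering-style cutoff
(half the lowest member self-score, never below the floor).  The pipeline
uses the gathering cutoff because the null floor only separates
*composition*: a reversed member — same residues, destroyed architecture —
still clears a composition null but falls far below the gathering cutoff.
Profile names are free text so real Pfam accessions can be recorded.

**Gene prediction.**  Seeds are exact 4-mers; a band needs two seeds
within 60 residues; banded windows get affine local alignments that are
split at gaps ≥ 10 residues and rescored per segment (minimum 60).
Segments chain per scaffold/strand/query when query spans and genomic
coordinates increase (query overlaps ≤ 20 residues are tolerated — local
alignments overrun exon boundaries into introns by a few chance-matching
residues), genomic gaps ≤ 20 kb.  Splice refinement considers GT..AG pairs
within ± 60 nt of the chained boundary, keeps each exon's codon phase, and
scores candidates codon-by-codon against each hit's own gap-free-block
query registration under a query-continuity constraint; this recovers
exact boundaries even under overruns, where a nearest-dinucleotide rule
does not.  ORF completion walks to the nearest in-frame ATG (both
directions) and stop codon (≤ 60 nt); a stop inside the final 12 codons
pulls the model back (an overrun artefact), while deeper stops are
reported as `internal_stops` (pseudogene evidence).  One model per locus:
genomically overlapping models keep the best chain score.  Internal
coordinates are 0-based half-open on the coding strand; GFF3 output is
1-based inclusive.

**Numbering.**  Residue numbering is 1-based anchored on bovine rhodopsin
(NP_001014890.1), which is packaged; its landmark residues (M1, E113,
ERY 134–136, E181, K296, NPVIY 302–306, C110/C187) are asserted by a test.
For panel-homologous sequences, motif residues are read through the master
alignment columns and the panel's column→anchor map (exact wherever the
columns are); for arbitrary single sequences a pairwise alignment to the
anchor is used instead, which can wobble by a column at weakly conserved
sites — expected behaviour for alignment-based numbering.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes:

- **Species tree**: pure-birth (Yule) topology rescaled to an ultrametric
  height of 1.0, 16 species by default; internal nodes are labeled in
  preorder and key all per-branch event tables.
- **Gene histories**: one copy enters the root; along every branch each
  copy duplicates at rate λ_d and dies at rate λ_l per unit branch length.
  Defaults: λ_d = 0.02 ("static") or 0.5 ("dynamic"), λ_l = 0.1 —
  calibration choices spanning retinochrome-like stasis to xenopsin-like
  recurrent expansion.  The simulator records raw per-branch event counts
  and the *observable* counts a reconciliation can recover: a duplication
  is observable when both daughter copies leave descendants; each maximal
  extinct subtree hanging off a surviving speciation lineage below the
  pruned tree's visible root contributes exactly one observable loss
  (stem losses above the visible root, and losses under a fully lost
  duplication copy, are invisible in principle).
- **Sequences**: family founder templates are derived from the anchor with
  randomised loops (hydrophilic alphabet) and TM cores (strict {I,L,V}),
  protected motif slots, and a synthetic TM layout (segments of 23–30
  residues, inter-segment loops ≥ 20) chosen so that window-19 hydropathy
  resolves exactly seven segments with margin even after substitution
  along deep gene trees (K296 and NPxxY burden TM7, which is therefore
  longer).  Evolution is substitution-only (no indels) and
  class-preserving: TM positions stay strongly hydrophobic, loops stay
  hydrophilic.  Within-family identity stays ≥ ~0.8; between families
  ≤ ~0.35.  Motif alleles are written into the slots by seeded
  largest-remainder quotas so realised counts match configured frequencies
  exactly — the property the motif calibration checks require.
- **Genomes**: proteins are back-translated with fixed codons, split into
  1–4 exons by phase-0 GT..AG introns (90–300 nt), and embedded on
  individual random-background scaffolds on either strand, with exact
  truth GFF3.  Decoys: fragments (interior truncations lacking start,
  stop, K296 and most TM segments), pseudogenes (an in-frame stop or the
  anchor lysine replaced), and contaminants (diverged outgroup-template
  genes on < 5 kb scaffolds).  A knockout list deletes every family from
  chosen species (the deep-sea total-loss analogue).
- **Panel and metadata**: a few lightly diverged references per family
  plus an outgroup lineage, with labels; per-species habitat/eye-type
  metadata, "deep sea / aphotic / eyeless" for knockouts.

**What passing tests do and do not show.**  The generator's sequences are
indel-free, its introns phase-0, its splice sites canonical, its families
well separated, and its scaffolds uncontaminated by repeats or
low-complexity DNA.  Perfect recovery on this substrate demonstrates that
the algorithms are correct and internally consistent, not that they would
achieve the same accuracy on real assemblies, where fragmentation,
frameshifts, indels, non-canonical splicing and annotation noise all
degrade every stage.  Dataset-scale survey totals from the original study
(e.g. 1,196 predicted opsins, 440 CRY-PL models, per-species counts)
depend on 80 real genome assemblies and are deliberately out of scope; the
exhaustive oracle, simulation-recovery, and end-to-end fixture checks
stand in for them.

## The packaged fixture

`photorep.simulate.fixture_config(seed)`: 16 species, the seven opsin
families (five static, two dynamic), 5 % fragment and 5 % pseudogene
conversion, four short-scaffold contaminants, and species P with every
family deleted.  `run_all` on this fixture is the end-to-end check: exact
gene-model recall/precision against the truth GFF3, ≥ 95 % correct
classification at support ≥ 0.7, a repertoire matrix equal to the true
copy numbers, and the knockout species flagged opsinless and
photopigmentless.  Problem sizes (16 species, ≈ 100 genes, 100 bootstrap
replicates, ≤ 6-leaf oracle enumeration) are chosen to keep the whole
suite runnable on a laptop in minutes while still exercising every code
path.

## Known limitations

- Parsimony reconciliation, not the probabilistic duplication–loss
  likelihood used by dedicated reconciliation software; no transfers, no
  dated reconciliation, no ILS awareness.
- Neighbor joining with bootstrap replaces maximum-likelihood inference;
  adequate for placement into well-separated clades, not for branch-length
  fidelity or deep-node resolution.
- The domain screen is a PSSM, not a profile HMM; no forward/Viterbi, no
  per-domain alignments.
- Gene prediction assumes phase-0-splittable, frameshift-free genes and
  GT..AG introns; there is no ab initio model and no isoform handling
  (one model per locus).
- Pairwise anchor-based motif numbering can be off by a column at weakly
  conserved positions; panel-column extraction avoids this for homologous
  sets.
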
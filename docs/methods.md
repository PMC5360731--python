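# Methods

## Scope and model of the analysis

`famscape` treats a gene family as four linked observables: (i) a conserved
sequence motif that defines membership, (ii) a phylogeny that partitions
members into named groups, (iii) an exon–intron architecture whose
positions and phases record ancient insertion events, and (iv) expression
and metabolite profiles that nominate functional candidates. Each stage is
a pure library operation over standard formats (FASTA, GFF3, aligned FASTA,
TSV, Newick); the pipeline module only wires them together and stamps
provenance. The multiple alignment is an *input* everywhere: the package
projects onto alignments and never builds them.

## Family identification

Membership is called by Smith–Waterman local alignment of a flat 44-residue
consensus against each protein, scored with BLOSUM62 and affine gaps (open
10, extend 1) — conventional protein local-alignment defaults. The decision
statistic is the best local score divided by the motif's self-alignment
score, capped into [0, 1]; the default call threshold of 0.40 is permissive
enough for a family whose members can diverge substantially in the motif,
and is exposed as a flag. There is no E-value model, profile or HMM: the
scan is deliberately a flat-consensus similarity search. Residues outside
the standard alphabet are scored as X (logged once per sequence). The
published length range of family proteins is reported as a result, never
applied as a filter.

## Distances, tree and groups

Distances are p-distances with pairwise gap deletion: columns gapped in
either row are excluded and the distance is mismatches over compared
columns. No Poisson or Kimura correction is applied by default — the
method names no model, and p-distance is the simplest defensible choice.
A pair with zero comparable columns is an error naming the pair, not a
silent NaN.

Neighbor joining follows the Saitou–Nei Q-criterion with the standard
branch-length formulas. Two determinism contracts are part of the
interface: among equal Q values the pair earliest in the current node
order is joined, and negative branch lengths are clamped to zero with the
deficit logged. Two taxa are handled by a separate trivial-edge path; the
general algorithm requires three.

Group labels come from anchors — characterized reference sequences with
known group letters. Every non-anchor leaf takes the label of its nearest
anchor by path length; equidistant cases (within 1e-9) take the
lexicographically smaller label and are flagged. Because visual clade
assignment is not reproducible, the formalization is audited rather than
trusted: for each label the implied {anchors + assigned leaves} set is
checked for monophyly against the tree's bipartitions and violations are
reported, not hidden.

## Intron phase, projection and events

Phase is computed from the cumulative coding length L upstream of each
intron, *never* from the GFF3 CDS phase column (that column encodes
bases-to-skip, a different convention): phase = L mod 3, with phase 0
between codons, 1 after the first base, 2 after the second. The projection
anchor residue is ⌊L/3⌋ + 1 for every phase — the split (host) codon for
phases 1/2 and the residue immediately following the insertion point for
phase 0. This single formula gives one well-defined alignment column per
intron and makes the generator's planted positions exactly recoverable.
Genes whose CDS length is not a multiple of three, or whose translation
contains an internal stop, are flagged partial and excluded from phase
analysis; introns inside UTRs are outside scope since phase is undefined
there.

Projected introns are clustered into insertion events by single-linkage
merging along the column axis with a default window of 0 (exact column
classes): with a correct alignment, homologous introns co-project, and the
window exists only for gappy alignments. Events are numbered I-1, I-2, …
by column; each carries a phase tally, a dominant phase, and flagged status
when it has fewer members than the reporting floor. Input order never
affects membership or numbering.

Reported percentages (intronless share, per-event carrier and phase
shares, tissue shares) all use half-away-from-zero integer rounding —
e.g. 68.75 → 69, 96.97 → 97, 42.86 → 43.

## Expression summaries

Row z-scores use the population (n) standard deviation, matching the
convention of heatmap tools that draw a −2..2 scale; constant rows map to
zeros and are flagged. Row ordering uses average-linkage agglomeration on
1 − Pearson; constant rows, for which the metric is undefined, are placed
last and flagged. Tissue-max calls are the argmax of replicate-mean
abundance over sample groups; ties break toward metadata order and are
flagged, all-zero genes are excluded as "no signal". UV induction is
operationalized as |log2((treated mean + 1)/(control mean + 1))| ≥ 1 on
replicate means — a reproducible stand-in chosen because no statistical
test is prescribed for this comparison; the threshold is a flag, and the
call table is antisymmetric under swapping treated/control labels.

## Correlation and ion masses

Gene–compound association is the Pearson correlation of stage-mean
expression with compound abundance over shared stages (≥ 3 required; stage
name mismatches are resolved only by an explicit mapping table, never by
heuristics). p-values come from the t-distribution with n − 2 df,
adjusted by Benjamini–Hochberg across *all* gene × compound pairs;
"significant positive" means r > 0 and q ≤ 0.05 by default. With six
stages this is a deliberately blunt instrument — only strong correlations
survive family-wide correction, which is the honest behavior.

The ion-mass calculator uses nominal integer masses by default: each
hexose adds 162 Da (glucose minus water), deprotonation subtracts 1, the
formate adduct adds a further 46. A monoisotopic mode (162.05282 /
1.00728 / 46.00548) exists for instrument-facing work.

## The synthetic generator

`simulate_family` builds the *alignment first*: a random root row with the
motif placed 30 residues from the C terminus, group rows mutated at the
per-branch substitution rate (motif columns at one quarter of it — the
motif is conserved, not frozen), then leaf rows at half the group rate.
Proteins are the ungapped rows; by default the generator is indel-free so
the true alignment equals the raw sequences and planted columns equal
residue indices exactly. An optional indel mode deletes three-column
blocks in alternating groups, away from the motif and planted columns, to
stress projection through gaps.

Planted intron events specify (alignment column, phase, carrier groups);
each carrier gets an intron at coding offset 3·(residue − 1) + phase,
where residue is the column's ungapped index in that row. A configurable
fraction of genes is forced intronless. Coding sequences are
back-translated with codons drawn uniformly among synonyms (determinism
without codon-bias modeling), introns get GT…AG ends with lengths uniform
on [80, 2000] nt — a placeholder range, configurable, since real intron
length distributions are not modeled — and genes are laid round-robin
across eight chromosomes on random strands with fixed 500-nt spacers. An
optional clustering mode lays groups contiguously to emulate tandem
arrays. Decoy proteins are uniform random sequences of 150–616 residues;
at the default threshold their best motif scores sit far below 0.40
(observed ≲ 0.2), so planted-recovery tests are clean.

`simulate_expression` plants an argmax sample group per gene: the planted
group's mean is `effect_size` × baseline before noise, and lognormal
multiplicative noise (default log-sd 0.2, effect 8 — strong but not
degenerate) is applied per sample from a per-gene named substream, so a
gene's row is invariant to which other genes are simulated.
`simulate_metabolites` takes the stage-mean expression table and builds
each linked compound as r·z(gene) + √(1−r²)·ε⊥, where ε⊥ is an
orthogonalized standardized residual — so the *sample* correlation equals
the target exactly (an affine shift keeps abundances positive without
touching r). When several genes link to one compound, the first listed
gene defines the profile; the others correlate only as strongly as they
correlate with that gene, which is why linked genes should share a planted
stage pattern. Unlinked compounds are independent lognormal profiles.

All generator randomness flows from one seed through CRC32-named
substreams; a fixed seed fixes every emitted byte, which the suite checks
at file level.

What the generator does *not* emulate: alignment error (the true MSA is
emitted), sequencing noise or count overdispersion (expression is
TPM-like lognormal, not negative binomial — the pipeline consumes
normalized matrices), pseudogenes, alternative splicing beyond
longest-transcript selection, and UTRs. Passing recovery tests therefore
demonstrates correctness of the bookkeeping and statistics under clean
planted truth, not robustness to annotation or alignment error in real
genomes.

## Problem sizes and numerical choices

The test suite runs the family generator at 24–96 genes, trees up to 12
taxa against exact additive oracles (50 random trees), the exhaustive
local-alignment oracle at ≤ 6-residue pairs (path enumeration is
exponential), the null-calibration check at 10,000 independent pairs, and
the permutation/t p-value comparison at 10 stages with 10,000 draws and a
0.025 agreement band (at very small n the t approximation and the exact
permutation distribution differ systematically; by n = 10 they agree well
inside that band). Monte-Carlo recovery of the eight linked candidates
uses 40 seed pairs with a ≥ 95% pass requirement. Distance ties in NJ and
clustering are broken by fixed index/label order so outputs are identical
across platforms.

## Known limitations

- Nearest-anchor assignment can differ from visual clade reading on trees
  with long-branch attraction; the monophyly audit surfaces, but does not
  resolve, such cases.
- The event detector's window is a column tolerance, not an alignment
  realignment; badly gapped alignments need a nonzero window and lose the
  exact-column guarantee.
- The UV "induced" call is a fold-change rule, not a test; counts derived
  from it are descriptive.
- BH correction across all pairs makes candidate selection conservative
  when many compounds are profiled at few stages.
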
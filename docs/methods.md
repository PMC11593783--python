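# Methods

This note records the models, conventions and numerical choices behind
`mitobias`, and what the synthetic-data calibrations do and do not show
about real data.

## Genome model and coordinates

A mitogenome is a circular sequence over {A,C,G,T,N} with typed features
(CDS, tRNA, rRNA, control_region, pseudo_control_region). Internal
coordinates are 0-based half-open; GenBank I/O converts from/to 1-based
inclusive, and two-part `join()` locations that meet the sequence origin
become single wrapping features. Gene names are canonicalized through an
editable synonym table (`data/gene_synonyms.tsv`); unknown names pass
through untouched with a log note, because public mitogenome annotations
are inconsistent.

CDS extraction reverse-complements minus-strand features, accepts any
start codon (ATN and GTG both occur in real mitogenomes), trims an
incomplete terminal codon (T or TA — completed in vivo by
polyadenylation) and rejects sequences with internal stops under the
vertebrate mitochondrial code (table 2). Codons containing N are excluded
from every codon-level statistic: the conservative choice when ambiguity
codes appear.

Intergenic spans are located strictly between two single-copy anchor
genes in circular order (CR1: tRNA-Thr → tRNA-Pro; CR2: tRNA-Glu →
tRNA-Phe). Mitochondrial genes overlap routinely (e.g. ATP8/ATP6), so a
circularly inconsistent or negative-length span is reported as length 0
rather than as an error.

## Codon-usage statistics

Table 2 has 60 sense codons. The six-fold amino acids of the standard
code do not exist here as exchange-complete families: the third position
alone cannot interconvert Leu(TTR)↔Leu(CTN) or Ser(TCN)↔Ser(AGY), so both
are split, leaving 14 two-fold and 8 four-fold families. This fixes
Wright's ENc to the range [22, 60]: per family
F̂ = (nΣp̂² − 1)/(n − 1) with n the family codon count; families with
fewer than 2 observations (or non-positive F̂) are imputed with their
degeneracy-class mean; ENc = 14/F̄₂ + 8/F̄₄, capped at 60. Tables under a
configurable minimum (default 100 codons) are flagged low-confidence
rather than suppressed, since ATP8-sized genes sit near that limit.

GC3 is the GC fraction at all third positions of sense codons; GC3s
restricts to synonymous families of size ≥ 2, which under table 2 is
every sense codon — both are computed and reported because the two names
refer to different quantities under other codes. The ENc null curve uses
GC3s; the neutrality regression (OLS of GC12 on GC3, one point per
species over concatenated PCGs by default) uses GC3.

P2 = (WWC + SST)/(WWY + SSY) with W/S classifying codon positions 1–2 and
Y the third position, the positional convention of the index's source;
the printed formula leaves the positions implicit, so this convention is
a documented choice. P2 is scale-invariant in the counts and reported
missing when the denominator is empty.

## Selection statistics

K2P and TN93 distances use pairwise deletion of gap/N columns; TN93
estimates base frequencies from the averaged composition of the pair and
reduces to K2P (to ~1e-7 in practice) when composition is balanced.
Saturated pairs (log argument ≤ 0) yield missing values; the distance
matrix builder falls back to the p-distance with a logged warning rather
than dropping the taxon. Nucleotide diversity is the mean pairwise
per-site difference (Nei–Li, pairwise deletion).

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site fractions from
the nine single-base neighbors, with stop-codon neighbors counted as
nonsynonymous so that S + N = 3L exactly; multi-hit codon pairs averaged
over all shortest substitution pathways, excluding pathways that pass
through a stop (all pathways are used only if every one does);
Jukes–Cantor correction applied separately to pS and pN, missing at the
3/4 ceiling. The per-gene summary aggregates unordered species pairs by
arithmetic means and reports mean(Ka)/mean(Ks) (a per-pair-ratio mean is
available behind `ratio_mode`). Cross-species CDSs are codon-aligned by
translating, aligning the proteins globally (BLOSUM62, gap open −10,
extend −0.5) and threading codons back.

**Estimator bias, quantified.** The simulator rejects mutations into stop
codons, while NG86 counts stop-adjacent changes as nonsynonymous sites.
At neutrality (ω = 1) the estimate therefore converges not to 1 but to
the stop-channel factor ≈ 0.91 under this generator's codon composition
(computable in closed form from the mutational channel counts), with a
further ~1–2% depression from multiple hits at divergence 0.2
substitutions/site. The calibration tests assert this predicted factor
rather than pretending the estimator is exactly unbiased; the neutrality
calibration band [0.9, 1.1] is met. With transition bias (kappa > 1)
NG86's unweighted site counting depresses the ratio further — rankings
across genes are unaffected, which is why the end-to-end test checks rank
recovery, not absolute ω, at kappa = 2.

Neighbor joining is the Saitou–Nei algorithm with the standard Q
criterion; ties break deterministically toward the lexicographically
smallest leaf-label pair, and a negative branch length is clamped to zero
with the deficit moved to its sister. On additive matrices the
reconstruction is exact (tested on 4- and 5-taxon suites and
cross-checked against scikit-bio's NJ topology).

## Control-region analysis

Box scanning is an IUPAC-aware sliding-window Hamming match on both
strands; each box allows at most ⌊len × max_mismatch_fraction⌋
mismatches (default 0.2), overlapping hits of the same box resolve to the
best-scoring non-overlapping set, and surviving hits are numbered
copy_index 1..k — duplicated CSBb/Bird-box arrangements surface naturally
this way. Domains: ETAS requires the ETAS box, Central requires D-box
plus (C-box or CSBb), CSB requires CSB1; all requirement sets are
configurable. The shipped consensus library is synthetic (the real
vertebrate consensuses are not distributed with this package), which is
why every test plants its boxes explicitly.

The tandem-repeat detector is a bespoke period scan, not a
reimplementation of a full repeat-finder scoring model: for each period p
the sequence is compared to itself shifted by p, maximal runs with match
fraction ≥ min_purity (default 0.85) become candidates, each is re-scored
against its column-majority consensus motif, and candidates explained by
a smaller accepted period are suppressed. Defaults: period 2–200, ≥ 2.0
copies. On i.i.d. random kilobase sequences the detector makes no
(period ≥ 5, copies ≥ 3, purity ≥ 0.95) calls — the false-positive control
in the suite. Repeat motifs are classed AT-rich (AT ≥ 0.9) or T-rich
(T ≥ 0.8) as lineage markers.

CR1–CR2 identity is global alignment (match +1, mismatch −1, gap open −5,
extend −1) with gap columns in the denominator — the convention of common
alignment viewers; parameters are exposed because published identity
percentages depend on them. GO classification: GO-II requires all three
CR2 domains and identity ≥ 60% (published concerted pairs sit at ~78–89%
and degenerate ones at ≤ ~39%, so any threshold in the gap separates
them; 60 is mid-gap); GO-IV is a present-but-failing CR2; "other" means
no CR2 span. Note that heavy substitution alone (30% of sites) leaves
~2/3 alignment identity — degenerate calls in that regime rest on domain
loss, which is the biologically meaningful signal.

## Synthetic-data generator

The generator is deliberately stylized: amino acids drawn uniformly over
the 22 (split) families, synonymous codons from per-family
Dirichlet-categorical distributions with concentration α (α → ∞ even
usage, ENc → 60; α → 0 single-codon families, ENc → 22); divergence by
single-base proposals (transition probability kappa/(kappa+2)), stop
proposals rejected, nonsynonymous proposals accepted with probability
min(1, ω), event count Poisson(t·L); independent evolution along newick
trees with true per-branch event counts returned. Whole genomes follow
the typical avian layout (tRNA-Phe first, ND6 and eight tRNAs on the
light strand, CR1 and CR2 between their anchor tRNAs); tRNA/rRNA blocks
are random placeholders since no consumer relies on their internal
structure. Control regions plant library boxes left-to-right with random
spacers; CR2 degeneration applies substitutions, short indels, excision
of named boxes and a 3' tandem-repeat expansion. In multi-species
GO-IV datasets the degraded CR2s share a common degenerate ancestor with
small per-species noise, so orthologous copies cluster while paralogous
copies separate — the concerted-vs-independent-evolution contrast the NJ
tree of CR copies is meant to expose.

What passing these tests shows: the estimators recover their own model's
truth at realistic sizes, the classifiers separate the regimes they
define, and the pipeline is deterministic. What it does not show:
performance under real mitogenome features absent from the generator —
among-site rate heterogeneity, strand-asymmetric mutation, realistic
tRNA/rRNA structure, genuine vertebrate box consensuses, heterogeneous
base composition — so quantitative agreement with any particular
published dataset still depends on curating inputs (a real box library,
real alignments) rather than on these defaults.

## Problem sizes and defaults

Calibrations run at 5,000–10,000 codons and 6–20 replicate seeds;
multi-species studies at 4–6 species with 55–606-codon genes and branch
lengths of 0.05–0.06 substitutions/site — sizes chosen so each statistic's
Monte-Carlo error is small against the tolerances tested while a full
suite run stays interactive. Default kappa is 2 (a typical mitochondrial
transition bias for short divergences); default ω targets are well inside
the purifying regime seen in mitochondrial PCGs (0.02–0.33). All
randomness flows from explicit integer seeds; fixed seeds give
byte-identical outputs, including the full pipeline bundle.
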
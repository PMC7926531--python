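# Methods

This note documents the statistical procedures, the defaults, the numerical
choices, and the limits of what the synthetic-data experiments demonstrate.

## Diversity statistics and Hardy–Weinberg testing

All per-locus statistics are computed from integer genotype counts, never
from pre-rounded frequencies: published frequency tables carry rounding
error (frequency triples that sum to 1.001 and the like), and counts are
the sufficient statistic. For a diallelic locus with counts
$(n_{AA}, n_{AB}, n_{BB})$, the reference-allele frequency is
$p = (2n_{AA} + n_{AB}) / 2n$. $H_e$, $N_e$ and PIC follow the standard
formulas (PIC is implemented in its general $k$-allele form; the diallelic
closed form $H_e - 2p^2q^2$ agrees to 1e-12 and is asserted as a property).
Identities maintained and tested: $N_e (1 - H_e) = 1$ exactly,
$0 \le PIC \le H_e \le 1 - 1/k$.

The HWE test is the uncorrected Pearson chi-square over the three genotype
classes with expected counts $(p^2 n, 2pq\,n, q^2 n)$ and df = 1 (three
classes, one estimated allele frequency). No Yates correction: the
uncorrected statistic reproduces the reference results from reconstructed
counts, the corrected one does not, and with one df and typed cohorts of
~150 animals the correction is overly conservative anyway. Monomorphic loci
get defined statistics ($H_e=0$, $N_e=1$, $PIC=0$) but the test is refused
(`DegenerateStatisticError`): there is no free genotype class to test.
Under exact HWE ($p=0.5$, $n=150$) the empirical rejection rate of the 5%
test over 1000 simulated cohorts stays inside the exact binomial 99%
interval — a calibration check, not a power claim.

Report rounding is half-away-from-zero (the convention of the published
tables), default 3 decimals. One known edge: at counts (110, 40, 4) the
PIC is 0.2285 from counts but 0.229 when computed from the rounded allele
frequencies 0.844/0.156; the package reports the count-based value and does
not treat the frequency-path value as canonical.

Linked-locus screening declares two loci concordant when their alt-allele
dosage vectors agree on all jointly typed samples, directly or after
swapping allele roles. This is deliberate *exact-identity* screening, not
an $r^2$ estimate: the phenomenon it captures is complete co-segregation of
mutation sites in a small panel, and a single discordant sample breaks the
pair.

## The litter-size model

The response is each parity record's litter size; each record is an
independent observation (the model is all-fixed: a two-level parity factor
absorbs the systematic parity difference, and no animal random effect is
fitted, matching the analysis design the package reimplements). Factors
enter in the fixed order parity, G1, G2, G1×G2 with treatment coding
(first observed level = reference).

**Sequential sums of squares.** Data of this kind are unbalanced, so Type I
(order-of-entry) SS are used and the order matters. They are computed from
the QR factorization of the ordered design: squared orthogonalized
projections per term, which makes term SS + residual SS = total SS an exact
identity (tested to 1e-8 relative, and against statsmodels' `anova_lm`
type-I output on unbalanced simulated cohorts).

**Rank handling.** Genotype cross-classifications are sparse (a rare
homozygote class may occur in a single combination). Empty interaction
cells produce all-zero columns, which are dropped and logged. Beyond that,
a kept column can still be aliased by earlier ones (e.g. a rare class
observed only inside one cell); such columns are dropped in entry order
with a warning — the pivoting behavior of standard linear-model fitters —
which leaves earlier terms' sequential SS untouched. A factor whose columns
are *all* aliased (complete confounding, as with duplicated loci) raises an
error instead: silently dropping an entire requested factor would change
the model's meaning.

**Least-squares means.** A level's LS mean is the model prediction averaged
with equal weight over the observed levels of the other factors. Cells
whose genotype combination never occurs are excluded from the average and
the level is flagged non-estimable rather than silently reported: with
dropped interaction columns the prediction for such a cell would be a pure
model extrapolation. On balanced data LS means equal raw means (tested).
Raw per-genotype mean ± SD (sample SD, ddof 1; a single-record class
reports 0.0) accompany the model output, because the two are routinely
confused in published tables and reporting both disambiguates.

**Duncan's multiple range test** runs on the LS means. For a span of $p$
ordered means the critical range is
$R_p = q(\alpha_p;\, p,\, \nu)\sqrt{MSE/n_h}$ with protection level
$\alpha_p = 1 - (1-\alpha)^{p-1}$, $\nu$ the residual df and $n_h$ the
harmonic mean of level replication (the standard unbalanced extension; the
procedure is undefined in the unbalanced case and any choice here is a
convention). Studentized-range quantiles come from numeric inversion of the
distribution function (scipy), accurate well beyond 1e-6 and memoized
because an analysis touches only a handful of $(p, \nu)$ pairs. Letter
assignment marks maximal non-significant spans; a sub-span inside a
non-significant span is never declared significant (the contiguity rule),
so letter sharing is transitive within each marked span. At span 2 the
range reduces to the unprotected studentized-range (pairwise) test, and
ranges are non-decreasing in span — both asserted. The whole construction
is validated against a classic five-treatment worked example (MSE 8.06 on
20 df, published range values 2.95/3.10/3.18/3.25).

## Annotation

The gene model is CDS-only: ordered exon intervals in transcript order
whose concatenated length equals the CDS length (multiple of 3, optional
start-codon check). The reverse strand is first-class: residue numbers that
*increase* while genomic coordinates *decrease* force minus-strand mapping,
so CDS position counts from the genomically-highest base of the first exon
and called bases are complemented before codon substitution. The mapping
and its inverse are mutually inverse on every exonic position (property
test over random models, both strands).

SNP calling is a column-wise comparison of pre-aligned, indel-free
sequences; alignment itself is out of scope (SNP-only Sanger consensus
data need none). Heterozygotes are the two-fold IUPAC codes; a code whose
decoding does not include the reference base cannot be expressed as a
diallelic call and is an error rather than a guess. Effects are classified
by translating the affected codon before and after substitution (standard
nuclear code); the generator's manifest instead translates the *entire*
mutant CDS and diffs proteins, so the closure test crosses two independent
paths.

Assembly lift-over is a verified constant offset: inferred from the first
coordinate pair and required to hold exactly on all others. This is
deliberately not a chain-file implementation — within a small gene-scale
region a single translation is the correct model, and the code refuses to
extrapolate when constancy fails.

## Phylogenetics

K2P distances use pairwise deletion of N/gap sites, maximizing usable
sites on short CDS alignments. Saturation ($1-2P-Q \le 0$ or
$1-2Q \le 0$) is an error, not a clamped value. Gamma rate heterogeneity
is *not* applied to the distances (plain K2P): a deliberate simplification,
as the distance+NJ path is fully self-contained while ML tree search is
out of scope. Neighbor-joining follows Saitou–Nei with the Q-criterion;
negative branch lengths are clamped to zero with the deficit moved to the
sister edge, and ties break by lexicographic taxon-pair order so output is
bit-for-bit reproducible. NJ is exact on additive matrices; the test
generates random 5–12-taxon trees, derives their path-length matrices with
an independent graph-traversal oracle, and requires the NJ tree to induce
the same matrix to 1e-9. Trees are dendropy objects; newick output prints
branch lengths at 6 significant digits. No bootstrap support is computed.

## Synthetic data

The generator's defaults emulate the study conditions: 154 ewes; nine
diallelic loci at reference-allele frequencies 0.994, 0.994, 0.955, 0.286,
0.955, 0.286, 0.844, 0.844, 0.682 (spanning minor-allele frequencies
0.007–0.71); two parity records per ewe; integer litter sizes concentrated
on 1–3. Genotypes come from the F-adjusted trinomial
$(p^2+Fpq,\; 2pq(1-F),\; q^2+Fpq)$ — $F=0$ is exact HWE, $F>0$ a
heterozygote deficit, $F=1$ none at all. Litter sizes are Gaussian around
$\mu + P + G_1 + G_2 + G_1G_2$ and, in integer mode, rounded half away
from zero and clamped to 1–4 lambs. The Gaussian-then-round choice matches
the fitted model's assumptions rather than an ordinal data-generating
story; continuous mode exists so recovery tests are exact. Default
effects for planted-pattern runs are a heterozygote advantage at G1
(+0.4 litter units for AG, −0.5 for the rare GG) and a wild-type deficit
at G2 (+0.9 for either mutant genotype), sized to the qualitative pattern
the association stage should detect at this cohort size. Seeds are
mandatory everywhere.

Calibration runs (type-I error of the G1 F-test) use continuous mode with
baseline $\mu = 2.5$, so the ≥1-lamb floor binds for ~0.6% of records and
the F-test's null distribution is essentially exact; 1000 cohorts of
154 × 2 records keep the rejection rate inside the exact binomial 99%
interval around 0.05. Pattern-recovery runs (200 cohorts) require the G1
heterozygote to carry the highest LS mean and Duncan letters to separate
the G2 wild type in ≥95% of replicates.

What passing these simulations does **not** show: the generator draws loci
independently (no linkage disequilibrium except the explicit clone option),
has no pedigree or permanent-environment structure, no missingness process,
and Gaussian errors; real litter-size data are ordinal, correlated within
ewe, and unbalanced in ways the parity factor only partly captures. The
tests demonstrate the *procedures* are implemented correctly under their
own assumptions, not that those assumptions hold in the field.

## Numerical conventions

- Report rounding: half away from zero; default 3 decimals.
- Genotypes: unordered, alphabetically sorted two-character strings;
  missing = `NN` on disk, `None` in memory; excluded locus-wise.
- Coordinates: 1-based inclusive throughout.
- Duncan quantiles: inversion tolerance far below 1e-6; memoized.
- NJ tie-break: lexicographic smallest-leaf pair; floating-point Q values
  compared with a 1e-12 tolerance before the tie-break applies.
- CLI exit codes: 0 ok, 2 validation, 3 degenerate statistic. All CSV
  outputs carry a `# ovistat <version> seed=<seed> config=<hash>` header
  (output paths excluded from the hash so identical analyses hash
  identically wherever they are written).

## Known limitations

- The HWE test is asymptotic; with expected class counts near zero (MAF
  ~0.007 at n=154) its p-values are approximate. An exact test is
  deliberately out of scope.
- Duncan's test controls no modern error rate; it is provided because it
  is the field's reporting convention for this analysis, not as a
  recommendation.
- LS means for levels with empty interaction cells average observed cells
  only and are flagged; they are not the broadcast population means.
- Lift-over handles translation-only assembly differences.
- The phylogeny stage computes distances and NJ topology only: no ML, no
  rate heterogeneity, no bootstrap.
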
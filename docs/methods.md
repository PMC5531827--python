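# Methods

## Representation

Everything is computed at SNP-marker resolution; no nucleotide sequence is
represented.  A chromatid is a pair of strand-origin vectors over the
markers of one chromosome (origins: `R` = W303-1A-derived, `B` =
YJM789-derived) plus a centromere origin.  Heteroduplex DNA is, by
construction, the set of markers where the two strands disagree; it is
always recomputed from the strands, never stored.  Coordinates are 1-based
bp internally; BED exports are 0-based half-open.  Heterology blocks
(e.g. an inverted-Ty hotspot insertion) are modeled purely as marker-free
intervals, since such events are detected only through flanking markers.

The default simulated chromosome mirrors the selection chromosome of the
assay: 577 kb, centromere at 152 kb, the *SUP4-o* ochre-suppressor
insertion on the B homolog near 30 kb, 2,750 markers of which a 13/55
fraction (~650, ~0.9 kb mean spacing) is assayed — the genome-wide study
design (55,000 SNPs, 13,000 on the arrays, ~1 kb spacing) scaled to one
chromosome.  Marker positions are uniform draws; the real SNP spacing
distribution is not published.  Tests also construct the full 55,000 /
12 Mb / 13,000 map to check the genome-scale constructor.

## Forward model

One selected event per colony (independent unselected events on other
chromosomes are out of scope).  A break occurs in G1 with probability
`p_g1 = 0.5`; a G1 break is replicated into two sister chromatids broken
at the same position (DSCB), a S/G2 break affects one chromatid (SCB).
Both homologs are equally likely recipients.  Break positions are uniform
over the chromosome, redrawn in the zero-measure case where they coincide
with a marker coordinate (the assay cannot resolve a lesion at the SNP
itself, and such a draw would leave an unphysical one-marker parental
island at the cut).

Each broken sister draws its repair mechanism independently (DSCB repairs
are treated as two events).  Mechanism products, per the repair-pathway
models:

* **one-ended SDSA** — heteroduplex on one strand, extending
  unidirectionally from the break; NCO.
* **two-ended SDSA / dHJ dissolution** — one chromatid with bidirectional
  heteroduplex and a strand switch at the break.
* **dHJ resolution, CO** — reciprocal exchange of the telomere-ward arms;
  heteroduplex tracts flank the break on the two products, pointing in
  opposite directions (the nick-directed pattern, which is the
  configuration the data supported).
* **dHJ resolution, NCO** — conversion tract on the recipient adjacent to
  the break with a heteroduplex over the same interval on the donor (the
  invading strand left behind), plus a second-end heteroduplex on the
  recipient's other side.  The second-end tract is short by default
  (median 500 bp), so it usually contains no assayed marker and the
  event presents as the conversion+donor-heteroduplex pattern (Class 8).
  The pathway figures admit two idealizations of this product; the one
  realized here is the one whose visible pattern matches the published
  class definitions.
* **BIR** — both strands donor from the break to the telomere,
  no heteroduplex, no reciprocal product.
* **gap repair** — both strands donor over the gap (3:1 segregation; 4:0
  when both sisters convert the same interval), optionally flanked by a
  heteroduplex on the same side (hybrid tract) or the opposite side of
  the break.

Optional complex-event channels: **branch migration** (probability 0.10)
extends a junction-bearing intermediate with *symmetric* heteroduplex —
one strand flipped against the local duplex on both interacting
chromatids over the same interval; **template switching** (probability
0.05) interrupts an SDSA heteroduplex with a restored block.  Both
produce patterns outside the eight simple classes, emulating the study's
substantial complex fraction without reproducing its (unpublished)
sub-mechanism breakdown.

**Tract lengths.**  Heteroduplex/gap side lengths are gamma(shape 2) with
median 5.4 kb — the published median for NCO conversion/heteroduplex
tracts.  The shape is a modeling choice: resection is two-step (short
MRX/Sae2 processing followed by processive long-range resection), which
makes near-zero tracts rare; a shape-1 (exponential) distribution would
overweight sub-kilobase tracts relative to the ~80% per-chromatid
detection the study reports.  The dHJ-NCO second-end heteroduplex uses
median 500 bp (see above).  All medians are configurable.

**Mismatch repair.**  The *mlh1* default is `NONE` (identity).
`CONVERSION`, `RESTORATION` and `PATCHY` (alternating patches, geometric
lengths, median 300 bp) model the MMR-proficient outcomes; restoration
makes the chromatid identical to an unbroken parental chromatid and is
asserted invisible to the reconstruction.

**Segregation and selection.**  Each daughter receives one chromatid per
centromere origin.  When a crossover allows the 2:0 *SUP4-o* segregation
the sectored pairing is chosen (white daughter = two copies, red = none);
`simulate_cohort(selection=True)` emits only sectored colonies, mirroring
the red/white assay.  Replication is semiconservative at marker
resolution: each chromosome's Watson strand seeds one granddaughter
homolog and its Crick strand the other, so the eight granddaughter
homologs are exactly the eight mother strands (a tested invariant).
Mechanism weights default to 0.30 one-ended SDSA, 0.25 gap repair, 0.20
dHJ-CO, 0.08 two-ended SDSA, 0.07 dissolution, 0.05 dHJ-NCO, 0.05 BIR —
chosen to echo the observed preponderance of unidirectional-heteroduplex
and conversion-tract events while keeping every pathway exercised;
sister-chromatid repair, being invisible to the assay, defaults to a
discarded fraction of zero.

## Readout and inference

Hybridization ratios per assayed marker: heterozygous ≈ 1.0 on both
allele channels, duplicated allele ≈ 1.7, absent allele ≈ 0.3 (the
running-text alternative of 1.5 for the duplication is available as a
preset).  Noise is multiplicative log-normal, sigma 0.1 by default — no
noise model is published; this value keeps single-marker miscalls rare,
consistent with the study resolving single-SNP segments.  Calling
thresholds are the midpoints between the stated means (hom ≥ 1.35 with
the other channel ≤ 0.65; het = both in [0.65, 1.35]; anything else
UNCALLED).  Segmentation takes maximal runs of identical calls over the
called markers and reports transition intervals as (last bp of run i,
first bp of run i+1); no smoothing by default.

Phasing uses one spore-derived haplotype per granddaughter: homolog 1 is
the spore, homolog 2 the complement in heterozygous segments and the
called allele in homozygous segments; a spore allele inside a homozygous
segment of the opposite allele raises a conflict error.  In the pipeline
the spore is one true homolog restricted to the assayed panel — the
laboratory spore arrays are separate hybridizations whose noise is not
modeled; they serve only to fix coupling.

Reconstruction pairs the two granddaughter homologs of a sector by
centromere origin into daughter chromosomes (= mother chromatids), then
assigns daughters to sister pairs by centromere origin, with the strand
numbering white-R (1,2), red-R (3,4), white-B (5,6), red-B (7,8).  The
centromere origin of a homolog is read at the nearest marker where the
two homologs of that granddaughter *disagree*: agreement regions carry no
coupling information, and tract regions (a foreign or converted strand
matching the other homolog) are precisely the agreeing ones, so the
readout self-corrects around tracts.  A sector whose homologs cannot be
paired one-R-one-B raises a reconstruction error (the aneuploidy/BIR
review flag); when both pairings are consistent the one minimizing strand
disagreement (then heteroduplex run count) is taken.  A sector with a
single genotype is entered as the same granddaughter twice and yields
homoduplex chromatids.

**Measurability limit.**  When a repair tract covers the assayed markers
flanking the centromere (break within a tract length of the centromere),
the coupling readout that pairing relies on is undefined and no method
can recover the strand assignment.  `centromere_coupling_readable`
detects this from ground truth; round-trip identity checks skip and count
such colonies (~0.5% of uniform-position events; a few percent of
*selected* events, because the selected interval ends at the
centromere).  Initiation-accuracy figures include all colonies.

## Classification

Per chromatid, against its centromere origin: parental, heteroduplex
(strands disagree) or converted (both strands opposite origin) markers,
collected into maximal runs over the called markers.  Converted runs
reaching a chromosome end are coupling switches: two of them at the same
end on chromatids from different sister pairs form a crossover; an
unpartnered one is BIR.  Remaining tract-bearing chromatids anchor NCO
events; a conversion-bearing chromatid absorbs an overlapping
heteroduplex-only chromatid from the other homolog (the Class 8
pattern).  Initiation is the event count: 0 → NONE, 1 → SCB, ≥2 → DSCB
(two repairs on different homologs are reported DSCB with a note, as in
the source data).  Conversion runs overlapping a sister conversion are
annotated 4:0, otherwise 3:1.

Crossover geometry is resolved by candidate exchange brackets: on the
recipient-centromere product the exchange lies between its heteroduplex
and the exchanged arm, on the donor-centromere product between the
parental region and its heteroduplex; the assignment whose brackets
overlap fixes the recipient and a tight DSB interval.  Class templates
are matched strictly (COMPLEX otherwise): 1 = single unidirectional
heteroduplex without strand switch; 2 = single conversion run; 3 = hybrid
conversion+heteroduplex, contiguous; 4 = CO with heteroduplex on one
product; 5 = heteroduplex and conversion on opposite sides of the break;
6 = CO with opposite-direction heteroduplexes on both products; 7 = CO
with no visible tract; 8 = conversion on one chromatid with an
overlapping heteroduplex on the other, NCO.  A heteroduplex run whose
foreign strand flips (strand switch) marks the break tightly and is
COMPLEX on an NCO chromatid (the two-ended SDSA/dissolution product,
which the eight templates do not cover).

Classes 3 and 5 present identically on a single chromatid (the pattern is
mirror-symmetric and carries no information about which tract edge held
the break).  The junction is called Class 5 only when another repair of
the same colony localizes the break tightly at it (a crossover exchange
point or strand switch — the DSCB situation, matching the study's use of
all recombinant chromatids to place the lesion); otherwise the hybrid
tract is reported as Class 3.  BIR events carry no class (they sit
outside the 1–8/complex taxonomy).

DSB intervals are never point estimates: a strand switch or exchange
yields the flanking marker pair; a unidirectional tract yields its full
span; no tract yields none.  Tract length = (maximum tract + minimum
tract)/2, with the maximum measured between the closest unaffected
flanking markers and the minimum between the outermost affected markers;
a missing flank at a chromosome end is replaced by the end and flagged.
Crossover events measure each product against its exchange-side flank and
sum the two chromatids.  For NCO events with identical sister chromatids
the donor is not identifiable; recipient labels come from tract context
(conversion chromatid, or heteroduplex base origin), with `AMBIGUOUS` for
tract-free crossovers and inconsistent geometries.

## Statistics

Detection fraction `(2·both + one) / (2·(both + one + none))`; expected
DSCB composition `(n·p², 2·n·p·(1−p), n·(1−p)²)` at full precision with
rounding only at presentation; densities and sectoring rates as plain
ratios.  Medians carry percentile-bootstrap 95% intervals (10,000
resamples by default, seeded; the source's interval method is unstated).
Count comparisons delegate to scipy: two-sided Fisher for 2×2 tables;
chi-square against a ratio with Yates continuity correction for 1×2
tables (the correction is required to reproduce the quoted p = 0.16 for
15:25 vs 1:1); Mann-Whitney for two samples.  The squared-SCB-rate
independence calculation is computed, never hard-coded: (0.75%)² =
5.6 × 10⁻⁵.

## Problem sizes and what the tests show

The validation suites run on the chrV-scale maps: a 200+-event noise-free
full-panel round trip asserting exact strand recovery and the
mechanism→class map; a 500-colony selected cohort on the 13k/55k panel at
sigma 0.1 asserting ≥95% SCB/DSCB accuracy and per-called-marker
agreement with truth; and a 120-colony default-condition cohort whose NCO
tract median must fall inside the published 95% confidence band
(3.6–7.2 kb).  The study's empirical per-class counts, SCB/DSCB tallies
and exact medians derive from per-colony supplementary data that are not
in the main text and are deliberately not asserted.

Passing tests show the pipeline is internally consistent and correctly
inverts its own forward model under the stated noise model.  They do not
show that real microarray noise is log-normal, that real tract lengths
are gamma-distributed, that real complex events arise only from branch
migration/template switching, or anything about probe-level artifacts,
segmental aneuploidy, or multiple overlapping events on one chromosome —
all outside the model.
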
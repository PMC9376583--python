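# Methods

## The screen being analysed

A pooled barcoded-LNP screen injects N chemically distinct lipid
nanoparticles, each encapsulating a unique single-stranded DNA barcode
(plus cargo mRNA at a 10:1 mRNA:barcode mass ratio), into reporter mice,
sorts the cell populations of interest, amplifies the barcodes by nested
PCR, and sequences them. A naked (unencapsulated) barcode is co-injected as
a negative control. The sequenced **input pool** — an aliquot of the
injected mixture — defines each barcode's baseline abundance. The analysis
questions are: which LNPs delivered to which cell types (normalized
delivery), and which formulation components distinguish the best from the
worst particles (decile fold enrichment).

## Scaffold anatomy and primer panel

Every barcode scaffold is a 91-nt single strand with fixed segment order:
forward primer region (20 nt), ddPCR probe site (20 nt), 8-nt barcode, 7-nt
random region, spacer (16 nt), reverse primer region (20 nt). The primer
regions are the universal anchors shared by all eight staggered forward and
eight staggered reverse nested-PCR primers (the packaged panel: a
sequencing-adapter prefix, a 0–7-nt stagger that desynchronises sequencing
cycles across the pool, then the 20-nt anchor). Anchors and staggers are
*derived* from the primer table as the longest common 3′ suffix / common
prefix, never hard-coded. The probe-site and spacer sequences are
configurable; the defaults are balanced, homopolymer-free sequences chosen
to sit at Hamming distance ≥ 6 from the forward anchor at every offset, so
they cannot be mis-anchored. Terminal phosphorothioate modifications are
carried as annotation only (they protect against exonucleases but affect no
computation). The exact published segment map of the original scaffolds is
not public, so the layout is a config object rather than a guess presented
as fact.

## Barcode set design

Barcodes are sampled by greedy rejection: a candidate is kept only if its
Hamming distance to every accepted code is ≥ `min_hamming` (default 3, so
that one-substitution assignment is provably unambiguous:
3 ≥ 2·1 + 1). "Sequence bleaching" resistance — low per-cycle base
diversity confusing the sequencer — is operationalised as a per-position
ceiling: no single base may occupy more than `ceil(0.75·n)` members at any
barcode position; a violating set is resampled. Failure after the attempt
budget (default 2000·n draws) raises; a silently smaller set is never
returned. The reported minimum pairwise distance is always recomputed by an
all-pairs scan at construction.

## Quality control and pooling

The DLS gate follows strict inequalities: pass iff
20 nm < diameter < 200 nm **and** monodisperse (stable autocorrelation /
single inflection point). When only a polydispersity index is available,
monodispersity is derived as PDI ≤ 0.3. The boundary convention (strict,
not inclusive) is a deliberate choice between two plausible readings and is
configurable. The pooled dose is split per particle
(`total / n_members`); the naked control barcode participates in the input
proportions (it is sequenced) but not in the per-particle dose (it is not
an LNP). Whether real pools are mixed at equal mass or equal particle
number is rarely stated; the default is uniform barcode proportion with a
config override.

## Generative model of a screen (synthetic data)

* **Propensity**: each LNP × cell type gets an i.i.d. log-normal relative
  delivery weight, `exp(N(0, σ))` with σ = 1.0 by default — delivery in
  real screens spans roughly two orders of magnitude across particles.
  Optional component effects multiply the weight of every LNP carrying a
  given level (e.g. 10× for one ionizable lipid) to plant a
  structure–function signal.
* **Control**: the naked barcode's weight is 0.1 × the minimum LNP weight
  in each cell type — lowest by construction, since free DNA does not
  readily enter cells.
* **Molecules**: a sample of depth D draws `D / reads_per_molecule`
  molecules (default ratio 10) multinomially with probability ∝ input
  proportion × propensity; each molecule gets a fresh random 7-mer UMI.
* **PCR bias**: each molecule's read count is multinomial over per-molecule
  log-normal weights (`sd = 0.5` default). Bias multiplies reads, not
  molecules, so distinct-UMI counts are insensitive to it — the property
  that makes the 7-mer a useful bias monitor.
* **Reads**: single-end, full amplicon, prefixed by a uniformly chosen
  stagger (primers are mixed equimolar), with i.i.d. substitutions at
  0.005/base and constant quality.

Not modelled: indels, quality-dependent error profiles, paired-end
structure, FACS sorting efficiency, mouse-to-mouse biology, carryover
between samples. Passing tests therefore demonstrate correctness of the
analysis under multinomial sampling + substitution noise, not robustness to
structural read artefacts. No per-particle QC table is published for the
original screen, so synthetic QC tables (with a designated pass count for
the standard 128 → 65 scenario) stand in; they are labelled synthetic in
the generator's docstring.

## Counting

Anchor-first extraction: the forward anchor is located within the first
(max stagger + adapter + anchor) bases, allowing ≤ 1 substitution, leftmost
best match winning ties; barcode and UMI are sliced at fixed layout offsets
past the anchor; the observed 8-mer is assigned to the unique barcode
within ≤ 1 substitution (exact match wins; sets too tight for tolerant
matching force exact with a warning). Reads failing forward anchoring are
retried reverse-complemented (configurable). Assigned + unassigned = total
is enforced at construction. Raw read counts feed normalized delivery; UMI
collapse is exact-match on the 7-mer (no directional clustering — at 7 nt
and these depths the simplest rule is defensible) and is reported as
PCR-bias QC, not as the delivery statistic.

## Normalized delivery

`d_i = (p_i/q_i) / Σ_j (p_j/q_j)` with p the within-sample proportions and
q the input proportions; columns are rescaled to sum to 1 (the rescaling
convention is one consistent reading of "counts divided by counts for all N
barcodes, normalized to the injected mixture" and is isolated in a single
function so alternatives can be swapped). A pseudocount of 0.5 is added to
every barcode in both sample and input before forming proportions
(configurable, including off) — it prevents division by zero and stabilises
the bottom of the ranking; with it off, zero input counts raise. Aggregation
across samples is the arithmetic mean of normalized columns; ranks are
1 = best, ties broken lexicographically by barcode id so the pipeline is
deterministic.

## Enrichment

Decile size k = round-half-up(0.10·N) with floor 1 (N = 65 → k = 7). The
statistic is a **ratio of fractions** — fraction of the decile carrying a
level over the level's fraction in the screened library — not a 2×2 odds
ratio; "odds relative to random chance" is informal usage in the field, and
both variants are implemented with the fraction ratio as default. Expected
fractions use the screened (QC-passing) library, never the designed one,
and the control barcode is excluded from ranking and enrichment. Under a
null permutation of ranks the mean fold is 1 per level by construction (the
acceptance suite verifies |mean − 1| < 0.05 at 10,000 permutations).
Percentile bootstrap intervals resample sample columns with replacement and
recompute aggregation → ranks → deciles → folds.

## Problem sizes used by the test suite

Simulation depths in tests are chosen as the smallest sizes at which the
statistical claims are meaningful, and are stated here as the package's own
choices: recovery (Spearman ≥ 0.9) uses 3 replicates at 100,000 reads each;
the 100-seed negative-control study uses 3 samples × 20,000 reads — below
~10,000 reads/sample the weakest LNPs and the control all draw zero reads
and their ordering degenerates to input-count noise through the
pseudocount, which is a shallow-depth artefact rather than a property of
the method; the 200-seed planted-effect study uses the counts-level
simulator (multinomial sampling without read synthesis), since the
read-level path is validated separately.

## Degenerate inputs and numerical conventions

Zero depth yields an empty, valid FASTQ with a logged warning. Empty FASTQ
counts to an all-zero table. Unknown axes/levels and decile fractions
outside (0, 0.5] raise. `fold = 0` is a valid observation (level absent
from the decile); `expected = 0` yields NaN (undefined, reported as such).
All column sums are asserted to 1 within 1e-9. Every stochastic routine
takes an explicit integer seed; the pipeline derives per-stage,
per-sample seeds from one root seed via `numpy.random.SeedSequence`.

## Known limitations

Substitution-only error model; single-end reads; exact-match UMI collapse
(slightly undercounts molecules under sequencing errors in the UMI);
enrichment treats components marginally (no interactions or regression —
matching the screen's own analysis); bootstrap intervals resample samples,
not mice, so with few mice they understate between-animal variance.
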
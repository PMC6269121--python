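# Methods

This note documents the models, statistics and design choices behind the
package, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic tests do and do not show.

## Affinity scoring

MHC-I binding is consumed as a predicted IC50 in nM. Production use
reads an external predictor's table (a NetMHCpan-style adapter locates
columns by header name); duplicate (peptide, allele) rows keep the
*minimum* IC50, the most optimistic binding call — conservative for a
binder filter, since a peptide is never excluded on account of a worse
duplicate row. Peptides with non-canonical residues are rejected at
parse time because scoring matrices are defined only over the 20
canonical residues.

The bundled `toy_model` is a seeded position-weight matrix (weights
i.i.d. Normal(0.6, 0.5) per position × residue) with the strictly
decreasing calibration IC50 = 50000·e^(−score). It exists so the whole
pipeline runs offline and so tests have a deterministic, fully
inspectable scorer; it is a test double, not a predictor of real
binding. The parameters were chosen once so that roughly half of random
8-mers pass the 500 nM cut, keeping design runs well supplied with
binders at small proteome sizes.

The binder definition is strict: IC50 < threshold, default 500 nM. The
boundary case (exactly 500) is a non-binder.

## Library design

- All unique 8-mers of the proteome are enumerated with first-occurrence
  provenance (0-based starts internally; mutated positions are reported
  1-based, matching how positions are discussed in the field).
- The wild-type library is a uniform without-replacement sample of the
  binder-filtered k-mers. Candidates are sorted before sampling, so the
  draw depends only on the seed, not on input order.
- Each wild-type peptide receives one random single-residue substitution
  (position uniform over k, residue uniform over the 19 alternatives)
  subject to: the mutant still passes the binder cut, and it does not
  equal any *proteome* k-mer. The proteome-wide exclusion is the default
  because a "mutant" that matches a self peptide elsewhere in the
  proteome is not a neoantigen; a library-only check is available via
  `forbid_scope="library"` for the narrower reading. Requiring mutants
  to pass the same <500 nM cut operationalises "the substitution must
  not eliminate MHC binding" with the only binding criterion the
  pipeline defines.
- Sampling is by rejection (budget `max_mutation_attempts=200`, above
  the 8×19 = 152 candidate space); an exhaustive mode enumerates the
  admissible neighbourhood and picks uniformly — deterministic search
  space, used by tests and by anyone wanting guaranteed termination
  behaviour. A peptide with no admissible mutant is flagged unmutable
  and excluded with a log entry rather than silently dropped.
- Characterisation: the |ΔIC50| histogram has a dedicated first bin at
  100 nM; mutated-position counts run 1..k; the substitution-class
  matrix uses a fixed three-class convention — hydrophobic
  {A,C,F,I,L,M,P,V,W}, polar {G,H,N,Q,S,T,Y}, charged {D,E,K,R}. Any
  such coarse classification is a convention; this one is documented and
  applied consistently, and histogram totals always equal the mutant
  count.

## Minigene encoding

A minigene is adapter–SfiI–signal–epitope–stop–SfiI–adapter. Encoding
choices:

- Codon choice starts from the highest-frequency mouse codon per residue
  and repairs forbidden motifs by re-drawing synonymous codons (seeded),
  checking the epitope *in context* — 12 bp of fixed flank on each side,
  one base short of the 13-bp SfiI motif, so junction-spanning sites are
  caught while the two intended cloning sites are not.
- The SfiI site class GGCCNNNNNGGCC is its own reverse complement, so a
  top-strand scan covers both strands.
- The signal-sequence CDS bundled as a default is a generic secretion
  signal peptide in preferred codons and is explicitly a placeholder:
  the production construct's exact signal sequence should be supplied by
  the user. Likewise the default adapters are generic T3/T7
  promoter-primer sequences, config-overridable.
- Per-peptide codon draws are seeded by CRC32(peptide) XOR master seed,
  making pool construction order-independent: permuting the input
  permutes the output identically.
- Pool QC reports duplicate encodings and stray SfiI sites (hard
  failures) plus the length distribution and the minimum pairwise
  Hamming distance between same-length encodings — the relevant number
  for barcode confusability under sequencing errors. The pairwise scan
  is quadratic and subsamples beyond 2000 encodings.

## Read counting

Because every epitope encoding is unique and positionally fixed in the
amplicon, counting is anchored Hamming matching rather than general
alignment: a read's window is looked up in an exact dictionary of
references and (at `max_mismatch=1`) a dictionary of all
single-substitution neighbours. A read equidistant from two or more
references at the best distance is discarded as ambiguous; distance 0
always beats distance 1. This is linear in reads, fully deterministic,
and is verified in tests against an independent brute-force all-pairs
scanner. Conservation holds by construction: mapped + unmapped +
ambiguous = total.

## Screen comparison

- Replicates are averaged arithmetically on the abundance scale.
- log2 fold change uses pseudocount ε = 1/(2·max total mapped reads)
  across the samples involved — half a read at the deepest sample's
  scale, so drop-outs get a finite, depth-aware fold change. When
  abundances arrive without read totals a documented fallback of 1e-7 is
  used; pass `pseudocount=` to control it.
- The trend of log10(post) vs log10(pre) is fitted with LOESS
  (statsmodels lowess, local linear, span 0.5); residuals are reported
  per minigene. Degenerate neighbourhoods that make the local fit
  undefined fall back to the y = x expectation.
- Depletion calls require both lfc ≤ −1 (2-fold) *and* pre-abundance ≥
  1/10,000. The floor exists because clones rarer than ~1/10,000 of a
  5×10⁶-cell inoculum drop out by sampling alone; calling them depleted
  would mistake the injection bottleneck for immunity. Both knobs are
  exposed and reported, never silently applied. Enrichment is called
  symmetrically.

## Two-colour depletion statistics

- Normalisation discards non-fluorescent events: eGFP and mCherry
  percentages are rescaled to sum to 100. A tumor with neither colour is
  flagged rejected and excluded from testing (counts reported); a
  sensitivity path is to treat such tumors at the assay floor, which
  users can do by editing the table — the default follows the exclusion
  convention.
- The group test is a one-sample t-test of log10 FC against 0. The
  alternative is **one-sided, mean < 0**: the scientific alternative is
  depletion, a directional hypothesis, and a two-sided test at the same
  α with a post-hoc direction guard is both unconventional (its
  effective level is α/2) and, at the small group sizes this assay uses
  (3–5 tumors), underpowered to the point of being unable to flag even
  noise-free 10-fold depletion at α = 0.001 (|t| = 10 < t₀.₉₉₉₅,₃ =
  12.9). A two-sided mode remains available via `alternative=`.
  α defaults to 0.001, mirroring the four-star reporting convention.
- Zero-variance groups have no t-statistic; the report falls back to the
  sign of the common value.
- The detection threshold uses a monotone frontier: the smallest
  fraction significant with all larger fractions also significant. The
  construct being estimated is a detection *limit*, so an isolated
  significant group below a non-significant one does not move the
  threshold; `frontier=False` gives the isolated-significance reading.

## Synthetic data

The generator produces inputs with the statistical structure the
analysis assumes, and only that:

- Pre-injection abundances are log-uniform over [2×10⁻⁷, 5×10⁻³]
  (normalised), matching the ~4 orders of magnitude of observed spread
  without claiming the real distribution's shape.
- A screen is a chain of bottlenecks per tumor: multinomial draw of the
  5×10⁶-cell inoculum; binomial survival with each minigene's
  multiplier, applied **only** when its realised inoculum fraction
  reaches its clonal-fraction threshold (the minimal mechanism
  consistent with fraction-dependent rejection — a generative
  assumption, not a biological model); deterministic growth (default
  ×400, the scale of a 17-day expansion from 5×10⁶ cells to a ~2 cm³
  tumor); multinomial sequencing at the configured depth (default 10⁶).
  Rare-clone drop-out emerges from the inoculum draw, not from a rule.
  Defaults of 3 pretumor and 5 tumor replicates mirror the screen's
  sample structure.
- Two-colour experiments draw each tumor's measured log10 FC from
  Normal(kill·1[f ≥ threshold], sd²) and reconstruct the colour
  percentages from it. The default effect, kill = −2.5 (≈300-fold loss)
  with sd = 0.2, encodes near-complete elimination of antigen-bearing
  cells above threshold, which is the observed fate of strongly
  immunogenic subclones in bulk mixtures; at 4 mice/group this gives the
  detection procedure >99% recovery of the generative threshold, so the
  parameter-recovery tests probe the procedure rather than the noise. A
  tumor is emitted as rejected when the surviving-cell fraction falls
  below 1% of the inoculum.
- Reads are emitted per minigene with i.i.d. substitution errors and
  placeholder qualities; with zero error rate, counting recovers the
  simulated counts exactly (a round-trip oracle in the tests).

What passing these tests shows: the pipeline's bookkeeping is exact, its
calls are calibrated against the generative mechanisms above, and known
thresholds/effects are recovered at the stated sample sizes. What it
does not show: anything about real immune dynamics, PCR bias, indels,
UMI structure, or predictors of real MHC binding — all out of scope by
design.

## Problem sizes

Test-suite simulations use 200–1000 minigenes at sequencing depth 10⁶,
20-replicate null checks, and 100-replicate threshold-recovery runs at 4
mice/group; the design pipeline runs on an ~80 × 400-residue synthetic
proteome (~31k unique 8-mers). These sizes were chosen so the full suite
completes in well under a minute while keeping multinomial sampling
error far below every tested effect.

## Known limitations

- The anchored counting assumes reads are pre-trimmed so the epitope
  window sits at a fixed offset; paired-end merging and quality handling
  are out of scope.
- The toy affinity model shares no information with real H-2Kb motifs;
  design statistics computed from it (e.g. position spectra) are
  structural checks, not biology.
- The exact production signal sequence and vendor primer sequences are
  not bundled; defaults are documented placeholders.
- Thresholds detected by the frontier rule are resolution-limited by the
  tested fraction grid; the procedure reports group tests so users can
  inspect near-threshold behaviour.
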
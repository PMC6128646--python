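# Methods

This note records the models, defaults and numerical choices behind
`toxprof`, and what the synthetic-data generator does and does not emulate.

## Pool growth and the GI score

The screen model is deterministic exponential competition. Mutant *i* has a
latent relative growth rate ρ_i ∈ [0, 1]: the fraction of the pool's
doublings it achieves under treatment (ρ = 1 neutral, ρ = 0 no growth).
Over g pool doublings, treated abundance is proportional to
a0_i·2^(g·ρ_i) and control abundance to a0_i·2^g; both vectors are
renormalized to sum to 1 (tolerance 1e-12 asserted in tests). The GI score
computed downstream, log2(f_control/f_treatment)/g, then equals
(1 − ρ_i) plus a common normalization offset that vanishes as the mutant's
abundance → 0; for trace-abundance mutants GI → 1 − ρ (verified to within
0.005 in tests). This parameterization was chosen so that a complete
non-grower scores ≈ 1 per doubling and a neutral mutant exactly 0 in the
noise-free model.

Defaults: g = 5 pool doublings (the selective-growth depth of the screens
this emulates), uniform initial abundances, pseudocount 0.5.

**Noise model.** Stochasticity enters only at sequencing: per-sample read
counts are one multinomial draw at the configured depth, and base
substitutions are i.i.d. per base. Replicate-to-replicate biological
variability is modeled as optional log-normal jitter on ρ (σ = 0.02 by
default, applied per screen and clipped back to [0, 1]); there is no
published replicate-noise model for this assay, so the value is a
package choice sized to keep screen-to-screen GI scatter small relative to
the planted effects it is meant to obscure. PCR amplification bias and
paired-tag layouts are not modeled.

## Barcode assignment

Matching is substitution-only (Hamming), default tolerance 1 mismatch,
with the barcode extracted at a fixed offset from the read start; the
platform emulated here is substitution-dominated, and indel-aware edit
distance would buy little at the cost of ambiguity. Ties at the minimal
distance are left unassigned — arbitrary tie-breaking would leak miscounts
into GI scores. Reads shorter than the layout, reads with no barcode within
tolerance, and ties are tallied under distinct reason codes, and
assigned + unassigned always equals the reads processed. The library
simulator guarantees a minimum pairwise barcode distance (default 3) and
the read simulator warns when two barcodes sit within distance 2, where
error-tolerant matching could cross-assign. Exact duplicate barcodes are a
library-integrity violation and are rejected at construction rather than
warned about at read time.

## Robust standardization and the tail-area FDR

Screens are standardized with z = (GI − median)/NIQR, NIQR = IQR/1.349
(Φ⁻¹(0.75) − Φ⁻¹(0.25)), quantiles by linear interpolation. The median and
NIQR are insensitive to the minority of true positives, so z is
approximately standard normal for the null mutants.

The tail-area FDR is realized as the Benjamini–Hochberg step-up envelope on
one-sided p = 1 − Φ(z), scaled by a null proportion π0 (default 1,
conservative): q_i = min over p_j ≥ p_i of (π0·M·p_j/rank_j), clipped to
[0, 1]. Density-estimation variants of tail-area FDR (e.g. a Grenander fit
to the z histogram) are deliberately not reproduced; with π0 = 1 the
step-up envelope is the same tail-area quantity with the empirical null
replaced by the theoretical one, and it is exactly testable against a
brute-force oracle (asserted for all inputs up to size 50, plus a
statsmodels cross-check).

Calling: default cutoff q ≤ 0.1. A mutant covered by ≥ 2 screens that
passes in all screens with data is `sensitive_both`; passing in at least
one screen gives `sensitive_one`; single-screen mutants can at best be
`sensitive_one`. Coverage differs between library versions, so it is
reported per mutant rather than assumed uniform. Expressivity labels
(high/medium/low) default to tertiles of GI among called mutants; they are
advisory and not comparable to categories from orthogonal plate assays,
which can be passed through as annotations.

At the default operating point (2000 mutants, 30 planted at ρ = 0.5,
depth 2×10⁶, two screens) the planted z is ≈ 40 null SDs, so recovery is
essentially complete; the acceptance suite verifies ≥ 90% recall with a
zero-false-positive median over five seeds, and a both-screen call rate
≤ 0.1% over 100 null screens.

## Term enrichment

Over-representation only, via the hypergeometric upper tail
P(X ≥ k) for overlap k between an n-gene list and a K-gene term in an
N-gene universe, evaluated through scipy's log-space survival function
(exact against exhaustive subset enumeration for all N ≤ 12 in tests).
Correction is Bonferroni over the m terms actually tested (within the
configured size bounds); m is recorded on the result because published
tables typically print corrected values without m, which is why recomputed
raw tails can only be compared against printed corrected values in the ≤
direction. Genes absent from the background are dropped with a warning,
never added: background fidelity is what the p-values condition on. GO
graph up-propagation is out of scope; terms are taken as given (GMT).

## Profile clustering

Similarity is uncentered correlation r = Σxy/√(Σx²·Σy²) — cosine
similarity without mean-centering, appropriate because GI = 0 is a
meaningful origin. Distance d = 1 − r; agglomeration is unweighted average
linkage (UPGMA) with the Lance–Williams size-weighted update, which equals
the mean over original leaf pairs (asserted against an O(n³)
recompute-from-scratch oracle for n ≤ 8 and against scipy's linkage on
precomputed distances). UPGMA merge heights cannot invert; monotonicity is
asserted on every run. Ties in the minimum distance break toward the
lexicographically smallest cluster-id pair, making trees deterministic.
Missing cells are handled by pairwise deletion with a minimum-overlap
requirement (default 2 shared finite entries, capped at the profile
length so single-column matrices still cluster). Leaf order is simple
left-first traversal; no optimal-leaf-ordering pass. Output formats are
tab-delimited CDT/GTR/ATR (similarities = 1 − d, non-increasing down the
file) so standard dendrogram viewers open them, plus Newick per axis.

## Flow-cytometry competition assay

Event tables are linear arbitrary-unit intensities in six channels
(FSC_A, FSC_H, SSC, DAPI, FITC, PE). The three hard gates are
intersective, so their order cannot change the retained set (asserted by
permutation in tests):

1. viability: DAPI ≤ 300 (DAPI-permeable dead cells light up 450/50);
2. scatter box: FSC_A ∈ [150, 1e5], SSC ∈ [50, 1e5] (debris removal);
3. doublet band: FSC_A/FSC_H ∈ [0.8, 1.4] — pulse area outgrows pulse
   height for adhered pairs, a shape criterion that remains valid when
   genotoxins elongate cells. The band realization of the "area versus
   height" criterion is a package choice; the bounds are calibrated to the
   simulator's singlet ratio (1.05 ± 0.06) and doublet ratio (1.95 ± 0.12).

GFP classification: FITC > 10³ is GFP+, FITC in [10², 10³] is excluded as
ambiguous, below is GFP−. Fractions W = GFP−/(GFP− + GFP+) per sample feed
the normalization W_n = W_m/W_r (cancelling GFP+ cells that silenced the
marker, simulated at 0.3% by default, within the 0.1–1% range observed for
this assay class) and the growth ratio W_n*/W_n. The raw count ratio
W_N = GFP−/GFP+ of the treated mutant run is compared against the 0.03
detection floor and flagged — not clamped — so downstream statistics can
censor explicitly. Replicate comparisons use the pooled-variance two-tailed
Student's t-test (Welch by flag); both mutant-vs-reference and
mutant-vs-unity comparisons are possible since the ratios are returned
raw. Binary FCS files are not read; event tables are CSV.

The flow simulator draws class counts multinomially (GFP+, GFP−, dead,
doublet, debris; fractions renormalized if they sum below 1) and
intensities log10-normally per class, with truth labels retained for
oracle tests. With the default 4% doublets+debris load, total gate
attrition lands in the 3–5% band (asserted over 100 seeds). The simulator
does not model spectral spillover compensation, instrument drift, or
time-dependent acquisition effects.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* the analysis assumes:
exponential competition, multinomial sampling, substitution errors,
log-normal intensity clusters. Real screens add effects it omits —
PCR bias, barcode-specific amplification efficiency, strain crosstalk,
batch structure, non-normal GI tails from biology rather than sampling.
Passing recovery and calibration tests therefore validates the arithmetic
and its operating characteristics under the stated model, not the
biological accuracy of any particular screen.

## Problem sizes and determinism

Simulation-based tests run at 2000 mutants × 2×10⁶ reads (screens),
2×10⁴–10⁵ events (cytometry) and 100–200 seeds for calibration loops —
sizes at which the Monte-Carlo assertions are stable yet the full suite
completes in well under a minute. All generators take explicit seeds and
are bit-reproducible; the pipeline writes its fully-resolved configuration,
a config hash and per-stage record counts alongside every run, and refuses
to overwrite a completed run directory.
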
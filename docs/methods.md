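# Methods

This note documents the models, conventions and numerical choices behind
`rnarray`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic-data validation does and
does not establish.

## Sequence model

All sequences are stored and displayed 5′→3′; surface attachment is a 3′
flag, never a string reversal, so the shared linker/primer block of a
surface probe always appears at the end of the string. Chemistry (DNA, RNA,
2′-*O*-methyl RNA) is tracked per segment, not per base, because every
species in the workflow is a block chimera (psoralen-primer + RNA
extension, variable + block + linker). U and T are distinct characters;
the only sanctioned cross-chemistry comparison is the explicit
`normalize_tu` mapping. `revcomp` is an involution under chemistry swap and
is validated against 10⁴ random strings plus property tests.

The universal primer defaults to the 15 nt 5′-psoralen 2′-*O*-methyl RNA
`UAGGGACACGGCGAA`; a 12 nt floor is enforced because shorter primers cannot
be made selective on libraries with ≥10⁵ unique variable regions. The
psoralen crosslink validator requires a perfect Watson–Crick duplex over
the whole primer (U:A allowed), a terminal U·A (or T·A) pair at the
psoralen end, and a dT as the first linker base — the geometry the
intercalated psoralen needs to form its covalent adduct.

## Library generators

**Variant series (ink-jet platform).** For each linker length dT₅/₁₀/₁₅/₂₀
the generator emits the reference template, all distinct rearrangements of
the 3 bases at the 3′ terminus of the primer-complement block, all distinct
rearrangements of 3 central variable-region positions, and the matched
no-block control; a single direct-hybridization reference probe is added
once (the control already carries the product sequence as DNA, so it *is*
the direct-hybridization reference — the extra probe just keeps that role
explicit). "Distinct rearrangements" include the identity ordering, so
three identical bases collapse to one variant. Central positions default to
the three centermost indices (⌊L/2⌋−1 … ⌊L/2⌋+1, 0-based) and are
overridable. Every full sequence must fit the 150 nt ink-jet platform cap;
the photolithography platform is capped only by the cycle budget.
Replicates (default 60 per probe) are placed at seeded random grid
positions, mirroring randomized probe placement on real arrays.

**Single-dA walk.** Template components are listed surface-outward
(linker, block, then the TGC concatemer), i.e. 3′→5′. Reading the 20×TGC
repeat in that direction, the single dA sits either at the very start
(variant 0, extension position 1, surface-proximal — the convention chosen
because the labelled-rU signal is strongest there) or immediately after the
k-th dC (variants 1–20, extension positions 3k+1, up to position 61 at the
5′-distal end). Each 61 nt variable region therefore contains exactly one A
and twenty each of T/G/C, keeping the fluorophore's sequence context
constant. The annotation is verified against a brute-force base-by-base
extension oracle. Matched no-block controls carry the same positional
annotation for background pairing.

**Selectivity screen.** For each template the longest contiguous primer
substring whose complement (either strand) occurs in the variable region is
found by exhaustive substring search; stretches ≥12 nt are flagged. The
intended block lies outside the variable region and is never flagged.

## Image encoding

Brightness is quantized by floor binning (`level = value·k/256`, k = 8 by
default) — floor, not rounding, so encoded layouts are bit-reproducible.
Per channel, a calibration of truncation length → mean intensity is reduced
to k lengths whose intensities best match k evenly spaced targets spanning
the observed range (both extremes included): an exhaustive subset search
when ≤25 calibration points (ties → lexicographically smallest length
tuple), a greedy nearest-target assignment otherwise. Truncations are
5′ truncations — the 3′-most L bases are kept so the primer-adjacent end
survives.

Pixel expansion is explicit configuration: by default each pixel becomes a
2×2 feature block (red, green, blue, plus a duplicate of the brightest
channel) and the expanded image is tiled 2×2, taking a 256×192 source
exactly onto the 1024×768 mirror grid (768 K features). This expansion is a
documented package convention — the only reading under which four such
images fill the grid — not a claim about any particular physical array.
Level-0 (black) pixels map to a dedicated untranscribable, non-hybridizing
dark control (a TG-repeat 20mer, response length 0) rather than to the
shortest truncation, guaranteeing zero specific signal; the full 3×8
truncation template set is still emitted into the design table.

## Synthesis planning

Synthesis proceeds 3′→5′. The dT run shared by all placed probes (the
minimum linker length) is coupled first as unmasked flood cycles of
acid-deprotected DMTr-dT, because acid deprotection cannot be spatially
addressed; probes with longer linkers get their extra dT via masked cycles.
Remaining positions cycle through a fixed base order (default ACGT): the
cycle for base b exposes exactly the features whose next unsynthesized base
is b; empty cycles are dropped. No shortest-common-supersequence
optimization is attempted. Masks are 0-based row-major boolean matrices
with a 1:1 mirror-to-feature mapping (optics are out of scope). Per-cycle
constants: BzNPPOC-dN 3 J/cm² and 15 s; NPPOC-HEG 6 J/cm² and 300 s;
DMTr-dT 0 J/cm² (acid) and 120 s. The `replay` simulator reconstructs
sequences from the plan and is the round-trip verifier: schedule → replay
is the identity on full sequences, property-tested on 200 random layouts
and on a 48×64 window of the full image layout.

## Scan simulator

The simulator generates the signal structure the estimators assume, not an
optical model. Specific signal for a transcribable probe is
`A·e·s(L)·r`, for a control `A·s(L)·r`, with `s(L) = L/(K+L)` a saturating
(Michaelis-type) duplex-length response — chosen because hybridization
signal grows with template length without a published functional form —
with K = 8 nt and `L` the probe-overlap (response) length. `e` is the
conversion efficiency (default 0.20); unconverted arms give templates zero
specific signal (the template strand is not probe-complementary);
degradation arms scale all specific signal by a residual `r`. In Cy3-UTP
mode the length response is replaced by a distance-decay profile
`d(pos) = max(0.96^(pos−1), 0.70)` at the probe's rU position — an explicit
modeling choice keyed to the observed initial decay and terminal plateau,
not a measured constant. Noise is multiplicative lognormal with unit mean
(CV 0.2 by default, the standard regime for fluorescence scans); background
is drawn around its mean with the same CV and reported in the background
column. Everything is seeded; CV = 0 reproduces the closed-form expectation
exactly. Not modeled: spatial gradients, dust, PSF blur, scanner
saturation — so passing recovery tests demonstrates estimator correctness
under the assumed noise model, not robustness to real-scan artifacts.

## Quantification

Aggregation is the mean and SD of replicate foregrounds per probe. An
optional dust rule (off by default, matching the ordinary no-exclusion
policy) removes replicates more than 5 median absolute deviations *above*
the probe median — one-sided, since dust produces abnormally high signal.
Correction subtracts the matched control mean and floors at zero (negative
corrected intensities are not meaningful); normalization divides by the
maximum corrected value and is idempotent.

Ratio estimators use means of replicate means, mirroring the averaged
recipe; uncertainty comes from a seeded bootstrap (1000 resamples,
percentile 95% CI) over replicates of both arms. When a non-hybridizing
background probe class is available its resampled mean is subtracted from
each arm first — without this the additive scanner background biases the
raw ratio upward (e.g. a true 20% efficiency reads ≈21% at the default
background), and with it the estimators are unbiased, which the recovery
tests verify at replicate counts 8–85. GPR foreground is the `F<λ> Median`
column; the local-background column is read but unused by default, since
correction is control-based rather than local.

The positional profile aggregates the dA-walk scan, subtracts the matched
control at each rU position, normalizes, and re-expresses every variant
relative to the position-1 variant. The plateau statistic averages the
variants whose rU lies within the final 20 *nucleotides* of the product
(positions 43–61 for the 61 nt walk, 7 variants) — the window on which the
decay model is exactly flat, so the noise-free statistic equals the plateau
parameter exactly.

## Problem sizes and determinism

Validation runs use the workflow's native replicate counts (24, 60, 62, 85)
and full-scale image encoding (768 K features); the synthesis round trip is
exercised exhaustively on randomized small grids (≤32×32) and on a 48×64
window of the full layout, which covers every probe class at a fraction of
the full-frame mask volume. All stochastic steps take explicit seeds, and
the simulate → quantify pipeline is byte-stable for a fixed seed.

## Known limitations

- No thermodynamics: duplex stability, secondary structure and
  cross-hybridization among variable regions are out of scope (only primer
  selectivity is screened).
- The published truncation-length tables and the exact deposited variant
  design are not reproduced probe-for-probe; generators implement the
  stated construction rules with documented defaults.
- The scan simulator's functional forms (saturating length response,
  exponential-with-plateau decay) are modeling choices; estimator recovery
  on them does not certify behavior on scans with spatial artifacts.
- GAL/GPR support covers the minimal ATF dialect defined here, not the full
  GenePix specification; TIFF-level feature extraction is out of scope.
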
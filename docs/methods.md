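# Methods

## Glycan composition model

Compositions are integer counts over the alphabet HexNAc / Hex / Fuc /
NeuAc / NeuGc.  Two string dialects are accepted everywhere
(`HexNAc(4)Hex(5)` and `HexNAc4Hex5`), and an opt-in alias table maps
named-sugar vocabulary (Gal, GalNAc, GlcNAc, Man, Glc, Neu5Ac/Gc, dHex)
onto that alphabet so O-glycan names such as `NeuAc2GalGalNAc` parse.
Aliasing is opt-in at the API level (and on by default when reading tables)
because collapsing Gal→Hex is lossy and should be a deliberate choice.

Classification is deliberately composition-level; no topology or linkage is
inferred:

- **Antennae** = HexNAc − 2.  A bisecting GlcNAc is indistinguishable from
  an antenna in a composition and is therefore counted as one; users working
  with bisected material should interpret antennarity as an upper bound.
- **Fucose**: the first Fuc of any composition is assigned to the core, the
  remainder to antennae.  This is a reporting convention, not a structural
  claim — core/antenna placement is not decidable from composition.
- **LacdiNAc**: all non-core Hex (beyond the 3 of the trimannosyl core) are
  placed on LacNAc antennae, one Hex per antennal HexNAc; if ≥ 2 antennal
  HexNAc remain bare, a GalNAc-GlcNAc pair is possible.  The closed form
  `unoccupied = antennae − min(max(hex − 3, 0), antennae)` is proven in the
  tests against an oracle that enumerates every Hex-to-antenna assignment
  over the full grid hexnac ≤ 8, hex ≤ 10.
- **Family**: hexnac = 2 with hex ≥ 5 is high-mannose, hexnac = 2 with
  hex ≤ 4 is labeled paucimannose-or-core (rather than complex, to avoid
  claiming antennarity where none exists); anything else hybrid-or-complex.

Oxonium m/z uses monoisotopic residue masses fixed at six decimals
(HexNAc 203.079373, Hex 162.052824, Fuc 146.057909, NeuAc 291.095417,
NeuGc 307.090331) plus a 1.007276 Da proton.  [HexNAc₂+H]⁺ computes to
407.1660; published values of this diagnostic ion are sometimes printed as
407.1658 (a ~0.2 mDa discrepancy of unstated origin), well inside the
default 20 ppm (≈ 8 mDa at this mass) matching tolerance chosen for HCD
Orbitrap spectra.

## Quantification conventions

Redundant rows (same site and composition; different peptide, missed
cleavages or charge) are summed before normalization — peptide identity is
deliberately ignored after grouping.  Fractions are normalized per site with
the unglycosylated form in the denominator; this single denominator
convention makes occupancy and the mole ratios mutually consistent (a site
at 74.45% occupancy whose glycoforms average ~1.95 NeuAc reports
0.7445 × 1.95 ≈ 1.45 mol NeuAc/mol protein).  Mole ratios are
abundance-weighted counts; the unglycosylated form contributes zero.

Antennarity percentages rescale the bi/tri/tetra classes to 100 within each
site's multi-antennary pool; mono-antennary abundance is reported separately
and unrescaled, and zero-antenna glycans never enter the pool.  A site with
no multi-antennary glycan has an *undefined* distribution (`None`), not
zeros.  Aggregation: mole ratios add across N sites (each site contributes
its own moles per mole of protein), whereas percentages — already normalized
per site — are averaged unweighted; overall sialylation adds O-site mole
ratios to the N total and overall occupancy averages all sites.  Display
rounding (4 decimals for ratios, 2 for percentages) is applied only in the
table writer; all arithmetic and the structured JSON report keep full
precision.

Degenerate inputs: a site whose rows sum to zero abundance is an error (no
denominator); a site with only an unglycosylated row reports occupancy 0
and undefined antennarity; a table with no N site cannot be aggregated.

## Kinetics

µ is the OLS slope of ln(VCD) vs time; the exponential-phase window is
user-specified (indices or an inclusive range) because automated phase
detection is fragile on 10-point fed-batch series — the default uses every
sample with VCD > 0.  IVCD is the cumulative trapezium integral (exact for
piecewise-linear VCD; within 1% of the analytic exponential integral at a
step of one tenth of the growth timescale, verified in tests).  q_p
defaults to the regression slope of titer vs IVCD, which uses every sample;
the literal two-point quotient is available for comparability with reports
that define it that way.  Times are hours internally.

Titer conversion divides U/mL by a specific activity in U/µg (identity:
U/mL ÷ U/µg = µg/mL = mg/L), with optional nearest-integer display
rounding.  The specific activity is configurable (default 150 U/µg, the
WHO 3rd International Standard for erythropoietin) because published
activity-to-mass factors for EPO vary by assay and standard; the
µU/cell/day → pg/cell/day conversion is the same quotient (1 µU ÷ 1 U/µg =
1 pg).

## ddPCR

Copies per droplet follow the Poisson occupancy estimator
λ = −ln(1 − p̂) with p̂ the positive fraction; copies per reaction scale λ
by reaction volume / droplet volume (defaults 20 µL and 0.85 nL, the
typical droplet-generator geometry — configurable since instruments vary).
Saturated (all positive) and empty (none positive) wells raise typed
errors rather than returning ±∞.  Copies/ng divides by the input mass;
genomic copies per cell ratio a target against a reference locus of known
copy number (default 2, a diploid locus).  Fold changes against a
detection-limit baseline ("< x copies/ng") are returned flagged as lower
bounds; a literal zero baseline is an error unless flagged as such a bound.

## Synthetic data

The glycopeptide generator emulates the structure of a site-specific
glycoprofiling input for an EPO-like protein: per-site glycoform libraries
with true fractional weights, true occupancies (defaults: Asn24 and Asn38
fully occupied, Asn83 99.96%, Ser126 74.45%, matching published
site-occupancy estimates for HEK-derived EPO; the default glycoform
libraries are plausible sialylated core-fucosylated complex N-glycans plus
minor high-mannose/agalacto species and core 1 O-glycans), k redundant
features per species split by a symmetric Dirichlet(α = 1) draw (an
uninformative split that grouping must undo exactly), and multiplicative
lognormal(0, σ) noise on every feature abundance — XIC areas are positive
and right-skewed, so lognormal is the natural noise model; σ defaults
to 0.1.  The unglycosylated peptide is split across the same k features:
missed-cleavage redundancy applies to it exactly as to glycoforms, and its
occupancy estimate then benefits from the same feature averaging.  Ground
truth is computed by closed-form weighted sums straight from the
configuration, never through the grouping/normalization pipeline.

The culture generator produces VCD₀·e^{µt} (optionally capped at a
stationary ceiling) and sets titer = q_p × the *trapezium* IVCD of the
sampled VCD rather than the continuous integral: the package's estimators
operate on sampled series, so this makes noiseless recovery of q_p exact
by construction instead of carrying an irrelevant ~1% discretization bias
into every recovery test.  The droplet generator draws positives as
binomial(total, 1 − e^{−λ}).  All generators are bit-reproducible under a
fixed seed.

What the simulations do *not* emulate: retention times, spectra,
misidentified glycopeptides, in-source fragmentation (which biases real
occupancy estimates), charge-state-dependent ionization efficiency,
droplet "rain", or feeding-driven departures from exponential growth.
Passing recovery tests therefore demonstrate correctness of the arithmetic
under the stated statistical model, not robustness to those instrument
effects.

## Test problem sizes and tolerances

The recovery suites use: noisy glycopeptide tables at σ = 0.1 with 500
features per species — the per-species abundance error has standard
deviation σ·√(2/(k+1)) ≈ 0.63%, so three standard deviations of the
worst-case single-glycoform metric sit inside the 2% tolerance; 100 random
(µ, q_p, VCD₀) cultures with daily sampling over 10 days and 5% titer
noise against a 10% per-draw tolerance; and 200 replicate droplet wells of
10⁴ droplets per occupancy λ ∈ {0.05, 0.5, 2} against a 2% tolerance on
the mean.  All randomness is seeded; the full suite runs in well under a
minute.

## Known limitations

Composition-level inference cannot distinguish bisecting GlcNAc from an
antenna, cannot place fucoses structurally, and cannot detect α-Gal (which
is invisible in Hex counts); NeuGc presence is flagged but its linkage is
unknowable here.  Occupancy from XIC areas assumes equal ionization of
glycosylated and unglycosylated peptides.  The q_p regression assumes a
constant cell-specific rate over the fitted span.
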
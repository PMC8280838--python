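# Methods

## The triage model

The pipeline treats kinase–substrate discovery as a sequence of
conservative filters over localized phosphorylation events, each with an
explicit, recorded threshold. No p-values are computed anywhere: the
design is deliberately threshold-based, because the quantities being
compared (log-ratio depletion, time-course contrasts) are screened for
effect size, and confirmation is delegated to the downstream in vitro
peptide-array step that the shortlist feeds.

A site is identified by (gene symbol, 1-based protein position, residue);
multiplicity variants collapse to the best-localized record. Coordinates
are protein-relative throughout; there are no genomic coordinates. The
sequence context is a 15-mer window with the phosphoacceptor at index 7
(1-based character 8) and `_` padding at protein termini.

### SILAC screen

Reverse-orientation ratios are assumed reciprocal-corrected at ingestion,
so every stored value is log₂(DKO/WT). Two per-experiment depletion rules
are supported because the screen definition admits both readings:
`both_orientations` (each orientation strictly below θ = −1.5; the
default, and the stricter of the two) and `mean_of_orientations`. All
inequalities at thresholds are strict, matching the printed definitions
("< −1.5", controls "outside ±0.5", correlation "> 0.7"); boundary values
therefore never pass, and tests freeze that convention.

Label-bias exclusion uses the WT/WT control mixes: any control with
|log₂(WT/WT)| > 0.5 excludes the site from the combined call. Absence of
controls cannot exclude. The protein-level-change flag (≥ 3 detected
sites, ≥ 80 % of them depleted) is a caution annotation only — the
phenomenon it captures (uniform depletion across a protein's sites with
divergent windows, indicative of abundance change) is handled
definitively by the conservation filter later, so flagged sites are never
removed at this stage. The 3/0.8 defaults are heuristics; the underlying
observation is qualitative and the values are configurable.

### Motif engine

The motif grammar implements the bracket/brace notation with juxtaposed
groups at one position read as conjunction. Position 0 is auto-detected
as the first group whose allowed set is within {S, T}; fragments without
such a group require an explicit anchor. The pad character `_` fails
every allowed-set constraint (an unknown residue cannot be shown to
conform) but passes forbidden-only positions (it is demonstrably not the
forbidden residue). With position-0 allowed = {S, T}, tyrosine sites can
never match — the matcher needs no special-casing of the acceptor.

Enrichment matrices use value(a, p) = log₂((f_fg + ε)/(f_bg + ε)) with
pseudocount ε = 0.01 by default; pads are excluded from the per-column
frequencies, so truncated windows contribute only their observed
positions. The background set for logos defaults to all detected sites of
the same screen (the natural null for "what is special about depleted
sites"); the choice is configurable because no canonical background
exists. Matrix rendering is a cosmetic matplotlib heatmap behind an
optional extra and is untested.

### TMT screen

The ten conditions are always ordered WT(0, 10, 30, 60, RF) then
DKO(0, 10, 30, 60, RF); this matters because V4 is a Pearson correlation
over the concatenated vector and correlation is order-sensitive across
segments. Only profiles positive in all ten conditions are triaged.
Three normalizations are provided; V1–V3 are identical between
`log10_raw` and `anchored_to_DKO0` modes because the anchor cancels in
differences. The `relative_log2` mode satisfies Σ 2^value = 10 exactly
(to floating point) and is the heat-map normalization.

θ₁ = θ₂ = θ₃ = 0.1 log₁₀ units (≈ 26 % intensity change) are the default
contrast thresholds. No principled value exists for them — the original
procedure set them by inspection — so they were fixed once against the
synthetic generator's default noise level (0.05 log₁₀ units per
condition, at which 0.1 is two condition-level standard deviations) and
are fully configurable. V4 uses all ten conditions by default
(`r_min = 0.7`, strict). Profiles with zero variance have undefined V4
and can only be tier `none`.

Correlation clustering is hierarchical agglomerative with distance
1 − r and average linkage, cut at k = 6 clusters by default. Flat
profiles (variance below 1e-9) are set aside in a dedicated cluster
labelled 0 rather than entering a correlation distance that is undefined
for them. Determinism and input-order invariance are obtained by
canonicalizing row order by site_id before computing the linkage and by
relabelling clusters (size-descending, then smallest member id). By
default the pipeline clusters the 3,000 most variable profiles — the
global pattern survey does not need every flat profile, and the distance
matrix stays small; ties in the variance ranking break by site_id.

### Shortlist

Shortlist rule: (combined_depleted ∧ tier ∈ {primary, similarity_only})
∨ manual inclusion, with manual exclusion dominating. Manual curation is
a config list of site_ids with free-text reasons — reproducible curation
rather than automated judgement; the shipped default is empty. Every
decision writes the rule that fired into the audit log, and reruns are
byte-identical.

Conservation identity is the fraction of aligned non-pad positions at
which the mouse and human 15-mers agree; pads are excluded from both
numerator and denominator, making the measure symmetric. A site is
dropped when identity < 0.6 (no number exists for "particularly low
conservation"; 0.6 is the package's default and configurable) or when
the human window has lost the central S/T. Sites without an ortholog
pair are left untouched: unknown conservation is not evidence against.

PPI distance is the BFS shortest path to the nearer of ULK1/ULK2
(networkx); it annotates (`within 2 nodes` flag) and never filters.

Peptide variants per shortlisted site: WT (human sequence when an
ortholog window is available), single S/T→A at the centre, total S/T→A
only when the window carries further phosphoacceptors (otherwise it
would duplicate the single mutant), and the murine window only when it
differs — up to four variants. Control peptides are appended verbatim
from configuration.

## Synthetic generator

The generator is first-class, tested code and defines the study
conditions: ~10,000 sites over 2,000 proteins (1 + Poisson(4) sites per
protein), 5 true substrates per 1,000 sites, SILAC noise 0.4 log₂ units
per orientation, control noise 0.15, TMT noise 0.05 log₁₀ units per
condition, 10 % site×experiment SILAC missingness and 5 % incomplete TMT
profiles. Amino-acid backgrounds are uniform over the 20 residues
(analytically tractable: the motif-positive rate of null windows equals
the product of per-position acceptance probabilities, which tests check
binomially); acceptor residues are drawn S/T/Y at 65/25/10 %.

Planted classes and their rationale:

- **true_substrate** (0.5 % of sites): motif-conforming windows; a shared
  site effect drawn from a normal (mean −2.5, sd 0.3 log₂) *truncated
  above at −1.8*, applied to both orientations of all three experiments
  with independent orientation noise. The truncation encodes that the
  planted class is "highly depleted" by construction — every planted
  substrate is genuinely below the −1.5 threshold, so the noiseless
  depleted set is exactly the planted set. TMT dynamic: WT rises
  0/0.1/0.25/0.4 log₁₀ over the starvation course, refeed returns to
  +0.1, DKO flat at −0.3 below baseline (the reference-substrate
  pattern).
- **label_bias** (1 %): same apparent DKO/WT depletion, but WT/WT
  controls pushed outside the ±0.5 band (magnitude 0.6 + |N(0, 0.2)|,
  sign alternating across experiments). These must be caught by the
  control exclusion, never by the depletion rule.
- **protein_level** (0.5 % of proteins): one common depletion offset for
  all sites of the protein, non-motif windows, and divergent human
  ortholog windows (9 of 14 flank positions randomized → identity ≈ 0.4)
  so the conservation filter removes them downstream. Their TMT profile
  shows basal DKO deficit without starvation dynamics — they correlate
  with the reference and legitimately reach the similarity tier, which
  is precisely why the conservation step exists.
- **proline_background** (15 %): +1-proline windows with a starvation
  response that is ULK-independent and opposite in sign in both
  genotypes (dephosphorylated on starvation, recovering on refeed — the
  canonical nutrient-signalling counter-pattern). A same-sign
  ULK-independent response would correlate > 0.7 with the reference over
  the concatenated conditions and be indistinguishable from a substrate
  by V4 alone; the opposite-sign choice keeps this class a pure
  background for the triage-recovery tests.
- **null**: centred noise in both screens.

A noiseless reference control site `Prkab2_S38` carrying the exact
substrate template is always planted so the default similarity reference
resolves in-table. Its window is synthetic — generated to conform to the
motif, not the real Prkab2 sequence.

`GeneratorConfig.noiseless()` zeroes all measurement noise *and*
missingness: "zero noise" is read as a perfect measurement process, under
which recovery must be exact. One integer seed drives a single
`numpy.random.Generator`; identical seeds give byte-identical tables.

### What the generator does not emulate

Intensity-dependent missingness, TMT ratio compression, peptide-level
ambiguity (each site is one row), correlated noise between orientations
beyond the shared site effect, realistic amino-acid composition, and
protein-length distributions. Passing recovery tests therefore
demonstrate the correctness and calibration of the filtering logic under
the modelled confounders, not performance on real spectra-derived
tables.

## Numerical choices

- Threshold comparisons are strict everywhere a printed definition is
  strict; documented per-operation.
- Float columns round-trip exactly: tables are written with shortest
  repr and re-read with exact (`float()`-based / round_trip) parsing, so
  write∘read∘write is byte-identical.
- Correlation distances are clipped to [0, 2] before linkage to absorb
  floating-point excursions beyond ±1.
- Degenerate inputs: missing orientation → per-experiment call
  `incomplete` (not an error); no controls → cannot exclude; constant
  reference profile → hard error (correlation undefined); non-positive
  intensity under a log transform → hard error naming the condition.
- Problem sizes in the shipped tests and acceptance script: full
  ~10,000-site screens for the SILAC/TMT recovery checks, a ~2,000-site
  screen for the end-to-end determinism check, 10⁵ random windows plus
  the 46,656-case exhaustive reduced-alphabet sweep for the motif
  oracle. These sizes give binomial error bars comfortably inside the
  asserted margins.

## Known limitations

- The dialect map covers column renaming only; search-engine exports
  with per-multiplicity ratio columns need flattening upstream.
- The conservation step requires a precomputed ortholog window-pair
  table; no ortholog inference is performed.
- The similarity reference must be a complete profile in the analysed
  table (or supplied externally); there is no fallback template when it
  is missing.
- Tier assignment is threshold-based by design; users wanting error
  control should treat the shortlist as candidates for orthogonal
  confirmation, which is the intended use.
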
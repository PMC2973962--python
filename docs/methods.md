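# Methods

## Model and procedure

The object of study is the *ambivalent* (chameleon) α-helix: a peptide
sequence that is fully helical in one protein chain while an identical copy
of it elsewhere is partly or wholly non-helical. The pipeline operates on
two chain databases — a *query* set supplying helices and a *target* set
supplying the mapped copies — each chain carrying a one-letter sequence, an
8-state DSSP secondary-structure string, an optional per-residue absolute
solvent accessibility (Å²), and structure metadata.

Stages, in execution order:

1. **Quality filter.** Keep X-ray chains with resolution ≤ 3 Å and
   R-factor ≤ 0.3 (inclusive at both thresholds; chains lacking a value are
   dropped while the corresponding filter is active). Both databases are
   filtered identically.
2. **Binarization and extraction.** DSSP codes H and G are helical; B, E,
   I, S, T, `-` are not. Binarization precedes run-finding, so a run mixing
   H and G is one helix. Maximal runs of length ≥ 5 become helix segments;
   shorter runs are discarded. Segments containing a non-standard residue
   (`X`) are extracted but excluded from mapping and from all residue
   counts.
3. **Exact mapping.** For each helix (length *N*) and target chain (length
   *M*) the reference algorithm forms the *N*×*M* Boolean match matrix and
   reports every start *l* whose length-*N* diagonal sums to *N* — i.e.
   every verbatim occurrence, overlapping ones included; nothing is
   deduplicated. The production path uses a 5-mer index with full
   verification, contractually identical to the matrix algorithm (property-
   and acceptance-tested against it). By default occurrences in chains of
   the helix's own structure are excluded (`exclude_self`), since
   self-matches would contribute tautological 0 %-shift occurrences.
4. **Shift, bin, class.** Per occurrence, shift = 100 × (non-helical
   positions)/*N*, computed over the mapped window only — flanking context
   never enters the shift. Per helix, the bin is the decade of the maximum
   shift with left-open/right-closed decades: bin 0 iff max = 0, else
   10·⌈max/10⌉. Classes: CONSERVED (max 0), VARIABLE (≥ 1 occurrence at
   exactly 100), PARTIAL otherwise, UNMAPPED if no occurrence. Fold/domain
   concordance is the fraction of a helix's occurrences whose target chain
   shares the query chain's SCOP label, computed only when labels exist on
   both sides.
5. **Conformational parameter.** CP_ij = (n_ij/Σn_ij)/(N_i/ΣN_i). The
   background N_i is the residue composition of the *entire* filtered query
   database, not only its helical residues. Zero-background residues yield
   an absent CP, never an infinity. Every emitted table satisfies
   Σ_i f_i·CP_i = 1 (f_i the background fraction) to 1e-9; this identity is
   asserted in the acceptance suite.
6. **Residue groups.** Conformation-class tables use: conserved-helix
   residues; variable-helix residues in their helical (query) conformation;
   and the residues of their fully non-helical occurrences, counted once
   per occurrence (configurable to once per unique sequence — per
   occurrence is the default because the mapping stage is
   occurrence-centric). Per-bin tables pool the query-helix residues of
   each bin; occurrence residues are not pooled there, a deliberate choice
   where either convention is defensible.
7. **Flanks.** Up to four residues immediately preceding (N) or following
   (C) a helix or occurrence, truncated at chain ends; `X` is kept in the
   flank string but never counted. Six populations are analysed: {N, C} ×
   {helical conformation of variable helices, their 100 %-shift
   occurrences, conserved helices}.
8. **Accessibility.** RSA = ACC / max-ACC(residue) with per-residue maxima
   for an extended Gly-X-Gly tripeptide. The embedded default is the
   theoretical scale of Tien, Meyer, Sydykova, Spielman & Wilke (2013),
   *PLoS ONE* 8:e80635; any two-column TSV can replace it. Values above
   the maximum (which DSSP occasionally produces) are capped at 1.0 and
   counted. Flank means are averaged over usable residues and histogrammed
   in width-0.1 bins over [0, 1] (configurable); fractions sum to 1 per
   class.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `max_resolution` | 3.0 Å | inclusive resolution cutoff |
| `max_r` | 0.3 | inclusive crystallographic R-factor cutoff |
| `min_helix_length` | 5 residues | shortest helix retained |
| `flank_width` | 4 residues | flank window on each terminus |
| `exclude_self` | true | drop occurrences in the helix's own structure |
| `rsa_bin_width` | 0.1 | RSA histogram bin width |
| length-class breaks | 9, 14, 19, 29 | upper edges for the length-vs-shift table (the natural short/medium/long split around the ≤ 15-residue regime where switching is commonest; fully configurable) |

## Synthetic databases

The generator emulates the *structure* of a real database pair: each plant
specifies a helix length, its number of target occurrences and their
shifts, optional residue/flank sampling biases and SCOP-label agreement
flags. Per plant it emits one query chain (planted segment fully helical,
embedded in non-helical random context with biased four-residue flanks) and
one target chain per occurrence, with ⌊s·N/100⌉ (round-half-up) positions
re-annotated non-helically — contiguously from the C-terminal end by
default, mimicking fraying, with N-terminal and scattered options. A
requested shift that rounds to 0 or to N positions is rejected as
infeasible because it would silently change the planted class. Non-helical
codes are sampled uniformly from {B, E, I, S, T, -}, exercising the
binarization rule without affecting ground truth. Accessibilities are
Beta-sampled per region (helix, occurrence, flanks, context) and scaled by
the residue's Gly-X-Gly maximum, so N/C accessibility contrasts can be
planted. After generation, every planted sequence is scanned against both
databases; accidental extra occurrences trigger bounded regeneration
(default 20 attempts) and otherwise a hard error. All randomness flows
from a single integer seed; identical seeds reproduce the written tables
byte for byte.

What the generator does **not** emulate: evolutionary sequence statistics,
realistic secondary-structure grammars, sequence redundancy, chain breaks,
or correlated accessibility along the chain. Passing tests therefore
demonstrate correctness of the bookkeeping and statistics (exact shift
recovery, unbiased composition estimates, terminus separation), not that
real databases will show any particular effect size.

## Numerical and design choices

- Coordinates are 0-based half-open internally and 1-based inclusive in
  every file and report.
- Binning uses exact float comparison against decade edges; shifts are
  rational numbers k/N·100 so no tolerance is needed. Non-integer shifts
  (N not dividing 100) use the same ceiling rule.
- The chain-table format serializes floats with `repr`, which round-trips
  exactly; the round trip is byte-stable and tested.
- DSSP files carry no resolution/R-factor/method metadata, so chains read
  from DSSP default to method OTHER with absent resolution — callers either
  pass overrides or relax the filter. Chain-break rows split chains by
  default (configurable), and split segments get `/2`, `/3`… chain-id
  suffixes to keep keys unique; how breaks inside a crystallographic chain
  should interact with mapping is genuinely open, and splitting is the
  conservative choice (a mapped window never spans a gap).
- Helices equal to an entire chain, empty flank windows at chain ends, and
  empty bins/classes are all handled as absent rather than errors.
- Problem sizes in the test and acceptance suites (a six-plant standard
  design; 1000 random mapper instances; 10,000 residues per enriched
  group) were chosen as the smallest sizes at which exact checks are
  exhaustive and statistical checks have comfortable power at ±3 MC SE.

## Known limitations

- Mapping is exact-match only; no tolerance for substitutions, hence no
  treatment of near-identical chameleon pairs.
- Concordance uses chain-level SCOP labels; a chain spanning several
  domains is represented by whatever single label the input provides.
- The structure-quality filter cannot recover metadata the input lacks; a
  database without R-factors filters to empty under default settings.
- CP values for rare residues in small groups are noisy; the package
  reports raw CP without confidence intervals.
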
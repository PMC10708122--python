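# Methods

## The analysis in brief

Formaldehyde crosslinks two tryptic peptides; in MS the pair appears as one
precursor whose mass is the sum of both peptide masses plus a crosslink
mass class CM of +12 Da or +24 Da. The pipeline (i) computes theoretical
precursor and fragment m/z for candidate pairs, (ii) schedules each
(pair, charge) precursor as a PRM target in a six-minute retention window,
(iii) builds per-transition extracted ion chromatograms and passes them
through a strict filter cascade, (iv) accepts a precursor only when enough
independent transitions survive somewhere in the cohort, and (v) compares
validated crosslinks across the four blood-collection conditions
(Streck S, formaldehyde F, EDTA E, allantoin A) over three donors.

## Mass conventions

- Monoisotopic residue masses (pyteomics' standard table); water
  18.010565 Da; proton 1.007276 Da.
- Carbamidomethyl (+57.02146 Da) is a fixed modification on every
  cysteine, reflecting iodoacetamide alkylation during sample preparation.
- The crosslink mass classes are taken as exactly 12.000 and 24.000 Da
  (one and two carbon atoms). The +24 Da adduct's chemical identity is not
  settled in the literature; two bare carbons are a convention, chosen
  because they reproduce the packaged roster's calculated m/z values to
  4 decimals (worst deviation 5·10⁻⁵ Th over all 57 entries).
- Variable modifications (Met oxidation, N-terminal acetylation) are not
  applied: the roster's calculated values are reproduced without them, and
  transition math stays unambiguous.

## Transition generation

For each peptide of a pair, all b and y ions with fragment index from 3 to
L−1 (b_L/y_L equal the precursor and are excluded) at fragment charges 1–2,
each emitted twice: with and without a flat +CM mass. Only linear fragments
of each constituent peptide are enumerated — fragments carrying the intact
partner peptide are deliberately out of scope, since the flat ±CM variants
are what the validation monitors. Fragments shorter than 3 residues are
omitted at generation because they are poorly sequence-specific; the
stricter index ≥ 5 rule is applied later, at validation, so both published
stages of filtering act where they belong. Pairs containing a peptide
shorter than 7 residues produce a flagged-excluded, transition-less target
rather than being dropped silently, so exclusion reports can enumerate
them.

## The validation cascade

Defaults (all exposed in `FilterConfig`):

| parameter | default | meaning |
|---|---|---|
| rt_window_min | 6.0 min | scheduling window centered on the expected RT |
| extract_ppm | 10 ppm | XIC construction tolerance |
| min_fragment_index | 5 | b/y index must be > 4 |
| min_peptide_len | 7 | both peptides at least 7 residues |
| noise_floor | 3000 counts | trace apex must strictly exceed this |
| accept_ppm | 1 ppm | mass accuracy at the trace apex |
| min_transitions | 5 | surviving transitions in ≥ 1 cohort sample |

Decisions where the procedure was underdetermined:

- **Apex-based thresholds.** The noise-floor and the 1 ppm rule are
  evaluated at the trace apex (a per-point noise rule would annihilate
  every baseline; the apex is the natural signal-level test). The measured
  m/z at the apex is the intensity-weighted mean of the peaks inside the
  extraction window.
- **Extraction wider than acceptance.** XICs are built at 10 ppm but
  accepted at 1 ppm: the deviation can only be measured if the extraction
  window is wider than the acceptance bound.
- **Area.** Peak area is the trapezoidal integral of a surviving trace
  over the whole window. Multiple chromatographic peaks inside one window
  are not split; peak picking/deconvolution is out of scope.
- **Cohort acceptance.** A precursor failing everywhere is rejected in all
  samples; once any sample reaches 5 surviving transitions, every sample
  reports its own surviving count and area. Boundary conventions: a trace
  apex of exactly 3000 counts fails; exactly 5 surviving transitions pass;
  a candidate confidence ratio of exactly 1.5 fails (strict inequality).
- **Donor averaging.** Missing donor samples enter the group mean as zero
  area (configurable), keeping group means comparable across conditions.
- **Per-sample counting.** "Validated crosslinks per sample" counts
  precursor ions (before charge merging) with ≥ 5 surviving transitions in
  that sample, matching how the per-condition counts are usually reported.

## Discovery-stage pre-filters

- Precursors with neutral mass > 8000 Da — computed as
  (m/z − m_H)·z, i.e. on mass, not m/z — are removed.
- A spectrum is condition-unique if no spectrum of another condition
  matches it within 0.01 Th precursor m/z, identical charge and 2 min RT.
  These tolerances are a documented convention (the matching criteria are
  not standardized anywhere); they are exposed as parameters.
- Crosslink candidates are kept when matched-fragment-count divided by the
  summed peptide length exceeds 1.5, strictly.

## Group statistics

One-way ANOVA across the four conditions on per-sample validated counts
(n = 3 per condition), followed by Tukey HSD for all six pairwise
comparisons (scipy's implementations), with significance tiers at p ≤ 0.05
and p ≤ 0.0001. When every group is internally constant the F statistic is
0/0 or infinite; the report is flagged `degenerate` and uses the limit
semantics — equal constant groups are not significant (p = 1), perfectly
separated constant groups are significant at any level (p = 0). This case
occurs routinely in simulated cohorts where all S/F samples recover every
target and all E/A counts coincide.

The heatmap scales each pair's donor-averaged areas by the row maximum
(all-zero rows stay zero), columns ordered F, S, E, A; z-scoring is
available as an alternative mode.

## The synthetic cohort

The generator's defaults are the emulated study conditions, not tuning
knobs:

- Roster: all 57 (pair, charge) precursors of the packaged table, plus 10
  decoys. Decoys are residue-shuffled copies of roster pairs; because
  shuffling preserves mass (the decoy would co-isolate with its source and
  could share fragment masses through suffix/prefix composition
  coincidences), the first residue is additionally substituted with
  tryptophan so decoy precursor and fragment masses detach from every real
  target. Nothing is injected at decoy transitions.
- Group intensity multipliers S = F = 1.0, E = A = 0.05; per-pair base
  apex lognormal around 40 000 counts (cv 0.25), per-sample donor factor
  cv 0.10, per-transition relative abundance uniform on [0.3, 1.0]. With
  these levels S/F transitions sit far above the 3000-count floor while
  E/A signals mostly fall below it — the "present in S/F, largely absent
  in E/A" phenomenology.
- Chromatography: Gaussian elution, sigma 0.1 min; scan interval 2 s; RT
  jitter sigma 0.05 min per (pair, sample). These make a full 12-sample
  cohort generate in seconds.
- Noise: 20 uniform-m/z peaks per scan with Exponential(mean 1000 counts)
  intensities. Interference: 8-fragment co-isolating peptides on the first
  5 targets, apex 20 000 counts, eluting 0.8 min after the target, present
  in every condition.
- Fragment m/z are perturbed by N(0, 0.3 ppm); mass errors beyond 1 ppm
  (rare at this sigma) make a transition legitimately undetectable, and
  the ground truth records that.

**Exact ground truth.** Noise and interference m/z are drawn at least
25 ppm away from every monitored transition, so only injected signal can
enter a 10 ppm extraction window. Ground-truth detectability then mirrors
the cascade arithmetic on the noise-free injected peaks — including
cross-contributions between isomeric precursors that share an isolation
target (the packaged roster contains one such pair) and between a target's
own transitions that happen to lie within the extraction tolerance of each
other. End-to-end tests can therefore demand exact set equality between
validated and injected-detectable precursors, and zero decoy acceptance,
rather than statistical agreement.

What the simulator does **not** model: isotope envelopes, chimeric
fragmentation, detector saturation, RT drift between runs, correlated
noise, and real co-isolation interference *on* the monitored m/z values.
Passing end-to-end tests therefore demonstrates the correctness of the
filter arithmetic and bookkeeping under the stated signal model, not
robustness to every artifact of real chromatography.

## DDA simulation

Each real roster pair yields one spectrum assigned round-robin to S or F;
background spectra are identical across all four conditions. The expected
outcome of the condition-uniqueness filter is computed from the injected
spectra themselves, including the near-isobaric co-eluting roster pairs
that are condition-shared by definition when assigned to different groups.

## File formats

MGF via pyteomics (with a structural pre-check that reports unbalanced
BEGIN/END IONS blocks by line number). mzML reading and writing use the
package's own minimal implementation (plain mzML 1.1.0, 64-bit float
arrays, isolation-window targets, scan times in minutes; the reader also
accepts 32-bit floats, zlib compression and seconds). A long-format TSV
("chromatogram table") is the default light-weight medium for PRM runs in
tests. Crosslink rosters, candidate tables and all result tables are TSV.

## Known limitations

- The +24 Da composition is a convention (see mass conventions).
- The uniqueness-filter key and the XIC extraction tolerance are
  conventions exposed as parameters, not published constants.
- `group_unique_spectra` is an all-pairs comparison; it is intended for
  filtered candidate sets, not for full-depth shotgun runs.
- Protein annotations are carried as fixture metadata; no sequence-database
  inference is performed.
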
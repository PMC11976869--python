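# Methods

## Digestion model

Digestion is modelled as deterministic, fully specific cleavage: a rule is
a residue set plus a terminus (C or N), and a cut exists at every
inter-residue bond adjacent to a matched residue, except at the protein
termini (a terminal matched residue contributes no cut, which would
otherwise create zero-length products). Cut positions are 0-based
inter-residue offsets internally; reported peptide coordinates are 1-based
inclusive, the convention of proteomics tools. An optional proline block
suppresses a cut when the residue C-terminal to it is proline; it is off by
default in every preset because the simulated rules are stated as bare
residue sets. Nonstandard residues (X, U, B, Z, O) are tolerated in
sequences but never match a rule unless explicitly listed, so unknown
residues cannot create cuts.

Peptides are enumerated as windows over consecutive cut points: with `s`
internal sites and a missed-cleavage cap `k`, the unfiltered count is
`Σ_{j=0..min(k,s)} (s+1−j)`. Default criteria are ≤ 2 missed cleavages and
lengths 6–60 residues; a 7–30 window (`SEARCH_STYLE`) mirrors common
database-search settings. Peptides are counted as positional occurrences;
proteome-wide distinct-sequence counts are reported alongside, because
"number of peptides" is ambiguous between the two and the conservative
occurrence-level reading is the default numerator in ratios. Semi-specific
digestion, PTMs, masses and protease kinetics are out of scope.

GluC is shipped in two variants: `gluc` with the conventional Glu (E)
specificity and `gluc_paper` with the F/Y/W/I residue set that has also
appeared in print for this enzyme; the package takes no position between
them — the choice is the caller's.

## Complexity metrics

Coverage is protein-level presence (≥ 1 passing peptide), not residue-level
sequence coverage. Medians of peptides-per-protein are taken over **all**
database proteins, zeros included — the literal per-protein statistic over
the database; the per-protein table is emitted so the zeros-excluded
convention can be recomputed. Ratios are pairwise against a named
reference, trypsin by default. `relative_complexity` refuses mismatched
protein universes and a zero-peptide reference; a zero reference *median*
yields NaN rather than an error, since sparse digests legitimately produce
it.

## Identification statistics

* Confidence filtering keeps rows with q-value strictly below the
  threshold (default 0.01).
* CVs use the sample (n−1) standard deviation over raw abundances;
  a log-scale option exists. Protein-level CVs sum peptide abundances
  within (protein, replicate) first; peptide-level CVs are exposed because
  figure conventions differ between panels in published work. With 3
  replicates the per-protein sample CV is biased low (the sample sd scales
  as a chi(2) variate: median ≈ 0.83 × truth); recovering a generative CV
  therefore uses the pooled root-mean-square CV, whose square is the
  ~unbiased variance estimate.
* "Proportion quantified" means complete: a peptide counts as quantified
  only with a non-missing abundance in every replicate of the condition —
  the strictest reproducible reading of an undefined term.
* Rank-abundance tables rank by decreasing mean abundance with
  lexicographic accession tie-break, so outputs are deterministic.
* The "rank-uniformity" question — do proteins unique to a condition sit
  inside the bulk abundance distribution or at its edge? — is answered two
  ways, and reports label which ran: a one-sample KS of mid-rank fractions
  `(rank−0.5)/n_total` against Uniform(0,1), and a two-sample KS of
  unique-protein abundances vs all abundances. The wording in the
  literature supports either; the package refuses to silently pick one.
* Tests wrap scipy.stats. Exact modes: one-sample KS for n ≤ 10 (else the
  asymptotic Kolmogorov distribution), two-sample KS by scipy's automatic
  exact/asymptotic switch (the exact mode matches permutation enumeration
  at small n), Mann-Whitney U exact for both n ≤ 10 (average ranks on
  ties; the asymptotic branch applies continuity and tie corrections),
  Welch t with Welch–Satterthwaite df. No multiple-testing correction is
  applied; p-values are reported raw with the number of tests logged,
  matching the single-pairwise-test setting they serve.

## Synthetic-data generator

The generator emulates the statistical structure the analysis consumes,
not mass spectra:

* **Proteome** — residues i.i.d. from a configurable composition
  (default: human proteome averages, e.g. K 5.7%, R 5.6%, L 10%); lengths
  log-normal with median 375 residues and log-sd 0.8, approximating the
  human protein-length distribution (right-skewed, mean ≈ 515).
* **Abundances** — log10-normal. The scale is calibrated from the sample
  size via the Blom approximation to the expected extreme order statistic,
  so the *realised* log10(max/min) spans the target dynamic range
  (default 6 orders of magnitude, the within-cell range between the most
  and least abundant proteins).
* **Observation** — each protein's abundance is split equally among its
  zero-missed peptides; missed-cleavage products get that share scaled by
  0.3 per missed site (exposed as `missed_share_factor`; no peptide-level
  intensity model exists to fit, so the simplest conserving choice is
  used). Replicate noise is multiplicative log-normal at the target CV
  (log-sd `sqrt(ln(1+cv²))`, so the noise CV equals the parameter exactly)
  and is **shared across a protein's peptides within a replicate** —
  emulating sample-handling variation that moves the whole peptide
  complement together, and making protein-level CV recovery well-posed;
  independent peptide-level noise can be added on top. Detection is an
  independent Bernoulli per (peptide, condition, replicate) with logistic
  probability in log10 parent abundance — a deliberately simple stand-in
  for DDA's intensity-biased precursor sampling, clearly labelled as such.
  q-values are a two-component mixture (default 5% of rows above 0.01);
  no decoy/FDR machinery is simulated because the pipeline only consumes
  thresholded q-values.

**What passing tests do and do not show.** The generator's sequences are
i.i.d. per residue. Real proteomes cluster K/R, contain low-complexity
regions and bias the composition of short proteins; consequently the
LysC/trypsin peptide ratio on the synthetic database is ≈ 0.47, whereas
real human databases give a lower ratio (< 0.40). Tests on synthetic data
validate the *machinery* (enumeration, aggregation, statistics, recovery
of generative parameters), and the < 50% and ≥ 98%-coverage properties do
transfer; the exact ratio on a real database must be measured on that
database (`monodigest profile <uniprot.fasta>`).

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; identical models and seeds give byte-identical outputs.
* Calibration checks (type-I error within the 95% binomial interval at
  α = 0.05) run each test in its asymptotically valid regime: 200 ranks of
  4,000 for KS uniformity, 30 vs 30 for Wilcoxon, 10 vs 10 for Welch.
  Outside these regimes the tests are *conservative*, which is a property
  of the tests, not a defect: Welch at 3 vs 3 has true type-I ≈ 0.036, and
  the asymptotic KS p at n = 50 rejects at ≈ 0.035.
* Problem sizes for the from-scratch reproduction script: 2,000-protein
  synthetic database for complexity ratios (ratios are stable to ±1 point
  across seeds at this size), 500 proteins × 3 replicates for CV recovery,
  1,000 null replicates per calibration estimate.
* Degenerate inputs: empty proteomes, empty rank lists, sub-2 samples and
  all-zero-variance t inputs raise `ValueError`; an all-constant,
  equal-mean t comparison returns (0, 1) as the natural limit.

## Known limitations

* No spectrum, retention-time, chromatography or isobaric-labelling
  modelling; the detection curve is phenomenological.
* Protein grouping/parsimony is assumed done upstream; input tables are
  taken at face value.
* The i.i.d. sequence model understates real-proteome complexity
  reduction, as quantified above.
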
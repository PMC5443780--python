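# Methods

## The identification model

The unit of identification is the open reading frame (ORF) called from a
community transcriptome assembly: any span beginning with ATG and ending
at an in-frame stop codon whose coding length (start codon through last
sense codon, stop excluded) exceeds 300 nt. Since coding length is a
codon multiple, the effective default minimum is 303 nt / 101 aa. The
boundary is configurable (`min_orf_nt`, default 301) so the variant that
counts the stop codon in the length is one setting away. Both boundary
codons are required — ORFs running off contig ends are not reported.
By default only the longest ORF per (strand, frame, stop codon) is kept;
`longest_per_stop=False` reports every qualifying ATG. Longest-per-stop
is the common proteogenomics choice: nested starts produce near-duplicate
proteins and ill-defined emPAI denominators. Coordinates are 0-based
half-open on the forward strand regardless of ORF strand; codons
containing any non-ACGT letter translate to 'X' and never act as start
or stop.

### Two-round search

Round 1 deliberately uses a *more permissive* search space than the ORF
definition: all six-frame stop-to-stop fragments of at least 7 aa,
including contig-edge fragments with no ATG. Round 1 exists only to
attribute spectra to contigs, so sensitivity matters and strictness does
not; round 2 then enforces the strict ORF rule on the matched contigs
only and re-searches the original spectra. A protein is reported only
when at least one accepted peptide maps to its ORF (`min_peptides`
raises the bar). Proteins with identical peptide sets collapse into one
group represented by the lexicographically smallest ORF id; groups whose
peptides are all shared with other groups are kept but flagged
`shared_only` so downstream counts can include or exclude them.

### Scoring and calibration

The matcher is not a Mascot re-implementation and does not aim for score
parity; the workflow's contract is the acceptance rule, *peptides with
expect ≤ 0.05*. Candidates are peptides whose neutral mass lies within
10 ppm of the observed precursor neutral mass; the score is the number
of theoretical singly charged b- and y-ions (modifications applied)
matched by any observed peak within ±0.1 Da, each theoretical ion
counted once. Tie-breaking for rank 1 is total: score, then |ppm error|,
then peptide sequence, then parent id — identical inputs give
byte-identical PSM tables.

Decoys are pseudo-reversed tryptic peptides (sequence reversed, the
C-terminal K/R kept in place) so the decoy mass distribution matches the
targets. The expect of a PSM scoring s is the empirical decoy exceedance

    expect(s) = (1 + #{best decoy score per spectrum ≥ s}) / (1 + N_null)

stratified by precursor charge. The null observation for each spectrum
is its best decoy score — a separate decoy competition — which yields a
stable null even when decoys rarely win rank 1 outright. Strata with
fewer than 50 null observations pool across charges; if the pooled null
is still smaller the engine falls back to a Poisson model of the decoy
score with the mean null score as rate (floor 0.25) and logs a notice.
Accepted = rank-1 target with expect ≤ 0.05.

### Quantification

emPAI = 10^(N_observed/N_observable) − 1. N_observed counts *distinct
peptide sequences* (modified forms of one sequence count once, which is
standard emPAI practice and robust to modification-search breadth).
N_observable counts distinct fully tryptic peptides (≤ 1 missed cleavage
by default) of length 6–40 whose m/z falls inside the acquisition window
150–2000 Th at some charge in {2, 3, 4} — an acquisition-window proxy
for the retention-time-based observability of the original formulation,
mirroring an instrument that excludes singly charged precursors. Molar
percentage normalises emPAI by the emPAI sum of the same
(sample, fraction, replicate) run; "per sample" is read as per LC-MS/MS
run, which is what per-column heatmap values require.

Masses: monoisotopic residue masses frozen as constants (cross-checked
against an independent calculator in the test suite), water 18.010565,
proton 1.007276, carbamidomethyl +57.021464 fixed on C, oxidation
+15.994915 on M and deamidation +0.984016 on N/Q variable, capped at 3
variable modifications per peptide to bound the search space.

### Consensus, fractions, clustering

A protein is *consensus* when identified in every biological replicate
of its sample, in any fraction. "Present in a fraction" then means
identified there in at least one replicate; the stricter
`per_fraction=True` variant requires the fraction itself to be seen in
every replicate. The Venn identity n_BF + n_SNT − n_shared = n_total is
asserted on construction.

The clustering summary z-scores each protein row of the molar-percentage
matrix (sample standard deviation, ddof = 1; constant rows become zeros;
missing protein–run cells are 0 before scaling), clips to [−2, 2] *for
display only*, and clusters run columns by average-linkage (UPGMA)
agglomeration on Euclidean distances of the unclipped scaled columns.
Columns are sorted by label before linkage so distance ties break
deterministically. The dendrogram is serialised as Newick with labels
quoted where needed. Plain column-bootstrap support fractions are
available (`bootstrap_column_support`, default 1000 resamples);
approximately-unbiased multiscale-bootstrap p-values are intentionally
out of scope.

### Annotation and classification

External predictors are consumed, never run: BLASTP outfmt-6 (best hit
per protein at E ≤ 1e-20; the taxon string is the bracketed organism in
the subject title), hmmscan domtblout for dbCAN (domain i-E-value;
alignment length = ali span; kept iff length > 80 aa and E < 1e-5, or
length ≤ 80 aa and E < 1e-3 — the 80 aa boundary falls in the lenient
branch because "> 80" is strict), SignalP 4.x short format (any positive
D-decision across provided organism models counts), TMHMM short format
(PredHel). Compartments: membrane iff ≥ 1 predicted helix; secreted iff
signal peptide and no helix; otherwise unassigned — mutually exclusive
and exhaustive. Taxonomy comes from a user-supplied lineage table keyed
by the BLAST taxon string, keeping the pipeline fully offline.
Transporters are tallied by keyword match on BLAST descriptions
(TonB-dependent, ABC, porin, ...), configurable.

## The synthetic community

The generator emulates the study design — two fractions × three
replicates over one shared assembly — with complete ground truth:

* 30 planted proteins (16 BF-only, 11 SNT-only, 3 shared ≈ 10% overlap,
  echoing the small fraction overlap of real BF/SNT designs), lengths
  180–400 aa as typical of secreted bacterial enzymes and receptors;
  compartments cycle secreted/membrane/unassigned; every sixth protein
  carries a CAZy family; taxa come from five lignocellulolytic genera.
* Abundance weights are lognormal (σ = 0.7), a moderate dynamic range
  the default sampling depth can resolve.
* Each protein is reverse-translated with uniform synonymous codons into
  a contig between codon-aligned stop-rich flanks (stop codons of both
  strands), 30% of contigs carry a second, *unexpressed* qualifying ORF
  (the multi-ORF decoy scenario), and five wholly unexpressed contigs are
  added. Every contig is verified against the ORF caller and resampled on
  mismatch, so the truth table is exact by construction, not assumption.
* Spectra: 30 spectra per expressed protein per run on average, sampled
  proportional to abundance weight × observable-peptide count — spectral
  flux scales with molar amount times the number of distinct precursors,
  which is precisely the sampling model emPAI's denominator corrects
  for. Peaks are the peptide's b/y ions with Gaussian m/z jitter
  (σ = 0.01 Da, a tenth of the matching tolerance), 10% random peak
  dropout and lognormal intensities; 2 ppm precursor jitter; 10% of
  spectra are pure noise (uniform random peaks and precursors).

What the fixture does *not* emulate: chimeric spectra, realistic
intensity models, isotope envelopes, retention time, semi-tryptic
peptides, homologous protein families with extensive peptide sharing,
and abundance ranges beyond ~2 orders of magnitude. Passing tests
therefore demonstrate the correctness of the bookkeeping, calibration
and guard logic under clean instrument-like noise — not search-engine
performance on real community data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline on the
30-protein community (~3,800 spectra over six runs, a few seconds per
seed), the multi-ORF guard over ten seeds on a 12-protein community, the
ORF-caller oracle on 1,000 random contigs of 500–3,000 nt, and the
linkage oracle on 50 × 6 matrices — sizes chosen to exercise every code
path at seconds-to-minutes scale. Normalisation sums are asserted to
1e-6; linkage heights to 1e-9 against an O(n³) oracle. All randomness
flows from explicit seeds through `numpy.random.default_rng`; derived
streams use `[seed, k]` seed sequences with distinct k per stage.

## Configuration defaults

| Setting | Default | Meaning |
|---|---|---|
| precursor_tol_ppm | 10 | precursor match tolerance |
| fragment_tol_da | 0.1 | b/y ion match tolerance |
| expect_cutoff | 0.05 | PSM acceptance threshold |
| max_missed | 1 | tryptic missed cleavages |
| max_var_mods | 3 | variable modifications per peptide |
| min_orf_nt | 301 | ORF coding-length bound (effective 303) |
| window | 6–40 aa, m/z 150–2000, z ∈ {2,3,4} | emPAI observability |
| min_peptides | 1 | peptides required per reported protein |

The run configuration is YAML (`metasecretome run-all --config run.yaml`)
declaring the contig FASTA, one MGF per (sample, fraction, replicate),
optional annotation files (blast/dbcan/signalp/tmhmm/cog/lineage) and any
setting overrides; all outputs carry a header with the tool version and
a hash of the configuration.

## Known limitations

The scorer is a shared-peak count: it ignores intensities and is weaker
than a probabilistic engine on noisy real spectra — real deployments
should import external PSM tables for the search step and use this
package for the two-round orchestration, quantification and
classification. emPAI observability uses the acquisition window, not the
retention-time model of the original publication; absolute emPAI values
therefore differ from engine-internal ones even when ranks agree.
Protein inference collapses only identical peptide sets; maximal
parsimony grouping is not attempted.
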
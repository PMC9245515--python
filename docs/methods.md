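# Methods

## Model and scope

The pipeline identifies and quantifies collagen post-translational
modifications from fragment spectra and MS1 extracted areas.  Its core
assumptions:

- **Motif-restricted chemistry.** Hydroxylation of proline is allowed at any
  P (the search must see both Xaa- and Yaa-position hydroxyprolines);
  hydroxylation and O-glycosylation of lysine are restricted to lysines in
  G-X-K context, with the context checked on the *chain*, not the peptide,
  so a peptide starting at or near a K still inherits the correct motif.
- **Positional 3-HyP inference.** 3-HyP and 4-HyP are isobaric; a
  hydroxylated P at the Yaa position of a Gly-Xaa-Yaa frame is called 4-HyP,
  and a hydroxylated P at the Xaa position is called 3-HyP only when the Yaa
  residue of the same frame is a proline observed hydroxylated **on the same
  peptidoform** (strict reading of the G-Xaa-HyP motif).  A flag
  (`strict_hyp3=False`) relaxes this to "Yaa hydroxylation observed at that
  position in any peptidoform".  Xaa hydroxyprolines with any other Yaa
  partner are reported `HYP_AMBIGUOUS` rather than guessed.
- **Coordinates.** Sites are stored in 1-based full-length coordinates
  (signal peptide included); mature numbering is a bijective view obtained
  after removing signal/propeptide intervals.  Propeptide boundaries can be
  transferred from an annotated ortholog through a global alignment
  (BLOSUM62, gap open 10 / extend 0.5 — the choice of aligner parameters is
  ours, recorded in the alignment result metadata).  A boundary opposite an
  alignment gap snaps to the nearest aligned reference residue within ±3
  positions, preserving the offset; farther than that the transfer fails
  loudly rather than guess.
- **A proline serving two frames** (Yaa of one triplet and Xaa of the next,
  as in G-G-P-…) is classified Yaa: 4-HyP is the dominant, near-complete
  modification at Yaa positions, so that reading loses the least
  information; the frame is kept in the annotation's triplet context.

## Search stage

Digestion is fully tryptic (cleave after K/R except before P — the plain
rule, without the W-K-P/M-R-P exceptions some engines add), up to a
configurable number of missed cleavages; search candidates are 5–60
residues.  Peptidoforms are the Cartesian product of per-site states — P ∈
{unmod, HyP}, G-X-K lysine ∈ {unmod, HyK, G-HyK, GG-HyK}, M ∈ {unmod,
oxidized} — truncated to at most `max_dynamic_mods` dynamic modifications,
with carbamidomethyl-C static.  Glycosylated states are disallowed on a
peptide C-terminal lysine by default (a bulky glycan is assumed to block
tryptic cleavage; configurable), which also reflects that such forms would
mostly appear on the missed-cleavage peptide instead.  A guard aborts
enumeration if the pre-cap state space exceeds 10^6.

Scoring is a transparent stand-in for a production engine: theoretical b/y
series (charges up to 2), greedy nearest-peak matching within a ppm window
(each experimental peak consumed at most once), and score = −log10 of the
binomial tail P(≥k matches among n ions) with the per-ion match probability
estimated from the fragment tolerance and the spectrum's peak density.  The
score is deterministic and monotone in the matched-ion count; spectra with
no peaks score 0.

Decoys are whole-protein sequence reversals; a decoy peptide whose sequence
collides with any target peptide is counted as target only.  One best PSM
per spectrum (ties break toward the target, then the lexicographically
smallest peptidoform string — reproducibility over optimism).  q-values are
the suffix-minimized decoy/target ratio over score cutoffs; peptide- and
protein-level estimates repeat the procedure on each unit's best PSM.  Two
parameter presets mirror the two common engine configurations: 10/20 ppm
with 4 missed cleavages and 10 dynamic mods, and 50/25 ppm with 3 and 5.

Where two searches are merged, the merge is the union of post-FDR site
identifications (`SiteCatalog.merge`), keeping per-state support counts and
letting a 3-HyP call from either side stand.

## Quantitation

Spectral counts are normalized multiplicatively to the *mean* per-file
total, keeping values count-like so the ≥3-count heatmap eligibility
threshold stays meaningful (a fraction-of-total normalization would not);
this was a genuinely open choice and is configurable.  Heatmap scaling is a
per-row z-score (sample SD) clipped to [−2, +2], constant rows mapping to 0.
Fold change is the ratio of condition mean to baseline mean; the percent
change is computed from the ratio, i.e. a 0.93-fold level is a 7.0%
decrease by the formula regardless of any rounded presentation.

Site occupancy divides, per replicate, the summed MS1 area of peptidoforms
in each modification state by the total over all states at that site;
peptidoforms whose state at the site is unlocalized are excluded rather than
apportioned (conservative; an equal-split option exists).  Replicates with
zero total area are not-detected and propagate as ND, never as 0%.  Cluster
occupancy collapses a set of co-resident sites to "any hydroxylation in the
cluster" vs none, with the same arithmetic.  Dispersion is reported as SD
for hydroxylation-occupancy tables and SEM for microheterogeneity tables,
matching the two table conventions.  One-way ANOVA across the four
conditions uses the classical F test; all-identical values report p = 1 by
convention, and groups without ≥2 replicates are flagged untestable rather
than tested.  The identification catalog records modified states only;
unmodified fractions are a quantitation question, which keeps catalog
merging exactly idempotent.

## Synthetic data

The generator emulates the study design end to end: procollagen-like chains
(22-residue signal peptide, 24-residue propeptides, a (G-X-Y)n core with
prolines enriched at X and Y, K at the Yaa of every 5th triplet and a
tryptic R at the Xaa of every 7th), per-site state occupancy over
4 conditions × 2 biological replicates, MS1 areas with multiplicative
log-normal noise (sigma set from the configured CV; the default is CV 10%),
and HCD spectra with per-peak dropout (default 10%), ppm jitter
within half the fragment tolerance, log-normal intensities and uniform noise
peaks.  Default occupancy profiles are shaped like the published sham/
regeneration trajectories (a lysine whose GG-HyK fraction rises from ~3% to
~15%, a four-state microheterogeneous lysine, and two proline profiles).
One global seed fans out to per-component child seeds through a SHA-256 name
hash (all below 2^31), so chains, features and spectra regenerate
independently and byte-identically.  Planted sites are placed on disjoint
tryptic peptides where the chain allows, so each site's features quantify
that site alone; on very short chains placement falls back to overlapping
peptides.

What the generator does **not** emulate: chimeric/co-eluting spectra,
isotope envelopes, retention-time structure, charge-state heterogeneity,
semi-tryptic peptides, and real spectral noise correlation.  Passing tests
therefore demonstrate the correctness of the *logic* (enumeration, scoring
discrimination under dropout, FDR calibration against planted truth,
occupancy arithmetic and power), not engine-grade performance on raw
instrument data.

## Problem sizes and numerics

The default synthetic dataset is one 250-residue chain (60 triplets), 4
planted sites, 200 spectra, 2 replicates × 4 conditions — chosen so the full
simulate→search→catalog→quantify loop runs in well under a minute on one
CPU while leaving every stage non-trivially exercised; the repeated-search
calibrations use 24-triplet chains and 30 spectra per run.  Monoisotopic
constants are stated to 9 decimals (proton 1.007276467, water 18.010564684,
oxygen 15.994914620, hexose 162.052823418); residue and element masses come
from the pyteomics tables.  The two differently-printed oxygen deltas in
the source material (+15.9949 and +15.994,916) are unified to the elemental
value, with the printed strings preserved in the modification table for
traceability.  Mass additivity holds to <1e-9 Da and is independent of
modification order.

## Known limitations

- The scorer is intentionally simple; it has no intensity model, neutral
  losses, or isotope peaks, and its absolute scores are not comparable to
  production engines — only its ranking and FDR behavior are validated.
- 3-HyP calls inherit the strictness of the co-occurrence rule; sparse
  sampling of the Yaa partner can leave true 3-HyP sites in the ambiguous
  class.
- The packaged reference tables transcribe printed values; two
  microheterogeneity rows (one lysine site at two timepoints) sum to 99.80
  and 100.59 rather than 100 ± 0.1, a rounding artifact of the printed
  source that the self-check reports as-is.
- Occupancy assumes equal ionization efficiency across modification states
  of the same peptide backbone, as all MS1-area stoichiometry methods do.
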
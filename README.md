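# colptm — motif-constrained collagen PTM mapping and quantitation

Collagen chains are procollagen molecules — signal peptide, N-propeptide, a
(Gly-Xaa-Yaa)n triple-helical core, C-propeptide — that are heavily modified
during biosynthesis: prolines at the Yaa position are near-completely
4-hydroxylated (4-HyP), prolines at the Xaa position of a G-Xaa-HyP motif can
be 3-hydroxylated (3-HyP), and lysines in G-X-K context are hydroxylated
(HyK) and O-glycosylated with one (G-HyK, galactosyl) or two (GG-HyK,
glucosylgalactosyl) hexoses.  Because 3-HyP and 4-HyP are mass-identical
(+15.994915 Da, one oxygen), they can only be distinguished *positionally*;
the glyco ladder adds 162.052823 Da per hexose (G-HyK +178.047738, GG-HyK
+340.100562).

`colptm` is a pipeline for proteomics researchers mapping these PTMs from
shotgun MS data of extracellular-matrix preparations (the packaged reference
catalogs come from zebrafish heart ECM during regeneration, with sham, 7-,
14- and 30-days-post-amputation conditions):

- **chain_model** — chain representation, Gly-Xaa-Yaa / G-X-K motif
  annotation, global alignment to an annotated ortholog for propeptide
  cleavage-site transfer, full-length vs mature coordinates;
- **mass_digest** — tryptic digestion (cleave after K/R, not before P),
  monoisotopic masses, the modification table;
- **motif_search** — motif-constrained peptidoform enumeration (each P may be
  HyP; each G-X-K lysine may be HyK/G-HyK/GG-HyK; each M may be oxidized), a
  binomial b/y-ion scorer, reversed-decoy generation, and target-decoy FDR
  (q-values) at PSM/peptide/protein level;
- **site_catalog** — collapse of filtered PSMs into per-site catalogs with
  the positional 3-HyP rule (Xaa-P counts as 3-HyP only when the Yaa of the
  same frame is a hydroxylated proline on the same peptidoform), sequence
  coverage on the mature chain, per-chain tallies, and cross-species
  conserved-site matching through an alignment;
- **quantitation** — spectral-count abundance (normalized to mean file
  depth), fold changes, row-standardized heatmap scaling, and MS1-area site
  occupancy / lysine microheterogeneity (percent of extracted area per state,
  per condition and replicate) with one-way ANOVA across conditions;
- **synthetic_data** — a fully seeded generator of collagen-like chains,
  planted occupancy profiles, noisy MS1 features and HCD spectra, so the
  whole pipeline is testable offline;
- packaged **fixtures** transcribing the published zebrafish site catalogs
  and occupancy tables.

For a single site and replicate, the occupancy of state *s* is

    occ(s) = 100 · Σ area(peptidoforms in state s) / Σ area(all states),

so the states partition 100% of the MS1 signal; lysine microheterogeneity is
this vector over {K, HyK, G-HyK, GG-HyK}.

## Worked example

The numbered drivers under `analysis/` run the whole loop on the default
synthetic dataset (seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate.py        # chain + features + spectra + truth
python analysis/02_search_identify.py # search + 1% FDR
python analysis/03_site_catalog.py    # site catalog + published tallies
python analysis/04_occupancy_dynamics.py
python analysis/05_fixture_checks.py
```

A complete run prints (seed 1):

```
chain SIM_COL1: 250 residues, mature interval (47, 226)
planted sites: K61, K76, P94, P115
200 spectra -> 200 PSMs at 1% FDR (200 targets, 200 match the generating peptidoform)
synthetic catalog: 4 sites, planted-state recall 100.0%
published catalog: 23 chains; totals 3-HyP=95, HyK=108, G-HyK=29, GG-HyK=128
COL1A1a 3-HyP: 10 conserved + 14 novel = 24 sites
  K61 HyK     sham: planted  34.82  recovered  33.31
  K61 GG-HyK  sham: planted   2.74  recovered   2.42
planted 0.68-fold collagen decrease recovered as 32.0% decrease at 7 DPA
```

Reading: every spectrum was assigned back to its generating peptidoform at
1% FDR; all planted modification states were recovered in the site catalog;
occupancy estimated from two noisy replicates lands within ~1-2 points of
the planted truth; and a 0.68-fold drop in collagen counts is reported as
the equivalent 32% decrease.

The same machinery is available as a CLI
(`colptm simulate|digest|search|sites|quant|verify`).

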
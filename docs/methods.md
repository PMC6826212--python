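# Methods

## The problem

An "all-pX" search allows variable phosphorylation on nine residue
classes (S, T, Y, H, D, E, K, R, C). Because every modifiable position
doubles the candidate space, a peptide with *n* such positions has
2<sup>n</sup> modification states, and the question shifts from *is this
peptide phosphorylated* to *which residue carries the phosphate, and how
often is that call wrong*. This package implements the informatics core
of that problem: isoform enumeration, binomial localisation scoring,
decoy-amino-acid FLR calibration, diagnostic-ion analysis, site-level
aggregation and motif discovery — validated end to end against a
simulator with known ground truth.

## Localisation scoring

For a PSM carrying *k* phospho groups we enumerate every isoform placing
*k* groups on modifiable residues and score each against the peak list:

1. **Peak filtering.** At most `depth` most-intense peaks are retained
   per non-overlapping 100 m/z window (default 8); intensity ties at the
   boundary keep the lower-m/z peak so filtering is deterministic.
2. **Theoretical ions.** b/y for HCD; b/y/c/z for EThcD (supplemental
   activation retains b/y; z is generated as the z• radical, the common
   ETD readout; c = b + NH₃ and z• = y − NH₃ + H). Fragment charges run
   1..min(2, precursor charge). Neutral-loss ions are excluded from
   scoring by default (`ignore_neutral_loss=True`); when enabled they are
   generated only from fragments that span a phosphorylated position.
3. **Binomial evidence.** With *n<sub>i</sub>* theoretical ions,
   *k<sub>i</sub>* of them matched within ±`tolerance`, and per-ion
   chance-match probability *p = depth · 2 · tolerance / 100* (the
   fraction of each window expected to be covered by retained peaks),
   the isoform's evidence is the upper tail
   *P<sub>i</sub> = P(X ≥ k<sub>i</sub> | n<sub>i</sub>, p)*.
4. **Normalisation.** Isoform weights are *w<sub>i</sub> ∝ 1 /
   P<sub>i</sub>*, normalised to sum to 1; a site's probability is the
   summed weight of isoforms containing it, so site probabilities sum to
   *k* per PSM.

This reproduces the characteristic tri-modal score structure of binomial
site scorers: PSMs whose top two isoforms match identical ion sets split
0.5/0.5; a single extra matched ion yields a score strictly inside
(0.5, 1) (≈0.85–0.9 for typical ion counts); two or more extra ions push
the winner above 0.95. Numerical guards: *p* is clamped to (0, 0.5],
binomial tails floored at 1e-300, weights accumulated with `math.fsum`.

Key parameters: fragment `tolerance` 0.5 Da (ion-trap product-ion
readout; configurable), `depth` 8 peaks / 100 m/z, a "treat all spectra
as EThcD" switch, optional fixed Cys carbamidomethylation (+57.02146 Da).
No numerical equivalence with any proprietary scorer is claimed — only
the published binomial scheme and its qualitative score structure.

## Decoy-amino-acid FLR

Alanine cannot be phosphorylated. Searching with pAla as a variable
modification (substituted for pCys, so the alphabet size is unchanged)
turns every apparent pAla site into a measured random mislocalisation.
The residue-specific false localisation rate at score threshold *t* is

    FLR_X(t) = min(1, [N_A(t) · f_X / f_A] / N_X(t))

where *N<sub>X</sub>(t)* counts **unique** sites — one (protein
accession, protein position) pair, scored by the maximum over supporting
PSMs — and *f<sub>X</sub>* is the relative frequency of residue X.
Frequency basis: the residue composition of the identified peptide set by
default (that is the pool random assignment draws from), with database
composition available as an alternative. Undefined ratios (no sites at
the threshold) are reported as missing rather than zero, to avoid
silently inflating true-positive counts. True positives are
`round(N_X · (1 − FLR_X))`, half-up; the decoy's own FLR is identically 1.
An independent upper bound comes from catalogue overlap: if *m* of *n*
sites are already known, the maximum FLR is 100·(1 − m/n) %. FLR is not
guaranteed monotone in *t* (both numerator and denominator shrink);
site counts are.

## Diagnostic ions

Phosphopeptide precursors shed HPO₃ (Δ79.96633), H₃PO₄ (Δ97.97690) and
H₃PO₄+H₂O (Δ115.98746). Each scan is assessed for the three loss peaks at
(precursor m/z − Δ/z) within ±0.5 Da at ≥ 2, 5 or 10 % of the base peak
(inclusive comparison; 5 % is the headline threshold), giving a triplet
score 0–3; the Δ98 flag doubles as the neutral-loss trigger used by
loss-triggered EThcD acquisition. By default only the precursor's own
charge is searched; a config option adds lower charge states. Immonium
scanning checks phosphoimmonium m/z values (residue − CO + proton
+ 79.96633; pTyr 216.04, pHis 190.04) at ≥ 5 % relative intensity. All
masses are monoisotopic; "80/98/116" are display conventions.

## Site pipeline

PSM q-values come from target-decoy competition (running #decoy/#target
down the score-sorted list, monotonised from the bottom). Site calls on
peptide C-terminal Lys/Arg are removed — tryptic cleavage after a
phosphorylated Lys/Arg contradicts the protease mechanism, and the
abundant y₁+80 ions at such positions bias localisation — with a removal
log so filtered and unfiltered counts always reconcile. Protein
coordinates are 1-based; Leu/Ile are distinct; peptides matching multiple
protein positions emit one row per occurrence, flagged ambiguous, and
unique-site counting deduplicates per accession (protein-group inference
is out of scope).

## Motif analysis

Unique sites contribute ±7-residue 15-mers (padded with `-` at termini;
padding never counts toward residue frequencies; identical windows are
merged). Enrichment is the greedy motif-x recursion: fix the
(position, residue) cell with the smallest binomial upper-tail p-value
below the threshold (default 1e-6) subject to a minimum occurrence count
(default 20 — the conventional motif-x settings, configurable), restrict
to matching windows, recurse; emit the accumulated constraints as one
motif and remove its windows before restarting, so motifs are mutually
exclusive over the foreground. No multiple-testing correction is applied
inside the greedy loop (motif-x convention); the p-threshold is the
user-facing control. A residue never seen in the background uses the
pseudo-rate 1/(N+1). Logos are emitted as position × residue count
matrices, not images.

## The simulator

`simulate_spectra` emulates the data the analyses assume: random
proteins with human-like residue composition (or a supplied FASTA),
tryptic digestion (cleave after K/R, never before P, ≤ 2 missed
cleavages), peptides of 6–30 residues, precursor charge 2–3, one planted
phosphosite drawn by per-class abundance weights, fragment ladders at
charges 1..min(2, z) with per-ion detection probability (default 0.9),
log-normal fragment intensities, uniform-m/z noise with exponential
intensities, per-class precursor neutral-loss propensities (defaults
echo the empirical pattern that hydroxyl-residue phosphopeptides favour
phosphoric-acid loss while pHis/pTyr lose HPO₃ relatively more often),
and two controlled failure modes:

- **ambiguity**: with probability `ambiguous_fraction` only the ions
  shared with the *adjacent* candidate isoform are emitted, so the
  scorer provably cannot separate the pair (ions spanning neither or
  both sites are identical, and no third candidate lies between them);
- **scrambling**: with probability ε the emitted site is relabelled to a
  uniformly chosen alternative candidate position — the random-assignment
  null the decoy FLR estimator is built to measure.

`simulate_sitecalls` is the fast path for FLR statistics: per-class true
sites, frequency-weighted scrambling over the candidate classes
(including the decoy, which can only ever receive scrambled calls), and
scores drawn from a tri-modal mixture (point mass at 0.5, a mode near
0.85, a mode near 1) identical for true and scrambled calls — the
estimator's premise is precisely that the score distribution is
residue-independent. Everything is deterministic given the seed; the
simulator writes the same MGF dialect the reader consumes.

What the simulator does **not** model: chromatography and retention
time, isotope envelopes, m/z measurement error, intensity physics,
co-isolation. Passing tests therefore demonstrate the correctness of the
inference machinery under its stated assumptions, not instrument-level
realism. One consequence of exact simulated centroids: the end-to-end
separability check ("complete ladders localise every planted site above
0.99") is run at a matching tolerance of 0.02 Da, because at 0.5 Da a
fraction of a percent of peptides have site-determining ions that are
isobaric with other ladder ions within the window — a genuine property
of coarse-tolerance matching, not a defect.

## Problem sizes and test design

The validation suite runs entirely on simulated data: parameter-recovery
checks use ≥ 500 sites per class with ε = 0.2 (agreement within 3
binomial standard errors of the realised false fraction, where the band
is the SE of the *difference* — the decoy count is itself a binomial
draw); the tri-modal corpus uses 150 mixed spectra; the pipeline
reproducibility check runs a 1,000-spectrum corpus twice and compares
every output byte-for-byte. Scorer oracle equivalence is checked against
an independent brute-force implementation (explicit subset enumeration,
literal mass sums, exact `math.comb` tails) to 1e-9.

## Known limitations

- The scorer's per-ion chance probability treats retained peaks as
  uniformly distributed within windows; strongly structured noise would
  violate this.
- FLR calibration assumes mislocalisation is frequency-proportional and
  score-independent across residues; a residue with systematically
  atypical fragmentation would break the transfer from pAla.
- The exact frequency basis for normalisation (database vs identified
  peptides vs phosphopeptides only) is a configuration choice; results
  shift by a few percent between bases.
- Motif discovery inherits motif-x's greedy behaviour: overlapping true
  motifs can shadow one another, and p-values are conditional on the
  greedy path.
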
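# Methods

This note documents the models behind `baddisplay`, the defaults and their
rationale, what the synthetic-data generators do and do not emulate, and
the numerical conventions used.

## Kabat numbering

Queries are numbered by global alignment (Biopython `PairwiseAligner`,
BLOSUM62, affine gaps: open 10, extend 1, so a gap of length L costs
`10 + (L−1)·1`) against a pre-numbered subgroup germline. Residues aligned
to reference residues inherit the reference Kabat position; residues
aligned to reference gaps receive insertion letters appended to the last
assigned number (…, 100, 100A, 100B, 101). Ties between equal-scoring
alignments resolve deterministically to the aligner's first reported path.
Insertions outside CDR interiors are numbered the same way but trigger a
warning, because framework indels are not expected in this coordinate
system; query residues preceding Kabat 1 cannot carry an insertion code
and raise an error. An optional score floor rejects unalignable input.
Sequence length is checked against the variable-domain range 60–150 by
default; the bounds are a parameter so that toy-scale references can be
used in exhaustive-enumeration tests.

The bundled references are *synthetic* consensus frameworks (kappa and
VH3-style, Kabat L1–107 and H1–113) constructed so that the landmark
framework positions referenced throughout (light M4; heavy E6, F27, M34,
V37, V48) carry the expected wild-type residues. They are fixtures, not
database alleles: no germline allele assignment is attempted, and any real
analysis should substitute the user's subgroup consensus via
`read_reference_tsv`.

CDR boundaries follow the Kabat convention (L24–34, L50–56, L89–97;
H31–35B, H50–65, H95–102). Light-chain positions are prefixed L and heavy
H in chain-qualified outputs.

## Library design

`tally_natural_diversity` counts unique `(position, from, to)` germline
deviations over a repertoire; `design_library` retains those that are
framework-located, buried, not excluded, and sufficiently supported. Filter
defaults and reasoning:

* `rsa_max = 0.2` — the common relative-solvent-accessibility convention
  separating buried from exposed residues. Burial is consumed as an
  annotation table (chain, position, RSA), keeping the package free of 3-D
  structure dependencies; positions missing from the table count as
  exposed unless `strict_burial` demands an annotation.
* `min_count = 1` — any observed natural change is eligible; raising it
  models designs restricted to recurrent somatic mutations.
* `excluded_positions` — paratope or binding-critical positions supplied
  per target; empty by default.

Positions observed with several alternative residues yield one library
member per alternative; light and heavy libraries are designed
independently (no combinatorial variants at design time). The output TSV
is byte-deterministic for identical inputs, and every retained variant is
traceable to an observation — nothing is synthesized.

## Synthetic SHM repertoire

`simulate_repertoire` emulates a subgroup repertoire shaped by somatic
hypermutation at the amino-acid level: each position of each sequence
mutates independently with probability `per_position_rate` (default 0.01
per position, giving ~1 substitution per 100-residue domain, a light SHM
load), with optional relative position weights for hotspot structure and a
uniform default over the 19 alternative residues (a transition-biased
table may be supplied). Planted variants are carried at
Binomial(n, target_frequency) counts, drawn exclusively per position, and
override background mutations at their position so that planted support is
exact. The generator records a ground-truth table that equals the
position-wise differences from germline by construction; indels are off by
default (an optional CDR3 insertion rate exists only to exercise
insertion-code numbering).

What this does not emulate: nucleotide-level AID hotspot motifs, clonal
lineage structure, indel-containing CDR length variation, or sequencing
error. Tests passing on this generator therefore demonstrate pipeline
correctness (closure of numbering → tally → design against known truth),
not robustness to real repertoire artifacts.

## Selection simulator

Per-cell fluorescence for a variant with expression fold `f` is a
two-component lognormal mixture:

* with probability `p_unpermeabilized` (default 0.1), background only —
  median `mu_background`;
* otherwise bound signal — median `mu_background + scale · f^gamma`;
* both components share the lognormal shape parameter `cv` (default 0.6);
* non-binders are background-only regardless of expression.

`gamma` (default 0.17) is the least-squares slope through the origin of
log mean-fluorescence fold on log expression fold, calibrated from the
paired folds of the resolution experiment (expression 3.7/5.6/7.2 vs MFI
1.25/1.37/1.4); with `mu_background = 20` and `scale = 1000` (arbitrary
fluorescence units, chosen so background is small against bound signal) a
7.2-fold expresser shows the observed ~1.4-fold median shift. Affinity is
deliberately absent from the signal model because staining is assumed at
antigen concentrations far above KD.

A sort round draws `cells_analyzed_per_round` cells multinomially from the
current frequencies, assigns each a signal, keeps the highest
`ceil(gate_fraction · n)` values (signals are continuous, so ties have
measure zero), and regrows the kept pool multinomially to `regrow_to`
(growth is neutral — no fitness differences between variants). The gate is
a sample quantile, not a fixed threshold, and its realized value is
recorded per round together with the analyzed and gated per-variant
tallies (the computational analogue of plating sort input and output).
`FluorescenceModel.gate_pass_probability` provides the closed-form
mixture tail probability used as the analytic oracle for selection
monotonicity.

Known limitation, established quantitatively by the closed-form recursion
and confirmed by simulation: with the calibrated signal compression (a
maximum 1.4-fold median shift at cv 0.6), two rounds of top-1% gating
discriminate the two brightest of four variants to a joint ~80% of the
population, not fixation; complete fixation within two rounds, as observed
in real screens, requires sharper effective discrimination than this
mixture model provides. Doublet discrimination, DNA-dye gating, instrument
optics and staining variability are not modeled.

## Sort quantification

* Plating ratio: `marker/(total − marker)` with log-scale standard error
  `sqrt(1/marker + 1/(total−marker))` (delta method on two Poisson
  counts); the dilution factor cancels for same-dilution pairs.
* Fold enrichment: output ratio / input ratio, with a lognormal 95%
  interval from the combined log-scale errors. Defined as a ratio of
  ratios so that per-round factors telescope across rounds.
* Clone frequencies: `count/n` with Wilson 95% intervals (statsmodels);
  Wilson is preferred over Wald for the small counts typical of sequencing
  92–226 colonies.
* Calls: `not_detected` when the final count is zero (kept distinct from
  `depleted`); `enriched`/`depleted` require a frequency change of at
  least `min_fold` (default 2) *and* non-overlapping Wilson intervals;
  otherwise `neutral`. No multiplicity correction is applied by default
  (the report is descriptive); a Benjamini–Hochberg pass can be layered on
  by the caller for large libraries.

## DSF melt curves

Model: `F(T) = b0 + b1·T + Σ_j A_j / (1 + exp((Tm_j − T)/w_j))` on a
20–100 °C grid at 0.2 °C steps, plus Gaussian noise. Extraction proceeds
in three stages: (1) candidate detection on a Savitzky–Golay first
derivative (window ≈ 5 °C, cubic), with a permissive prominence gate at
25% of the derivative maximum; (2) local logistic-plus-baseline refinement
in a ±8 °C window around each candidate, discarding candidates whose
fitted amplitude is below `min_prominence` (default 5%) of the total
signal range; (3) when several transitions survive, a joint refit of the
shared baseline and all logistics over the full grid, which removes the
bias that overlapping transition tails induce in the local fits. A
single-stage fixed prominence threshold on the raw derivative was rejected
because it either misses genuine small CH2/CH3 transitions or fires on
noise, depending on the scale chosen. Transition widths are bounded to
(grid step/2, 8 °C). The Fab melt is assigned to the largest-amplitude
transition — a convention appropriate for Fab-dominated constructs whose
CH2/CH3 transitions are smaller and consistent across variants.
Noiseless recovery of an isolated transition is grid-limited (≤ 0.2 °C
for widths ≥ 1 °C).

## SPR kinetics

The 1:1 Langmuir model is integrated piecewise in closed form. During an
injection at concentration C from bound level R0:
`R(t) = Req + (R0 − Req)·exp(−(ka·C + kd)·t)` with
`Req = Rmax·C/(C + KD)`; during dissociation `R(t) = R0·exp(−kd·t)`.
Multi-cycle designs reset R0 = 0 at each injection (surface regeneration);
single-cycle designs carry R0 across the ascending series. The two bundled
designs follow the acquisition protocols exactly: multi-cycle two-fold
1.56–50 nM, 120 s association / 1000 s dissociation; single-cycle
three-fold 6.17–500 nM, 120 s / 300 s. The time grid is 1 s.

Fitting is unweighted global nonlinear least squares in
log-parameter space over all segments sharing (ka, kd, Rmax),
multistarted from a 3×3 log-spaced grid of ka ∈ [10³, 10⁷] 1/(M·s) and
kd ∈ [10⁻⁵, 10⁻¹] 1/s with Rmax initialized from the response maximum;
the best-objective solution is returned and `KD = kd/ka` is derived
exactly (nM = molar × 10⁹). Mass-transport limitation, drift and
bulk-shift terms are omitted. Table-style scale factors (ka printed
× 10⁵, kd printed × 10⁻⁵) are handled only at I/O via
`params_from_table`/`params_to_table`.

Problem sizes: the kinetics worked examples fit 6,720-point (multi-cycle)
and 2,100-point (single-cycle) traces; the screening acceptance checks use
10⁵-cell rounds (50 seeds) for calibration, 10⁷-cell rounds for the
spiking bound, 2×10⁴-cell rounds across 200 seeds for interval coverage,
and a 500-sequence repertoire for design closure — sizes chosen to make
sampling error negligible relative to the tested effects while remaining
desk-scale.
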
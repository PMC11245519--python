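# Methods

This note documents the models and procedures implemented in `dcachepu`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generators do and do not emulate.

## The motif model

The purine-binding motif of dCache_1 sensor domains (the dCache_1PU
subfamily) is represented as five ordered positions with allowed residue
sets and bounded spacings, in the full-length numbering of the reference
receptor (McpH from *Pseudomonas putida*):

| position | reference residue | allowed set | residues to next position |
|----------|-------------------|-------------|---------------------------|
| P1 | Y121 | {Y, F} | 7 |
| P2 | R129 | {R, K, H} | 10 |
| P3 | W140 | {W, F} | 26 |
| P4 | F167 | {F, Y} | 1 |
| P5 | D169 | {N, D} | — |

Spacings count residues strictly between consecutive positions; the
centre gaps 7/10/26/1 follow from the reference indices. A *companion*
aromatic {F, Y, W} sits immediately after P3 (F141 in McpH). It does not
contact the ligand but is structurally conserved, so the scanner requires
it by default (`require_companion=False` disables this — whether the
original screen enforced it is not documented, so it is a flag).

Allowed sets default to the union of residues observed across the
experimentally characterised variant strings; because the printed motif
diagram cannot be transcribed exactly, all sets, spacings and tolerances
are configurable through the YAML motif schema.

### Scanning modes

*Aligned mode* reads, for every row of a shared alignment, the residues at
the alignment columns of the reference anchor positions. A sequence
matches iff every position carries a non-gap residue from its allowed set.
No spacing tolerance is involved — indel structure is absorbed by the
alignment. A trimmed-away anchor column yields an unmatched result with
the reason `"reference position deleted"`.

*Linear mode* searches a bare sequence for 5-tuples of positions
satisfying the residue sets and spacing windows. The default tolerance is
±4 residues per gap (±1 for the adjacent P4→P5 pair), absorbing the small
indels between motif positions seen in real homologs. If several tuples
are admissible, the one with minimal total |deviation from the centre
gaps| is reported, ties broken by leftmost positions. With tolerance 0
and singleton sets, linear scanning degenerates to literal string
matching, which the tests exploit as a sanity anchor.

### Deriving the motif

`derive_motif` combines the ligand-contact positions from the structure
with per-column conservation: a contact position is kept when the most
frequent residues of its column — each with non-gap frequency ≥ τ_res
(default 0.05), at most `max_set_size` (default 4) of them — jointly cover
≥ τ (default 0.90) of non-gap rows. The cap matters: without it, a column
of near-uniform composition could accumulate twelve ~5% residues and pass
τ spuriously; with it, only genuinely low-entropy columns survive. τ is a
design choice — "consistently conserved" has no published numeric
threshold — and is exposed as a parameter.

## Ligand contacts

A residue contacts the ligand when any of its heavy atoms lies within
3.5 Å of any heavy ligand atom (minimum over atom pairs is recorded).
Hydrogens are excluded: at ~2 Å resolution they are not reliably placed,
and a heavy-atom rule is reproducible across refinement protocols. Two
lightweight labels are attached: `hydrogen-bond-capable` when the closest
pair is N/O–N/O within the cutoff (donor/acceptor geometry and
protonation are deliberately not modelled — the protonation state of the
bound purine is genuinely ambiguous), and `aromatic-proximal` when an
F/Y/W/H side-chain ring atom lies within cutoff + 1.0 Å of a ligand C/N
atom. π-stacking is *not* verified geometrically (no ring-plane angle
test); the label marks candidates for the aromatic sandwich, which is how
the interaction was originally identified (visually, in a viewer).
Because the exact interaction criteria of such viewers are unpublished,
the contact *count* around a real structure may differ slightly from a
published count; the contract is the exhaustive all-pairs result, which
the tests enforce against a brute-force oracle.

## Alignment, position tracking, trimming

The pairwise anchoring aligner is a deterministic Gotoh implementation:
BLOSUM62, gap open 11, gap extend 1 (a gap run of length L costs
11 + (L−1)·1), semi-global by default (terminal gaps in the query row are
free, so a domain fragment lands anywhere on the reference without
penalty). Ties are broken substitution > gap-in-reference > gap-in-query,
so traceback is reproducible. The published pipeline used a progressive
multiple aligner; pairwise anchoring to the reference is this package's
equivalent path for position tracking, and `map_positions` accepts either
a pairwise alignment or an existing MSA with a designated reference row.

Column trimming implements the rule used before phylogenetic inference:
remove columns with gap fraction ≥ 0.10 ("10% or more", closed bound),
unless fewer than 60% of columns would remain, in which case the
⌈0.6·N⌉ columns with the smallest gap fraction are kept (ties to the
lower column index). The retention floor is exercised explicitly by the
randomized oracle tests.

## ITC one-site fitting

Per-injection heats follow the standard single-cell perfusion-calorimeter
formulation of the one-site model (cumulative heat from the quadratic
binding polynomial, displaced-volume corrections for cell concentrations
and for material pushed into the inactive stem; see the docstring of
`binding_assays` for the equations). Raw heats are corrected by the mean
ligand-dilution heat, normalised per mole of injectant, and the first
(lead-off) injection is dropped from fitting but kept in the record.

The fit minimises squared residuals over (log₁₀ K_A, ΔH, n) with
`scipy.optimize.least_squares` from three deterministic starts — a c≈10
heuristic, a weak-binding start, and the best of a log-spaced K_A grid —
to avoid the local minima that afflict low-c isotherms. Standard errors
are asymptotic from the Jacobian; K_D = 1/K_A by definition. Flat
isotherms (span below 3× the point-to-point scatter) return a
`"no binding detectable"` outcome rather than a meaningless fit,
mirroring how saturating-but-silent titrations are reported in practice.
The cell volume is not published for the instrument class, so it defaults
to 1.4 mL and is an overridable configuration field. Units are µcal for
raw heats, mol/L for concentrations, kcal/mol for ΔH.

Fold reductions are K_D(mutant)/K_D(reference), rounded
half-away-from-zero to match printed integer tables.

## Thermal shift (DSF) analysis

Tm is the temperature of the maximum of the first derivative of
fluorescence: the trace is moving-average smoothed (default window 7
points; the published smoothing is unstated, so the window is a
parameter), differentiated by central differences, and the peak searched
over the interior (first/last window excluded, where one-sided smoothing
artefacts live). A peak below 3× the median absolute derivative is
called "no transition", which correctly rejects flat traces and pure
linear drift. The call is invariant under affine transforms of the
fluorescence axis. A ligand-induced shift is significant iff
Tm(ligand) − Tm(apo) > 2.0 °C, strictly — increases of exactly 2 °C or
any decrease are not significant.

## Synthetic data: what it emulates, what it does not

The generators provide every input at desk scale, seeded and pure in
(config, seed).

**Cohorts.** Positives are background-composition sequences (defaults
approximate globular-domain residue frequencies) with exactly one planted
motif instance: variant drawn from the frequencies observed across the
characterised receptor panel, gaps jittered within ±2 (inside the scan
tolerance), companion planted after P3. A candidate positive is re-drawn
until the scanner recovers exactly the planted tuple, so the truth table
is authoritative. Decoys are rejection-sampled against the scanner
itself, making specificity checks exact rather than probabilistic.
Domain lengths are drawn from 180–260 residues, the typical extracellular
dCache_1 span. Annotations (taxonomy lineage, domain architecture) are
sampled from pools weighted like the characterised panel. What this does
*not* emulate: phylogenetic correlation between sequences, positional
composition structure, or motif degradation in true homologs — so scan
sensitivity/specificity on synthetic cohorts bound performance on ideal
data, not on a real database search.

**Reference and panel.** The bundled reference domain and six-receptor
panel are synthetic stand-ins (see `reference_synthetic`): the true
reference sequence is not redistributed, so a background sequence carries
the motif residues at the correct full-length indices (numbering offset
94), the companion aromatic, and the five non-conserved contact
positions. Panel members carry the six published variant strings, three
of them with small indels so alignment anchoring is non-trivial.
Conclusions about the real proteins' sequences cannot be drawn from these
objects; they exercise the code paths with the correct coordinate
bookkeeping.

**ITC.** Heats are computed from the same one-site model the fitter uses,
plus a constant dilution heat and i.i.d. Gaussian noise scaled to the
maximum |raw heat|. The default protocol (1.6 µl lead-off + 27 × 12.8 µl
of 300 µM ligand into 18 µM protein, K_D 2.6 µM, ΔH −8 kcal/mol) matches
a typical titration of the wild-type reference domain. Because generator
and fitter share the model, noiseless round-trips test the optimiser and
the normalisation conventions, not model adequacy; thermogram-level
artefacts (baseline drift, injection broadening) are out of scope.

**Melts.** F(T) = linear baseline + amplitude·θ(T) + noise with logistic
θ on the 23–85 °C, 0.5 °C grid. The steepness default (width 1.0 °C,
i.e. 10–90% transition over ≈4.4 °C) reflects the sharp cooperative
unfolding of folded domains in dye-based DSF; broad or multi-state melts
are not modelled.

## Numerical and design choices

- All residue and column coordinates are 1-based inclusive everywhere;
  full-length reference numbering is used for anchors (offset stored on
  the anchor object). This matches the residue naming convention (Y121)
  and eliminates off-by-one ambiguity.
- Non-canonical residues (B, Z, U, O, …) map to `X` on input and never
  match any motif set — conservative classification.
- Receptor classification applies the first matching rule by explicit
  priority (chemoreceptor > diguanylate cyclase/phosphodiesterase >
  histidine kinase > Ser/Thr phosphatase > other); hybrid architectures
  exist and the original tie-breaking is unstated, so the ordering is
  configurable data, not code.
- Envelope (not alignment) coordinates define extracted domain regions
  from scanner hit tables; E-value filtering (threshold 0.01) is a
  separate explicit step, not folded into parsing.
- Scan tie-breaks, aligner tie-breaks and trimming tie-breaks are all
  deterministic and documented above, so every pipeline output is
  reproducible bit-for-bit given inputs and seeds.

## Known limitations

- The database-scale census (thousands of motif-positive proteins) is
  not reproducible offline and is out of scope; cohort summaries operate
  on whatever cohort they are given.
- The aligner is pairwise only; it does not build progressive MSAs.
- The ITC fitter covers the single-site model only (no sequential or
  multi-site schemes, no van 't Hoff analysis of melts).
- Contact labelling is heuristic by design: no protonation inference,
  no ring-plane geometry, no water-mediated contacts.
- Problem sizes in the test-suite simulation studies (200 titration
  replicates, 200 melt curves, 100+1000 cohort sequences, 500 trimming
  cases) were chosen as the smallest sizes at which the measured rates
  are stable to the asserted precision.
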
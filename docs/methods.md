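# Methods

## Enrichment model

A SILAC pull-down experiment yields, per protein group, a fold ratio
bait/control, optional TNF channels, a summed ion intensity and a unique
peptide count. We model the log2 ratio of a non-interacting (background)
protein as symmetric noise around the experiment median with a spread that
grows toward low intensity — the empirical signature of ion-count
statistics. Ratios are median-centered in log2 space per experiment; this
stands in for the upstream search engine's ratio normalization, which is
not reproducible from protein-level tables.

The outlier statistic ("significance B") operationalizes that model
without assuming a parametric form for the spread: proteins are sorted by
decreasing intensity (ties broken by protein id for determinism) and cut
into consecutive rank bins of `bin_size` (default 300); a trailing bin
shorter than `bin_size/2` is merged into its neighbor, and tables with
fewer than `2·bin_size` proteins use a single global bin. Within a bin the
robust z-score uses the 15.87/50/84.13 log-ratio percentiles (linear
interpolation between closest ranks), i.e. the one-sigma quantiles of a
Gaussian, and `sigB = ½ erfc(z/√2)` is the Gaussian upper-tail probability
of that z. A bin whose upper (or lower) spread is zero is degenerate and
raises an error unless all its ratios are identical, in which case
`sigB = 1` for the whole bin.

Enrichment calling uses the published criteria as strict inequalities:
unique peptides ≥ 2, fold ratio > 1.9 on the natural scale (applied to the
raw, un-centered ratio, as printed), `sigB < 0.1`, and the protein on the
upper side of its bin — pull-down enrichment is one-sided; depleted
outliers are never interactors. TNF regulation classes reuse the same
thresholds on the TNF/untreated channel (> 1.9 with its own `sigB < 0.1`
for positive, < 1/1.9 for negative, everything else — including absent
data — independent); no separate threshold is published for that channel.

Open choices: whether the statistic is computed on normalized or raw
ratios, and the bin size, are not documented for the original software;
both are configuration-exposed (we default to normalized ratios and
bin 300).

## Interactome and pathway labels

Edges are undirected, keyed by canonical (sorted) pair; self-loops drop;
duplicate and reciprocal records collapse. MITAB detection-method and
score columns are ignored — literature pairs are binary evidence. The
literature-overlap diagnostic is |both| / (|experimental| + |both|).
Complexes among a bait's preys are connected components (size ≥ 2) of the
literature edges induced on the prey set; experimental edges can be
included by flag but are off by default since the complex evidence is
meant to be independent of the pull-down itself.

The over-representation test is an exact hypergeometric upper tail
computed in log space (`gammaln` + `logsumexp`), so p-values of 1e-30 keep
full relative precision. No multiple-testing correction is applied by
default — the labeling criterion is a raw p < 0.005, matching the reported
procedure; Benjamini–Hochberg is available as an option. The default
background is the union of all annotation-set members and all network
nodes, overridable by file. One label per bait (best p below alpha); the
full ranked table is always written.

## Substrate inference

A "binding step" is one physical-interaction edge; a direct
phosphatase–substrate edge is one step. Path enumeration is a depth-first
search over simple paths from the bait, with two structural rules: the
first pathway member reached terminates the path (bridges lie outside the
pathway model), and the step budget is 2 edges, or 3 when the phosphatase
is declared a holoenzyme catalytic subunit in the phosphatase metadata
table (the regulatory subunit consumes a step). Holoenzyme membership is
explicit input, never inferred. Output ordering is deterministic (steps,
then lexicographic path), and the whole inference is invariant to input
permutation.

The five filter rules form a pipeline: residue compatibility (rule 4) is
evaluated on the functional sites surviving rule 3, and phenotype
consistency (rule 5) on the compatible sites surviving rule 4. A rule
whose input is empty therefore fails, and every rule downstream of a
failure is recorded as failed too; the meaningful datum for a rejected
hypothesis is the *first* failed rule. All five flags are always present
in the output record.

Sign semantics for rule 5: phosphatase knockdown raises the substrate
site's phosphorylation (one logical step); the site's functional effect
(+1 activating, −1 inhibiting) then propagates along every simple directed
pathway route from substrate to readout of at most `max_pathway_depth`
edges (default 4), multiplying edge signs. The substrate equal to the
readout contributes the identity (+1) influence. Routes may disagree,
giving the ambiguous prediction {+1, −1}; ambiguity is reported, never
silently resolved. Strict mode requires the observed sign to be the unique
prediction; permissive mode (default) only requires membership. The
default is permissive because real pathway models contain genuine
feedback: in the curated bundle the ERK ⊣ RAF1 negative feedback makes the
prediction for a direct ERK substrate ambiguous, and the observed negative
sign from the screen is only explainable permissively. Rule 5 must hold
for all of the phosphatase's readout records by default (`any` by flag);
with no phenotype records the rule is not evaluable and fails with a
logged reason.

Motif scans are supporting evidence only, never a filter. The SH3 scanner
matches the class-II polyproline core `[RK]P.{2,3}P..P` and extends each
match rightwards across the maximal contiguous run of P/R/K residues, so
the reported interval covers the whole proline-rich stretch (the
documented 11-mer RPPPPYPPPRP is reported in full rather than truncated at
the core); when the core finds nothing, a permissive fallback reports
7-mers with ≥ 4 prolines containing a PxxP. The pattern is
configuration-overridable. The PDZ scanner checks the terminal tripeptide
against L-[DE]-Φ with Φ ∈ {A,V,L,I,M,F,W,Y}. Motif coordinates are 1-based
inclusive; site positions are 1-based on the annotation's sequence.

## Synthetic benchmark

The generator emulates the statistical structure the enrichment analysis
assumes, not mass spectra: log10 intensities uniform on [5, 10) for
background, [8.5, 10) for true interactors (specific interactors dominate
the eluate); log2 ratios Gaussian with spread `noise_sd · (1 + slope · d)`
piecewise-constant over intensity deciles `d` counted from the top —
the minimal structure that makes the binned statistic differ from a global
z-test; a +`log2_shift` mean for true interactors; peptide counts
2 + Poisson(3) with ≥ 10 % of background forced to a single peptide so the
peptide rule is exercised. Defaults: 1000 background, 30 true interactors,
shift 2.0, sd 0.3, slope 0.1 per decile. Every generator is a pure
function of (seed, label) — byte-identical reruns.

Two closed forms accompany the generator. Expected recall integrates
`Φ((shift − log2 1.9)/sd_d)` over the analytically computed decile weights
of the true-interactor intensity distribution; expected background
false-positive rate integrates `Φ(−log2 1.9 / sd_d)` over the background
weights times the multi-peptide fraction. Both rely on the fold cutoff
dominating the `sigB` cutoff under the default conditions
(`z* · spread < log2 1.9` in every bin, even allowing for the planted
interactors inflating the upper bin percentiles); tests compare
Monte-Carlo means against these predictions within two Monte-Carlo
standard errors (recall, one-sided as the prediction is the target to
meet) or a few relative percent (false positives, where percentile
estimation noise is ignored by the closed form).

The network generator plants phosphatase–bridge–substrate chains on
dedicated nodes wired only along their chain, over a G(n, m) background
graph (200 nodes, mean degree 4): recovery or failure of a chain is then
attributable to exactly the planted cause, never to accidental shortcuts.
The first planted triad is a holoenzyme (regulatory subunit + bridge,
3 steps). One decoy per rule: an "other"-role substrate, an
unknown-effect site, a Tyr-phosphatase with a Ser site, a flipped
phenotype sign, and a monomeric phosphatase with a 3-edge chain.
Annotations are generated with the same sign-propagation function the
inference uses, so planted chains are consistent by construction — the
benchmark validates the plumbing and the filter logic, not the biological
truth of any rule.

What passing does not show: real AP-MS tables have correlated ratios,
missing values, shared peptides and non-Gaussian tails; real PPI layers
have hub-dominated degree distributions and study bias; and real pathway
models are incomplete. The benchmark makes no claim about those.

## Curated fixture

The miniature bundle hand-codes published case-study relations
(DUSP18–CAT–SHP2, DUSP26–SCRIB–ERK with the ATM/Fanconi/TTT prey complex,
PPP3CA→PPP3R1→AKAP5→RAF1 with the inhibitory Thr401 site, PTPN21–GRB2
with the SH3 motif). SILAC values and sequences are synthetic stand-ins
shaped to produce the documented calls; the AKAP5–RAF1 edge is an
illustrative stand-in for an unnamed anchor. Its literature layer is
arranged so that exactly 1 of 10 bait–prey edges is literature-supported,
echoing the ~10 % overlap typical of such screens.

## Numerical and engineering choices

- Percentiles: linear interpolation between closest ranks (the numpy
  default); the test oracle re-implements this from scratch.
- Intensity ties: broken lexicographically by protein id, making bin
  assignment — and hence every downstream number — order-invariant.
- Hypergeometric tail: log-space accumulation; exhaustively checked
  against rational-arithmetic enumeration for all backgrounds N ≤ 25.
- Determinism: no timestamps in outputs; the run manifest records a
  configuration hash, package version, seed and per-stage row counts, and
  fully determines the outputs.
- Failure handling: a failing stage renames its partial outputs to
  `*.partial` and aborts naming the stage; a missing phenotype table is
  rejected up front because filter rule 5 cannot be evaluated without it.
- Problem sizes in tests: oracle comparisons use up to 5000-protein
  tables, 12-node graphs and N ≤ 25 backgrounds; calibration uses 10 000
  proteins; recall/false-positive checks use 200 single-bait replicates —
  sizes at which the Monte-Carlo error bounds above are meaningful while
  the full suite stays fast.

## Known limitations

- Protein identity is a single uppercase-symbol namespace; accession
  mapping must happen upstream.
- The pathway model is small and hand-made by design; sign propagation
  over large, densely cyclic models would need path sampling rather than
  exhaustive simple-path enumeration.
- Rule 5 treats one logical dephosphorylation step and multiplicative
  sign propagation; kinetics, partial effects and combinatorial site
  logic are out of scope.
- The enrichment statistic assumes within-bin unimodality; bimodal
  contamination (e.g. affinity-resin keratins not flagged upstream) will
  distort the bin percentiles.
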
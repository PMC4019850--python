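# phosbridge

Inference of phosphatase substrates and adapter ("bridge") proteins from
quantitative interaction proteomics and network analysis.

Protein phosphatases often lack intrinsic sequence specificity for their
substrates: specificity is instead encoded in the network of physical
interactions — scaffold and adapter proteins — that bring the catalytic
subunit next to its target. `phosbridge` implements, as a reusable tested
pipeline, a strategy for exploiting that observation:

1. **SILAC AP-MS enrichment calling.** Each bait phosphatase's pull-down
   is quantified against an empty-vector control. Log2 ratios are
   median-centered and scored with an intensity-binned outlier statistic
   ("significance B"): proteins are ranked by intensity, split into bins of
   300, and within each bin the standardized distance
   `z = (r − r50) / (r84.13 − r50)` (upper side; symmetric below the
   median) is converted to a tail probability `sigB = ½ erfc(z/√2)`.
   A prey is *significantly enriched* when it has ≥ 2 unique peptides, a
   fold ratio strictly > 1.9, and `sigB` strictly < 0.1 on the upper side;
   everything else is the equal-abundance contaminant background. Preys
   are further classed as TNFα-positive/negative/independent from the
   TNF/untreated channel with the same thresholds.
2. **Interactome assembly.** Bait–prey edges are overlaid with a
   literature PPI layer (PSI-MITAB 2.5 or edge list); edges seen in both
   are flagged, and complexes among a bait's preys are read off as
   connected components of the literature edges induced on the prey set.
3. **Guilt by association.** Each bait's prey set is tested against
   KEGG-like gene sets (GMT) with an exact one-sided hypergeometric test
   `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`; the bait is labeled with its best
   pathway at raw p < 0.005.
4. **Substrate inference.** Simple paths
   phosphatase → bridge(s) → substrate are enumerated in the combined
   network (bridges must lie outside the pathway model) and filtered by
   five rules: (1) at most two binding steps — three for holoenzyme
   catalytic subunits such as PP2A/PPP3CA; (2) the substrate is a kinase,
   phosphatase or scaffold of the pathway; (3) it carries phosphosites with
   annotated functional effect; (4) those sites are compatible with the
   enzyme class (a tyrosine phosphatase only removes phospho-Tyr); (5) the
   inferred dephosphorylation explains the siRNA knockdown phenotype:
   knockdown raises site phosphorylation, and the site effect (±1) times
   the product of signed pathway-edge signs along each route to a readout
   must match the observed sign. SH3 polyproline and C-terminal PDZ motif
   scans provide supporting evidence for bridge binding.

A synthetic-data module generates every input with planted ground truth
(true interactors, bridge chains, single-rule-violating decoys), so the
whole pipeline is testable without any external downloads.

## Worked example

The package ships a hand-curated miniature bundle encoding published case
studies (DUSP18–catalase–SHP2, DUSP26–SCRIB–ERK, calcineurin→RAF1 Thr401,
PTPN21–GRB2):

```bash
phosbridge generate demo --mini
phosbridge run demo/config.yaml
cat demo/results/report.md
```

The report shows (abridged):

```
Network: 18 nodes, 19 edges; 10.0% of bait-prey interactions literature-supported.

## DUSP18
- enriched preys: 1 (tnf_independent: 1)
- accepted substrate hypothesis: DUSP18->CAT->SHP2 (substrate SHP2; ...)

## DUSP26
- enriched preys: 7 (tnf_independent: 7)
- pathway label: DNA_DAMAGE_RESPONSE
- prey complex (6): ATM;FANCD2;FANCI;TELO2;TTI1;TTI2
- accepted substrate hypothesis: DUSP26->SCRIB->ERK (substrate ERK; ...)

## PPP3CA
- accepted substrate hypothesis: PPP3CA->PPP3R1->AKAP5->RAF1 (substrate RAF1; ...)
```

Reading the DUSP18 entry: catalase (CAT) was the single significantly
enriched prey; the inference connects DUSP18 through catalase to the
phosphatase SHP2 in two binding steps, all five filter rules pass, and the
hypothesis is accepted. DUSP26's seven preys form one literature-connected
complex (ATM with the Fanconi and TTT-complex proteins) and give the bait
a DNA-damage pathway label; its path to ERK is accepted in the default
permissive mode because the ERK ⊣ RAF1 negative feedback makes the
predicted knockdown sign ambiguous ({+1, −1}), which tolerates the
observed −1. The calcineurin catalytic subunit PPP3CA is granted three
binding steps (holoenzyme) and reaches RAF1 via its regulatory subunit;
the inhibitory Thr401 site is Ser/Thr-compatible and explains the
observed MAPK phenotype.

The same stages are available programmatically
(`phosbridge.silac.call_enrichment`,
`phosbridge.interactome.assemble_interactome`,
`phosbridge.inference.infer_substrates`, ...) and as separate subcommands
(`enrich`, `network`, `pathways`, `infer`, `report`).

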
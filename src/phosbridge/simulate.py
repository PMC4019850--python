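"""Synthetic input generation with planted ground truth.

Every pipeline input can be generated from a seed: SILAC protein-group
tables with intensity-dependent log-ratio noise and a planted positive
shift for true interactors, a random PPI with planted
phosphatase-bridge-substrate chains, and pathway/site/phenotype
annotations generated to be consistent with the planted chains — plus a
family of decoy chains each violating exactly one inference rule. The
generators are pure functions of their configuration (byte-identical
reruns), which makes every downstream stage testable against known truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .inference import predict_knockdown_sign
from .interactome import PPINetwork
from .io import InputBundle
from .pathways import AnnotationSet
from .types import (
    FILTER_RULES,
    Interaction,
    PathwayModel,
    PhenotypeRecord,
    PhosphataseInfo,
    PhosphoSite,
    ProteinGroup,
    ValidationError,
)

#: decoy classes, one per inference rule
DECOY_CLASSES = (
    "max_steps",
    "substrate_role",
    "functional_sites",
    "residue_compatibility",
    "phenotype_consistency",
)

READOUT = "RDOUT"

#: log10 intensity ranges of background proteins and planted interactors
#: (specific interactors dominate the eluate, hence the high range)
LOG10_INTENSITY_BG = (5.0, 10.0)
LOG10_INTENSITY_TRUE = (8.5, 10.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe a realistic single pull-down: ~1000 quantified
    background proteins with log2-ratio noise of 0.3 at high intensity
    (widening by 10% per intensity decile toward the low end), 30 true
    interactors shifted by +2 log2 units, a 200-node literature PPI of mean
    degree 4, three planted phosphatase-bridge-substrate chains and one
    decoy per inference rule.
    """

    seed: int = 0
    n_background: int = 1000
    n_true_interactors: int = 30
    log2_shift: float = 2.0
    noise_sd: float = 0.3
    intensity_spread_slope: float = 0.1
    network_size: int = 200
    mean_degree: float = 4.0
    n_planted_triads: int = 3
    decoy_classes: tuple[str, ...] = DECOY_CLASSES

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if min(self.n_background, self.n_true_interactors,
               self.network_size, self.n_planted_triads) < 0:
            raise ValidationError("counts must be >= 0")
        unknown = set(self.decoy_classes) - set(DECOY_CLASSES)
        if unknown:
            raise ValidationError(f"unknown decoy classes {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted: per-bait true interactors, consistent
    phosphatase-bridge-substrate chains, and single-rule-violating decoys."""

    true_interactors: dict[str, set[str]] = field(default_factory=dict)
    planted_triads: list[tuple[str, tuple[str, ...], str]] = field(
        default_factory=list
    )
    decoys: list[tuple[tuple[str, tuple[str, ...], str], str]] = field(
        default_factory=list
    )


def _rng(cfg: SimulationConfig, label: str) -> np.random.Generator:
    # independent, reproducible stream per (seed, label)
    return np.random.default_rng(
        [cfg.seed & 0x7FFFFFFF, zlib.crc32(label.encode()) & 0x7FFFFFFF]
    )


# --------------------------------------------------------------------------
# SILAC tables
# --------------------------------------------------------------------------

def simulate_protein_groups(
    cfg: SimulationConfig,
    bait: str,
    true_interactor_names: list[str] | None = None,
) -> tuple[list[ProteinGroup], GroundTruth]:
    """One bait's protein-group table with planted true interactors.

    Background proteins get log10 intensities uniform on [5, 10) and log2
    ratios ~ Normal(0, sd) with sd = noise_sd * (1 + slope * d), d counting
    deciles down from the most intense; true interactors sit in the
    high-intensity range (log10 intensity in [8.5, 10), as specific
    interactors dominate the eluate) and are shifted by +log2_shift. At
    least 10% of background proteins carry a single unique peptide so the
    peptide filter is exercised; true interactors always have >= 2.
    """
    if cfg.n_true_interactors > cfg.n_background / 10:
        import logging
        logging.getLogger(__name__).warning(
            "n_true_interactors > n_background/10: bin percentiles will be "
            "visibly contaminated by planted interactors"
        )
    rng = _rng(cfg, f"silac:{bait}")
    n_bg, n_true = cfg.n_background, cfg.n_true_interactors

    names_bg = [f"P{i + 1:04d}" for i in range(n_bg)]
    if true_interactor_names is None:
        true_interactor_names = [f"{bait}T{j + 1:03d}" for j in range(n_true)]
    if len(true_interactor_names) != n_true:
        raise ValidationError("need exactly n_true_interactors names")

    log10_int = np.concatenate([
        rng.uniform(*LOG10_INTENSITY_BG, n_bg),
        rng.uniform(*LOG10_INTENSITY_TRUE, n_true),
    ])
    intensity = 10.0 ** log10_int

    # spread grows toward low intensity, piecewise-constant over deciles
    deciles = np.searchsorted(
        np.quantile(log10_int, np.linspace(0.1, 0.9, 9)), log10_int,
        side="right",
    )  # 0 = lowest decile, 9 = highest
    sd = cfg.noise_sd * (1.0 + cfg.intensity_spread_slope * (9 - deciles))

    log2_ratio = rng.normal(0.0, 1.0, n_bg + n_true) * sd
    log2_ratio[n_bg:] += cfg.log2_shift

    peptides = 2 + rng.poisson(3.0, n_bg + n_true)
    n_single = max(1, int(np.ceil(0.10 * n_bg))) if n_bg else 0
    single_idx = rng.choice(n_bg, size=n_single, replace=False) if n_bg else []
    peptides[single_idx] = 1

    tnf_ratio = 2.0 ** (rng.normal(0.0, 1.0, n_bg + n_true) * sd)

    groups = [
        ProteinGroup(
            protein_id=name,
            unique_peptides=int(peptides[i]),
            intensity=float(intensity[i]),
            ratio_bait_vs_ctrl=float(2.0 ** log2_ratio[i]),
            ratio_tnf_vs_untreated=float(tnf_ratio[i]),
        )
        for i, name in enumerate(names_bg + list(true_interactor_names))
    ]
    truth = GroundTruth(true_interactors={bait: set(true_interactor_names)})
    return groups, truth


def analytic_recall_prediction(
    cfg: SimulationConfig, min_ratio: float = 1.9
) -> float:
    """Expected fraction of true interactors passing the fold cutoff.

    A true interactor in intensity decile d (d = 0 the most intense) has
    log2-ratio spread noise_sd * (1 + slope * d) and clears the fold
    threshold with probability Phi((shift - log2 min_ratio) / sd). The
    decile boundaries of the background/true intensity mixture are computed
    in closed form (both components are uniform on log10 intensity), and
    the Gaussian tail is averaged over the deciles weighted by the mass of
    true interactors they contain. The significance-B cutoff is looser than
    the fold cutoff under these conditions (z* * sd << log2 min_ratio even
    with the planted interactors inflating the bin percentiles), so the
    fold term alone gives the prediction.
    """
    from scipy.stats import norm

    bg_lo, bg_hi = LOG10_INTENSITY_BG
    tr_lo, tr_hi = LOG10_INTENSITY_TRUE
    n_bg, n_true = cfg.n_background, cfg.n_true_interactors
    n = n_bg + n_true

    def mixture_cdf(x: float) -> float:
        bg = np.clip((x - bg_lo) / (bg_hi - bg_lo), 0.0, 1.0)
        tr = np.clip((x - tr_lo) / (tr_hi - tr_lo), 0.0, 1.0)
        return (n_bg * bg + n_true * tr) / n

    def quantile(q: float) -> float:
        lo, hi = bg_lo, bg_hi
        for _ in range(80):  # bisection on the piecewise-linear CDF
            mid = 0.5 * (lo + hi)
            if mixture_cdf(mid) < q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    edges = [bg_lo] + [quantile(k / 10.0) for k in range(1, 10)] + [bg_hi]
    threshold = float(np.log2(min_ratio))
    prediction = 0.0
    for decile in range(10):
        lo = max(edges[decile], tr_lo)
        hi = min(edges[decile + 1], tr_hi)
        weight = max(0.0, hi - lo) / (tr_hi - tr_lo)
        if weight == 0.0:
            continue
        sd = cfg.noise_sd * (1.0 + cfg.intensity_spread_slope * (9 - decile))
        prediction += weight * float(
            norm.sf((threshold - cfg.log2_shift) / sd)
        )
    return prediction


def analytic_false_positive_prediction(
    cfg: SimulationConfig, min_ratio: float = 1.9
) -> float:
    """Expected fraction of background proteins called enriched.

    A background protein in decile d passes the fold cutoff with
    probability Phi(-log2 min_ratio / sd_d); the forced single-peptide
    fraction can never pass. As for the recall prediction, the
    significance-B cutoff sits below the fold cutoff in every bin under
    the default conditions, so the fold tail gives the rate. The closed
    form ignores bin-percentile estimation noise, so empirical agreement
    is expected only to within a few relative percent.
    """
    from scipy.stats import norm

    bg_lo, bg_hi = LOG10_INTENSITY_BG
    n_bg = cfg.n_background
    threshold = float(np.log2(min_ratio))
    single_fraction = np.ceil(0.10 * n_bg) / n_bg if n_bg else 0.0

    # background is uniform on log10 intensity, so the mixture deciles cut
    # it almost uniformly; weight each decile by its background mass
    tr_lo, tr_hi = LOG10_INTENSITY_TRUE
    n_true = cfg.n_true_interactors
    n = n_bg + n_true

    def mixture_cdf(x: float) -> float:
        bg = np.clip((x - bg_lo) / (bg_hi - bg_lo), 0.0, 1.0)
        tr = np.clip((x - tr_lo) / (tr_hi - tr_lo), 0.0, 1.0)
        return (n_bg * bg + n_true * tr) / n

    def quantile(q: float) -> float:
        lo, hi = bg_lo, bg_hi
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if mixture_cdf(mid) < q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    edges = [bg_lo] + [quantile(k / 10.0) for k in range(1, 10)] + [bg_hi]
    rate = 0.0
    for decile in range(10):
        weight = (edges[decile + 1] - edges[decile]) / (bg_hi - bg_lo)
        sd = cfg.noise_sd * (1.0 + cfg.intensity_spread_slope * (9 - decile))
        rate += weight * float(norm.sf(threshold / sd))
    return (1.0 - single_fraction) * rate


# --------------------------------------------------------------------------
# PPI with planted chains
# --------------------------------------------------------------------------

def _triad_nodes(cfg: SimulationConfig):
    """Names of planted and decoy chain members.

    The first planted triad models a holoenzyme: its catalytic subunit
    reaches the substrate through a regulatory subunit plus one bridge
    (3 binding steps); the remaining triads use a single bridge (2 steps).
    The ``max_steps`` decoy is a monomeric phosphatase with a 3-edge chain,
    one step beyond its budget.
    """
    planted = []
    for i in range(cfg.n_planted_triads):
        phos, sub = f"PHOS{i + 1}", f"SUB{i + 1}"
        if i == 0:
            bridges = (f"REG{i + 1}", f"BRG{i + 1}")
        else:
            bridges = (f"BRG{i + 1}",)
        planted.append((phos, bridges, sub))
    decoys = []
    for rule in cfg.decoy_classes:
        tag = rule.upper()[:6]
        if rule == "max_steps":
            bridges = (f"DBRA_{tag}", f"DBRB_{tag}")
        else:
            bridges = (f"DBRG_{tag}",)
        decoys.append(((f"DPHOS_{tag}", bridges, f"DSUB_{tag}"), rule))
    return planted, decoys


def simulate_ppi(cfg: SimulationConfig) -> tuple[PPINetwork, GroundTruth]:
    """Random literature PPI with planted chains.

    A G(n, m) background graph provides realistic clutter; planted and
    decoy chains use dedicated nodes wired only along their chain, so each
    chain is recoverable (or fails) for exactly the planted reason rather
    than through accidental shortcuts.
    """
    if cfg.network_size < 20:
        raise ValidationError("network_size must be >= 20")
    rng = _rng(cfg, "ppi")
    n = cfg.network_size
    m = int(round(cfg.mean_degree * n / 2.0))
    seed = int(rng.integers(0, 2**31 - 1))
    background = nx.gnm_random_graph(n, m, seed=seed)

    net = PPINetwork()
    for i in range(n):
        net.add_node(f"N{i + 1:04d}")
    for u, v in sorted(background.edges):
        if u == v:
            continue
        net.add_interaction(
            Interaction(a=f"N{u + 1:04d}", b=f"N{v + 1:04d}",
                        source="literature")
        )

    planted, decoys = _triad_nodes(cfg)
    truth = GroundTruth(planted_triads=planted, decoys=decoys)
    for phos, bridges, sub in planted + [d[0] for d in decoys]:
        chain = (phos,) + bridges + (sub,)
        for a, b in zip(chain, chain[1:]):
            net.add_interaction(Interaction(a=a, b=b, source="literature"))
    return net, truth


# --------------------------------------------------------------------------
# Pathway model + annotations consistent with the planted chains
# --------------------------------------------------------------------------

_GOOD_ROLES = ("kinase", "phosphatase", "scaffold")


def simulate_pathway_and_annotations(
    cfg: SimulationConfig,
    truth: GroundTruth,
) -> tuple[PathwayModel, list[PhosphoSite], list[PhenotypeRecord],
           list[PhosphataseInfo]]:
    """Annotations that make every planted chain pass all five rules and
    every decoy fail exactly its designated rule.

    Each substrate gets a direct signed edge to the readout node and a
    functional phosphosite compatible with its phosphatase's specificity;
    the observed knockdown sign is then computed with the same sign
    propagation the inference uses, so planted chains are consistent by
    construction. Decoys deviate in exactly one ingredient: an "other"
    substrate role, an unknown-effect site, an incompatible residue, a
    flipped phenotype sign, or a chain one step too long.
    """
    rng = _rng(cfg, "annotations")
    triads = list(truth.planted_triads)
    decoy_items = list(truth.decoys)

    members: set[str] = {READOUT}
    roles: dict[str, str] = {READOUT: "other"}
    edges: list[tuple[str, str, int]] = []
    sites: list[PhosphoSite] = []
    phenotypes: list[PhenotypeRecord] = []
    infos: list[PhosphataseInfo] = []

    def plant(phos: str, sub: str, rule: str | None, holoenzyme: bool) -> None:
        members.add(sub)
        roles[sub] = ("other" if rule == "substrate_role"
                      else str(rng.choice(_GOOD_ROLES)))
        edge_sign = int(rng.choice([+1, -1]))
        edges.append((sub, READOUT, edge_sign))

        if rule == "residue_compatibility":
            specificity = "tyrosine"  # dual enzymes accept everything
        elif holoenzyme:
            specificity = "ser_thr"
        else:
            specificity = str(rng.choice(["tyrosine", "ser_thr", "dual"]))
        infos.append(
            PhosphataseInfo(
                id=phos, specificity=specificity,
                holoenzyme_group="HOLO1" if holoenzyme else None,
            )
        )

        if rule == "residue_compatibility":
            residue = "S"  # functional but untouchable by a Tyr phosphatase
        elif specificity == "tyrosine":
            residue = "Y"
        elif specificity == "ser_thr":
            residue = str(rng.choice(["S", "T"]))
        else:
            residue = str(rng.choice(["S", "T", "Y"]))
        effect = ("unknown" if rule == "functional_sites"
                  else str(rng.choice(["activating", "inhibiting"])))
        site = PhosphoSite(protein=sub, residue=residue,
                           position=int(rng.integers(1, 500)),
                           functional_effect=effect)
        sites.append(site)

        # observed sign from the same propagation logic the inference uses
        reference = (site if site.functional_effect != "unknown"
                     else PhosphoSite(protein=sub, residue=residue,
                                      position=site.position,
                                      functional_effect="activating"))
        predicted = (+1 if reference.functional_effect == "activating"
                     else -1) * edge_sign
        observed = -predicted if rule == "phenotype_consistency" else predicted
        phenotypes.append(
            PhenotypeRecord(phosphatase=phos, readout=READOUT,
                            knockdown_sign=observed,
                            concordant_sirnas=int(rng.integers(2, 5)))
        )

    for i, (phos, bridges, sub) in enumerate(triads):
        plant(phos, sub, rule=None, holoenzyme=(i == 0))
    for (phos, bridges, sub), rule in decoy_items:
        plant(phos, sub, rule=rule, holoenzyme=False)

    pathway = PathwayModel(members=members, edges=edges, roles=roles,
                           readouts={READOUT})

    # consistency guard: re-derive each planted observed sign with the real
    # propagation function (direct edge, so the sets are singletons)
    by_phos = {r.phosphatase: r for r in phenotypes}
    for i, (phos, bridges, sub) in enumerate(triads):
        site = next(s for s in sites if s.protein == sub)
        signs = predict_knockdown_sign(sub, site, pathway, READOUT)
        assert signs == {by_phos[phos].knockdown_sign}

    return pathway, sites, phenotypes, infos


# --------------------------------------------------------------------------
# Full bundle
# --------------------------------------------------------------------------

def simulate_bundle(cfg: SimulationConfig) -> tuple[InputBundle, GroundTruth]:
    """Generate every pipeline input with one coherent ground truth.

    Each planted or decoy phosphatase becomes a bait whose SILAC table
    contains its first bridge among the planted true interactors, so the
    experimental stage (enrichment -> interactome) links the bait to its
    chain exactly as a real pull-down would.
    """
    net, truth = simulate_ppi(cfg)
    pathway, sites, phenotypes, infos = simulate_pathway_and_annotations(
        cfg, truth
    )

    protein_groups: dict[str, list[ProteinGroup]] = {}
    all_chains = truth.planted_triads + [d[0] for d in truth.decoys]
    for phos, bridges, sub in all_chains:
        names = [bridges[0]] + [
            f"{phos}T{j + 1:03d}" for j in range(cfg.n_true_interactors - 1)
        ]
        groups, silac_truth = simulate_protein_groups(cfg, phos, names)
        protein_groups[phos] = groups
        truth.true_interactors.update(silac_truth.true_interactors)

    rng = _rng(cfg, "annotation_sets")
    nodes = sorted(net.nodes)
    annotation_sets = []
    for k in range(3):
        size = int(rng.integers(8, 20))
        members = frozenset(rng.choice(nodes, size=size, replace=False))
        annotation_sets.append(AnnotationSet(name=f"SET{k + 1}",
                                             members=members))

    bundle = InputBundle(
        protein_groups=protein_groups,
        literature=set(net.interactions()),
        pathway=pathway,
        sites=sites,
        phenotypes=phenotypes,
        phosphatases={p.id: p for p in infos},
        annotation_sets=annotation_sets,
    )
    return bundle, truth
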
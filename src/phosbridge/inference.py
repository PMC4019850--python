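"""Graph-based phosphatase substrate inference.

The core procedure: enumerate short phosphatase -> bridge -> substrate
paths in the combined (experimental + literature) PPI that end at a member
of a directed signed pathway model, then apply five filter rules to each
candidate path:

1. binding-step limit — at most two interaction edges, three when the
   phosphatase is the catalytic subunit of a holoenzyme;
2. the substrate must act as a kinase, phosphatase or scaffold in the
   pathway;
3. the substrate must carry phosphosites with an annotated functional
   effect;
4. those sites must be chemically compatible with the enzyme class
   (a tyrosine phosphatase only removes phospho-tyrosine);
5. the inferred dephosphorylation must explain the readout phenotype seen
   when the phosphatase is knocked down: knockdown raises the substrate
   site's phosphorylation, the site's effect (activating/inhibiting) and
   the signs along directed pathway routes to each readout propagate
   multiplicatively, and the predicted sign set must match the observed
   sign (strictly unique match, or permissive set membership).

Rules 3-5 form a pipeline (rule 4 sees only rule-3 survivors, rule 5 only
rule-4 survivors); a rule that cannot be evaluated because its input is
empty is recorded as failed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .interactome import PPINetwork
from .motifs import scan_pdz_cterm_motif, scan_sh3_motif
from .types import (
    FILTER_RULES,
    PathwayModel,
    PhenotypeRecord,
    PhosphataseInfo,
    PhosphoSite,
    SubstrateHypothesis,
    SUBSTRATE_ROLES,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class InferenceConfig:
    """Tunables of the substrate-inference stage.

    ``mode`` controls rule 5: ``permissive`` accepts an observed sign that
    is merely a member of the predicted sign set (ambiguous pathway routes
    tolerated); ``strict`` demands a unique matching prediction.
    ``require_all_readouts`` applies rule 5 over every phenotype record of
    the phosphatase (default) rather than at least one.
    """

    mode: str = "permissive"
    max_pathway_depth: int = 4
    require_all_readouts: bool = True
    max_steps_override: Optional[int] = None
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "permissive"):
            raise ValidationError(f"invalid mode {self.mode!r}")


def max_steps_for(p: PhosphataseInfo) -> int:
    """Binding-step budget: two edges, three for holoenzyme catalytic
    subunits (the regulatory subunit consumes one step)."""
    return 3 if p.holoenzyme_group else 2


def enumerate_bridge_paths(
    net: PPINetwork,
    p: PhosphataseInfo,
    pathway: PathwayModel,
    max_steps: int,
) -> list[tuple[str, ...]]:
    """All simple paths of 1..max_steps edges from the phosphatase to a
    pathway member whose intermediate nodes are NOT pathway members.

    The first pathway member reached terminates a path, so bridges always
    lie outside the pathway. Output is deterministic: sorted by step count,
    then lexicographically by the node sequence.
    """
    bait = p.id.upper()
    if bait not in net.nodes:
        raise ValidationError(f"phosphatase {bait} absent from network")
    members = {m.upper() for m in pathway.members}
    paths: list[tuple[str, ...]] = []

    def extend(path: list[str]) -> None:
        here = path[-1]
        if len(path) - 1 >= max_steps:
            return
        for nbr in sorted(net.neighbors(here)):
            if nbr in path:
                continue
            if nbr in members:
                paths.append(tuple(path) + (nbr,))
                continue  # pathway member terminates the path
            extend(path + [nbr])

    extend([bait])
    return sorted(paths, key=lambda pth: (len(pth), pth))


def filter_substrate_role(substrate: str, pathway: PathwayModel) -> bool:
    """Rule 2: substrate acts as kinase, phosphatase or scaffold."""
    role = pathway.role_of(substrate)
    if substrate not in pathway.roles:
        logger.info("substrate %s has no role annotation; treated as other",
                    substrate)
    return role in SUBSTRATE_ROLES


def filter_functional_sites(
    substrate: str, sites: Iterable[PhosphoSite]
) -> list[PhosphoSite]:
    """Rule 3: the substrate's phosphosites with a defined functional role."""
    return [s for s in sites
            if s.protein == substrate and s.functional_effect != "unknown"]


def filter_residue_compatibility(
    p: PhosphataseInfo, sites: Sequence[PhosphoSite]
) -> list[PhosphoSite]:
    """Rule 4: keep sites the enzyme class can dephosphorylate."""
    if p.specificity == "tyrosine":
        allowed = {"Y"}
    elif p.specificity == "ser_thr":
        allowed = {"S", "T"}
    else:  # dual-specificity
        allowed = {"S", "T", "Y"}
    return [s for s in sites if s.residue in allowed]


def predict_knockdown_sign(
    substrate: str,
    site: PhosphoSite,
    pathway: PathwayModel,
    readout: str,
    max_pathway_depth: int = 4,
) -> set[int]:
    """Predicted readout response to phosphatase knockdown via one site.

    Knockdown raises the site's phosphorylation; the site effect (+1
    activating, -1 inhibiting) then propagates along every simple directed
    pathway route substrate -> readout of at most ``max_pathway_depth``
    edges, multiplying edge signs. When the substrate IS the readout the
    influence product is +1. Disagreeing routes yield {+1, -1}; no route
    yields the empty set.
    """
    if substrate not in pathway.members or readout not in pathway.members:
        raise ValidationError("substrate and readout must be pathway members")
    site_sign = +1 if site.functional_effect == "activating" else -1

    if substrate == readout:
        return {site_sign}

    g = nx.DiGraph()
    g.add_nodes_from(pathway.members)
    for src, dst, sign in pathway.edges:
        g.add_edge(src, dst, sign=sign)
    signs: set[int] = set()
    for path in nx.all_simple_paths(g, substrate, readout,
                                    cutoff=max_pathway_depth):
        product = site_sign
        for u, v in zip(path, path[1:]):
            product *= g.edges[u, v]["sign"]
        signs.add(product)
        if signs == {+1, -1}:
            break
    return signs


def filter_phenotype_consistency(
    p: PhosphataseInfo,
    substrate: str,
    sites: Sequence[PhosphoSite],
    pathway: PathwayModel,
    phenotypes: Iterable[PhenotypeRecord],
    mode: str = "permissive",
    max_pathway_depth: int = 4,
    require_all_readouts: bool = True,
) -> tuple[bool, dict[str, tuple[tuple[int, ...], int]]]:
    """Rule 5: does dephosphorylation of ``substrate`` explain the screen?

    For each observed (readout, knockdown sign) of the phosphatase the
    predicted sign set is the union over compatible ``sites`` of
    :func:`predict_knockdown_sign`. Strict mode requires the observed sign
    to be the unique prediction; permissive mode only requires membership.
    Returns (passed, detail) with detail mapping each readout to
    (predicted signs sorted, observed sign).
    """
    records = [r for r in phenotypes if r.phosphatase == p.id]
    detail: dict[str, tuple[tuple[int, ...], int]] = {}
    if not records:
        logger.info("rule 5 not evaluable for %s: no phenotype records", p.id)
        return False, detail
    if not sites:
        for r in records:
            detail[r.readout] = ((), r.knockdown_sign)
        return False, detail

    verdicts: list[bool] = []
    for r in records:
        predicted: set[int] = set()
        for site in sites:
            predicted |= predict_knockdown_sign(
                substrate, site, pathway, r.readout, max_pathway_depth
            )
        detail[r.readout] = (tuple(sorted(predicted)), r.knockdown_sign)
        if mode == "strict":
            verdicts.append(predicted == {r.knockdown_sign})
        else:
            verdicts.append(r.knockdown_sign in predicted)
    passed = all(verdicts) if require_all_readouts else any(verdicts)
    return passed, detail


def _motif_support(
    hypothesis_nodes: Sequence[str], sequences: Mapping[str, str]
) -> list[tuple[str, str, str]]:
    """Supporting motif evidence on the proteins of one path."""
    support: list[tuple[str, str, str]] = []
    for node in hypothesis_nodes:
        seq = sequences.get(node)
        if not seq:
            continue
        for start, end, match in scan_sh3_motif(seq):
            support.append((node, "sh3_class_ii", f"{start}-{end}:{match}"))
        if len(seq) >= 3 and scan_pdz_cterm_motif(seq):
            support.append((node, "pdz_cterm", seq[-3:]))
    return support


def infer_substrates(
    net: PPINetwork,
    p: PhosphataseInfo,
    pathway: PathwayModel,
    sites: Sequence[PhosphoSite],
    phenotypes: Sequence[PhenotypeRecord],
    config: InferenceConfig = InferenceConfig(),
) -> list[SubstrateHypothesis]:
    """Run the full five-rule inference for one phosphatase.

    Every enumerated path is emitted with its per-rule record; a hypothesis
    is accepted when all five rules pass. Output is sorted accepted-first,
    then by step count and substrate symbol — deterministic and invariant
    to input ordering.
    """
    max_steps = (config.max_steps_override
                 if config.max_steps_override is not None
                 else max_steps_for(p))
    hypotheses: list[SubstrateHypothesis] = []
    for path in enumerate_bridge_paths(net, p, pathway, max_steps):
        substrate = path[-1]
        flags = dict.fromkeys(FILTER_RULES, False)
        flags["max_steps"] = True  # enumerated paths respect the budget
        flags["substrate_role"] = filter_substrate_role(substrate, pathway)

        functional = filter_functional_sites(substrate, sites)
        flags["functional_sites"] = bool(functional)

        compatible = filter_residue_compatibility(p, functional)
        flags["residue_compatibility"] = bool(compatible)

        passed, detail = filter_phenotype_consistency(
            p, substrate, compatible, pathway, phenotypes,
            mode=config.mode,
            max_pathway_depth=config.max_pathway_depth,
            require_all_readouts=config.require_all_readouts,
        )
        flags["phenotype_consistency"] = passed

        hypotheses.append(
            SubstrateHypothesis(
                phosphatase=p.id,
                path=path,
                filters_passed=flags,
                consistency_detail=detail,
                motif_support=_motif_support(path, config.sequences),
            )
        )
    hypotheses.sort(
        key=lambda h: (not h.accepted, h.steps, h.substrate, h.path)
    )
    return hypotheses


def write_hypotheses_tsv(hypotheses: Sequence[SubstrateHypothesis], path) -> None:
    """One row per (path, readout); all five filter flags as columns."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["phosphatase", "path", "substrate", "steps", "accepted"]
            + list(FILTER_RULES)
            + ["readout", "predicted_signs", "observed_sign", "motif_support"]
        )
        for h in hypotheses:
            motifs = ";".join(f"{n}|{kind}|{ev}" for n, kind, ev in
                              h.motif_support)
            readout_rows = sorted(h.consistency_detail.items()) or [
                ("", ((), ""))
            ]
            for readout, (predicted, observed) in readout_rows:
                writer.writerow(
                    [h.phosphatase, "->".join(h.path), h.substrate, h.steps,
                     int(h.accepted)]
                    + [int(h.filters_passed[rule]) for rule in FILTER_RULES]
                    + [readout, ",".join(str(s) for s in predicted),
                       observed, motifs]
                )


def write_accepted_graphml(
    hypotheses: Sequence[SubstrateHypothesis], path
) -> None:
    """Accepted hypotheses as a GraphML of their union of path edges."""
    g = nx.Graph()
    for h in hypotheses:
        if not h.accepted:
            continue
        for u, v in zip(h.path, h.path[1:]):
            g.add_edge(u, v)
        g.nodes[h.path[0]]["kind"] = "phosphatase"
        g.nodes[h.substrate]["kind"] = "substrate"
        for bridge in h.bridges:
            g.nodes[bridge].setdefault("kind", "bridge")
    nx.write_graphml(g, path)
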
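"""A hand-curated miniature input bundle built from published case studies.

The bundle encodes, at toy scale, documented phosphatase-bridge-substrate
relations around the RAS-PI3K/MAPK axis:

* DUSP18 - catalase (CAT) - SHP2: the SH2 domains of SHP2 bind
  tyrosine-phosphorylated catalase, which links the phosphatase to its
  putative substrate in two binding steps;
* DUSP26 - SCRIB - ERK: the SCRIB scaffold binds DUSP26 through a PDZ
  domain (DUSP26 carries an atypical C-terminal L-[DE]-Phi PDZ motif) and
  docks ERK, bridging the phosphatase to the kinase;
* PPP3CA (calcineurin) ...> RAF1 via its regulatory subunit PPP3R1 and an
  anchor protein, a three-binding-step holoenzyme path ending at the
  inhibitory RAF1 Thr401 site whose removal activates MAPK signaling;
* PTPN21 - GRB2: a direct interaction supported by a class-II polyproline
  SH3-binding motif (RPPPPYPPPRP) in PTPN21 matching GRB2's SH3
  specificity.

DUSP26's preys additionally include ATM with the Fanconi proteins FANCI
and FANCD2 and the TTT complex (TELO2, TTI1, TTI2), whose literature
interconnections form a single prey complex.

The signed pathway model is a coarse MAPK cascade with the measured
phospho-ERK level as readout node (ERK_P); it includes the physiological
ERK -| RAF1 negative feedback, which makes the predicted knockdown sign
for a direct ERK substrate ambiguous ({+1, -1}) — exactly the situation
the permissive consistency mode exists for.

Everything here is deterministic and hand-coded. SILAC ratios and protein
sequences are SYNTHETIC stand-ins: the tables are shaped so the documented
preys are called enriched, and the sequences carry the documented motifs
without reproducing real protein sequences.
"""

from __future__ import annotations

import math

from .io import InputBundle
from .pathways import AnnotationSet
from .types import (
    Interaction,
    PathwayModel,
    PhenotypeRecord,
    PhosphataseInfo,
    PhosphoSite,
    ProteinGroup,
)

#: enriched preys of each bait phosphatase
BAIT_PREYS: dict[str, tuple[str, ...]] = {
    "DUSP18": ("CAT",),
    "DUSP26": ("SCRIB", "ATM", "TELO2", "FANCI", "FANCD2", "TTI1", "TTI2"),
    "PPP3CA": ("PPP3R1",),
    "PTPN21": ("GRB2",),
}

#: literature PPI layer (bridge-substrate links, prey complexes, and the
#: PTPN21-GRB2 pair, which is also seen experimentally -> source "both")
LITERATURE_EDGES: tuple[tuple[str, str], ...] = (
    ("CAT", "SHP2"),
    ("SCRIB", "ERK"),
    ("PPP3R1", "AKAP5"),
    ("AKAP5", "RAF1"),
    ("PTPN21", "GRB2"),
    ("ATM", "FANCI"),
    ("ATM", "FANCD2"),
    ("ATM", "TELO2"),
    ("TELO2", "TTI1"),
    ("TELO2", "TTI2"),
)

#: synthetic sequence stand-ins carrying the documented motifs
SEQUENCES: dict[str, str] = {
    # class-II SH3-binding polyproline stretch flanked by non-P/R/K residues
    "PTPN21": "MSEGTQAVNDSTALRPPPPYPPPRPAESFDGKKLSTNE",
    # C-terminus ends with the atypical PDZ-binding motif L-E-L
    "DUSP26": "MGSDKQVAGTNEWFRSTPDACKHLEL",
}

_N_BACKGROUND = {"DUSP26": 60}  # more background where many preys are planted
_DEFAULT_BACKGROUND = 24
_ENRICHED_RATIO = 9.0
_ENRICHED_INTENSITY = 5e9


def _background_rows(bait: str, n: int) -> list[ProteinGroup]:
    """Deterministic equal-abundance background: log2 ratios quasi-uniform
    in [-0.25, 0.25], varied intensities, 2-8 unique peptides."""
    rows = []
    for i in range(n):
        log2_ratio = 0.25 * math.sin(2.399 * (i + 1))
        rows.append(
            ProteinGroup(
                protein_id=f"{bait}BG{i + 1:02d}",
                unique_peptides=2 + ((i * 13) % 7),
                intensity=10.0 ** (6.0 + 3.0 * ((i * 37) % 97) / 97.0),
                ratio_bait_vs_ctrl=2.0 ** log2_ratio,
            )
        )
    # one high-ratio single-peptide identification: excluded by the
    # unique-peptide rule no matter how strong its ratio
    rows.append(
        ProteinGroup(protein_id=f"{bait}SP1", unique_peptides=1,
                     intensity=2e8, ratio_bait_vs_ctrl=8.0)
    )
    return rows


def _protein_groups() -> dict[str, list[ProteinGroup]]:
    tables: dict[str, list[ProteinGroup]] = {}
    for bait, preys in BAIT_PREYS.items():
        rows = _background_rows(bait, _N_BACKGROUND.get(bait,
                                                        _DEFAULT_BACKGROUND))
        for j, prey in enumerate(preys):
            rows.append(
                ProteinGroup(
                    protein_id=prey,
                    unique_peptides=5 + j,
                    intensity=_ENRICHED_INTENSITY * (1.0 + 0.1 * j),
                    ratio_bait_vs_ctrl=_ENRICHED_RATIO + 0.25 * j,
                )
            )
        tables[bait] = rows
    return tables


def _pathway() -> PathwayModel:
    members = {"GRB2", "SHP2", "RAS", "RAF1", "MEK", "ERK", "ERK_P"}
    roles = {
        "GRB2": "scaffold",
        "SHP2": "phosphatase",
        "RAS": "other",
        "RAF1": "kinase",
        "MEK": "kinase",
        "ERK": "kinase",
        "ERK_P": "other",
    }
    edges = [
        ("GRB2", "RAS", +1),
        ("SHP2", "RAS", +1),
        ("RAS", "RAF1", +1),
        ("RAF1", "MEK", +1),
        ("MEK", "ERK", +1),
        ("MEK", "ERK_P", +1),   # MEK writes the measured phospho-ERK level
        ("ERK", "ERK_P", +1),
        ("ERK", "RAF1", -1),    # ERK -| RAF1 negative feedback
    ]
    return PathwayModel(members=members, edges=edges, roles=roles,
                        readouts={"ERK_P"})


def curated_mini_bundle() -> InputBundle:
    """The full hand-coded input bundle (no randomness; see module docs)."""
    sites = [
        # SHP2 C-terminal activating tyrosine
        PhosphoSite("SHP2", "Y", 542, "activating", "activity"),
        # ERK activation-loop TEY sites
        PhosphoSite("ERK", "T", 185, "activating", "activity"),
        PhosphoSite("ERK", "Y", 187, "activating", "activity"),
        # inhibitory RAF1 threonine removed by calcineurin
        PhosphoSite("RAF1", "T", 401, "inhibiting", "activity"),
        # GRB2 tyrosine whose phosphorylation disrupts SH3 binding
        PhosphoSite("GRB2", "Y", 209, "inhibiting", "interaction"),
    ]
    phenotypes = [
        # knockdown of DUSP18 raises phospho-ERK (negative ERK regulator)
        PhenotypeRecord("DUSP18", "ERK_P", +1, 3),
        # the screen scored DUSP26 knockdown as lowering ERK activation
        PhenotypeRecord("DUSP26", "ERK_P", -1, 2),
        # calcineurin activates MAPK via RAF1 Thr401 removal
        PhenotypeRecord("PPP3CA", "ERK_P", -1, 3),
        PhenotypeRecord("PTPN21", "ERK_P", -1, 2),
    ]
    phosphatases = {
        "DUSP18": PhosphataseInfo("DUSP18", "dual"),
        "DUSP26": PhosphataseInfo("DUSP26", "dual"),
        "PPP3CA": PhosphataseInfo("PPP3CA", "ser_thr",
                                  holoenzyme_group="CALCINEURIN"),
        "PTPN21": PhosphataseInfo("PTPN21", "tyrosine"),
    }
    annotation_sets = [
        AnnotationSet("DNA_DAMAGE_RESPONSE",
                      frozenset({"ATM", "FANCI", "FANCD2", "TELO2",
                                 "TTI1", "TTI2"})),
        AnnotationSet("RTK_SIGNALING",
                      frozenset({"GRB2", "SHP2", "RAS", "RAF1", "MEK",
                                 "ERK", "SOS1", "EGFR"})),
        AnnotationSet("PEROXISOME",
                      frozenset({"CAT", "PEX1", "PEX5", "ACOX1"})),
    ]
    return InputBundle(
        protein_groups=_protein_groups(),
        literature={Interaction(a=a, b=b, source="literature")
                    for a, b in LITERATURE_EDGES},
        pathway=_pathway(),
        sites=sites,
        phenotypes=phenotypes,
        phosphatases=phosphatases,
        annotation_sets=annotation_sets,
        sequences=dict(SEQUENCES),
    )
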
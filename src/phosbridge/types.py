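"""Domain types shared across the pipeline.

All protein identifiers are uppercase gene symbols in a single namespace;
any accession mapping happens upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted in its declared format."""


class BinSpreadError(ValueError):
    """Raised when an intensity bin has zero upper/lower log-ratio spread
    but non-constant ratios, making the outlier z-score undefined."""


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable records."""


# --------------------------------------------------------------------------
# SILAC quantification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinGroup:
    """One quantified protein from a single bait pull-down experiment.

    Ratios are positive fold changes on the natural scale:
    ``ratio_bait_vs_ctrl`` compares the untreated bait purification to the
    empty-vector control; the two TNF channels are optional and compare the
    TNF-alpha-treated purification to control and to the untreated bait.
    """

    protein_id: str
    unique_peptides: int
    intensity: float
    ratio_bait_vs_ctrl: float
    ratio_tnf_vs_ctrl: Optional[float] = None
    ratio_tnf_vs_untreated: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if self.unique_peptides < 0:
            raise ValidationError(
                f"{self.protein_id}: unique_peptides must be >= 0"
            )
        if self.intensity < 0:
            raise ValidationError(f"{self.protein_id}: intensity must be >= 0")
        for name in ("ratio_bait_vs_ctrl", "ratio_tnf_vs_ctrl",
                     "ratio_tnf_vs_untreated"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValidationError(
                    f"{self.protein_id}: {name} must be > 0, got {value!r}"
                )


REGULATION_CLASSES = ("tnf_positive", "tnf_negative", "tnf_independent")


@dataclass(frozen=True)
class EnrichmentCall:
    """Per-protein outcome of the enrichment analysis for one bait.

    ``sig_b`` is the intensity-binned outlier probability of the normalized
    log2 ratio; ``side`` records which tail of the bin the protein fell on.
    Only upper-tail (above-median) proteins can be enriched: the experiment
    is a pull-down, so depleted outliers are never interactors.
    """

    protein_id: str
    log_ratio: float
    sig_b: float
    side: str  # "above_median" | "below_median"
    enriched: bool
    regulation: Optional[str] = None  # set only for enriched calls

    def __post_init__(self) -> None:
        if not (0.0 < self.sig_b <= 1.0):
            raise ValidationError(
                f"{self.protein_id}: sig_b must be in (0, 1], got {self.sig_b}"
            )
        if self.side not in ("above_median", "below_median"):
            raise ValidationError(f"invalid side {self.side!r}")
        if self.enriched and self.side != "above_median":
            raise ValidationError("enriched calls must be above the bin median")
        if self.regulation is not None and self.regulation not in REGULATION_CLASSES:
            raise ValidationError(f"invalid regulation {self.regulation!r}")


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Cutoffs for calling a prey significantly enriched.

    Defaults follow the published criteria: at least two unique peptides,
    fold ratio strictly above 1.9 and significance B strictly below 0.1.
    ``bin_size`` controls the intensity binning of the outlier statistic.
    """

    min_unique_peptides: int = 2
    min_ratio: float = 1.9
    max_sig_b: float = 0.1
    bin_size: int = 300

    def __post_init__(self) -> None:
        if not self.min_ratio > 1:
            raise ValidationError("min_ratio must be > 1")
        if not (0 < self.max_sig_b < 1):
            raise ValidationError("max_sig_b must be in (0, 1)")
        if self.bin_size < 20:
            raise ValidationError("bin_size must be >= 20")


# --------------------------------------------------------------------------
# Interactome
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    """An undirected protein-protein interaction.

    ``source`` is ``experimental`` (seen in a pull-down), ``literature``
    (reported in a curated PPI resource) or ``both``. (a, b) is stored in
    canonical (sorted) order so (a, b) and (b, a) compare equal.
    """

    a: str
    b: str
    source: str = "literature"
    regulation: Optional[str] = None
    bait: Optional[str] = None

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValidationError(f"self-interaction {self.a!r} not allowed")
        if self.source not in ("experimental", "literature", "both"):
            raise ValidationError(f"invalid source {self.source!r}")
        a, b = sorted((self.a.upper(), self.b.upper()))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


# --------------------------------------------------------------------------
# Pathway / annotation inputs for substrate inference
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhosphataseInfo:
    """Catalytic specificity and holoenzyme membership of a bait phosphatase."""

    id: str
    specificity: str  # "tyrosine" | "ser_thr" | "dual"
    holoenzyme_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.specificity not in ("tyrosine", "ser_thr", "dual"):
            raise ValidationError(
                f"{self.id}: invalid specificity {self.specificity!r}"
            )


SUBSTRATE_ROLES = ("kinase", "phosphatase", "scaffold")


@dataclass
class PathwayModel:
    """Directed signed model of a signaling pathway.

    ``edges`` are (src, dst, sign) with sign +1 (activation) or -1
    (inhibition); ``roles`` classify members as kinase / phosphatase /
    scaffold / other; ``readouts`` are the phospho-level endpoints scored in
    the functional siRNA screen.
    """

    members: set[str]
    edges: list[tuple[str, str, int]]
    roles: dict[str, str]
    readouts: set[str]

    def __post_init__(self) -> None:
        for src, dst, sign in self.edges:
            if src not in self.members or dst not in self.members:
                raise ValidationError(
                    f"pathway edge {src}->{dst} has endpoint outside members"
                )
            if sign not in (+1, -1):
                raise ValidationError(f"edge sign must be +1/-1, got {sign!r}")
        if not self.readouts:
            raise ValidationError("pathway model needs at least one readout")
        if not self.readouts <= self.members:
            raise ValidationError("readouts must be pathway members")

    def role_of(self, node: str) -> str:
        return self.roles.get(node, "other")


@dataclass(frozen=True)
class PhosphoSite:
    """A residue-level phosphosite annotation with its functional effect."""

    protein: str
    residue: str  # "S" | "T" | "Y"
    position: int
    functional_effect: str = "unknown"  # "activating" | "inhibiting" | "unknown"
    regulates: str = "activity"  # "activity" | "interaction"

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValidationError(f"invalid residue {self.residue!r}")
        if self.position < 1:
            raise ValidationError("site position must be >= 1 (1-based)")
        if self.functional_effect not in ("activating", "inhibiting", "unknown"):
            raise ValidationError(
                f"invalid functional_effect {self.functional_effect!r}"
            )
        if self.regulates not in ("activity", "interaction"):
            raise ValidationError(f"invalid regulates {self.regulates!r}")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Observed readout response to phosphatase knockdown in the siRNA screen.

    ``knockdown_sign`` is +1 when down-regulating the phosphatase raised the
    readout phosphorylation and -1 when it lowered it; ``concordant_sirnas``
    counts independent siRNAs agreeing on the sign.
    """

    phosphatase: str
    readout: str
    knockdown_sign: int
    concordant_sirnas: int = 1

    def __post_init__(self) -> None:
        if self.knockdown_sign not in (+1, -1):
            raise ValidationError("knockdown_sign must be +1 or -1")
        if self.concordant_sirnas < 1:
            raise ValidationError("concordant_sirnas must be >= 1")


# --------------------------------------------------------------------------
# Inference output
# --------------------------------------------------------------------------

FILTER_RULES = (
    "max_steps",               # rule 1: binding-step limit
    "substrate_role",          # rule 2: kinase / phosphatase / scaffold
    "functional_sites",        # rule 3: annotated functional phosphosites
    "residue_compatibility",   # rule 4: residue class matches enzyme class
    "phenotype_consistency",   # rule 5: explains the knockdown phenotype
)


@dataclass
class SubstrateHypothesis:
    """One phosphatase -> bridge(s) -> substrate path with its filter record.

    ``filters_passed`` holds one boolean per rule; a hypothesis is accepted
    when all five are True. Rules form a pipeline (residue compatibility is
    evaluated on the functional sites, phenotype consistency on the
    compatible sites), so a False early in the chain makes downstream rules
    unevaluable and they are recorded False as well.
    """

    phosphatase: str
    path: tuple[str, ...]
    filters_passed: dict[str, bool] = field(default_factory=dict)
    consistency_detail: dict[str, tuple[tuple[int, ...], int]] = field(
        default_factory=dict
    )  # readout -> (sorted predicted signs, observed sign)
    motif_support: list[tuple[str, str, str]] = field(default_factory=list)
    # (protein, motif kind, matched evidence)

    def __post_init__(self) -> None:
        if len(self.path) < 2 or self.path[0] != self.phosphatase:
            raise ValidationError("path must run from the phosphatase")

    @property
    def substrate(self) -> str:
        return self.path[-1]

    @property
    def bridges(self) -> tuple[str, ...]:
        return self.path[1:-1]

    @property
    def steps(self) -> int:
        return len(self.path) - 1

    @property
    def accepted(self) -> bool:
        return all(self.filters_passed.get(rule, False) for rule in FILTER_RULES)
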
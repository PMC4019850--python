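"""Readers and writers for the pipeline's tabular input bundle.

A bundle directory holds everything one analysis run needs:

    protein_groups/<BAIT>.tsv   per-bait SILAC quantification tables
    literature_ppi.tsv          2-column literature PPI edge list
    pathway_edges.tsv           directed signed pathway model (src, dst, sign)
    pathway_roles.tsv           node -> kinase/phosphatase/scaffold/other
    readouts.txt                readout nodes, one per line
    phosphosites.tsv            residue-level functional site annotations
    phenotypes.tsv              siRNA knockdown phenotype signs per readout
    phosphatases.tsv            bait specificity class + holoenzyme group
    annotations.gmt             pathway gene sets for guilt-by-association
    sequences.fasta             optional protein sequences for motif scans
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pathways import AnnotationSet, read_gmt
from .silac import DEFAULT_DIALECT, read_protein_groups
from .types import (
    FormatError,
    Interaction,
    PathwayModel,
    PhenotypeRecord,
    PhosphataseInfo,
    PhosphoSite,
    ProteinGroup,
)


@dataclass
class InputBundle:
    """All inputs of one pipeline run, in memory."""

    protein_groups: dict[str, list[ProteinGroup]]
    literature: set[Interaction]
    pathway: PathwayModel
    sites: list[PhosphoSite]
    phenotypes: list[PhenotypeRecord]
    phosphatases: dict[str, PhosphataseInfo]
    annotation_sets: list[AnnotationSet] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

def read_pathway_model(edges_path, roles_path, readouts_path) -> PathwayModel:
    edges: list[tuple[str, str, int]] = []
    members: set[str] = set()
    with open(edges_path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for col in ("src", "dst", "sign"):
            if col not in (reader.fieldnames or []):
                raise FormatError(f"{edges_path}: missing column {col!r}")
        for row in reader:
            src, dst = row["src"].strip().upper(), row["dst"].strip().upper()
            edges.append((src, dst, int(row["sign"])))
            members |= {src, dst}
    roles: dict[str, str] = {}
    with open(roles_path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            node = row["node"].strip().upper()
            roles[node] = row["role"].strip().lower()
            members.add(node)
    with open(readouts_path) as handle:
        readouts = {line.strip().upper() for line in handle if line.strip()}
    members |= readouts
    return PathwayModel(members=members, edges=edges, roles=roles,
                        readouts=readouts)


def read_phosphosites(path) -> list[PhosphoSite]:
    sites: list[PhosphoSite] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            sites.append(
                PhosphoSite(
                    protein=row["protein"].strip().upper(),
                    residue=row["residue"].strip().upper(),
                    position=int(row["position"]),
                    functional_effect=row["functional_effect"].strip().lower(),
                    regulates=row.get("regulates", "activity").strip().lower(),
                )
            )
    return sites


def read_phenotypes(path) -> list[PhenotypeRecord]:
    records: list[PhenotypeRecord] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            records.append(
                PhenotypeRecord(
                    phosphatase=row["phosphatase"].strip().upper(),
                    readout=row["readout"].strip().upper(),
                    knockdown_sign=int(row["knockdown_sign"]),
                    concordant_sirnas=int(row.get("concordant_sirnas", 1)),
                )
            )
    return records


def read_phosphatase_info(path) -> dict[str, PhosphataseInfo]:
    info: dict[str, PhosphataseInfo] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            pid = row["id"].strip().upper()
            holo = (row.get("holoenzyme_group") or "").strip() or None
            info[pid] = PhosphataseInfo(
                id=pid, specificity=row["specificity"].strip().lower(),
                holoenzyme_group=holo,
            )
    return info


def read_fasta(path) -> dict[str, str]:
    return {
        record.id.strip().upper(): str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def read_bundle(directory, dialect: Optional[dict[str, str]] = None) -> InputBundle:
    """Load a full bundle directory written by :func:`write_bundle`."""
    directory = Path(directory)
    pg_dir = directory / "protein_groups"
    protein_groups = {
        p.stem.upper(): read_protein_groups(p, dialect)
        for p in sorted(pg_dir.glob("*.tsv"))
    }
    from .interactome import read_edge_list  # local import avoids cycle
    literature = read_edge_list(directory / "literature_ppi.tsv")
    pathway = read_pathway_model(
        directory / "pathway_edges.tsv",
        directory / "pathway_roles.tsv",
        directory / "readouts.txt",
    )
    gmt = directory / "annotations.gmt"
    fasta = directory / "sequences.fasta"
    return InputBundle(
        protein_groups=protein_groups,
        literature=literature,
        pathway=pathway,
        sites=read_phosphosites(directory / "phosphosites.tsv"),
        phenotypes=read_phenotypes(directory / "phenotypes.tsv"),
        phosphatases=read_phosphatase_info(directory / "phosphatases.tsv"),
        annotation_sets=read_gmt(gmt) if gmt.exists() else [],
        sequences=read_fasta(fasta) if fasta.exists() else {},
    )


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def _writer(handle):
    return csv.writer(handle, delimiter="\t", lineterminator="\n")


def write_bundle(bundle: InputBundle, directory) -> Path:
    """Materialize a bundle as the directory layout read_bundle expects."""
    directory = Path(directory)
    pg_dir = directory / "protein_groups"
    pg_dir.mkdir(parents=True, exist_ok=True)

    cols = DEFAULT_DIALECT
    for bait, groups in sorted(bundle.protein_groups.items()):
        with open(pg_dir / f"{bait}.tsv", "w", newline="") as handle:
            w = _writer(handle)
            w.writerow([cols["protein_id"], cols["unique_peptides"],
                        cols["intensity"], cols["ratio_bait_vs_ctrl"],
                        cols["ratio_tnf_vs_ctrl"],
                        cols["ratio_tnf_vs_untreated"]])
            for g in groups:
                # repr gives the shortest exact round-trip representation
                w.writerow([
                    g.protein_id, g.unique_peptides, repr(g.intensity),
                    repr(g.ratio_bait_vs_ctrl),
                    "" if g.ratio_tnf_vs_ctrl is None
                    else repr(g.ratio_tnf_vs_ctrl),
                    "" if g.ratio_tnf_vs_untreated is None
                    else repr(g.ratio_tnf_vs_untreated),
                ])

    with open(directory / "literature_ppi.tsv", "w", newline="") as handle:
        w = _writer(handle)
        w.writerow(["protein_a", "protein_b"])
        for inter in sorted(bundle.literature, key=lambda i: i.pair):
            w.writerow([inter.a, inter.b])

    with open(directory / "pathway_edges.tsv", "w", newline="") as handle:
        w = _writer(handle)
        w.writerow(["src", "dst", "sign"])
        for src, dst, sign in sorted(bundle.pathway.edges):
            w.writerow([src, dst, sign])

    with open(directory / "pathway_roles.tsv", "w", newline="") as handle:
        w = _writer(handle)
        w.writerow(["node", "role"])
        for node in sorted(bundle.pathway.members):
            w.writerow([node, bundle.pathway.role_of(node)])

    with open(directory / "readouts.txt", "w") as handle:
        for readout in sorted(bundle.pathway.readouts):
            handle.write(readout + "\n")

    with open(directory / "phosphosites.tsv", "w", newline="") as handle:
        w = _writer(handle)
        w.writerow(["protein", "residue", "position", "functional_effect",
                    "regulates"])
        for s in sorted(bundle.sites,
                        key=lambda s: (s.protein, s.position, s.residue)):
            w.writerow([s.protein, s.residue, s.position,
                        s.functional_effect, s.regulates])

    with open(directory / "phenotypes.tsv", "w", newline="") as handle:
        w = _writer(handle)
        w.writerow(["phosphatase", "readout", "knockdown_sign",
                    "concordant_sirnas"])
        for r in sorted(bundle.phenotypes,
                        key=lambda r: (r.phosphatase, r.readout)):
            w.writerow([r.phosphatase, r.readout, r.knockdown_sign,
                        r.concordant_sirnas])

    with open(directory / "phosphatases.tsv", "w", newline="") as handle:
        w = _writer(handle)
        w.writerow(["id", "specificity", "holoenzyme_group"])
        for pid in sorted(bundle.phosphatases):
            p = bundle.phosphatases[pid]
            w.writerow([p.id, p.specificity, p.holoenzyme_group or ""])

    if bundle.annotation_sets:
        with open(directory / "annotations.gmt", "w") as handle:
            for aset in bundle.annotation_sets:
                handle.write(
                    "\t".join([aset.name, "na"] + sorted(aset.members)) + "\n"
                )

    if bundle.sequences:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(bundle.sequences.items())
        ]
        SeqIO.write(records, str(directory / "sequences.fasta"), "fasta")

    return directory
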
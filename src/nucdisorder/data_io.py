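"""Readers/writers for the external formats and assembly of the study datasets.

The analysis compares a non-nuclear control proteome against nuclear proteins
assigned to intra-nuclear compartments (nucleolus, chromatin, Cajal bodies,
nuclear speckles, PML bodies, nuclear lamina, nuclear pores, perinucleolar
compartment), with an optional mapping onto a protein-protein interaction
network.  This module reads sequences (FASTA), the compartment assignment
table, and the PPI edge list (plain TSV or PSI-MITAB), and builds the named
dataset roles used throughout:

``nnuclear``
    all proteins without a compartment assignment (the control pool);
``nuclear_a`` / ``nuclear_ap``
    compartment-assigned proteins with experimentally annotated provenance /
    with annotated-or-predicted provenance;
``ppi``, ``ppi_nnuclear``, ``ppi_nuclear_ap``
    proteins carrying at least one PPI edge, and the intersections of that
    set with the two groups above.

Residue indexing is 0-based with half-open ``[start, end)`` intervals
throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Controlled vocabulary of intra-nuclear compartment labels.
COMPARTMENTS = (
    "nucleolus",
    "chromatin",
    "cajal_body",
    "nuclear_speckle",
    "pml_body",
    "nuclear_lamina",
    "nuclear_pore",
    "perinucleolar",
)

PROVENANCES = ("annotated", "predicted")


@dataclass
class ProteinRecord:
    """One protein: sequence plus (optional) intra-nuclear localization."""

    protein_id: str
    sequence: str
    compartments: frozenset[str] = frozenset()
    localization_provenance: str = "none"  # annotated | predicted | none

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        self.compartments = frozenset(self.compartments)
        unknown = self.compartments - set(COMPARTMENTS)
        if unknown:
            raise ValueError(
                f"protein {self.protein_id!r}: unknown compartment(s) {sorted(unknown)}; "
                f"allowed: {list(COMPARTMENTS)}"
            )
        if self.compartments and self.localization_provenance == "none":
            raise ValueError(
                f"protein {self.protein_id!r} has compartments but provenance 'none'"
            )
        if not self.compartments and self.localization_provenance != "none":
            raise ValueError(
                f"protein {self.protein_id!r} has provenance "
                f"{self.localization_provenance!r} but no compartments"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_nuclear(self) -> bool:
        return bool(self.compartments)


@dataclass
class StudyDatasets:
    """The named protein subsets the analyses run over."""

    all_proteins: dict[str, ProteinRecord]
    nnuclear: frozenset[str]
    nuclear_a: frozenset[str]
    nuclear_ap: frozenset[str]
    ppi: frozenset[str]
    ppi_nnuclear: frozenset[str]
    ppi_nuclear_ap: frozenset[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def compartment_members(self, compartment: str, within: Iterable[str] | None = None) -> frozenset[str]:
        """Protein ids assigned to ``compartment``, optionally intersected with a role."""
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}; allowed: {list(COMPARTMENTS)}")
        ids = {
            pid
            for pid, rec in self.all_proteins.items()
            if compartment in rec.compartments
        }
        if within is not None:
            ids &= set(within)
        return frozenset(ids)


def read_fasta(path: str | Path, exclude_fragments: bool = False) -> list[ProteinRecord]:
    """Read protein sequences from FASTA; header token up to first whitespace is the id.

    With ``exclude_fragments=True``, entries whose description contains the word
    "fragment" (case-insensitive) are dropped, mirroring the exclusion of
    protein fragments from the source proteome.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if exclude_fragments and "fragment" in entry.description.lower():
            continue
        pid = entry.id
        if pid in seen:
            raise ValueError(f"duplicate protein id in FASTA: {pid!r}")
        seen.add(pid)
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"empty sequence for protein {pid!r}")
        records.append(ProteinRecord(protein_id=pid, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.protein_id, description="")
        for rec in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_compartments(path: str | Path) -> dict[str, tuple[frozenset[str], str]]:
    """Read the compartment assignment table.

    Tab-separated with a header row and columns ``protein_id``, ``compartment``,
    ``provenance``; one row per (protein, compartment).  A protein with any
    annotated row counts as annotated overall (experimental evidence dominates
    the predicted labels).
    """
    labels: dict[str, set[str]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if header and not header.strip():
            return {}
        expected = ["protein_id", "compartment", "provenance"]
        if header and header.rstrip("\n").split("\t") != expected:
            raise ValueError(
                f"compartment table header must be {expected!r}, "
                f"got {header.rstrip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pid, comp, prov = parts
            if comp not in COMPARTMENTS:
                raise ValueError(
                    f"{path}:{lineno}: unknown compartment {comp!r}; "
                    f"allowed: {list(COMPARTMENTS)}"
                )
            if prov not in PROVENANCES:
                raise ValueError(
                    f"{path}:{lineno}: unknown provenance {prov!r}; "
                    f"allowed: {list(PROVENANCES)}"
                )
            labels.setdefault(pid, set()).add(comp)
            if provenance.get(pid) != "annotated":
                provenance[pid] = prov
    return {
        pid: (frozenset(comps), provenance[pid]) for pid, comps in labels.items()
    }


def write_compartments(
    assignments: Mapping[str, tuple[frozenset[str], str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tcompartment\tprovenance\n")
        for pid in sorted(assignments):
            comps, prov = assignments[pid]
            for comp in sorted(comps):
                fh.write(f"{pid}\t{comp}\t{prov}\n")


def _strip_mitab_id(raw: str) -> str:
    # take the first identifier field, strip the "db:" prefix
    first = raw.split("|")[0]
    return first.split(":", 1)[1] if ":" in first else first


def read_edges(path: str | Path, format: str = "tsv") -> list[tuple[str, str]]:
    """Read an undirected interaction edge list.

    ``tsv`` expects two id columns; ``mitab`` a PSI-MITAB table whose first
    two columns carry the interactor identifiers (database prefixes such as
    ``uniprotkb:`` are stripped).  Self-loops are removed and duplicate pairs
    in either orientation collapse to a single edge; the returned pairs are
    lexicographically ordered within each edge and sorted overall.
    """
    if format not in ("tsv", "mitab"):
        raise ValueError(f"unknown edge format {format!r}; use 'tsv' or 'mitab'")
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge line")
            if format == "mitab":
                a, b = _strip_mitab_id(parts[0]), _strip_mitab_id(parts[1])
            else:
                a, b = parts[0], parts[1]
            if a == b:
                continue
            edges.add((a, b) if a < b else (b, a))
    return sorted(edges)


def write_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def assemble_datasets(
    records: Iterable[ProteinRecord],
    compartment_map: Mapping[str, tuple[frozenset[str], str]] | None = None,
    edges: Iterable[tuple[str, str]] | None = None,
) -> StudyDatasets:
    """Attach localization to the records and populate the dataset roles.

    Compartment-map ids absent from the proteome are logged and dropped, as
    are edges with an endpoint not in the proteome.  ``ppi`` is the set of
    proteins retaining at least one surviving edge.
    """
    compartment_map = compartment_map or {}
    proteins: dict[str, ProteinRecord] = {}
    for rec in records:
        if rec.protein_id in proteins:
            raise ValueError(f"duplicate protein id: {rec.protein_id!r}")
        if rec.protein_id in compartment_map:
            comps, prov = compartment_map[rec.protein_id]
            rec = ProteinRecord(
                protein_id=rec.protein_id,
                sequence=rec.sequence,
                compartments=comps,
                localization_provenance=prov,
            )
        proteins[rec.protein_id] = rec

    dropped_ids = sorted(set(compartment_map) - set(proteins))
    if dropped_ids:
        logger.warning(
            "%d compartment-table ids not in the proteome were dropped", len(dropped_ids)
        )

    kept_edges: list[tuple[str, str]] = []
    n_dropped_edges = 0
    for a, b in edges or []:
        if a in proteins and b in proteins and a != b:
            kept_edges.append((a, b) if a < b else (b, a))
        else:
            n_dropped_edges += 1
    kept_edges = sorted(set(kept_edges))
    if n_dropped_edges:
        logger.warning(
            "%d edges with an unresolvable endpoint were dropped", n_dropped_edges
        )

    nuclear_ap = frozenset(pid for pid, rec in proteins.items() if rec.is_nuclear)
    nuclear_a = frozenset(
        pid for pid in nuclear_ap if proteins[pid].localization_provenance == "annotated"
    )
    nnuclear = frozenset(proteins) - nuclear_ap
    ppi = frozenset(pid for edge in kept_edges for pid in edge)
    return StudyDatasets(
        all_proteins=proteins,
        nnuclear=nnuclear,
        nuclear_a=nuclear_a,
        nuclear_ap=nuclear_ap,
        ppi=ppi,
        ppi_nnuclear=nnuclear & ppi,
        ppi_nuclear_ap=nuclear_ap & ppi,
        edges=kept_edges,
    )
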
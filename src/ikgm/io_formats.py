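"""Core genome data model and readers/writers for all external file formats.

The data model mirrors the document analogy used throughout the package:
a species' proteome is a *text*, each protein a *sentence*, and the tokens
of a sentence are either Pfam-style domain names or short peptides.

External formats handled here: protein FASTA (one file per species), a TSV
species manifest (``species_id, label, fasta_path``), a Pfam-style domain
annotation TSV, a two-column protein-to-gene-symbol TSV, and TSV score
tables produced by :mod:`ikgm.attention_scores`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "SpeciesGenome",
    "Manifest",
    "ManifestRow",
    "read_manifest",
    "write_manifest",
    "read_proteome",
    "write_proteome",
    "read_domain_annotations",
    "write_domain_annotations",
    "filter_annotated",
    "read_gene_map",
    "write_gene_map",
    "attach_gene_symbols",
    "write_score_table",
    "read_score_table",
]

#: Residues accepted in protein sequences: the 20 standard amino acids plus
#: 'X' for an unknown residue.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: the *sentence* unit of a genome document."""

    protein_id: str
    sequence: str
    gene_symbol: str | None = None
    domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: illegal residue(s) "
                f"{sorted(bad)!r} (allowed: 20 standard amino acids + 'X')"
            )
        if any(not d for d in self.domains):
            raise ValueError(f"protein {self.protein_id!r}: empty domain name")


@dataclass(frozen=True)
class SpeciesGenome:
    """One species' labeled, ordered set of proteins (the *text* unit)."""

    species_id: str
    label: str
    proteins: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"species {self.species_id!r}: duplicate protein ids {dup}")

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(p.protein_id for p in self.proteins)

    def total_residues(self) -> int:
        return sum(len(p.sequence) for p in self.proteins)


@dataclass(frozen=True)
class ManifestRow:
    species_id: str
    label: str
    fasta_path: str


@dataclass(frozen=True)
class Manifest:
    """Species manifest: one row per species, exactly two taxon labels."""

    rows: tuple[ManifestRow, ...]

    def __post_init__(self) -> None:
        ids = [r.species_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species_id in manifest")
        if len(self.taxa) != 2:
            raise ValueError(
                f"manifest must declare exactly 2 taxon labels, got {sorted(set(r.label for r in self.rows))}"
            )

    @property
    def taxa(self) -> tuple[str, str]:
        """The two taxon labels, sorted lexicographically."""
        labels = sorted({r.label for r in self.rows})
        return tuple(labels)  # type: ignore[return-value]

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(r.species_id for r in self.rows)

    def label_of(self, species_id: str) -> str:
        for r in self.rows:
            if r.species_id == species_id:
                return r.label
        raise KeyError(species_id)

    def species_of(self, label: str) -> tuple[str, ...]:
        return tuple(r.species_id for r in self.rows if r.label == label)

    def __len__(self) -> int:
        return len(self.rows)


def read_manifest(path: str | Path) -> Manifest:
    """Read a TSV manifest with header ``species_id, label, fasta_path``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["species_id", "label", "fasta_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing column(s) {missing}")
    rows = tuple(
        ManifestRow(r.species_id, r.label, r.fasta_path) for r in df.itertuples()
    )
    return Manifest(rows)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.species_id, r.label, r.fasta_path) for r in manifest.rows],
        columns=["species_id", "label", "fasta_path"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_proteome(
    fasta_path: str | Path, species_id: str, label: str
) -> SpeciesGenome:
    """Read one species' protein FASTA into a :class:`SpeciesGenome`.

    The protein id is the first whitespace-delimited token of the FASTA
    header; sequences are uppercased.  Proteins are sorted by protein_id so
    that document order is deterministic regardless of file order.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty or unparseable FASTA: {fasta_path}")
    proteins = []
    seen: set[str] = set()
    for rec in records:
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{fasta_path}: duplicate protein id {pid!r}")
        seen.add(pid)
        proteins.append(ProteinRecord(pid, str(rec.seq).upper()))
    proteins.sort(key=lambda p: p.protein_id)
    return SpeciesGenome(species_id, label, tuple(proteins))


def write_proteome(genome: SpeciesGenome, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in genome.proteins
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_domain_annotations(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a protein-to-domain annotation table.

    Two dialects are auto-detected by column count:

    * 4 columns ``protein_id, domain_name, start, end`` (one row per domain
      hit; Pfam-style 1-based inclusive coordinates) — domains are ordered by
      start coordinate per protein;
    * 2 columns ``protein_id, domains`` where the second column is a
      semicolon-joined, already-ordered domain list.

    A header row is optional and recognised by its column names.  Proteins
    never mentioned are simply absent from the returned mapping.
    """
    starts: dict[str, list[tuple[int, str]]] = {}
    simple: dict[str, list[str]] = {}
    dialect: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("protein_id", "protein"):
                continue
            if dialect is None:
                if len(fields) == 4:
                    dialect = 4
                elif len(fields) == 2:
                    dialect = 2
                else:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 4 tab-separated "
                        f"columns, got {len(fields)}"
                    )
            if len(fields) != dialect:
                raise ValueError(
                    f"{path}:{lineno}: expected {dialect} columns, got {len(fields)}"
                )
            if dialect == 4:
                pid, dom, start_s, _end_s = fields
                if not dom:
                    raise ValueError(f"{path}:{lineno}: empty domain name")
                try:
                    start = int(start_s)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer start coordinate {start_s!r}"
                    ) from exc
                starts.setdefault(pid, []).append((start, dom))
            else:
                pid, doms = fields
                if not doms:
                    raise ValueError(f"{path}:{lineno}: empty domain list")
                simple[pid] = doms.split(";")
    if dialect == 4:
        return {
            pid: tuple(d for _, d in sorted(hits, key=lambda t: t[0]))
            for pid, hits in starts.items()
        }
    return {pid: tuple(doms) for pid, doms in simple.items()}


def write_domain_annotations(
    annotations: Mapping[str, Sequence[str]], path: str | Path
) -> None:
    """Write annotations in the simplified two-column dialect."""
    with open(path, "w") as fh:
        fh.write("protein_id\tdomains\n")
        for pid in sorted(annotations):
            doms = annotations[pid]
            if doms:
                fh.write(f"{pid}\t{';'.join(doms)}\n")


def filter_annotated(
    genome: SpeciesGenome, annotations: Mapping[str, Sequence[str]]
) -> SpeciesGenome:
    """Keep only proteins with at least one functional domain, attaching the
    domain lists; protein order is preserved.  Idempotent."""
    kept = []
    for p in genome.proteins:
        doms = tuple(annotations.get(p.protein_id, ())) or p.domains
        if doms:
            kept.append(replace(p, domains=doms))
    if not kept:
        warnings.warn(
            f"species {genome.species_id!r}: no annotated proteins remain",
            stacklevel=2,
        )
    return replace(genome, proteins=tuple(kept))


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein_id to gene symbol.

    Duplicate protein ids are tolerated only when they agree on the symbol.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("protein_id", "protein"):
                continue
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            pid, sym = fields
            if pid in mapping and mapping[pid] != sym:
                raise ValueError(
                    f"{path}:{lineno}: protein {pid!r} maps to conflicting "
                    f"symbols {mapping[pid]!r} and {sym!r}"
                )
            mapping[pid] = sym
    return mapping


def write_gene_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgene_symbol\n")
        for pid in sorted(mapping):
            fh.write(f"{pid}\t{mapping[pid]}\n")


def attach_gene_symbols(
    genome: SpeciesGenome, gene_map: Mapping[str, str] | None
) -> SpeciesGenome:
    """Attach gene symbols from ``gene_map``.

    With an empty/None map every protein falls back to its own protein_id as
    symbol; with a non-empty map, unmapped proteins keep ``gene_symbol=None``
    and are excluded from gene-level aggregation downstream.
    """
    if not gene_map:
        proteins = tuple(
            replace(p, gene_symbol=p.protein_id) for p in genome.proteins
        )
    else:
        proteins = tuple(
            replace(p, gene_symbol=gene_map.get(p.protein_id))
            for p in genome.proteins
        )
    return replace(genome, proteins=proteins)


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a PAS/GAS/DAS score table as TSV with header."""
    table.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
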
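"""Word-hierarchy construction: domain words (v=1) and variant-kmer words (v=2).

A genome is treated as a *document* whose sentences are proteins.  Two
token vocabularies ("word hierarchies") expose different evolutionary
mechanisms to the classifier:

* **v=1, domain words** — each sentence is the protein's ordered list of
  functional-domain names, so gene-family contraction/expansion shows up as
  token-count differences;
* **v=2, variant kmers** — protein sequences are split at high-frequency
  k-mers ("segment markers") into unequal short peptides, so fixed residue
  substitutions and small indels change the token stream locally.

Marker selection takes all length-k windows of the (augmented) corpus,
counts them, and keeps the k-mers whose count exceeds the chosen quantile
(default: the upper quartile) of the count distribution.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import SpeciesGenome

__all__ = [
    "Document",
    "MarkerSet",
    "tokenize_domains",
    "count_kmers",
    "build_marker_set",
    "segment_by_markers",
    "tokenize_kmer",
    "corpus_retention",
    "write_documents",
    "read_documents",
    "write_marker_set",
    "read_marker_set",
]

DOMAIN_VIEW = 1
KMER_VIEW = 2


@dataclass(frozen=True)
class Document:
    """The tokenized view of one genome under word hierarchy ``view``."""

    species_id: str
    label: str
    view: int
    sentences: tuple[tuple[str, tuple[str, ...]], ...]  # (protein_id, tokens)

    def __post_init__(self) -> None:
        if self.view not in (DOMAIN_VIEW, KMER_VIEW):
            raise ValueError(f"view must be 1 or 2, got {self.view}")
        for pid, tokens in self.sentences:
            if not tokens:
                raise ValueError(f"sentence {pid!r} has no tokens")

    def __len__(self) -> int:
        return len(self.sentences)

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.sentences)

    def token_lists(self) -> list[tuple[str, ...]]:
        return [tokens for _, tokens in self.sentences]


@dataclass(frozen=True)
class MarkerSet:
    """High-frequency k-mers used as segmentation markers."""

    k: int
    markers: frozenset[str]
    threshold: float

    def __post_init__(self) -> None:
        if any(len(m) != self.k for m in self.markers):
            raise ValueError("all markers must have length k")


def tokenize_domains(genome: SpeciesGenome) -> Document:
    """Domain-word document (v=1): one sentence per protein, tokens are the
    ordered domain names with repeats preserved."""
    sentences = []
    for p in genome.proteins:
        if not p.domains:
            raise ValueError(
                f"protein {p.protein_id!r} has no domains; apply "
                "filter_annotated before domain tokenization"
            )
        sentences.append((p.protein_id, tuple(p.domains)))
    return Document(genome.species_id, genome.label, DOMAIN_VIEW, tuple(sentences))


def count_kmers(genomes: Iterable[SpeciesGenome], k: int) -> Counter[str]:
    """Count all length-``k`` windows (step 1) over every protein sequence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    short = 0
    for g in genomes:
        for p in g.proteins:
            s = p.sequence
            if len(s) < k:
                short += 1
                continue
            for i in range(len(s) - k + 1):
                counts[s[i : i + k]] += 1
    if short:
        warnings.warn(f"{short} sequence(s) shorter than k={k} contributed no kmers")
    return counts


def build_marker_set(counts: Mapping[str, int], quantile: float = 0.75) -> MarkerSet:
    """Keep the k-mers whose count strictly exceeds the given quantile
    (linear interpolation) of the count distribution."""
    if not counts:
        raise ValueError("empty kmer counts")
    k = len(next(iter(counts)))
    values = np.fromiter(counts.values(), dtype=float)
    threshold = float(np.quantile(values, quantile))
    markers = frozenset(m for m, c in counts.items() if c > threshold)
    if not markers:
        warnings.warn("no kmer exceeds the quantile threshold; marker set is empty")
    return MarkerSet(k=k, markers=markers, threshold=threshold)


def segment_by_markers(sequence: str, marker_set: MarkerSet) -> tuple[str, ...]:
    """Greedy left-to-right split of a sequence at marker k-mers.

    On a marker match the accumulated prefix (if any) is emitted, then the
    marker itself; scanning resumes after the marker, so matches never
    overlap and concatenating the tokens reproduces the input exactly.
    """
    if not sequence:
        raise ValueError("empty sequence")
    k = marker_set.k
    markers = marker_set.markers
    if not markers or len(sequence) < k:
        return (sequence,)
    tokens: list[str] = []
    buf_start = 0
    i = 0
    last = len(sequence) - k
    while i <= last:
        if sequence[i : i + k] in markers:
            if i > buf_start:
                tokens.append(sequence[buf_start:i])
            tokens.append(sequence[i : i + k])
            i += k
            buf_start = i
        else:
            i += 1
    if buf_start < len(sequence):
        tokens.append(sequence[buf_start:])
    return tuple(tokens)


def tokenize_kmer(genome: SpeciesGenome, marker_set: MarkerSet) -> Document:
    """Variant-kmer document (v=2): each protein sequence segmented at the
    marker k-mers into unequal short peptides."""
    sentences = tuple(
        (p.protein_id, segment_by_markers(p.sequence, marker_set))
        for p in genome.proteins
    )
    return Document(genome.species_id, genome.label, KMER_VIEW, sentences)


def corpus_retention(documents: Sequence[Document], min_count: int = 2) -> float:
    """Fraction of token occurrences whose token type occurs at least
    ``min_count`` times in the corpus (occurrence-weighted coverage at the
    embedding frequency floor)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[str] = Counter()
    for doc in documents:
        for tokens in doc.token_lists():
            counts.update(tokens)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty corpus")
    kept = sum(c for c in counts.values() if c >= min_count)
    return kept / total


# --- serialization ---------------------------------------------------------


def write_documents(documents: Sequence[Document], directory: str | Path) -> None:
    """One ``<species>.v<view>.txt`` file per document (one sentence per
    line, space-joined tokens) plus a JSON-lines index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "index.jsonl", "w") as idx:
        for doc in documents:
            fname = f"{doc.species_id}.v{doc.view}.txt"
            with open(directory / fname, "w") as fh:
                for pid, tokens in doc.sentences:
                    fh.write(" ".join(tokens) + "\n")
            idx.write(
                json.dumps(
                    {
                        "species_id": doc.species_id,
                        "label": doc.label,
                        "view": doc.view,
                        "file": fname,
                        "protein_ids": list(doc.protein_ids),
                    }
                )
                + "\n"
            )


def read_documents(directory: str | Path) -> list[Document]:
    directory = Path(directory)
    docs = []
    with open(directory / "index.jsonl") as idx:
        for line in idx:
            meta = json.loads(line)
            with open(directory / meta["file"]) as fh:
                token_lines = [tuple(l.split()) for l in fh.read().splitlines()]
            sentences = tuple(zip(meta["protein_ids"], token_lines))
            docs.append(
                Document(meta["species_id"], meta["label"], meta["view"], sentences)
            )
    return docs


def write_marker_set(
    marker_set: MarkerSet, counts: Mapping[str, int], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# k={marker_set.k}\tthreshold={marker_set.threshold!r}\n")
        for m in sorted(marker_set.markers):
            fh.write(f"{m}\t{counts.get(m, 0)}\n")


def read_marker_set(path: str | Path) -> MarkerSet:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").split("\t")
        )
        markers = frozenset(line.split("\t")[0] for line in fh if line.strip())
    return MarkerSet(k=int(meta["k"]), markers=markers, threshold=float(meta["threshold"]))
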
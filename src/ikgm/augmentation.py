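"""Neutral-model proteome augmentation.

Deep-learning classifiers need far more labeled examples than there are
sequenced species, so each taxon's genomes are expanded by label-preserving
perturbations that mimic neutral within-species variation:

* **block rearrangement** — the ordered protein list is cut into contiguous
  blocks whose order is shuffled (gene order within a block is kept), and
* **residue substitution** — an exact count ``round(rate * total_residues)``
  of residue positions, sampled uniformly over the concatenated proteome,
  is replaced by a uniform draw from the other standard amino acids.

The substitution rate is capped at 1% so the perturbation stays in the
nearly-neutral regime and cannot plausibly flip the phenotype label.
Augmentation is performed separately per taxon so class balance can be
controlled via per-taxon replicate counts.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AMINO_ACIDS, SpeciesGenome

__all__ = [
    "AugmentationConfig",
    "rearrange_genome",
    "mutate_sequences",
    "augment_taxa",
    "balanced_replicates",
    "origin_id",
]

MAX_MUTATION_RATE = 0.01


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the neutral augmentation model.

    ``replicates_per_genome`` may be a single integer (same for every taxon)
    or a mapping label -> integer so uneven taxa can be balanced; within a
    taxon every original genome gets the same number of replicates.
    """

    n_parts: int = 10
    mutation_rate: float = 0.005
    replicates_per_genome: int | Mapping[str, int] = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parts < 1:
            raise ValueError("n_parts must be >= 1")
        if not (0.0 < self.mutation_rate <= MAX_MUTATION_RATE):
            raise ValueError(
                f"mutation_rate must be in (0, {MAX_MUTATION_RATE}]: substitution "
                "beyond 1% of the proteome is no longer a nearly-neutral perturbation"
            )

    def replicates_for(self, label: str) -> int:
        if isinstance(self.replicates_per_genome, int):
            return self.replicates_per_genome
        return int(self.replicates_per_genome[label])


def rearrange_genome(
    genome: SpeciesGenome, n_parts: int, rng: np.random.Generator
) -> SpeciesGenome:
    """Cut the protein list into ``n_parts`` contiguous near-equal blocks and
    shuffle the block order; order within each block is preserved."""
    n = len(genome.proteins)
    if n_parts > n:
        raise ValueError(f"n_parts={n_parts} exceeds protein count {n}")
    bounds = np.linspace(0, n, n_parts + 1).round().astype(int)
    blocks = [genome.proteins[bounds[i] : bounds[i + 1]] for i in range(n_parts)]
    order = rng.permutation(n_parts)
    proteins = tuple(p for b in order for p in blocks[b])
    return replace(genome, proteins=proteins)


def mutate_sequences(
    genome: SpeciesGenome, mutation_rate: float, rng: np.random.Generator
) -> SpeciesGenome:
    """Substitute exactly ``round(rate * N)`` residues, where N is the total
    residue count, at positions sampled without replacement over the
    concatenated proteome.  Each substitution draws uniformly from the 19
    other standard amino acids; lengths and domain lists are unchanged."""
    if not (0.0 < mutation_rate <= MAX_MUTATION_RATE):
        raise ValueError(
            f"mutation_rate must be in (0, {MAX_MUTATION_RATE}] (nearly-neutral bound)"
        )
    total = genome.total_residues()
    n_sub = int(round(mutation_rate * total))
    if n_sub == 0:
        return genome
    positions = rng.choice(total, size=n_sub, replace=False)
    positions.sort()
    # map flat positions onto (protein index, offset)
    lengths = [len(p.sequence) for p in genome.proteins]
    starts = np.concatenate([[0], np.cumsum(lengths)])
    seqs = [list(p.sequence) for p in genome.proteins]
    aa = np.array(list(AMINO_ACIDS))
    for pos in positions:
        pi = int(np.searchsorted(starts, pos, side="right") - 1)
        off = int(pos - starts[pi])
        current = seqs[pi][off]
        choices = aa[aa != current]
        seqs[pi][off] = str(rng.choice(choices))
    proteins = tuple(
        replace(p, sequence="".join(s)) for p, s in zip(genome.proteins, seqs)
    )
    return replace(genome, proteins=proteins)


def balanced_replicates(
    taxon_sizes: Mapping[str, int], target_per_taxon: int
) -> dict[str, int]:
    """Per-taxon replicate counts ``ceil(target / taxon_size)`` so that both
    taxa reach at least ``target`` genomes after augmentation."""
    return {
        label: math.ceil(target_per_taxon / size)
        for label, size in taxon_sizes.items()
    }


def _variant_rng(seed: int, species_id: str, replicate: int) -> np.random.Generator:
    # independent substream per (species, replicate): augmentation output does
    # not depend on the order genomes are processed in
    key = zlib.crc32(species_id.encode())
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key, replicate])
    return np.random.Generator(np.random.PCG64(ss))


def origin_id(species_id: str) -> str:
    """The original species id of a (possibly augmented) genome."""
    base, sep, tail = species_id.rpartition("_aug")
    if sep and tail.isdigit():
        return base
    return species_id


def augment_taxa(
    genomes: Sequence[SpeciesGenome], config: AugmentationConfig
) -> list[SpeciesGenome]:
    """Expand both taxa: every original genome yields exactly its taxon's
    replicate count of variants (rearrange, then mutate), each under a fresh
    RNG substream.  Originals are retained; variants get ``_augK`` suffixes.
    """
    labels = {g.label for g in genomes}
    if len(labels) != 2:
        raise ValueError(f"expected genomes from exactly 2 taxa, got {sorted(labels)}")
    out: list[SpeciesGenome] = list(genomes)
    for g in genomes:
        n_rep = config.replicates_for(g.label)
        n_parts = min(config.n_parts, len(g.proteins))
        for k in range(1, n_rep + 1):
            rng = _variant_rng(config.seed, g.species_id, k)
            variant = rearrange_genome(g, n_parts, rng)
            variant = mutate_sequences(variant, config.mutation_rate, rng)
            out.append(replace(variant, species_id=f"{g.species_id}_aug{k}"))
    return out
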
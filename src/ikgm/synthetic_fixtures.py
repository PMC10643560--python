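"""Two-taxon synthetic proteomes with planted discriminative genes.

The generator emulates the input side of a real study — per-species protein
FASTA, domain annotations, a protein-to-gene map — for two taxa that share
a common background proteome plus a small number of planted signal genes,
one per evolutionary mechanism the three attention views are meant to
detect:

* ``domain_copy`` — gene-family contraction/expansion: the gene is present
  in a different number of copies in the two taxa (detectable by the domain
  view, v=1);
* ``substitution`` — taxon-fixed non-synonymous substitutions: both taxa
  share a template sequence except at ``n_diagnostic_positions`` residues
  (detectable by the variant-kmer view, v=2);
* ``domain_indel`` — a domain (and its underlying sequence block) present
  in one taxon and absent in the other (detectable by both views, hence by
  the fused view, v=3).

Background genes are drawn once and shared by every species up to a small
per-species substitution noise, so they carry no taxon signal.  Ground
truth (gene to mechanism) is returned for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AMINO_ACIDS,
    Manifest,
    ManifestRow,
    ProteinRecord,
    SpeciesGenome,
    write_domain_annotations,
    write_gene_map,
    write_manifest,
    write_proteome,
)

__all__ = [
    "FixtureConfig",
    "FixtureData",
    "generate_fixture",
    "recovery_report",
    "write_fixture",
]

BACKGROUND = "background"
DOMAIN_COPY = "domain_copy"
SUBSTITUTION = "substitution"
DOMAIN_INDEL = "domain_indel"

#: attention view expected to recover each planted mechanism
MATCHED_VIEW = {DOMAIN_COPY: 1, SUBSTITUTION: 2, DOMAIN_INDEL: 3}


@dataclass(frozen=True)
class FixtureConfig:
    """Scale and signal strength of the synthetic study.

    Defaults are sized so the full pipeline (augmentation, embedding, two
    classifiers, scoring) runs in minutes on one CPU while every mechanism
    stays recoverable.
    """

    n_species_per_taxon: int = 5
    n_background_genes: int = 50
    background_length: tuple[int, int] = (100, 300)
    n_domain_signal_genes: int = 1
    n_substitution_signal_genes: int = 1
    n_indel_signal_genes: int = 1
    n_diagnostic_positions: int = 5
    copy_numbers: tuple[int, int] = (3, 1)
    domain_vocab_size: int = 30
    species_noise_rate: float = 0.005
    domain_noise_prob: float = 0.05
    taxa: tuple[str, str] = ("diurnal", "nocturnal")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species_per_taxon < 1:
            raise ValueError("need at least one species per taxon")
        for name in ("n_background_genes", "n_domain_signal_genes",
                     "n_substitution_signal_genes", "n_indel_signal_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.copy_numbers[0] == self.copy_numbers[1]:
            raise ValueError("copy_numbers must differ between taxa")
        if len(set(self.taxa)) != 2:
            raise ValueError("taxa must be two distinct labels")

    @property
    def n_signal_genes(self) -> int:
        return (
            self.n_domain_signal_genes
            + self.n_substitution_signal_genes
            + self.n_indel_signal_genes
        )


@dataclass
class FixtureData:
    """Everything downstream stages need, plus the planted ground truth."""

    genomes: list[SpeciesGenome]
    annotations: dict[str, tuple[str, ...]]
    gene_map: dict[str, str]
    truth: dict[str, str]  # gene symbol -> mechanism class
    config: FixtureConfig

    @property
    def manifest(self) -> Manifest:
        return Manifest(
            tuple(
                ManifestRow(g.species_id, g.label, f"{g.species_id}.fasta")
                for g in self.genomes
            )
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _noisy(seq: str, rate: float, rng: np.random.Generator,
           protected: frozenset[int] = frozenset()) -> str:
    n = int(round(rate * len(seq)))
    if n == 0:
        return seq
    eligible = np.array([i for i in range(len(seq)) if i not in protected])
    if len(eligible) == 0:
        return seq
    pos = rng.choice(eligible, size=min(n, len(eligible)), replace=False)
    chars = list(seq)
    aa = np.array(list(AMINO_ACIDS))
    for p in pos:
        chars[p] = str(rng.choice(aa[aa != chars[p]]))
    return "".join(chars)


@dataclass
class _GeneSpec:
    symbol: str
    mechanism: str
    base_seq: str
    domains: tuple[str, ...]
    # mechanism-specific payloads
    diag_positions: tuple[int, ...] = ()
    diag_residues: tuple[tuple[str, str], ...] = ()  # per position (taxonA, taxonB)
    insert_at: int = 0
    insert_seq: str = ""
    insert_domain: str = ""


def _build_gene_specs(config: FixtureConfig, rng: np.random.Generator) -> list[_GeneSpec]:
    vocab = [f"PFX{i:04d}" for i in range(config.domain_vocab_size)]
    specs: list[_GeneSpec] = []
    lo, hi = config.background_length
    for j in range(config.n_background_genes):
        length = int(rng.integers(lo, hi + 1))
        doms = tuple(rng.choice(vocab, size=int(rng.integers(1, 4)), replace=False))
        specs.append(_GeneSpec(f"BG{j:03d}", BACKGROUND, _random_seq(rng, length), doms))
    for j in range(config.n_domain_signal_genes):
        doms = (f"DCOPY{j}",) + tuple(rng.choice(vocab, size=1))
        specs.append(
            _GeneSpec(f"COPY{j}", DOMAIN_COPY, _random_seq(rng, 200), doms)
        )
    for j in range(config.n_substitution_signal_genes):
        seq = _random_seq(rng, 200)
        m = config.n_diagnostic_positions
        # diagnostic sites cluster inside one interior window so the taxon
        # difference lives in one shared kmer context, the way a handful of
        # fixed non-synonymous substitutions concentrate in one exon region
        window = max(2 * m + 2, 12)
        anchor = int(rng.integers(20, 200 - 20 - window))
        positions = tuple(
            int(p)
            for p in np.sort(
                rng.choice(np.arange(anchor, anchor + window), size=m, replace=False)
            )
        )
        residues = []
        aa = list(AMINO_ACIDS)
        for p in positions:
            a, b = rng.choice(aa, size=2, replace=False)
            residues.append((str(a), str(b)))
        doms = tuple(rng.choice(vocab, size=2, replace=False))
        specs.append(
            _GeneSpec(
                f"SUBST{j}", SUBSTITUTION, seq, doms,
                diag_positions=positions, diag_residues=tuple(residues),
            )
        )
    for j in range(config.n_indel_signal_genes):
        seq = _random_seq(rng, 180)
        motif = _random_seq(rng, 8)
        doms = tuple(rng.choice(vocab, size=2, replace=False))
        specs.append(
            _GeneSpec(
                f"INDEL{j}", DOMAIN_INDEL, seq, doms,
                insert_at=int(rng.integers(40, 140)),
                insert_seq=motif * 3,
                insert_domain=f"DINDEL{j}",
            )
        )
    return specs


def _materialize(
    spec: _GeneSpec,
    taxon_idx: int,
    species_id: str,
    config: FixtureConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, tuple[str, ...]]]:
    """Per-species protein instances of one gene:
    (protein_id, sequence, domains)."""
    out = []
    if spec.mechanism == DOMAIN_COPY:
        n_copies = config.copy_numbers[taxon_idx]
        for c in range(1, n_copies + 1):
            seq = _noisy(spec.base_seq, config.species_noise_rate, rng)
            out.append((f"{species_id}|{spec.symbol}_c{c}", seq, spec.domains))
        return out
    if spec.mechanism == SUBSTITUTION:
        chars = list(spec.base_seq)
        for p, (ra, rb) in zip(spec.diag_positions, spec.diag_residues):
            chars[p] = ra if taxon_idx == 0 else rb
        seq = _noisy(
            "".join(chars), config.species_noise_rate, rng,
            protected=frozenset(spec.diag_positions),
        )
        out.append((f"{species_id}|{spec.symbol}", seq, spec.domains))
        return out
    if spec.mechanism == DOMAIN_INDEL:
        if taxon_idx == 0:
            seq = (
                spec.base_seq[: spec.insert_at]
                + spec.insert_seq
                + spec.base_seq[spec.insert_at :]
            )
            doms = spec.domains + (spec.insert_domain,)
        else:
            seq, doms = spec.base_seq, spec.domains
        seq = _noisy(seq, config.species_noise_rate, rng)
        out.append((f"{species_id}|{spec.symbol}", seq, doms))
        return out
    # background
    seq = _noisy(spec.base_seq, config.species_noise_rate, rng)
    doms = spec.domains
    if rng.random() < config.domain_noise_prob:
        doms = doms + (f"PFX{int(rng.integers(config.domain_vocab_size)):04d}",)
    out.append((f"{species_id}|{spec.symbol}", seq, doms))
    return out


def generate_fixture(config: FixtureConfig) -> FixtureData:
    """Generate the full synthetic study: genomes for both taxa, domain
    annotations, gene map and planted-gene ground truth."""
    rng = np.random.default_rng(config.seed)
    specs = _build_gene_specs(config, rng)

    genomes: list[SpeciesGenome] = []
    annotations: dict[str, tuple[str, ...]] = {}
    gene_map: dict[str, str] = {}
    for taxon_idx, taxon in enumerate(config.taxa):
        for s in range(1, config.n_species_per_taxon + 1):
            species_id = f"{taxon[:3]}{s:02d}"
            srng = np.random.default_rng(
                np.random.SeedSequence([config.seed & 0x7FFFFFFF, taxon_idx, s])
            )
            proteins = []
            for spec in specs:
                for pid, seq, doms in _materialize(
                    spec, taxon_idx, species_id, config, srng
                ):
                    proteins.append(ProteinRecord(pid, seq))
                    annotations[pid] = tuple(doms)
                    gene_map[pid] = spec.symbol
            proteins.sort(key=lambda p: p.protein_id)
            genomes.append(SpeciesGenome(species_id, taxon, tuple(proteins)))
    truth = {spec.symbol: spec.mechanism for spec in specs}
    return FixtureData(genomes, annotations, gene_map, truth, config)


def recovery_report(
    das_tables: Mapping[int, pd.DataFrame],
    truth: Mapping[str, str],
    top_fraction: float | Mapping[int, float] = 0.05,
) -> pd.DataFrame:
    """Per (view, mechanism): the fraction of planted genes ranked inside the
    top ``top_fraction`` of that view's DAS."""
    from .attention_scores import rank_top_fraction

    planted = {m: sorted(g for g, c in truth.items() if c == m)
               for m in (DOMAIN_COPY, SUBSTITUTION, DOMAIN_INDEL)}
    rows = []
    for view in sorted(das_tables):
        das = das_tables[view]
        frac = top_fraction[view] if isinstance(top_fraction, Mapping) else top_fraction
        das_genes = set(das["gene_symbol"])
        missing = [g for genes in planted.values() for g in genes if g not in das_genes]
        if missing:
            raise ValueError(f"planted gene(s) {missing} absent from DAS view {view}")
        top = set(rank_top_fraction(das, frac))
        for mech, genes in planted.items():
            if not genes:
                continue
            hits = sum(g in top for g in genes)
            rows.append(
                {
                    "view": view,
                    "mechanism": mech,
                    "n_planted": len(genes),
                    "n_recovered": hits,
                    "recall": hits / len(genes),
                }
            )
    return pd.DataFrame(rows)


def write_fixture(data: FixtureData, directory: str | Path) -> None:
    """Write FASTA per species plus manifest, annotations, gene map and a
    truth TSV — a complete on-disk study input."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in data.genomes:
        fasta = directory / f"{g.species_id}.fasta"
        write_proteome(g, fasta)
        rows.append(ManifestRow(g.species_id, g.label, str(fasta)))
    write_manifest(Manifest(tuple(rows)), directory / "manifest.tsv")
    write_domain_annotations(data.annotations, directory / "annotations.tsv")
    write_gene_map(data.gene_map, directory / "gene_map.tsv")
    with open(directory / "truth.tsv", "w") as fh:
        fh.write("gene_symbol\tmechanism\n")
        for sym in sorted(data.truth):
            fh.write(f"{sym}\t{data.truth[sym]}\n")
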
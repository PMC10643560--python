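"""From attention weights to gene importance: PAS, GAS, DAS, and enrichment.

Score hierarchy, per word-hierarchy view v:

* **PAS** (protein attention score) — the sentence attention ``alpha_i`` a
  trained classifier assigns to protein *i* of species *s*; per species the
  PAS of views 1 and 2 sum to one by construction.
* **fusion (v=3)** — PAS are aggregated to gene level per species; for each
  gene the cosine similarity of its cross-species score vectors under the
  two views gates the mean of the two views' scores, so only genes flagged
  concordantly by the domain view and the kmer view keep weight.
* **GAS** (gene attention score) — per taxon, gene-level PAS summed over the
  taxon's species and normalized to sum to one within the taxon.
* **DAS** (differential attention score) — the sum of the two taxa's
  normalized GAS; the gene-importance measure that is ranked.  Under
  sum-to-one normalization the DAS of all genes sums to exactly 2.

The top fraction (default 1%) of genes by DAS are the candidate key genes;
they can be tested against GMT gene sets with a hypergeometric upper-tail
test and Benjamini–Hochberg correction.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .han_classifier import AttentionOutput
from .io_formats import Manifest

__all__ = [
    "compute_pas",
    "aggregate_by_gene",
    "cosine_similarity",
    "fuse_pas",
    "compute_gas",
    "compute_das",
    "rank_top_fraction",
    "read_gmt",
    "geneset_enrichment",
]

FUSED_VIEW = 3


def compute_pas(
    attention_outputs: Mapping[str, AttentionOutput],
    gene_map: Mapping[str, str] | None,
    view: int,
    species_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """PAS table for one view: one row per (species, protein) with the
    protein's sentence attention weight and its gene symbol.

    Proteins absent from the gene map keep an empty symbol and are excluded
    from gene-level aggregation downstream.  With ``gene_map=None`` every
    protein uses its own id as symbol.
    """
    if species_ids is not None:
        missing = sorted(set(species_ids) - set(attention_outputs))
        if missing:
            raise ValueError(f"missing attention outputs for species {missing}")
    rows = []
    for sid in sorted(attention_outputs):
        out = attention_outputs[sid]
        if len(out.protein_ids) != len(out.sent_attn):
            raise ValueError(f"species {sid!r}: protein/attention length mismatch")
        for pid, score in zip(out.protein_ids, out.sent_attn):
            if gene_map is None:
                sym = pid
            else:
                sym = gene_map.get(pid, "")
            rows.append((sid, pid, sym, float(score)))
    df = pd.DataFrame(rows, columns=["species_id", "protein_id", "gene_symbol", "score"])
    df.attrs["view"] = view
    return df


def aggregate_by_gene(pas_table: pd.DataFrame) -> pd.DataFrame:
    """Gene x species matrix of per-gene summed PAS (``V_v`` feature rows).

    Proteins with an empty gene symbol are dropped; a species lacking a gene
    gets 0 in that gene's row.
    """
    df = pas_table[pas_table["gene_symbol"].astype(str) != ""]
    mat = (
        df.pivot_table(
            index="gene_symbol", columns="species_id", values="score",
            aggfunc="sum", fill_value=0.0,
        )
        .sort_index()
    )
    mat.attrs["view"] = pas_table.attrs.get("view")
    return mat


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine of the angle between two score vectors; 0 (with a warning) if
    either vector is all-zero."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"length mismatch: {v1.shape} vs {v2.shape}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        warnings.warn("cosine similarity of a zero vector defined as 0")
        return 0.0
    return float(v1 @ v2 / (n1 * n2))


def fuse_pas(matrix_v1: pd.DataFrame, matrix_v2: pd.DataFrame) -> pd.DataFrame:
    """Cosine-gated fusion of the two views' gene x species matrices (v=3).

    Genes and species are outer-joined with zeros.  For each gene g,
    ``sim(g)`` is the cosine similarity of its two cross-species rows, and
    ``fused[g, s] = sim(g) * (m1[g, s] + m2[g, s]) / 2``.
    """
    common = matrix_v1.index.intersection(matrix_v2.index)
    if len(common) == 0:
        raise ValueError("gene sets of the two views are disjoint; nothing to fuse")
    genes = matrix_v1.index.union(matrix_v2.index).sort_values()
    species = matrix_v1.columns.union(matrix_v2.columns).sort_values()
    m1 = matrix_v1.reindex(index=genes, columns=species, fill_value=0.0)
    m2 = matrix_v2.reindex(index=genes, columns=species, fill_value=0.0)
    a1, a2 = m1.to_numpy(float), m2.to_numpy(float)
    norms1 = np.linalg.norm(a1, axis=1)
    norms2 = np.linalg.norm(a2, axis=1)
    denom = norms1 * norms2
    with np.errstate(invalid="ignore"):
        sim = np.where(denom > 0, (a1 * a2).sum(axis=1) / np.where(denom == 0, 1, denom), 0.0)
    fused = sim[:, None] * (a1 + a2) / 2.0
    out = pd.DataFrame(fused, index=genes, columns=species)
    out.attrs["view"] = FUSED_VIEW
    return out


def compute_gas(matrix: pd.DataFrame, manifest: Manifest) -> pd.DataFrame:
    """GAS table: per taxon, gene scores summed over the taxon's species and
    normalized to sum to one within the taxon."""
    view = matrix.attrs.get("view")
    rows = []
    for taxon in manifest.taxa:
        species = [s for s in manifest.species_of(taxon) if s in matrix.columns]
        if not species:
            raise ValueError(f"no species of taxon {taxon!r} present in the matrix")
        totals = matrix[species].sum(axis=1)
        denom = totals.sum()
        if denom <= 0:
            raise ValueError(f"taxon {taxon!r} has zero total attention mass")
        for gene, val in (totals / denom).items():
            rows.append((view, taxon, gene, float(val)))
    df = pd.DataFrame(rows, columns=["view", "taxon", "gene_symbol", "score"])
    df.attrs["view"] = view
    return df


def _normalized_series(gas: pd.DataFrame, taxon: str) -> pd.Series:
    s = gas.loc[gas["taxon"] == taxon].set_index("gene_symbol")["score"]
    total = s.sum()
    return s / total if total > 0 else s


def compute_das(gas_table: pd.DataFrame) -> pd.DataFrame:
    """DAS table: sum of the two taxa's normalized GAS per gene (genes absent
    from one taxon contribute 0 there); total DAS mass is exactly 2."""
    taxa = sorted(gas_table["taxon"].unique())
    if len(taxa) != 2:
        raise ValueError(f"expected 2 taxa in GAS table, got {taxa}")
    s1 = _normalized_series(gas_table, taxa[0])
    s2 = _normalized_series(gas_table, taxa[1])
    das = s1.add(s2, fill_value=0.0).sort_index()
    df = das.rename("score").reset_index()
    df.insert(0, "view", gas_table.attrs.get("view"))
    df.attrs["view"] = gas_table.attrs.get("view")
    return df


def rank_top_fraction(das_table: pd.DataFrame, fraction: float = 0.01) -> list[str]:
    """The top ``ceil(fraction * N)`` genes by DAS, ties broken by symbol."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if len(das_table) == 0:
        raise ValueError("empty DAS table")
    n_keep = math.ceil(fraction * len(das_table))
    ordered = das_table.sort_values(
        ["score", "gene_symbol"], ascending=[False, True], kind="mergesort"
    )
    return ordered["gene_symbol"].head(n_keep).tolist()


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def geneset_enrichment(
    selected: Sequence[str],
    background: Sequence[str],
    genesets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    For each set, with N = |background|, K = |set ∩ background|,
    n = |selected| and x = |set ∩ selected|, the p-value is the upper tail
    P(X >= x) of Hypergeom(N, K, n); p-values are Benjamini–Hochberg
    corrected across the tested sets.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    sel = set(selected)
    if not sel <= bg:
        raise ValueError("selected genes must be a subset of the background")
    rows = []
    for name in sorted(genesets):
        members = genesets[name] & bg
        if not members:
            warnings.warn(f"gene set {name!r} has no overlap with the background; skipped")
            continue
        overlap = len(members & sel)
        p = float(hypergeom.sf(overlap - 1, len(bg), len(members), len(sel)))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df
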
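"""Genotype and kinship input layer.

A :class:`GenotypeDataset` holds a sample-by-variant dosage matrix (alt-allele
counts in [0, 2], NaN for missing) together with its ordered variant index.
Dosages come from either a VCF (GT or DS fields) or a plain TSV matrix.
Pairwise LD is the squared Pearson correlation of dosage vectors over
pairwise-complete samples, the convention used by PLINK-style clumping.

Relatedness is represented as a :class:`KinshipGraph`: any positive kinship
coefficient is an edge (the sparsification threshold — 4th-degree, coefficient
2^(-9/2) — is applied upstream by the data provider).  The graph drives both
kinship-disjoint fold construction and unrelated-set extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .sumstats import InputError, VariantKey

logger = logging.getLogger(__name__)


@dataclass
class GenotypeDataset:
    """Sample-by-variant dosage matrix with its variant index."""

    sample_ids: list[str]
    variants: list[VariantKey]
    dosages: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        self._variant_idx = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, key: VariantKey) -> int:
        return self._variant_idx[key]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeDataset(list(sample_ids), self.variants, self.dosages[idx])


@dataclass
class KinshipGraph:
    """Undirected relatedness graph; edge weight = kinship coefficient."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str, float]],
        samples: Iterable[str] = (),
    ) -> "KinshipGraph":
        g = nx.Graph()
        g.add_nodes_from(samples)
        for a, b, kin in pairs:
            if a == b:
                continue
            if kin > 0:
                g.add_edge(a, b, kinship=float(kin))
        return cls(g)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def has_edge_within(self, samples: Iterable[str]) -> bool:
        s = set(samples)
        return any(a in s and b in s for a, b in self.graph.edges)

    def subgraph(self, samples: Iterable[str]) -> "KinshipGraph":
        # built by hand: nx subgraph views iterate an internal node *set*,
        # which would make downstream seeded tie-breaks hash-order dependent
        keep = list(dict.fromkeys(samples))
        kset = set(keep)
        g = nx.Graph()
        g.add_nodes_from(n for n in keep if n in self.graph)
        g.add_edges_from(
            (a, b, d) for a, b, d in self.graph.edges(data=True) if a in kset and b in kset
        )
        return KinshipGraph(g)


def load_kinship(path, samples: Iterable[str] = ()) -> KinshipGraph:
    """Read a 3-column (id1, id2, kinship) TSV into a KinshipGraph."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    id1, id2, kin = df.columns[:3]
    return KinshipGraph.from_pairs(
        zip(df[id1].astype(str), df[id2].astype(str), df[kin].astype(float)), samples
    )


# ---------------------------------------------------------------------------
# loading


def load_genotypes(path) -> GenotypeDataset:
    """Load genotypes from a VCF (``.vcf``/``.vcf.gz``) or a dosage TSV.

    VCF GT pairs are converted to alt-allele counts; DS fields are used when
    GT is absent; missing calls stay missing.  A dosage TSV has a
    ``sample_id`` column and one column per variant named
    ``chrom:pos:other_allele:effect_allele``.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        return _load_vcf(path)
    return _load_dosage_tsv(path)


def _load_vcf(path: Path) -> GenotypeDataset:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error type varies
        raise InputError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    variants: list[VariantKey] = []
    columns: list[np.ndarray] = []
    for i, rec in enumerate(vcf):
        try:
            if len(rec.ALT) != 1:
                raise ValueError("multi-allelic record")
            key = VariantKey(str(rec.CHROM).removeprefix("chr"), rec.POS, rec.ALT[0], rec.REF)
            gts = rec.genotype.array()
            if gts is not None and gts.shape[1] >= 2:
                alleles = gts[:, :2].astype(float)
                alleles[alleles < 0] = np.nan
                dos = alleles.sum(axis=1)
            else:  # fall back to dosage field
                dos = np.asarray(rec.format("DS"), dtype=float).ravel()
        except Exception as exc:
            raise InputError(f"malformed VCF record at {path} line (record {i + 1}): {exc}") from exc
        variants.append(key)
        columns.append(dos)
    if not variants:
        raise InputError(f"VCF {path} contains no usable records")
    return GenotypeDataset(sample_ids, variants, np.column_stack(columns))


def _load_dosage_tsv(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise InputError(f"dosage TSV {path} lacks a sample_id column")
    sample_ids = df["sample_id"].tolist()
    variants = [parse_variant_label(c) for c in df.columns[1:]]
    return GenotypeDataset(sample_ids, variants, df.iloc[:, 1:].to_numpy(dtype=float))


def variant_label(key: VariantKey) -> str:
    """Stable column label ``chrom:pos:other:effect`` for a variant."""
    return f"{key.chrom}:{key.pos}:{key.other_allele}:{key.effect_allele}"


def parse_variant_label(label: str) -> VariantKey:
    chrom, pos, other, effect = label.split(":")
    return VariantKey(chrom, int(pos), effect, other)


def write_dosage_tsv(g: GenotypeDataset, path) -> None:
    df = pd.DataFrame(g.dosages, columns=[variant_label(v) for v in g.variants])
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# statistics


def allele_freq(g: GenotypeDataset) -> dict[VariantKey, float]:
    """Effect-allele frequency per variant: mean(non-missing dosages) / 2.

    All-missing variants get NaN and are logged.
    """
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(g.dosages, axis=0) / 2.0
    out = {}
    for v, f in zip(g.variants, freqs):
        if np.isnan(f):
            logger.warning("allele_freq: variant %s has no non-missing dosages", v)
        out[v] = float(f)
    return out


def ld_r2(g: GenotypeDataset, a: VariantKey, b: VariantKey) -> float:
    """Squared Pearson correlation of the two dosage vectors.

    Uses pairwise-complete samples; a monomorphic variant gives r² = 0;
    fewer than 2 complete pairs raises.
    """
    xa = g.dosages[:, g.variant_index(a)]
    xb = g.dosages[:, g.variant_index(b)]
    ok = ~(np.isnan(xa) | np.isnan(xb))
    if ok.sum() < 2:
        raise ValueError(f"fewer than 2 pairwise-complete samples for {a} / {b}")
    xa, xb = xa[ok], xb[ok]
    va, vb = xa.var(), xb.var()
    if va == 0 or vb == 0:
        return 0.0
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def kinship_components(k: KinshipGraph, samples: Iterable[str] = ()) -> list[set[str]]:
    """Connected components of the kinship graph.

    Samples passed in ``samples`` but absent from the graph become singleton
    components, so the result is a partition of the full sample set.
    """
    g = k.graph.copy()
    g.add_nodes_from(samples)
    return [set(c) for c in nx.connected_components(g)]


def unrelated_set(k: KinshipGraph, seed: int, samples: Iterable[str] = ()) -> set[str]:
    """Greedy maximal independent set: repeatedly drop the max-degree node.

    Ties in degree are broken by a seed-shuffled order, so the result is
    deterministic given the seed.  The returned set is verified edge-free.
    """
    g = k.graph.copy()
    g.add_nodes_from(samples)
    rng = np.random.default_rng(seed)
    order = list(g.nodes)
    rng.shuffle(order)
    rank = {s: i for i, s in enumerate(order)}
    while True:
        degrees = dict(g.degree)
        worst = max(degrees.items(), key=lambda kv: (kv[1], -rank[kv[0]]), default=(None, 0))
        if worst[1] == 0:
            break
        g.remove_node(worst[0])
    keep = set(g.nodes)
    assert not k.has_edge_within(keep), "unrelated_set produced a related pair"
    return keep
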
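"""GWAS summary-statistics input, quality control, and allele harmonization.

Summary statistics for the blood-pressure traits (SBP, DBP in mmHg/allele;
hypertension as log odds ratios) are read from delimited text, filtered on
minor allele frequency in both the discovery GWAS and the target cohort, and
harmonized so every record's effect/other allele orientation matches the
target cohort's variant index.  Strand-ambiguous (A/T, C/G) variants are
dropped during harmonization: frequency-based disambiguation is deliberately
avoided so the result is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_TRAITS = ("SBP", "DBP", "HTN")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names expected in a summary-statistics file
DEFAULT_COLUMNS = {
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "eaf": "EAF",
    "n": "N",
}

MANDATORY_FIELDS = ("chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue")


class ConfigurationError(ValueError):
    """A required column is missing or the column map is incomplete."""


class InputError(ValueError):
    """The input file cannot be used (empty, malformed)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a bi-allelic variant: 1-based position plus allele pair."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        for a in (self.effect_allele, self.other_allele):
            if not a or any(c not in "ACGT" for c in a):
                raise ValueError(f"allele {a!r} is not a non-empty A/C/G/T string")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G SNPs."""
        return (
            len(self.effect_allele) == 1
            and len(self.other_allele) == 1
            and _COMPLEMENT[self.effect_allele] == self.other_allele
        )

    def swapped(self) -> "VariantKey":
        return VariantKey(self.chrom, self.pos, self.other_allele, self.effect_allele)

    def complemented(self) -> "VariantKey":
        return VariantKey(
            self.chrom,
            self.pos,
            "".join(_COMPLEMENT[c] for c in self.effect_allele),
            "".join(_COMPLEMENT[c] for c in self.other_allele),
        )


@dataclass(frozen=True)
class SumStatsRecord:
    """One variant's GWAS effect estimate."""

    key: VariantKey
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if not 0 < self.pvalue <= 1:
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not 0 <= self.eaf <= 1:
            raise ValueError(f"eaf must be in [0, 1], got {self.eaf}")


@dataclass
class SumStats:
    """Harmonizable collection of per-variant effects for one trait."""

    trait: str
    records: list[SumStatsRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait not in VALID_TRAITS:
            raise ValueError(f"trait must be one of {VALID_TRAITS}, got {self.trait!r}")
        self._sort_and_check()

    def _sort_and_check(self) -> None:
        self.records.sort(key=lambda r: (r.key.chrom, r.key.pos, r.key.effect_allele))
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys in SumStats")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def pvalues(self) -> np.ndarray:
        return np.array([r.pvalue for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "CHR": [r.key.chrom for r in self.records],
                "POS": [r.key.pos for r in self.records],
                "EA": [r.key.effect_allele for r in self.records],
                "OA": [r.key.other_allele for r in self.records],
                "BETA": [r.beta for r in self.records],
                "SE": [r.se for r in self.records],
                "P": [r.pvalue for r in self.records],
                "EAF": [r.eaf for r in self.records],
                "N": [r.n for r in self.records],
            }
        )


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "HTN",
) -> SumStats:
    """Read a delimited summary-statistics file into a :class:`SumStats`.

    ``column_map`` maps field names (``chrom``, ``pos``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, ``pvalue``, optionally ``eaf`` and
    ``n``) to header names in the file.  Rows failing numeric parsing are
    dropped and counted; duplicate variant keys keep the record with the
    smallest p-value.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise InputError(f"summary-statistics file {path} contains no data rows")

    for fld in MANDATORY_FIELDS:
        if colmap[fld] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {colmap[fld]!r} (field {fld!r}) missing from {path}"
            )

    has_eaf = colmap["eaf"] in df.columns
    has_n = colmap["n"] in df.columns

    n_dropped = 0
    records: dict[VariantKey, SumStatsRecord] = {}
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        try:
            key = VariantKey(
                str(d[colmap["chrom"]]),
                int(d[colmap["pos"]]),
                str(d[colmap["effect_allele"]]).upper(),
                str(d[colmap["other_allele"]]).upper(),
            )
            rec = SumStatsRecord(
                key=key,
                beta=float(d[colmap["beta"]]),
                se=float(d[colmap["se"]]),
                pvalue=float(d[colmap["pvalue"]]),
                eaf=float(d[colmap["eaf"]]) if has_eaf and pd.notna(d[colmap["eaf"]]) else None,
                n=float(d[colmap["n"]]) if has_n and pd.notna(d[colmap["n"]]) else None,
            )
            if not np.isfinite(rec.beta) or not np.isfinite(rec.se):
                raise ValueError("non-finite effect estimate")
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        prev = records.get(key)
        if prev is None or rec.pvalue < prev.pvalue:
            if prev is not None:
                logger.info("duplicate key %s: keeping p=%.3g over p=%.3g", key, rec.pvalue, prev.pvalue)
            records[key] = rec

    if n_dropped:
        logger.info("read_sumstats: dropped %d unparseable rows from %s", n_dropped, path)
    return SumStats(trait=trait, records=list(records.values()))


def filter_maf(
    ss: SumStats,
    target_freqs: Mapping[VariantKey, float],
    threshold: float = 0.01,
) -> SumStats:
    """Keep variants common in both the discovery GWAS and the target cohort.

    A record is retained when its minor allele frequency — ``min(f, 1 - f)``
    for both the discovery effect-allele frequency and the target cohort
    frequency — is at least ``threshold``.  Records without a discovery
    frequency pass the discovery-side filter (logged); records absent from
    ``target_freqs`` are dropped.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError(f"threshold must be in (0, 0.5], got {threshold}")

    kept: list[SumStatsRecord] = []
    n_no_eaf = 0
    for rec in ss.records:
        if rec.key not in target_freqs:
            continue
        f = target_freqs[rec.key]
        if min(f, 1.0 - f) < threshold:
            continue
        if rec.eaf is None:
            n_no_eaf += 1
        elif min(rec.eaf, 1.0 - rec.eaf) < threshold:
            continue
        kept.append(rec)
    if n_no_eaf:
        logger.info("filter_maf: %d records lacked a discovery frequency; target-side filter only", n_no_eaf)
    return SumStats(trait=ss.trait, records=kept)


def harmonize_alleles(
    ss: SumStats,
    target_index: Iterable[VariantKey],
) -> tuple[SumStats, dict[str, int]]:
    """Orient records to the target cohort's allele coding.

    For each record, in order: exact allele match keeps the record; a swapped
    effect/other pair flips the sign of beta and mirrors the frequency; a
    strand-complement match is complemented and re-tested; palindromic A/T
    and C/G variants are dropped; anything else is unmatched and dropped.

    Returns the harmonized ``SumStats`` and a per-outcome count dictionary
    with keys ``exact``, ``swapped``, ``complemented``, ``complement_swapped``,
    ``palindromic_dropped``, ``unmatched``.
    """
    by_locus: dict[tuple[str, int], list[VariantKey]] = {}
    for key in target_index:
        by_locus.setdefault(key.locus, []).append(key)

    counts = {
        "exact": 0,
        "swapped": 0,
        "complemented": 0,
        "complement_swapped": 0,
        "palindromic_dropped": 0,
        "unmatched": 0,
    }
    out: list[SumStatsRecord] = []
    for rec in ss.records:
        if rec.key.is_palindromic():
            counts["palindromic_dropped"] += 1
            continue
        candidates = by_locus.get(rec.key.locus, [])
        matched = _match_one(rec, candidates, counts)
        if matched is not None:
            out.append(matched)
        else:
            counts["unmatched"] += 1
    return SumStats(trait=ss.trait, records=out), counts


def _match_one(
    rec: SumStatsRecord,
    candidates: Sequence[VariantKey],
    counts: dict[str, int],
) -> SumStatsRecord | None:
    key = rec.key
    cand = set(candidates)
    if key in cand:
        counts["exact"] += 1
        return rec
    if key.swapped() in cand:
        counts["swapped"] += 1
        return _flip(rec, key.swapped())
    comp = key.complemented()
    if comp in cand:
        counts["complemented"] += 1
        return replace(rec, key=comp)
    if comp.swapped() in cand:
        counts["complement_swapped"] += 1
        return _flip(rec, comp.swapped())
    return None


def _flip(rec: SumStatsRecord, new_key: VariantKey) -> SumStatsRecord:
    return replace(
        rec,
        key=new_key,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def write_harmonization_report(counts: Mapping[str, int], path) -> None:
    """Write the per-category harmonization counts as a two-column TSV."""
    pd.DataFrame({"category": list(counts), "count": list(counts.values())}).to_csv(
        path, sep="\t", index=False
    )
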
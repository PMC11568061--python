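"""Taxonomic rollup of screening verdicts.

Confirmed hits are grouped at a chosen rank of a GTDB-style seven-rank
lineage (domain;phylum;class;order;family;genus;species, optional
``p__`` prefixes stripped). Counting is per genome when a record-to-
genome mapping is supplied — several confirmed ORFs in one genome count
once — matching the published "genomes containing methioninase" pies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .anchors import Status
from .errors import LineageError, MappingError, MissingTaxonomyError

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_PREFIX = re.compile(r"^[a-z]__")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon lineage into the seven named ranks."""
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) != len(RANKS):
        raise LineageError(
            f"lineage must have {len(RANKS)} ranks, got {len(parts)}: {lineage!r}"
        )
    return {rank: _PREFIX.sub("", name) for rank, name in zip(RANKS, parts)}


@dataclass
class TaxonSummary:
    """Positive/total counts for one taxon at one rank."""

    rank: str
    taxon: str
    n_positive: int
    n_total: int
    fraction: float
    share_of_positives: float


def genome_level_rollup(verdicts, record_to_genome: dict[str, str]) -> dict[str, bool]:
    """Per-genome positive flags: any confirmed record makes a genome positive."""
    flags: dict[str, bool] = {}
    for v in verdicts:
        genome = record_to_genome.get(v.id)
        if genome is None:
            raise MappingError(f"record {v.id!r} missing from genome mapping")
        flags.setdefault(genome, False)
        if v.status is Status.CONFIRMED:
            flags[genome] = True
    return flags


def summarize_by_rank(
    verdicts,
    taxonomy_table: pd.DataFrame,
    rank: str = "phylum",
    record_to_genome: dict[str, str] | None = None,
) -> list[TaxonSummary]:
    """Per-taxon (positive, total, fraction, share) counts at ``rank``.

    ``taxonomy_table`` needs columns ``id`` and ``lineage`` covering every
    verdict id. With ``record_to_genome`` the countable unit is the
    genome (de-duplicated); otherwise each record counts on its own.
    Taxa are sorted by positives descending, name ascending on ties.
    """
    if rank not in RANKS:
        raise LineageError(f"unknown rank {rank!r}; one of {RANKS}")
    lineage_of = dict(zip(taxonomy_table["id"], taxonomy_table["lineage"]))
    missing = [v.id for v in verdicts if v.id not in lineage_of]
    if missing:
        raise MissingTaxonomyError(missing)

    if record_to_genome is not None:
        flags = genome_level_rollup(verdicts, record_to_genome)
        # a genome's taxon comes from any of its records (assumed consistent)
        genome_taxon: dict[str, str] = {}
        for v in verdicts:
            g = record_to_genome[v.id]
            genome_taxon[g] = parse_lineage(lineage_of[v.id])[rank]
        units = [(g, genome_taxon[g], pos) for g, pos in flags.items()]
    else:
        units = [
            (v.id, parse_lineage(lineage_of[v.id])[rank], v.status is Status.CONFIRMED)
            for v in verdicts
        ]

    totals: dict[str, int] = {}
    positives: dict[str, int] = {}
    for _, taxon, pos in units:
        totals[taxon] = totals.get(taxon, 0) + 1
        positives[taxon] = positives.get(taxon, 0) + (1 if pos else 0)
    total_pos = sum(positives.values())
    if total_pos == 0:
        logger.warning("no confirmed records: shares reported as 0")
    summaries = [
        TaxonSummary(
            rank=rank,
            taxon=taxon,
            n_positive=positives[taxon],
            n_total=totals[taxon],
            fraction=positives[taxon] / totals[taxon],
            share_of_positives=(positives[taxon] / total_pos) if total_pos else 0.0,
        )
        for taxon in totals
    ]
    summaries.sort(key=lambda s: (-s.n_positive, s.taxon))
    return summaries


def summaries_to_table(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "taxon": s.taxon,
                "n_positive": s.n_positive,
                "n_total": s.n_total,
                "fraction": f"{s.fraction:.6f}",
                "share_of_positives": f"{s.share_of_positives:.6f}",
            }
            for s in summaries
        ],
        columns=[
            "rank",
            "taxon",
            "n_positive",
            "n_total",
            "fraction",
            "share_of_positives",
        ],
    )


def write_itol_annotation(summaries, path) -> None:
    """Per-taxon counts as a plain-text table for external pie rendering."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon\tn_positive\tn_total\n")
        for s in summaries:
            fh.write(f"{s.taxon}\t{s.n_positive}\t{s.n_total}\n")


def read_itol_annotation(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "taxon\tn_positive\tn_total":
            raise LineageError(f"unexpected annotation header in {path}")
        for line in fh:
            if not line.strip():
                continue
            taxon, npos, ntot = line.rstrip("\n").split("\t")
            out.append((taxon, int(npos), int(ntot)))
    return out
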
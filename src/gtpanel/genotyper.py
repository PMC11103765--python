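"""Allele-ratio amplicon genotyping from per-individual FASTQ files.

Each locus carries two in-silico probe sequences, one per allele; reads
are counted by exact forward-strand substring match and the genotype is
called from the allele-1 : allele-2 count ratio r:

* fewer than ``min_reads`` on-target reads → ``missing``
* r > 10 → homozygous allele 1 (r = +∞ when no allele-2 reads)
* r < 0.1 → homozygous allele 2
* 0.2 ≤ r ≤ 5.0 → heterozygous
* the dead zones (0.1, 0.2) and (5, 10] → ``nocall``

``nocall`` is kept distinct from depth-based ``missing`` but both count
as missing downstream.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .matrix import HET, HOM1, HOM2, MISSING, NOCALL, NOT_CALLED, GenotypeMatrix
from .snp_select import LocusDef

log = logging.getLogger(__name__)


@dataclass
class CallThresholds:
    """Allele-ratio calling rule parameters."""

    min_reads: int = 10
    hom1_ratio: float = 10.0
    hom2_ratio: float = 0.1
    het_lo: float = 0.2
    het_hi: float = 5.0

    def __post_init__(self) -> None:
        if not self.hom2_ratio < self.het_lo <= self.het_hi < self.hom1_ratio:
            raise ValueError("thresholds must satisfy hom2 < het_lo <= het_hi < hom1")


@dataclass
class AlleleCounts:
    """Per individual × locus probe-hit tallies."""

    individual: str
    locus_id: str
    n1: int
    n2: int
    total_reads: int
    on_target_reads: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.total_reads, self.on_target_reads) < 0:
            raise ValueError("counts must be non-negative")
        if not self.n1 + self.n2 <= self.on_target_reads <= self.total_reads:
            raise ValueError("need n1 + n2 <= on_target_reads <= total_reads")


def call_genotype(n1: int, n2: int, th: CallThresholds | None = None) -> str:
    """Call one genotype from allele-specific read counts."""
    th = th or CallThresholds()
    if n1 < 0 or n2 < 0:
        raise ValueError("read counts must be non-negative")
    if n1 + n2 < th.min_reads:
        return MISSING
    r = n1 / n2 if n2 else float("inf")
    if r > th.hom1_ratio:
        return HOM1
    if r < th.hom2_ratio:
        return HOM2
    if th.het_lo <= r <= th.het_hi:
        return HET
    return NOCALL


def _read_sequences(source) -> Iterable[str]:
    """Yield read sequences from a FASTQ path (.gz ok) or pass through strings."""
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq).upper()
    else:
        for seq in source:
            yield str(seq).upper()


def _probe_index(loci: list[LocusDef]):
    """Map probe sequence -> (rank, locus_id, allele); validate uniqueness."""
    index: dict[str, tuple[int, str, int]] = {}
    lengths: set[int] = set()
    for rank, ld in enumerate(sorted(loci, key=lambda l: l.locus_id)):
        for allele, probe in ((1, ld.probe1), (2, ld.probe2)):
            if not probe:
                raise ValueError(f"{ld.locus_id}: probe{allele} undefined")
            p = probe.upper()
            if p in index:
                raise ValueError(f"duplicate probe {p!r} across loci")
            index[p] = (rank, ld.locus_id, allele)
            lengths.add(len(p))
    return index, sorted(lengths)


def count_alleles(reads, loci: list[LocusDef], individual: str = "sample") -> list[AlleleCounts]:
    """Count allele-specific probe hits in one individual's reads.

    A read increments at most one locus-allele counter: when a read
    contains probes of more than one locus (a panel defect), the first
    locus in sorted locus_id order wins and the collision is logged.
    Matching is exact, forward-strand, full-probe substring.
    """
    index, lengths = _probe_index(loci)
    tallies = {ld.locus_id: [0, 0] for ld in loci}
    total = 0
    on_target = 0
    collisions = 0
    for seq in _read_sequences(reads):
        total += 1
        hits = []
        for k in lengths:
            for i in range(len(seq) - k + 1):
                entry = index.get(seq[i : i + k])
                if entry is not None:
                    hits.append(entry)
        if not hits:
            continue
        on_target += 1
        if len({h[1] for h in hits}) > 1:
            collisions += 1
        rank, locus_id, allele = min(hits)
        tallies[locus_id][allele - 1] += 1
    if collisions:
        log.warning("%s: %d reads matched probes of multiple loci", individual, collisions)
    return [
        AlleleCounts(individual, lid, n1, n2, total, on_target)
        for lid, (n1, n2) in sorted(tallies.items())
    ]


def counts_to_frame(counts: list[AlleleCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.individual, c.locus_id, c.n1, c.n2, c.total_reads, c.on_target_reads) for c in counts],
        columns=["individual", "locus_id", "n1", "n2", "total_reads", "on_target_reads"],
    )


def genotype_fastq_dir(
    fastq_by_individual: dict[str, object],
    loci: list[LocusDef],
    th: CallThresholds | None = None,
    meta: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Run counting + calling for many individuals.

    ``fastq_by_individual`` maps individual id to a FASTQ path or an
    iterable of read sequences. Returns the called matrix and the counts
    table.
    """
    th = th or CallThresholds()
    all_counts: list[AlleleCounts] = []
    calls: dict[str, dict[str, str]] = {}
    for ind in sorted(fastq_by_individual):
        counts = count_alleles(fastq_by_individual[ind], loci, individual=ind)
        all_counts.extend(counts)
        calls[ind] = {c.locus_id: call_genotype(c.n1, c.n2, th) for c in counts}
    matrix = pd.DataFrame.from_dict(calls, orient="index").sort_index()
    matrix.index.name = "individual"
    gm = GenotypeMatrix(matrix, meta.loc[matrix.index] if meta is not None else None)
    return gm, counts_to_frame(all_counts)


def filter_matrix(
    matrix: GenotypeMatrix,
    max_locus_missing: float = 0.5,
    max_ind_missing: float = 0.5,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Drop poorly genotyped loci, then poorly genotyped individuals.

    Bounds are inclusive: a locus (individual) with missingness at or
    above the threshold is removed. Loci go first; individual
    missingness is then assessed on the surviving loci.
    """
    if matrix.n_individuals == 0 or matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    lm = matrix.locus_missingness()
    bad_loci = list(lm.index[lm >= max_locus_missing])
    kept = matrix.subset(loci=[l for l in matrix.loci if l not in set(bad_loci)])
    if kept.n_loci == 0:
        warnings.warn("all loci removed by missingness filter")
        return kept, {"loci": bad_loci, "individuals": []}
    im = kept.individual_missingness()
    bad_inds = list(im.index[im >= max_ind_missing])
    kept = kept.subset(individuals=[i for i in kept.individuals if i not in set(bad_inds)])
    if kept.n_individuals == 0:
        warnings.warn("all individuals removed by missingness filter")
    return kept, {"loci": bad_loci, "individuals": bad_inds}


def genotyping_success(matrix: GenotypeMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Percent of loci genotyped per individual, summarised by sample type."""
    pct = 100.0 * (1.0 - matrix.individual_missingness())
    pct.name = "pct_genotyped"
    summary = (
        pct.groupby(matrix.meta["sample_type"])
        .agg(["mean", "min", "max", "median"])
        .rename_axis("sample_type")
    )
    return pct, summary
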
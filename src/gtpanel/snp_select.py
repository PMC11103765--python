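"""Candidate SNP selection for an amplicon panel.

Filters a genotype matrix of previously discovered SNPs down to panel
candidates: missingness below a ceiling, expected heterozygosity above a
floor, optional minor-allele-frequency / physical-spacing / depth rules,
and at most one SNP per scaffold. All thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .matrix import HET, HOM1, HOM2, GenotypeMatrix

log = logging.getLogger(__name__)

REJECT_MISSINGNESS = "MISSINGNESS"
REJECT_HE = "HE"
REJECT_MAF = "MAF"
REJECT_MIN_READS = "MIN_READS"
REJECT_SPACING = "SPACING"
REJECT_ONE_PER_SCAFFOLD = "ONE_PER_SCAFFOLD"


@dataclass(frozen=True)
class LocusDef:
    """A biallelic SNP locus with allele-specific probe sequences.

    ``probe1``/``probe2`` span the SNP for each allele and differ only at
    the SNP-bearing position(s); ``flank`` is the consensus sequence
    around the SNP used as amplicon template.
    """

    locus_id: str
    scaffold: str
    position: int  # 1-based
    allele1: str
    allele2: str
    probe1: str = ""
    probe2: str = ""
    flank: str = ""
    class_label: str = "neutral"

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValueError(f"{self.locus_id}: alleles must differ")
        if self.position < 1:
            raise ValueError(f"{self.locus_id}: position must be >= 1")
        if self.probe1 and self.probe2:
            if len(self.probe1) != len(self.probe2):
                raise ValueError(f"{self.locus_id}: probe lengths differ")
            if self.probe1 == self.probe2:
                raise ValueError(f"{self.locus_id}: probes must differ at the SNP")


@dataclass
class FilterConfig:
    """Thresholds for candidate selection (all strict inequalities).

    Defaults mirror a neutral-panel selection: <0.4 missing data,
    >0.1 expected heterozygosity, one SNP per scaffold. The discovery-
    pipeline rules (MAF, spacing, per-genotype depth, biallelic-only)
    sit behind the remaining flags and default to off.
    """

    max_missing: float = 0.4
    min_he: float = 0.1
    one_per_scaffold: bool = True
    min_maf: float = 0.0
    min_spacing_bp: int = 0
    min_reads: int = 0
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing", "min_he", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_spacing_bp < 0:
            raise ValueError("min_spacing_bp must be >= 0")


def expected_heterozygosity(p: float) -> float:
    """Gene diversity 2p(1-p) of a biallelic locus with allele frequency p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0,1], got {p}")
    return 2.0 * p * (1.0 - p)


def locus_missingness(matrix: GenotypeMatrix, locus_id: str) -> float:
    """Fraction of individuals with no genotype (missing or nocall) at a locus."""
    if locus_id not in matrix.calls.columns:
        raise KeyError(f"unknown locus {locus_id!r}")
    return float(matrix.locus_missingness()[locus_id])


def allele1_frequency(matrix: GenotypeMatrix, locus_id: str) -> float:
    """Observed allele-1 frequency among non-missing calls (NaN if none)."""
    col = matrix.calls[locus_id]
    n1 = 2 * (col == HOM1).sum() + (col == HET).sum()
    n2 = 2 * (col == HOM2).sum() + (col == HET).sum()
    tot = n1 + n2
    return n1 / tot if tot else float("nan")


def _he(matrix: GenotypeMatrix, locus_id: str) -> float:
    """Expected heterozygosity from observed allele frequencies (0 if untyped)."""
    p = allele1_frequency(matrix, locus_id)
    return expected_heterozygosity(p) if p == p else 0.0


def filter_candidates(
    matrix: GenotypeMatrix,
    loci: list[LocusDef],
    cfg: FilterConfig,
    depth: pd.DataFrame | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the selection cascade; return survivors and a rejection table.

    Rules are applied in the order missingness → He → MAF → depth →
    spacing → one-per-scaffold, and a rejected locus is tagged with the
    first rule it fails. Output order is (scaffold, position). The
    per-genotype ``min_reads`` rule runs only when a depth table
    (individuals × loci) is supplied; one-per-scaffold keeps the locus
    with highest He, ties broken by smallest position.

    Returns ``(survivor locus_ids, DataFrame[locus_id, reason])``.
    """
    defs = {ld.locus_id: ld for ld in loci}
    unknown = [lid for lid in matrix.loci if lid not in defs]
    if unknown:
        raise KeyError(f"loci without definitions: {unknown[:5]}")

    if matrix.n_individuals == 0 or matrix.n_loci == 0:
        warnings.warn("empty genotype matrix: no candidates to filter")
        return [], pd.DataFrame(columns=["locus_id", "reason"])

    ordered = sorted(
        (lid for lid in matrix.loci), key=lambda l: (defs[l].scaffold, defs[l].position)
    )
    miss = matrix.locus_missingness()
    rejections: list[tuple[str, str]] = []
    alive: list[str] = []

    if cfg.min_reads > 0 and depth is None:
        log.info("min_reads=%d requested but no depth table given; rule skipped", cfg.min_reads)

    for lid in ordered:
        he = _he(matrix, lid)
        p = allele1_frequency(matrix, lid)
        maf = min(p, 1.0 - p) if p == p else 0.0
        # a threshold at its trivial bound disables the rule entirely
        if cfg.max_missing < 1.0 and not miss[lid] < cfg.max_missing:
            rejections.append((lid, REJECT_MISSINGNESS))
        elif cfg.min_he > 0 and not he > cfg.min_he:
            rejections.append((lid, REJECT_HE))
        elif cfg.min_maf > 0 and not maf > cfg.min_maf:
            rejections.append((lid, REJECT_MAF))
        elif (
            cfg.min_reads > 0
            and depth is not None
            and not (depth[lid].dropna() > cfg.min_reads).any()
        ):
            rejections.append((lid, REJECT_MIN_READS))
        else:
            alive.append(lid)

    if cfg.min_spacing_bp > 0:
        spaced: list[str] = []
        last: dict[str, int] = {}  # scaffold -> position of last kept locus
        for lid in alive:  # already sorted by scaffold, position
            ld = defs[lid]
            if ld.scaffold in last and ld.position - last[ld.scaffold] <= cfg.min_spacing_bp:
                rejections.append((lid, REJECT_SPACING))
            else:
                spaced.append(lid)
                last[ld.scaffold] = ld.position
        alive = spaced

    if cfg.one_per_scaffold:
        best: dict[str, str] = {}
        for lid in alive:
            ld = defs[lid]
            cur = best.get(ld.scaffold)
            if cur is None:
                best[ld.scaffold] = lid
                continue
            he_new = _he(matrix, lid)
            he_cur = _he(matrix, cur)
            if he_new > he_cur or (he_new == he_cur and ld.position < defs[cur].position):
                rejections.append((cur, REJECT_ONE_PER_SCAFFOLD))
                best[ld.scaffold] = lid
            else:
                rejections.append((lid, REJECT_ONE_PER_SCAFFOLD))
        keep = set(best.values())
        alive = [lid for lid in alive if lid in keep]

    rej = pd.DataFrame(rejections, columns=["locus_id", "reason"])
    rej = rej.sort_values(
        "locus_id", key=lambda s: s.map(lambda l: (defs[l].scaffold, defs[l].position))
    ).reset_index(drop=True)
    return alive, rej


# -- locus table I/O -----------------------------------------------------

_LOCUS_COLS = [
    "locus_id", "scaffold", "position", "allele1", "allele2",
    "probe1", "probe2", "flank", "class_label",
]


def write_locus_table(loci: list[LocusDef], path) -> None:
    pd.DataFrame(
        [[getattr(ld, c) for c in _LOCUS_COLS] for ld in loci], columns=_LOCUS_COLS
    ).to_csv(path, index=False)


def read_locus_table(path) -> list[LocusDef]:
    df = pd.read_csv(path, comment="#", dtype={"scaffold": str, "locus_id": str})
    df = df.fillna({"probe1": "", "probe2": "", "flank": "", "class_label": "neutral"})
    return [
        LocusDef(
            locus_id=str(r.locus_id),
            scaffold=str(getattr(r, "scaffold", r.locus_id)),
            position=int(getattr(r, "position", 1)),
            allele1=str(r.allele1),
            allele2=str(r.allele2),
            probe1=str(getattr(r, "probe1", "") or ""),
            probe2=str(getattr(r, "probe2", "") or ""),
            flank=str(getattr(r, "flank", "") or ""),
            class_label=str(getattr(r, "class_label", "neutral")),
        )
        for r in df.itertuples(index=False)
    ]
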
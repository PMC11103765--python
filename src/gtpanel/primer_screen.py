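"""Multiplex primer screening and pooled-mix formulation.

Screens candidate primer pairs against desk-scale design rules — length,
annealing temperature window, hairpin stability, cross-primer
heterodimers, and internal binding sites within any expected amplicon —
and assigns pooled primer-mix concentrations from per-locus performance
quartiles.

The hairpin and heterodimer checks score the most stable ungapped,
perfectly complementary stem (≥ 4 bp) with the nearest-neighbor duplex
model; full secondary-structure folding is deliberately out of scope for
a screening pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .thermo import melting_temperature, revcomp, stem_tm, _check_alphabet

FAIL_LENGTH = "LENGTH"
FAIL_TM_RANGE = "TM_RANGE"
FAIL_HAIRPIN = "HAIRPIN"
FAIL_HETERODIMER = "HETERODIMER"
FAIL_INTERNAL_SITE = "INTERNAL_SITE"
FAILURE_ORDER = (FAIL_LENGTH, FAIL_TM_RANGE, FAIL_HAIRPIN, FAIL_HETERODIMER, FAIL_INTERNAL_SITE)

MIN_STEM = 4  # shortest stem worth scoring
SEED_LEN = 15  # 3'-anchored seed for internal-binding search


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair for one locus."""

    locus_id: str
    fwd: str
    rev: str
    concentration_nM: float = 160.0

    def __post_init__(self) -> None:
        _check_alphabet(self.fwd)
        _check_alphabet(self.rev)
        if self.concentration_nM <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class ScreenConfig:
    """Primer design rules.

    Length 18–24 bases, annealing temperature 58–63 °C, hairpins fail
    when their stem Tm is *above* ``hairpin_tm_max`` (exclusive), and
    heterodimers fail at ``heterodimer_tm_max`` *or higher* (inclusive).
    """

    min_len: int = 18
    max_len: int = 24
    tm_lo: float = 58.0
    tm_hi: float = 63.0
    hairpin_tm_max: float = 50.0
    heterodimer_tm_max: float = 50.0
    forbid_internal_binding: bool = True
    na_mM: float = 50.0
    primer_nM: float = 250.0
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.tm_lo > self.tm_hi:
            raise ValueError("tm_lo must be <= tm_hi")


@dataclass
class ScreenReport:
    """Per-primer-pair pass/fail flags plus a removal ledger."""

    results: pd.DataFrame  # locus_id, passed, failures (tuple of codes)

    @property
    def retained(self) -> list[str]:
        return list(self.results.loc[self.results["passed"], "locus_id"])

    @property
    def removed(self) -> list[str]:
        return list(self.results.loc[~self.results["passed"], "locus_id"])

    def summary(self) -> dict[str, int]:
        counts = {"candidates": len(self.results), "retained": len(self.retained),
                  "removed": len(self.removed)}
        for code in FAILURE_ORDER:
            counts[code] = int(self.results["failures"].map(lambda f: code in f).sum())
        return counts


def hairpin_tm(seq: str, min_loop: int = 3, na_mM: float = 50.0,
               primer_nM: float = 250.0) -> float | None:
    """Tm of the most stable intramolecular stem, or None if no stem ≥ 4 bp.

    Enumerates all ungapped stems: ``seq[i:i+k]`` pairing with
    ``seq[j:j+k]`` in antiparallel orientation with a loop of at least
    ``min_loop`` bases between them.
    """
    s = _check_alphabet(seq)
    n = len(s)
    best: float | None = None
    for k in range(MIN_STEM, n // 2 + 1):
        for i in range(0, n - 2 * k - min_loop + 1):
            stem5 = s[i : i + k]
            target = revcomp(stem5)
            for j in range(i + k + min_loop, n - k + 1):
                if s[j : j + k] == target:
                    tm = stem_tm(stem5, na_mM=na_mM, primer_nM=primer_nM)
                    if best is None or tm > best:
                        best = tm
    return best


def heterodimer_tm(a: str, b: str, na_mM: float = 50.0,
                   primer_nM: float = 250.0) -> float | None:
    """Tm of the best ungapped complementary stretch between two primers.

    Considers every antiparallel alignment of ``a`` against ``b``, finds
    maximal runs of Watson–Crick pairs, and returns the highest stem Tm
    among runs of ≥ 4 bp (None when no such run exists). Symmetric in
    its arguments.
    """
    sa = _check_alphabet(a)
    sb = _check_alphabet(b)
    comp = dict(zip("ACGT", "TGCA"))
    la, lb = len(sa), len(sb)
    best: float | None = None
    # antiparallel: a[i] pairs b[j] on diagonals i + j = const
    for const in range(la + lb - 1):
        run_start = None
        i_lo = max(0, const - lb + 1)
        i_hi = min(la - 1, const)
        for i in range(i_lo, i_hi + 2):  # +1 sentinel to flush the last run
            paired = i <= i_hi and comp[sa[i]] == sb[const - i]
            if paired and run_start is None:
                run_start = i
            elif not paired and run_start is not None:
                k = i - run_start
                if k >= MIN_STEM:
                    tm = stem_tm(sa[run_start:i], na_mM=na_mM, primer_nM=primer_nM)
                    if best is None or tm > best:
                        best = tm
                run_start = None
    return best


def find_internal_binding(
    primer: str,
    amplicons: dict[str, str],
    own_site: tuple[str, int, str] | None = None,
    seed_len: int = SEED_LEN,
) -> list[tuple[str, int, str]]:
    """Locate the primer's 3'-anchored seed inside expected amplicons.

    Searches for exact matches of the primer's 3'-terminal ``seed_len``
    bases (whole primer if shorter) on both strands of every amplicon.
    Returns ``(amplicon_id, offset, strand)`` hits with 0-based forward-
    strand offsets; ``own_site`` (the primer's designed position) is
    excluded.
    """
    if not amplicons:
        raise ValueError("no amplicons supplied")
    seed = _check_alphabet(primer)[-seed_len:]
    rc = revcomp(seed)
    hits: list[tuple[str, int, str]] = []
    for amp_id in sorted(amplicons):
        seq = amplicons[amp_id].upper()
        for query, strand in ((seed, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hit = (amp_id, start, strand)
                if hit != own_site:
                    hits.append(hit)
                start = seq.find(query, start + 1)
    return hits


def _expected_sites(ps: PrimerSet, amplicon: str, seed_len: int = SEED_LEN):
    """Designed seed positions of a primer pair within its own amplicon."""
    fwd_off = max(0, min(len(ps.fwd), len(amplicon)) - seed_len)
    rev_off = max(0, len(amplicon) - len(ps.rev))
    return (
        (ps.locus_id, fwd_off, "+"),
        (ps.locus_id, rev_off, "-"),
    )


def screen_panel(
    primers: list[PrimerSet],
    amplicons: dict[str, str],
    cfg: ScreenConfig | None = None,
) -> ScreenReport:
    """Screen every primer pair; record all failing rules per pair.

    Rules run in the order LENGTH → TM_RANGE → HAIRPIN → HETERODIMER →
    INTERNAL_SITE and every failure is recorded, not only the first.
    """
    cfg = cfg or ScreenConfig()
    seen: set[str] = set()
    for ps in primers:
        if ps.locus_id in seen:
            raise ValueError(f"duplicate locus_id {ps.locus_id!r}")
        seen.add(ps.locus_id)

    rows = []
    for ps in primers:
        failures: list[str] = []
        seqs = (ps.fwd, ps.rev)
        if any(not cfg.min_len <= len(s) <= cfg.max_len for s in seqs):
            failures.append(FAIL_LENGTH)
        tms = [melting_temperature(s, na_mM=cfg.na_mM, primer_nM=cfg.primer_nM) for s in seqs]
        if any(not cfg.tm_lo <= t <= cfg.tm_hi for t in tms):
            failures.append(FAIL_TM_RANGE)
        hp = [hairpin_tm(s, min_loop=cfg.min_loop, na_mM=cfg.na_mM, primer_nM=cfg.primer_nM)
              for s in seqs]
        if any(t is not None and t > cfg.hairpin_tm_max for t in hp):
            failures.append(FAIL_HAIRPIN)
        dimer = False
        for other in primers:
            for s in seqs:
                for o in (other.fwd, other.rev):
                    if s is o:
                        continue
                    t = heterodimer_tm(s, o, na_mM=cfg.na_mM, primer_nM=cfg.primer_nM)
                    if t is not None and t >= cfg.heterodimer_tm_max:
                        dimer = True
        if dimer:
            failures.append(FAIL_HETERODIMER)
        if cfg.forbid_internal_binding and amplicons:
            own = ps.locus_id in amplicons
            sites = _expected_sites(ps, amplicons[ps.locus_id]) if own else (None, None)
            hits = find_internal_binding(ps.fwd, amplicons, own_site=sites[0])
            hits += find_internal_binding(ps.rev, amplicons, own_site=sites[1])
            if hits:
                failures.append(FAIL_INTERNAL_SITE)
        rows.append((ps.locus_id, not failures, tuple(failures)))

    return ScreenReport(pd.DataFrame(rows, columns=["locus_id", "passed", "failures"]))


def formulate_primer_mix(performance: dict[str, float]) -> dict[str, float]:
    """Assign pooled concentrations from on-target read-share quartiles.

    Primers strictly in the top performance quartile are diluted to
    80 nM, primers strictly in the bottom quartile boosted to 320 nM,
    everything else stays at 160 nM. A locus only counts as top (bottom)
    quartile when its share strictly exceeds (is below) the share at the
    quartile boundary, so fully tied panels stay uniform at 160 nM.
    """
    if any(v < 0 for v in performance.values()):
        raise ValueError("performance shares must be >= 0")
    n = len(performance)
    if n < 4:
        warnings.warn("fewer than 4 loci: quartiles undefined, all primers at 160 nM")
        return {k: 160.0 for k in performance}
    q = n // 4
    ranked = sorted(performance.items(), key=lambda kv: (-kv[1], kv[0]))
    out = {k: 160.0 for k in performance}
    top_boundary = ranked[q][1]  # share just below the top-quartile cut
    for lid, share in ranked[:q]:
        if share > top_boundary:
            out[lid] = 80.0
    bottom_boundary = ranked[n - q - 1][1]
    for lid, share in ranked[n - q:]:
        if share < bottom_boundary:
            out[lid] = 320.0
    return out


# -- panel bookkeeping -----------------------------------------------------

def panel_ledger(designed: dict[str, int], removals: list[dict[str, int]]) -> pd.DataFrame:
    """Track panel composition through successive optimization rounds.

    ``designed`` maps SNP class (e.g. neutral/adaptive) to the number of
    primer sets designed; each entry of ``removals`` maps class to the
    SNPs removed in that round. Returns a table of candidates and
    survivors per round with a total column.
    """
    classes = list(designed)
    rows = []
    current = dict(designed)
    rows.append(("designed", *[current[c] for c in classes], sum(current.values())))
    for i, rem in enumerate(removals, start=1):
        rows.append((f"round{i}_candidates", *[current[c] for c in classes],
                     sum(current.values())))
        for c in classes:
            r = rem.get(c, 0)
            if r > current[c]:
                raise ValueError(f"round {i}: removing {r} > {current[c]} {c} SNPs")
            current[c] -= r
        rows.append((f"round{i}_removed", *[rem.get(c, 0) for c in classes],
                     sum(rem.values())))
    rows.append(("final_panel", *[current[c] for c in classes], sum(current.values())))
    return pd.DataFrame(rows, columns=["stage", *classes, "total"]).set_index("stage")


def conversion_rate(attempted: int, excluded: int) -> float:
    """Percent of attempted loci retained as working assays."""
    if attempted <= 0 or not 0 <= excluded <= attempted:
        raise ValueError("need 0 <= excluded <= attempted, attempted > 0")
    return 100.0 * (attempted - excluded) / attempted
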
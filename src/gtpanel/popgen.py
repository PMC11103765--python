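"""Population-genetic validation statistics.

Per-population observed heterozygosity (Ho), within-population gene
diversity with Nei's (1987) sample-size correction (Hs, reported as He),
and the inbreeding coefficient Fis = 1 − ΣHo/ΣHs over polymorphic loci;
pairwise population differentiation via the Weir & Cockerham (1984)
variance-components estimator θ, with locus-resampling bootstrap
percentile confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix


@dataclass
class PopStats:
    """Per-population diversity summary (means over usable loci)."""

    population: str
    n: int
    ho: float
    hs: float
    fis: float
    per_locus: pd.DataFrame  # columns: n_typed, p, ho, hs


@dataclass
class PairwiseFst:
    """Multilocus Weir–Cockerham θ with a bootstrap percentile CI."""

    pop_a: str
    pop_b: str
    theta: float
    ci_low: float
    ci_high: float
    n_boot: int


def _dosage_by_pop(matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
    numeric = matrix.to_numeric()
    return {
        pop: numeric.loc[matrix.meta["population"] == pop].to_numpy(dtype=float)
        for pop in matrix.populations()
    }


def _locus_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n typed, allele-1 freq, Ho, Hs) for one population.

    ``g`` is an individuals × loci allele-2 dosage array with NaN
    missing. Hs uses Nei's correction ñ/(ñ−1)·(1 − Σp² − Ho/(2ñ)).
    """
    typed = ~np.isnan(g)
    n = typed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p2 = np.nansum(g, axis=0) / (2.0 * n)  # allele-2 frequency
        p1 = 1.0 - p2
        ho = (g == 1.0).sum(axis=0) / n
        gene_div = 1.0 - (p1**2 + p2**2)
        hs = np.where(n > 1, n / (n - 1.0) * (gene_div - ho / (2.0 * n)), np.nan)
    return n, p1, ho, hs


def basic_stats(matrix: GenotypeMatrix, min_individuals: int = 8) -> list[PopStats]:
    """Ho, Hs (He) and Fis per population.

    Populations with fewer than ``min_individuals`` members are skipped.
    Fis is the ratio-of-sums 1 − ΣHo/ΣHs over loci with Hs > 0
    (monomorphic loci carry no information about inbreeding).
    """
    by_pop = _dosage_by_pop(matrix)
    out: list[PopStats] = []
    for pop, g in by_pop.items():
        if g.shape[0] < min_individuals:
            continue
        n, p1, ho, hs = _locus_stats(g)
        usable = (n > 1) & ~np.isnan(hs)
        per_locus = pd.DataFrame(
            {"n_typed": n, "p": p1, "ho": ho, "hs": hs},
            index=pd.Index(matrix.loci, name="locus_id"),
        )
        poly = usable & (hs > 0)
        fis = 1.0 - ho[poly].sum() / hs[poly].sum() if poly.any() else float("nan")
        out.append(
            PopStats(
                population=pop,
                n=g.shape[0],
                ho=float(ho[usable].mean()) if usable.any() else float("nan"),
                hs=float(hs[usable].mean()) if usable.any() else float("nan"),
                fis=float(fis),
                per_locus=per_locus,
            )
        )
    if not out:
        warnings.warn(f"no population has >= {min_individuals} individuals")
    return out


def _wc_components(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components for two populations.

    Returns arrays (a, a+b+c); loci with fewer than 2 typed individuals
    in either population are NaN.
    """
    comps = []
    for g in (ga, gb):
        typed = ~np.isnan(g)
        n = typed.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p = 1.0 - np.nansum(g, axis=0) / (2.0 * n)  # allele-1 freq
            h = (g == 1.0).sum(axis=0) / n
        comps.append((n, p, h))
    (na, pa, ha), (nb, pb, hb) = comps
    r = 2.0
    valid = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = na + nb
        nbar = nsum / r
        nc = (nsum - (na**2 + nb**2) / nsum) / (r - 1.0)
        pbar = (na * pa + nb * pb) / nsum
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (na * ha + nb * hb) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
    a = np.where(valid, a, np.nan)
    denom = np.where(valid, denom, np.nan)
    return a, denom


def pairwise_fst(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multilocus Weir–Cockerham θ between two populations.

    Components are summed over loci before the ratio (the estimator's
    recommended multilocus form); loci with zero total variance or
    insufficient data are skipped; negative estimates are retained.
    """
    a, denom = _fst_components(matrix, pop_a, pop_b)
    use = ~np.isnan(denom) & (denom != 0.0)
    if not use.any():
        raise ValueError(f"no usable locus for {pop_a} vs {pop_b}")
    return float(a[use].sum() / denom[use].sum())


def _fst_components(matrix: GenotypeMatrix, pop_a: str, pop_b: str):
    by_pop = _dosage_by_pop(matrix)
    for pop in (pop_a, pop_b):
        if pop not in by_pop:
            raise KeyError(f"unknown population {pop!r}")
    return _wc_components(by_pop[pop_a], by_pop[pop_b])


def fst_bootstrap_ci(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_boot: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PairwiseFst:
    """θ with a percentile CI from resampling loci with replacement."""
    a, denom = _fst_components(matrix, pop_a, pop_b)
    use = ~np.isnan(denom) & (denom != 0.0)
    a, denom = a[use], denom[use]
    if a.size == 0:
        raise ValueError(f"no usable locus for {pop_a} vs {pop_b}")
    theta = float(a.sum() / denom.sum())
    if a.size < 2:
        raise ValueError("bootstrap CI undefined with a single usable locus")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    boot = a[idx].sum(axis=1) / denom[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return PairwiseFst(pop_a, pop_b, theta, float(lo), float(hi), n_boot)


def pairwise_fst_table(
    matrix: GenotypeMatrix,
    min_individuals: int = 8,
    n_boot: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise θ with CIs for populations meeting the size threshold."""
    sizes = matrix.meta["population"].value_counts()
    pops = sorted(sizes.index[sizes >= min_individuals])
    rows = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            est = fst_bootstrap_ci(matrix, pa, pb, n_boot=n_boot, alpha=alpha, seed=seed)
            rows.append((pa, pb, est.theta, est.ci_low, est.ci_high, est.n_boot))
    return pd.DataFrame(
        rows, columns=["pop_a", "pop_b", "theta", "ci_low", "ci_high", "n_boot"]
    )
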
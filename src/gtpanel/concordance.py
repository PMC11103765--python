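"""Cross-method genotype concordance.

Compares two genotype matrices over their shared individuals and loci
and breaks discordant diploid calls into the three possible categories
for biallelic loci: method A homozygous / method B heterozygous, A het /
B hom, and A hom / B hom for opposite alleles. A het/het mismatch is
structurally impossible (there is only one heterozygous genotype), which
is asserted. Cells that either method left uncalled (missing or a
dead-zone nocall) are excluded from the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import HET, HOM1, HOM2, NOT_CALLED, GenotypeMatrix

CATEGORIES = ("a_hom_b_het", "a_het_b_hom", "a_hom_b_hom_diff")


@dataclass
class DiscordanceReport:
    """Aggregate concordance summary plus the per-individual table."""

    n_individuals: int
    n_loci_compared: int
    mean_both_called: float
    mean_discordant: float
    category_means: dict[str, float]
    category_pct_of_discordant: dict[str, float]
    discordance_rate: float
    per_individual: pd.DataFrame
    rate_mode: str = "ratio-of-means"

    def as_row(self) -> dict[str, float]:
        row = {
            "n_individuals": self.n_individuals,
            "n_loci_compared": self.n_loci_compared,
            "mean_both_called": self.mean_both_called,
            "mean_discordant": self.mean_discordant,
            "discordance_rate": self.discordance_rate,
        }
        for c in CATEGORIES:
            row[c] = self.category_means[c]
            row[f"{c}_pct"] = self.category_pct_of_discordant[c]
        return row


def _is_hom(calls: np.ndarray) -> np.ndarray:
    return (calls == HOM1) | (calls == HOM2)


def compare_matrices(
    a: GenotypeMatrix,
    b: GenotypeMatrix,
    rate_mode: str = "ratio-of-means",
) -> DiscordanceReport:
    """Compare two matrices over shared individuals and loci.

    ``rate_mode`` selects the aggregation of the discordance rate:
    ``ratio-of-means`` (mean discordant loci per individual over mean
    loci called by both methods) or ``mean-of-ratios`` (mean of the
    per-individual discordant fractions).
    """
    if rate_mode not in ("ratio-of-means", "mean-of-ratios"):
        raise ValueError(f"unknown rate_mode {rate_mode!r}")
    inds = [i for i in a.individuals if i in set(b.individuals)]
    loci = [l for l in a.loci if l in set(b.loci)]
    if not inds or not loci:
        raise ValueError(
            "no shared individuals/loci: "
            f"A has {len(a.individuals)} inds x {len(a.loci)} loci, "
            f"B has {len(b.individuals)} x {len(b.loci)}, "
            f"shared {len(inds)} x {len(loci)}"
        )
    ca = a.calls.loc[inds, loci].to_numpy(dtype=object)
    cb = b.calls.loc[inds, loci].to_numpy(dtype=object)

    called = ~np.isin(ca, list(NOT_CALLED)) & ~np.isin(cb, list(NOT_CALLED))
    differ = called & (ca != cb)
    hom_a, hom_b = _is_hom(ca), _is_hom(cb)
    het_a, het_b = ca == HET, cb == HET

    het_het_diff = differ & het_a & het_b
    assert not het_het_diff.any(), "impossible het/het discordance for biallelic loci"

    cats = {
        "a_hom_b_het": differ & hom_a & het_b,
        "a_het_b_hom": differ & het_a & hom_b,
        "a_hom_b_hom_diff": differ & hom_a & hom_b,
    }

    per_ind = pd.DataFrame(
        {
            "both_called": called.sum(axis=1),
            "discordant": differ.sum(axis=1),
            **{k: v.sum(axis=1) for k, v in cats.items()},
        },
        index=pd.Index(inds, name="individual"),
    )

    mean_both = float(per_ind["both_called"].mean())
    mean_disc = float(per_ind["discordant"].mean())
    cat_means = {k: float(per_ind[k].mean()) for k in CATEGORIES}
    cat_pct = {
        k: (100.0 * cat_means[k] / mean_disc if mean_disc > 0 else 0.0) for k in CATEGORIES
    }
    if rate_mode == "ratio-of-means":
        rate = mean_disc / mean_both if mean_both > 0 else float("nan")
    else:
        with np.errstate(invalid="ignore"):
            ratios = per_ind["discordant"] / per_ind["both_called"]
        rate = float(ratios.dropna().mean())

    return DiscordanceReport(
        n_individuals=len(inds),
        n_loci_compared=len(loci),
        mean_both_called=mean_both,
        mean_discordant=mean_disc,
        category_means=cat_means,
        category_pct_of_discordant=cat_pct,
        discordance_rate=rate,
        per_individual=per_ind,
        rate_mode=rate_mode,
    )


def discordance_rate(report: DiscordanceReport) -> float:
    """Mean discordant loci per individual over mean loci called by both."""
    if report.mean_both_called <= 0:
        raise ZeroDivisionError("no loci called by both methods")
    return report.mean_discordant / report.mean_both_called


def rate_from_means(mean_discordant: float, mean_both_called: float) -> float:
    """Discordance rate from published per-individual means."""
    if mean_both_called <= 0:
        raise ZeroDivisionError("mean_both_called must be positive")
    return mean_discordant / mean_both_called


def recompute_excluding(report: DiscordanceReport, excluded_category: str) -> float:
    """Discordance rate with one mismatch category treated as concordant."""
    if excluded_category not in CATEGORIES:
        raise ValueError(f"unknown category {excluded_category!r}; choose from {CATEGORIES}")
    if report.mean_both_called <= 0:
        raise ZeroDivisionError("no loci called by both methods")
    remaining = report.mean_discordant - report.category_means[excluded_category]
    return remaining / report.mean_both_called
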
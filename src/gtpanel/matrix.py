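"""Diploid genotype matrices with per-individual metadata.

The central container shared by every analysis step: individuals × loci
calls coded as ``hom1`` / ``het`` / ``hom2`` (homozygous allele 1,
heterozygous, homozygous allele 2), plus two flavours of "no genotype":
``missing`` (insufficient read depth, or absent from the input) and
``nocall`` (a read ratio that falls in a dead zone of the calling rule).
Both no-genotype codes count as missing for every downstream statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM1 = "hom1"
HET = "het"
HOM2 = "hom2"
MISSING = "missing"
NOCALL = "nocall"

CALL_CODES = (HOM1, HET, HOM2, MISSING, NOCALL)
NOT_CALLED = frozenset({MISSING, NOCALL})

#: numeric export: count of allele-2 copies (VCF ALT-dosage convention)
_NUMERIC = {HOM1: 0.0, HET: 1.0, HOM2: 2.0, MISSING: np.nan, NOCALL: np.nan}
_FROM_NUMERIC = {0: HOM1, 1: HET, 2: HOM2}


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid calls plus per-individual metadata.

    Parameters
    ----------
    calls
        DataFrame indexed by individual id, one column per locus id,
        entries drawn from :data:`CALL_CODES`.
    meta
        DataFrame indexed by individual id with columns ``population``
        and (optionally) ``sample_type`` (hair / swab / tissue).
    """

    calls: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"population": "pop1", "sample_type": "tissue"},
                index=self.calls.index,
            )
        if "sample_type" not in self.meta.columns:
            self.meta = self.meta.assign(sample_type="tissue")
        self.validate()

    # -- basic accessors ------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def validate(self) -> None:
        bad = set(np.unique(self.calls.values.astype(str))) - set(CALL_CODES)
        if bad:
            raise ValueError(f"unknown genotype codes: {sorted(bad)}")
        if not self.calls.index.equals(self.meta.index):
            missing = set(self.calls.index) ^ set(self.meta.index)
            raise ValueError(f"calls/meta individual mismatch: {sorted(missing)}")
        if (self.meta["population"].astype(str).str.len() == 0).any():
            raise ValueError("empty population ids in metadata")

    # -- derived views ---------------------------------------------------

    def to_numeric(self) -> pd.DataFrame:
        """Allele-2 dosage (0/1/2) with NaN for missing and nocall."""
        return self.calls.map(_NUMERIC.get).astype(float)

    def locus_missingness(self) -> pd.Series:
        """Fraction of individuals not called, per locus."""
        return self.calls.isin(NOT_CALLED).mean(axis=0)

    def individual_missingness(self) -> pd.Series:
        return self.calls.isin(NOT_CALLED).mean(axis=1)

    def populations(self) -> list[str]:
        return sorted(self.meta["population"].unique())

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        calls = self.calls
        meta = self.meta
        if individuals is not None:
            calls = calls.loc[list(individuals)]
            meta = meta.loc[list(individuals)]
        if loci is not None:
            calls = calls[list(loci)]
        return GenotypeMatrix(calls.copy(), meta.copy())

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path, numeric: bool = False, header_comment: str | None = None) -> None:
        """Write calls as CSV; ``numeric=True`` exports 0/1/2/NA dosages.

        Text codes use NA for ``missing`` and NC for ``nocall``.
        """
        if numeric:
            out = self.to_numeric()
        else:
            out = self.calls.replace({MISSING: "NA", NOCALL: "NC"})
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            out.to_csv(fh, index_label="individual")

    @classmethod
    def from_csv(cls, path, meta: pd.DataFrame | None = None) -> "GenotypeMatrix":
        """Read a matrix CSV (text codes or 0/1/2 dosage; NA/NC allowed)."""
        df = pd.read_csv(path, comment="#", index_col=0, dtype=str)
        df.index = df.index.astype(str)

        def decode(v: str) -> str:
            if pd.isna(v) or v in ("NA", ""):
                return MISSING
            if v == "NC":
                return NOCALL
            if v in CALL_CODES:
                return v
            try:
                return _FROM_NUMERIC[int(float(v))]
            except (KeyError, ValueError):
                raise ValueError(f"unrecognised genotype code {v!r}")

        calls = df.map(decode)
        return cls(calls, meta.loc[calls.index] if meta is not None else None)

    @classmethod
    def from_vcf(cls, path, meta: pd.DataFrame | None = None) -> "GenotypeMatrix":
        """Read biallelic SNP records from a VCF (REF allele = allele 1).

        Multiallelic or non-SNP records are skipped with a warning.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        data: dict[str, list[str]] = {}
        skipped = 0
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        code = {0: HOM1, 1: HET, 2: MISSING, 3: HOM2}
        for rec in vcf:
            if len(rec.ALT) != 1 or not rec.is_snp:
                skipped += 1
                continue
            locus = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
            data[locus] = [code[int(t)] for t in rec.gt_types]
        if skipped:
            warnings.warn(f"skipped {skipped} non-biallelic/non-SNP VCF records")
        calls = pd.DataFrame(data, index=pd.Index(individuals, name="individual"))
        return cls(calls, meta.loc[calls.index] if meta is not None else None)


def read_population_map(path) -> pd.DataFrame:
    """Read a CSV of individual, population[, sample_type]."""
    df = pd.read_csv(path, comment="#", dtype=str)
    df = df.set_index(df.columns[0])
    df.index.name = "individual"
    if "population" not in df.columns:
        df = df.rename(columns={df.columns[0]: "population"})
    return df
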
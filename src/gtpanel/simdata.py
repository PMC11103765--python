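"""Synthetic study generator: structured populations, amplicon reads, truth.

Emulates the data a panel-validation study collects, end to end:

* population allele frequencies under the Balding–Nichols island model
  (Beta-distributed around an ancestral frequency with a target F_ST),
* diploid genotypes drawn under Hardy–Weinberg equilibrium,
* per-individual single-end amplicon FASTQ reads with per-read
  false-allele errors and per-allele amplification dropout, where read
  depth follows a per-sample-type profile (hair ≈ ultra-low, swab ≈
  moderate, tissue ≈ high),
* an idealised low-coverage caller that mimics how shallow sequencing
  turns heterozygotes into homozygotes,

plus truth genotype and truth tally tables so every downstream module
can be validated without external data. Everything is reproducible from
the configured seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import HET, HOM1, HOM2, MISSING, GenotypeMatrix
from .snp_select import LocusDef

#: mean on-target depth per locus by sample type (Poisson λ)
DEPTH_PROFILES = {"hair": 2.0, "swab": 30.0, "tissue": 100.0}

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic population + read generator.

    Defaults describe the study conditions the toolkit targets: two
    moderately differentiated populations (F_ST 0.10, the middle of the
    range typical for fragmented small-mammal populations), 30
    individuals each, a ~300-locus panel, tissue-grade depth (λ=100),
    a 0.1% per-read false-allele rate and no amplification dropout,
    118-base single-end reads.
    """

    n_pops: int = 2
    fst_target: float = 0.10
    n_individuals_per_pop: int = 30
    n_loci: int = 300
    ancestral_freq_dist: tuple = ("uniform", 0.1, 0.9)
    depth_model: tuple = ("poisson", DEPTH_PROFILES["tissue"])
    error_rate: float = 0.001
    dropout: float = 0.0
    dropout_allele: int | None = None  # restrict dropout to allele 1 or 2 (None: both)
    read_length: int = 118
    probe_radius: int = 7  # probe = 2*radius + 1 bases centred on the SNP
    sample_type: str = "tissue"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in (0,1)")
        for name in ("error_rate", "dropout"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.read_length < 2 * self.probe_radius + 1:
            raise ValueError("read_length must cover the probe")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def sim_population_freqs(cfg: SimConfig) -> np.ndarray:
    """Per-population allele-1 frequencies, shape (n_pops, n_loci).

    Ancestral frequencies come from ``ancestral_freq_dist``; each
    population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with
    F = ``fst_target`` (Balding–Nichols).
    """
    rng = cfg.rng(salt=1)
    kind, *params = cfg.ancestral_freq_dist
    if kind == "uniform":
        lo, hi = params
        anc = rng.uniform(lo, hi, size=cfg.n_loci)
    elif kind == "beta":
        a, b = params
        anc = rng.beta(a, b, size=cfg.n_loci)
    else:
        raise ValueError(f"unknown ancestral_freq_dist {kind!r}")
    f = cfg.fst_target
    scale = (1.0 - f) / f
    return rng.beta(anc * scale, (1.0 - anc) * scale, size=(cfg.n_pops, cfg.n_loci))


def sim_genotypes(freqs: np.ndarray, cfg: SimConfig) -> GenotypeMatrix:
    """HWE genotypes: allele-1 copy number ~ Binomial(2, p_pop,locus)."""
    rng = cfg.rng(salt=2)
    n_pops, n_loci = freqs.shape
    code = {2: HOM1, 1: HET, 0: HOM2}
    blocks, inds, pops = [], [], []
    for p in range(n_pops):
        copies = rng.binomial(2, freqs[p], size=(cfg.n_individuals_per_pop, n_loci))
        blocks.append(np.vectorize(code.get)(copies))
        for i in range(cfg.n_individuals_per_pop):
            inds.append(f"pop{p + 1}_ind{i + 1:03d}")
            pops.append(f"pop{p + 1}")
    calls = pd.DataFrame(
        np.vstack(blocks),
        index=pd.Index(inds, name="individual"),
        columns=[f"locus{j + 1:04d}" for j in range(n_loci)],
    )
    meta = pd.DataFrame(
        {"population": pops, "sample_type": cfg.sample_type}, index=calls.index
    )
    return GenotypeMatrix(calls, meta)


def make_locus_defs(cfg: SimConfig) -> list[LocusDef]:
    """Random amplicon templates with centred SNPs and unique probes.

    The flank is a random sequence of ``read_length`` bases with the SNP
    at the midpoint; probes span ``probe_radius`` bases either side of
    the SNP. Probe collisions across loci are regenerated (astronomically
    rare for 15-mers).
    """
    rng = cfg.rng(salt=3)
    k = cfg.probe_radius
    snp_pos = cfg.read_length // 2
    loci: list[LocusDef] = []
    seen: set[str] = set()
    for j in range(cfg.n_loci):
        while True:
            flank = "".join(rng.choice(_BASES, size=cfg.read_length))
            a1, a2 = rng.choice(_BASES, size=2, replace=False)
            left, right = flank[snp_pos - k : snp_pos], flank[snp_pos + 1 : snp_pos + 1 + k]
            p1, p2 = left + a1 + right, left + a2 + right
            if p1 not in seen and p2 not in seen and p1 != p2:
                seen.update((p1, p2))
                break
        loci.append(
            LocusDef(
                locus_id=f"locus{j + 1:04d}",
                scaffold=f"scaffold{j + 1:04d}",
                position=snp_pos + 1,
                allele1=str(a1),
                allele2=str(a2),
                probe1=p1,
                probe2=p2,
                flank=flank,
            )
        )
    return loci


def _draw_depth(rng: np.random.Generator, model: tuple, size: int) -> np.ndarray:
    kind, *params = model
    if kind == "poisson":
        return rng.poisson(params[0], size=size)
    if kind == "negbin":
        mean, dispersion = params
        p = dispersion / (dispersion + mean)
        return rng.negative_binomial(dispersion, p, size=size)
    raise ValueError(f"unknown depth model {kind!r}")


def sim_reads(
    truth: GenotypeMatrix,
    loci: list[LocusDef],
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    gzip_fastq: bool = False,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Generate per-individual amplicon reads and the truth tally table.

    Per individual × locus the read depth is drawn from ``depth_model``.
    Heterozygote reads pick an allele with probability ½ each unless one
    allele dropped out (probability ``dropout`` per allele per cell), in
    which case all reads carry the surviving allele; a cell whose every
    allele drops out yields no reads. Each read then flips to the
    opposite allele's probe with probability ``error_rate``. Reads embed
    the allele base in the locus flank (the whole amplicon template).

    Returns ``(reads per individual, truth tallies)``; when ``out_dir``
    is given, FASTQ files (constant qualities) are also written there.
    """
    rng = cfg.rng(salt=4)
    snp_pos = cfg.read_length // 2
    templates = {
        ld.locus_id: (
            ld.flank[:snp_pos] + ld.allele1 + ld.flank[snp_pos + 1 :],
            ld.flank[:snp_pos] + ld.allele2 + ld.flank[snp_pos + 1 :],
        )
        for ld in loci
    }
    for ld in loci:
        if cfg.read_length < len(ld.probe1):
            raise ValueError("read_length shorter than probe length")
    qual = "I" * cfg.read_length
    reads: dict[str, list[str]] = {}
    tally_rows = []
    locus_ids = [ld.locus_id for ld in loci]
    for ind in truth.individuals:
        ind_reads: list[str] = []
        depths = _draw_depth(rng, cfg.depth_model, len(locus_ids))
        for lid, d in zip(locus_ids, depths):
            g = truth.calls.at[ind, lid]
            if d == 0 or g == MISSING:
                tally_rows.append((ind, lid, 0, 0))
                continue
            if g == HET:
                can_drop = np.array(
                    [cfg.dropout_allele in (None, 1), cfg.dropout_allele in (None, 2)]
                )
                alive = ~(can_drop & (rng.random(2) < cfg.dropout))
                if not alive.any():
                    tally_rows.append((ind, lid, 0, 0))
                    continue
                if alive.all():
                    allele1 = rng.random(d) < 0.5
                else:
                    allele1 = np.full(d, bool(alive[0]))
            else:
                allele = 1 if g == HOM1 else 2
                if cfg.dropout_allele in (None, allele) and rng.random() < cfg.dropout:
                    tally_rows.append((ind, lid, 0, 0))
                    continue
                allele1 = np.full(d, g == HOM1)
            if cfg.error_rate > 0:
                flip = rng.random(d) < cfg.error_rate
                allele1 = allele1 ^ flip
            t1, t2 = templates[lid]
            for is_a1 in allele1:
                ind_reads.append(t1 if is_a1 else t2)
            tally_rows.append((ind, lid, int(allele1.sum()), int(d - allele1.sum())))
        reads[ind] = ind_reads
    tallies = pd.DataFrame(tally_rows, columns=["individual", "locus_id", "n1", "n2"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for ind, seqs in reads.items():
            name = f"{ind}.fastq.gz" if gzip_fastq else f"{ind}.fastq"
            opener = gzip.open if gzip_fastq else open
            with opener(out / name, "wt") as fh:
                for i, seq in enumerate(seqs):
                    fh.write(f"@{ind}_read{i + 1}\n{seq}\n+\n{qual}\n")
    return reads, tallies


def sim_lowcov_calls(
    truth: GenotypeMatrix, depth: int, seed: int, error_rate: float = 0.0
) -> GenotypeMatrix:
    """Idealised low-coverage caller sampling ``depth`` reads per cell.

    A heterozygote whose ``depth`` sampled reads all agree is observed as
    the corresponding homozygote (allelic dropout by chance); in
    error-free mode homozygotes are never observed as heterozygotes.
    With ``error_rate`` > 0 each sampled read flips allele with that
    probability before calling, so false heterozygotes become possible.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    calls = truth.calls.copy()
    arr = calls.to_numpy(dtype=object)
    n_ind, n_loc = arr.shape
    p1 = np.where(arr == HOM1, 1.0, np.where(arr == HET, 0.5, 0.0))
    k1 = rng.binomial(depth, p1)  # reads carrying allele 1
    if error_rate > 0:
        flips_to_2 = rng.binomial(k1, error_rate)
        flips_to_1 = rng.binomial(depth - k1, error_rate)
        k1 = k1 - flips_to_2 + flips_to_1
    obs = np.where(k1 == depth, HOM1, np.where(k1 == 0, HOM2, HET))
    obs = np.where(arr == MISSING, MISSING, obs)
    return GenotypeMatrix(
        pd.DataFrame(obs, index=calls.index, columns=calls.columns), truth.meta.copy()
    )


def simulate_study(cfg: SimConfig, out_dir: str | Path | None = None):
    """Convenience wrapper: frequencies → genotypes → loci → reads.

    Returns ``(loci, truth matrix, reads per individual, truth tallies)``
    and, when ``out_dir`` is given, writes the full artifact set (locus
    table, FASTA amplicons, FASTQ reads, truth CSVs, population map).
    """
    from .snp_select import write_locus_table

    freqs = sim_population_freqs(cfg)
    truth = sim_genotypes(freqs, cfg)
    loci = make_locus_defs(cfg)
    reads, tallies = sim_reads(truth, loci, cfg, out_dir=out_dir)
    if out_dir is not None:
        out = Path(out_dir)
        write_locus_table(loci, out / "loci.csv")
        with open(out / "amplicons.fasta", "w") as fh:
            for ld in loci:
                fh.write(f">{ld.locus_id}\n{ld.flank}\n")
        truth.to_csv(out / "truth_genotypes.csv")
        tallies.to_csv(out / "truth_tallies.csv", index=False)
        truth.meta.to_csv(out / "population_map.csv", index_label="individual")
    return loci, truth, reads, tallies
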
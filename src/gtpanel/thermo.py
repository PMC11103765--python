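"""Nearest-neighbor DNA duplex thermodynamics.

Unified nearest-neighbor parameters (SantaLucia 1998): per-stack
enthalpies/entropies plus terminal initiation terms, a sodium entropy
correction of 0.368·(N−1)·ln[Na+], and

    Tm = 1000·ΔH / (ΔS + R·ln(CT)) − 273.15

with CT the effective strand concentration (mol/L). Self-complementary
sequences get the symmetry entropy penalty and use the full strand
concentration.
"""

from __future__ import annotations

import math

R_GAS = 1.987  # cal / (mol K)

# ΔH (kcal/mol), ΔS (cal/mol/K) per nearest-neighbor stack, top strand 5'->3'
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

# terminal initiation with a G·C vs A·T end
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_SYM = (0.0, -1.4)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> str:
    s = seq.upper()
    if not s or set(s) - set("ACGT"):
        raise ValueError(f"sequence must be non-empty ACGT, got {seq!r}")
    return s


def duplex_dh_ds(seq: str) -> tuple[float, float]:
    """Total ΔH (kcal/mol) and ΔS (cal/mol/K) of a perfect duplex."""
    s = _check_alphabet(seq)
    dh, ds = 0.0, 0.0
    for i in range(len(s) - 1):
        h, e = _NN[s[i : i + 2]]
        dh += h
        ds += e
    for end in (s[0], s[-1]):
        h, e = _INIT_GC if end in "GC" else _INIT_AT
        dh += h
        ds += e
    if s == revcomp(s):
        dh += _SYM[0]
        ds += _SYM[1]
    return dh, ds


def melting_temperature(
    seq: str,
    na_mM: float = 50.0,
    primer_nM: float = 250.0,
    target_nM: float = 250.0,
    min_len: int = 8,
) -> float:
    """Nearest-neighbor duplex Tm in °C.

    Parameters
    ----------
    seq
        Primer sequence (ACGT, length ≥ ``min_len``).
    na_mM
        Monovalent cation concentration (mM).
    primer_nM, target_nM
        Strand concentrations (nM); the effective duplex concentration is
        primer − target/2 for hetero-duplexes, primer for
        self-complementary sequences.
    """
    s = _check_alphabet(seq)
    if len(s) < min_len:
        raise ValueError(f"sequence shorter than {min_len} bases: {seq!r}")
    return _tm_from_dh_ds(s, na_mM, primer_nM, target_nM)


def _tm_from_dh_ds(
    s: str, na_mM: float = 50.0, primer_nM: float = 250.0, target_nM: float = 250.0
) -> float:
    dh, ds = duplex_dh_ds(s)
    ds += 0.368 * (len(s) - 1) * math.log(na_mM / 1000.0)
    if s == revcomp(s):
        ct = primer_nM * 1e-9
    else:
        ct = (primer_nM - target_nM / 2.0) * 1e-9
    return (1000.0 * dh) / (ds + R_GAS * math.log(ct)) - 273.15


def stem_tm(seq: str, na_mM: float = 50.0, primer_nM: float = 250.0,
            target_nM: float = 250.0) -> float:
    """Tm of a short perfectly paired stem (no minimum length)."""
    s = _check_alphabet(seq)
    if len(s) < 2:
        return -273.15
    return _tm_from_dh_ds(s, na_mM, primer_nM, target_nM)
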
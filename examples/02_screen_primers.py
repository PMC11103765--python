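"""Screen a small primer panel and formulate the pooled mix.

Builds a toy panel with one deliberately bad primer pair per failure
mode, screens it (length, Tm window, hairpins, heterodimers, internal
binding sites), then assigns pooled concentrations from performance
quartiles: strong amplifiers are diluted to 80 nM, weak ones boosted to
320 nM, the rest stay at 160 nM.
"""

import numpy as np

from gtpanel.primer_screen import (
    PrimerSet, ScreenConfig, formulate_primer_mix, screen_panel,
)
from gtpanel.thermo import melting_temperature, revcomp

rng = np.random.default_rng(2024)
bases = np.array(list("ACGT"))


def passing_primer():
    while True:
        seq = "".join(rng.choice(bases, 20))
        if 58 <= melting_temperature(seq) <= 63:
            return seq


primers = [PrimerSet(f"locus{i}", passing_primer(), passing_primer()) for i in range(5)]
primers.append(PrimerSet("too_short", passing_primer()[:15], passing_primer()))
d = passing_primer()
primers.append(PrimerSet("self_dimer", d, revcomp(d)))  # fwd/rev anneal to each other

amplicons = {
    p.locus_id: p.fwd + "".join(rng.choice(bases, 40)) + revcomp(p.rev) for p in primers
}

report = screen_panel(primers, amplicons, ScreenConfig())
print("screening ledger:", report.summary())
for lid, failures in zip(report.results["locus_id"], report.results["failures"]):
    if failures:
        print(f"  {lid}: fails {', '.join(failures)}")

# pooled-mix formulation from on-target read shares of a pilot run
shares = {p.locus_id: s for p, s in zip(primers, np.linspace(0.30, 0.01, len(primers)))}
mix = formulate_primer_mix(shares)
print("primer mix (nM):", mix)
# The top-quartile performers get 80 nM (they already amplify well),
# bottom-quartile performers get 320 nM to pull their read share up.
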
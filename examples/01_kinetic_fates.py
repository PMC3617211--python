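"""Fates of the two synthetic-lethal double mutants.

Builds the fragile reference pathway, knocks out gene pairs and prints the
long-time state of a damaged locus.  The between-pathway double knockout
(F1 + EC) leaves all probability on the unrepaired substrate S (death by
damage); the within-reversible-pathway double knockout (R1 + F2) traps it
all in the toxic intermediate I (death by toxicity), even though each
single knockout alone is survivable.
"""

from kinetrap import Enzyme, apply_perturbations, classify_fate, limiting_distribution, reference_ratesets
from kinetrap.scenarios import knockout

nf = reference_ratesets()["NF"]

for name, enzymes in [
    ("unperturbed", []),
    ("bpSL  (F1 + EC out)", [Enzyme.F1, Enzyme.EC]),
    ("wrpSL (R1 + F2 out)", [Enzyme.R1, Enzyme.F2]),
]:
    rates = apply_perturbations(nf, [knockout(e) for e in enzymes])
    d = limiting_distribution(rates)
    fate = classify_fate(rates)
    print(f"{name:22s} S={d.s:6.4f}  I={d.i:6.4f}  P={d.p:6.4f}  -> {fate.value}")

print()
print("S/I/P are the long-time probabilities of the damage substrate, the")
print("toxic intermediate and the repaired product; a dead fate means one")
print("unrepaired state holds more than 50% of the probability forever.")
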
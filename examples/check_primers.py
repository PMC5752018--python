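"""Quality-check PCR primers for marker assays.

Checks length (18-25 nt), GC content (~50%), melting temperature (~55 C,
Wallace rule), and hairpin/self-dimer potential.
"""

from sssltools import PrimerParams, check_primer

primers = [
    "AGCTAGACCATAGACCAGA",        # well-behaved 19-mer
    "GGGGGAAAAACCCCCTTTTT",       # GC fine (50%) but Tm 60 C exceeds 55 +/- 3
    "ACGTACGTACGTACGTA",          # 17 nt: too short, and self-complementary
    "GACGATCCAAAGGATCGTC",        # 8-nt inverted repeat -> hairpin risk
]

params = PrimerParams()
for p in primers:
    rep = check_primer(p, params)
    verdict = "PASS" if rep.passed else "FAIL (" + "; ".join(rep.failures) + ")"
    print(f"{p:24s} len={rep.length:2d}  GC={rep.gc_percent:5.1f}%  "
          f"Tm={rep.tm:5.1f}C  stem={rep.max_self_complementary_run}  {verdict}")
print("\n'stem' is the longest self-complementary run; runs of 6+ nt with a"
      " 3-nt loop can fold into hairpins or self-dimers during PCR.")
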
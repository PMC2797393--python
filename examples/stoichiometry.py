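"""Filament stoichiometry from refined helical parameters.

Given the refined rotation between successive protomers, the number of
protomers per helical turn is 360/twist; combined with the nucleotide span
of the fitted ssDNA this yields the nucleotide coverage per protomer and
per turn.
"""

from helifil.geometry import stoichiometry

FILAMENTS = [
    ("extended hDmc1-ssDNA", 110.0, 40.5, 15, 7),
    ("compressed hDmc1-ssDNA", 96.0, 42.5, None, None),
    ("hDmc1-dsDNA", 106.0, 56.5, None, None),
    ("RecA-ssDNA", 82.0, 59.0, 18, 6),
]

for name, pitch, twist, nt, span in FILAMENTS:
    rep = stoichiometry(pitch, twist, n_nucleotides=nt, n_protomers_spanned=span)
    line = (f"{name:26s} pitch {pitch:5.1f} A, twist {twist:4.1f} deg -> "
            f"{rep.protomers_per_turn:4.1f} protomers/turn, "
            f"rise {rep.rise_per_protomer:5.2f} A")
    if rep.nt_per_protomer is not None:
        line += (f", {rep.nt_per_protomer} nt/protomer, "
                 f"~{rep.nt_per_turn} nt/turn")
    print(line)

print("\nProtomers/turn is the key architectural number: ~8.9 for the "
      "extended ssDNA filament versus ~6 for the RecA family, i.e. one "
      "protomer covers ~2 nucleotides instead of 3.")
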
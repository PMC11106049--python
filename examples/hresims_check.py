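"""Check HRESIMS annotations for a set of isolated compounds.

For each neutral molecular formula we compute the adduct m/z (monoisotopic,
with electron-mass correction), compare it with the observed ion, and report
the ppm deviation and the degrees of unsaturation of the neutral molecule.
A |ppm| below ~5 supports the formula assignment.
"""

from osmactools.formula_mass import degrees_of_unsaturation, mass_match

# (compound, neutral formula, adduct, observed m/z)
OBSERVATIONS = [
    ("helvamide B", "C34H32N2O5", "[M+Na]+", 571.2193),
    ("helvamide B", "C34H32N2O5", "[M-H]-", 547.2215),
    ("helvamide C", "C31H34N2O5", "[M+Na]+", 537.2358),
    ("helvamide C", "C31H34N2O5", "[M-H]-", 513.2405),
    ("saroclazine A", "C19H26N2O3S2", "[M+Na]+", 417.1278),
    ("guaiane diol", "C15H24O2", "[M+Na]+", 259.1669),
    ("guaiane diol", "C15H24O2", "[M-H]-", 235.1701),
]

print(f"{'compound':<14} {'formula':<13} {'adduct':<8} {'observed':>10} "
      f"{'calcd':>10} {'dppm':>6} {'DBE':>4}")
for name, formula, adduct, observed in OBSERVATIONS:
    m = mass_match(formula, observed, adduct)
    dbe = degrees_of_unsaturation(formula)
    print(f"{name:<14} {formula:<13} {adduct:<8} {observed:>10.4f} "
          f"{m.calculated_mz:>10.4f} {m.ppm_delta:>+6.1f} {dbe:>4}")

print("\nAll deviations are within +-5 ppm, consistent with the assigned "
      "formulas; DBE counts the rings plus pi-bonds each formula implies.")
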
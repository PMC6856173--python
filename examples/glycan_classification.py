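"""Composition-level N-glycan classification and diagnostic oxonium ions.

Parses a few composition strings and prints family, antennarity, fucose
placement and LacdiNAc possibility, then checks a synthetic MS2 peak list
for the HexNAc2 oxonium ion that corroborates LacdiNAc.
"""

from glycoculture import (
    MonosaccharideCounts,
    classify_n_glycan,
    match_oxonium,
    oxonium_mz,
    parse_composition,
)

for text in ["HexNAc(4)Hex(5)Fuc(1)NeuAc(2)", "HexNAc(6)Hex(5)Fuc(1)",
             "HexNAc(2)Hex(9)"]:
    c = parse_composition(text)
    g = classify_n_glycan(c)
    print(f"{text}: {g.family}, {g.antennae} antennae, core Fuc {g.core_fucose}, "
          f"antenna Fuc {g.antenna_fucose}, bare antennal HexNAc "
          f"{g.unoccupied_hexnac}, LacdiNAc possible: {g.lacdinac_possible}")

target = oxonium_mz(MonosaccharideCounts(hexnac=2))
print(f"\n[HexNAc2 + H]+ diagnostic ion m/z = {target:.4f}")
peaks = [(204.087, 8e3), (366.140, 5e3), (407.166, 2.5e3)]
print(f"present in peak list at 20 ppm: {match_oxonium(peaks, target)}")
print("A HexNAc2 oxonium fragment indicates a GalNAc-GlcNAc (LacdiNAc) unit"
      "\nindependently of the composition arithmetic.")
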
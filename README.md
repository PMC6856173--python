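# glycoculture

Quantification toolkit for characterizing recombinant glycoprotein producer
cell lines — written for bioprocess and glycoanalytics scientists who have
upstream search/quantitation output (glycopeptide identification tables,
culture time courses, droplet-PCR well counts) and need the derived,
reportable numbers.

Four pipelines, usable from Python or a thin CLI:

1. **Site-specific glycosylation profiling.** From a table of identified
   (glyco)peptides — one row per site × glycan composition × missed-cleavage
   variant with an extracted-ion-chromatogram (XIC) abundance — compute, per
   site *s* with glycoform fractions *f*ₛ(g) normalized over the site
   (unglycosylated form included):
   - occupancy: `100 × (1 − fₛ(unglycosylated))`
   - mole ratios: `Σ_g fₛ(g) · count(g)` for NeuAc, core Fuc (the first
     fucose of a composition is always core), total Fuc — moles per mole of
     protein at the site
   - antennarity: antennae = HexNAc − 2 (beyond the chitobiose core);
     bi/tri/tetra percentages rescaled to 100 over the multi-antennary pool
   - aggregates: total-N mole ratios are *sums* over N sites, antennarity
     and occupancy are *unweighted means*; overall sialylation adds the
     O sites.

   Composition-level classification also flags possible LacdiNAc
   (GalNAcβ1-4GlcNAc): after placing all non-core Hex on LacNAc antennae,
   ≥ 2 bare antennal HexNAc imply a possible pair; the diagnostic
   [HexNAc₂+H]⁺ oxonium ion (m/z 407.166) can corroborate it from MGF
   peak lists.

2. **Fed-batch kinetics.** Specific growth rate µ from the slope of
   ln(VCD) vs *t* (VCD = VCD₀·e^{µt}); cumulative integral viable cell
   density by the trapezium rule, IVCDₜ = IVCDₜ₋₁ + ½(VCDₜ+VCDₜ₋₁)Δt; and
   specific productivity q_p = ΔP/ΔIVCD (two-point) or the slope of titer
   vs IVCD (regression, default).

3. **Titer unit conversion.** U/mL → mg/L via a specific activity
   (erythropoietin: 150 U/µg, WHO 3rd International Standard), and
   µU/cell/day → pg/cell/day.

4. **ddPCR copy number.** Poisson occupancy λ = −ln(1 − positive droplet
   fraction) → copies per reaction → copies per ng of input → genomic
   copies per cell against a reference locus of known copy number
   (default 2) → expression fold changes, with detection-limit baselines
   propagated as lower bounds.

A seeded synthetic-data module generates inputs for every stage — an
EPO-like glycoprotein (N sites Asn24/Asn38/Asn83, O site Ser126) with
configurable glycoform distributions, occupancy, missed-cleavage redundancy
and lognormal abundance noise — together with closed-form ground truth, so
the whole package is testable without any external dataset.

## Worked example

```python
from glycoculture import build_report, default_epo_config, simulate_glycopeptide_table
from glycoculture.io import report_to_frame

records, truth = simulate_glycopeptide_table(default_epo_config(noise_sigma=0.1, seed=7))
print(report_to_frame(build_report(records)).to_string(index=False))
```

```
                 site  mol_core_fuc  mol_neuac antennae_bi_tri_tetra_pct  occupancy_pct
       Asn24 N-glycan        0.9505     0.7331           87.39/7.73/4.88         100.00
       Asn38 N-glycan        1.0000     2.0674         54.12/14.86/31.02         100.00
       Asn83 N-glycan        0.9996     2.8047         41.94/11.13/46.93          99.96
      Ser126 O-glycan           NaN     1.2789                       n/a          75.56
Total N-glycosylation        2.9501     5.6052         61.15/11.24/27.61          99.99
Overall glycosylation           NaN     6.8841                       n/a          93.88
```

Each N-site row reads: this site contributes ~1 mol of core fucose and the
listed moles of NeuAc per mole of protein; its multi-antennary glycans split
bi/tri/tetra as shown; the site is (almost) fully occupied.  The O site at
this simulated 75.56% occupancy still carries 1.28 mol NeuAc per mole of
protein.  The totals row sums the mole ratios and averages the percentages;
the true overall sialylation of this simulation was 6.8345 mol NeuAc/mol,
recovered here as 6.8841 from a noisy (σ = 0.1) table.

More narrative examples live in `examples/` (glycan classification and
oxonium matching, kinetics, ddPCR); each runs standalone:
`python examples/glyco_report.py`.

The same pipelines are available as shell subcommands:

```
glycoculture simulate --kind glyco -o glyco.csv --truth-out truth.json
glycoculture glyco-report glyco.csv -o report.csv
glycoculture kinetics culture.csv
glycoculture ddpcr wells.csv --reference-target PDHA2
```

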
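# asphkit

Tools for analyzing AspH-catalyzed hydroxylation of EGF-like domains
(EGFDs): consensus-motif scanning, MS/MS hydroxylation-site localization,
label-free site-occupancy estimation, and SPE-MS enzyme kinetics — plus
seeded synthetic-data generators so the whole pipeline runs and can be
scored against ground truth without any external download.

## The science

AspH (aspartate/asparagine-β-hydroxylase) is a 2-oxoglutarate/Fe(II)
oxygenase that hydroxylates the β-carbon of Asp/Asn residues in EGF-like
domains of secreted and cell-surface proteins (coagulation factor X,
fibulins, hemicentin-1, ...). Two sequence-level substrate rules are
implemented and compared:

- **legacy consensus** `C-X-D/N-X-X-X-X-F/Y-X-C-X-C` (the historical
  C3-X-D/N-···-C4-X-C5 motif, 12 residues), and
- **revised rule**: a disulfide-bridged **10-residue macrocycle**
  (C3–C4 for EGFDs) whose 3rd residue is the D/N acceptor and whose 8th
  residue is F/Y — with *no* constraint on a downstream C5. Every legacy
  match is a revised match; the `revised_only` class is exactly the set of
  candidate sites the legacy rule misses (fibulin-type EGFDs with long
  C4–C5 inserts, and non-EGFD contexts).

Supporting analyses:

- **MS/MS evidence** — modification-aware monoisotopic b/y fragment masses
  (hydroxylation = +15.994915 Da, the "~16 Da" shift), peak matching at ppm
  tolerance, and localization of the shift to the smallest residue interval
  consistent with which fragments carry it.
- **Site occupancy** — the label-free estimator
  `occupancy = 100·Ih/(Ih+Ib)` over hydroxylated vs unmodified (base)
  peptide intensities, defined only when the base peptide was detected.
- **Kinetics** — `% conversion = 100·product/(substrate+product)` from
  ion-chromatogram integrals; noiseless progress curves from the integrated
  Michaelis–Menten relation `Km·ln(S0/S) + (S0−S) = kcat·E_active·t`;
  initial-rate extraction; nonlinear fitting of `v = vmax·S/(Km+S)`; and
  active-site-titration-corrected turnover,
  `kcat = vmax/(E_total·f_active)` with `f_active = 0.951 ± 0.143`,
  and catalytic efficiency `kcat/Km` in mM⁻¹s⁻¹.

## Worked example

```python
from asphkit.sequence_motif import ProteinRecord, scan_legacy, scan_revised
from asphkit.kinetics import EnzymePrep, simulate_progress, kcat_reported

# a fibulin-type ring: valid 10-residue macrocycle, no C4-X-C5
rec = ProteinRecord("demo", "AAAAA" + "CADGGGGYAC" + "KKAAA")
print([(h.ring_start, h.site_position, h.site_residue) for h in scan_revised(rec)])
print(scan_legacy(rec))

prep = EnzymePrep(total_concentration=0.1, active_fraction=0.951)
print(kcat_reported(0.029, prep))
tc = simulate_progress(kcat=0.30, km=7.9, prep=prep,
                       substrate_initial=2.0, times=[600.0])
print(round(tc.conversion[0], 1))
```

prints

```
[(6, 8, 'D')]
[]
0.3
85.8
```

i.e. the revised rule finds the D acceptor at position 8 inside the ring
starting at residue 6, the legacy rule finds nothing (no C5), a vmax of
0.029 µM·s⁻¹ with 0.1 µM enzyme at 95.1 % activity corresponds to
kcat = 0.30 s⁻¹, and that substrate reaches 85.8 % conversion after 10 min
in a 2 µM assay.

There is also a CLI (`asphkit scan|localize|occupancy|kinetics|simulate`)
and four numbered analysis drivers under `analysis/` that generate the
synthetic datasets, scan them, localize the planted modification sites,
estimate occupancies and fit the kinetics, writing their tables under
`results/`.

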
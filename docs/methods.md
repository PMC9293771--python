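# Methods

## Consensus-motif scanning

Both rules are pure fixed-width window predicates over the one-letter
sequence, reported in 1-based inclusive coordinates (UniProt numbering).
The revised rule accepts any 10-mer with Cys at window positions 1 and 10,
Asp or Asn at position 3 and Phe or Tyr at position 8; the legacy rule is
the same predicate extended to a 12-mer with Cys at position 12 (the C5 of
the historical C4-X-C5 suffix). Wildcard positions admit *any* canonical
residue, including further cysteines and further D/N/F/Y letters, because
the consensus treats them as unconstrained. Overlapping and nested windows
are all reported; deduplication is by (accession, rule, ring start).

By construction every legacy hit contains a revised hit with identical ring
coordinates, so `classify_sites` only distinguishes `both` from
`revised_only`; encountering a legacy hit without a revised counterpart is
an internal-consistency failure and raises, rather than being silently
repaired.

Scanning runs over whole sequences, not only annotated domains — productive
macrocycles occur outside classic EGFD context. Supplied domain annotations
are used *post hoc* to label hits and, where a domain has at least five
cysteines, to attach its C4–C5 spacing (residues strictly between the 4th
and 5th cysteine counted from the domain's N terminus; spacing 1 is exactly
the legacy C4-X-C5 arrangement). The scanner is sequence-level only: it does
not verify that a disulfide physically bridges the ring cysteines, and it
reports only exact 10-residue rings — no tolerance for longer rings is
implemented, since the evidence for such substrates is unresolved.

## Fragment masses and shift localization

Monoisotopic masses throughout (residue masses from pyteomics; water
18.0105646863 Da; proton 1.007276 Da), matching high-resolution QTOF data.
Only b/y series are generated, the series used in practice to annotate
hydroxylation evidence; a fragment's mass includes the deltas of the
modifications whose residues it spans, so the hydroxylation (+15.994915 Da,
one oxygen) moves exactly the b ions with index ≥ p and y ions with index
≥ n−p+1.

Localization matches an observed spectrum against two theoretical ladders —
the unmodified ions and the same ions offset by the delta — at a default
tolerance of 10 ppm (typical for the instrument class; no tolerance is
inherent to the method). Each matched ion contributes an interval
constraint (a shifted b_i bounds the site above by i, an unshifted y_i
bounds it above by n−i, and so on); the result is the intersection, the
smallest residue interval consistent with all evidence.

Two ambiguity rules keep localization sound in the presence of exact
residue-mass degeneracies (Pro+H₂O = Val+O, Ala+O = Ser, Phe+O = Tyr):
a *peak* that lies within tolerance of ions in both ladders is excluded
before matching, and an *ion* that ends up matched in both ladders is
dropped. Both rules only discard information, so the returned interval
always contains the true site; with a complete ion series the neighbouring
ions still pin the site uniquely in ≥95 % of cases. Evidence that remains
contradictory after these rules (an empty intersection) raises a
localization error naming the offending ions instead of guessing.

Thioether-bridged cyclic assay peptides are handled at intact-mass level
only, through a fixed per-peptide mass offset (ring closure by
chloroacetyl/Cys thioether chemistry expels HCl, −35.97668 Da); fragment
prediction for cyclic species is out of scope.

## Site occupancy

`occupancy = 100·Ih/(Ih+Ib)`, the standard label-free stoichiometry
estimator over the hydroxylated and base forms of the same peptide. It is
computed only when the base peptide was detected: a missing base intensity
yields a flagged not-estimable row, never a number. The estimator is
exposed per intensity pair; any aggregation across charge states or
peptidoforms (e.g. summing intensities per site before the ratio) is left
to the caller as a documented option rather than baked in.

## Kinetics

`% conversion = 100·(product integral)/(substrate integral + product
integral)`. Noiseless progress curves solve the integrated
Michaelis–Menten relation `Km·ln(S0/S) + (S0−S) = kcat·E_active·t` for
S(t); the left side is strictly decreasing in S, so Brent's method on
(0, S0] converges with relative tolerance 1e-10·S0. Cosubstrate (2OG,
Fe(II), ascorbate) depletion and enzyme inactivation are not modeled, so
only short-incubation conversions (minutes) are quantitative; multi-hour
plateaus are outside the model.

Initial rates are the least-squares slope of product concentration vs time
over the points with conversion ≤ 15 %, forced through the first point
(≥3 points required). The 15 % window keeps curvature bias below typical
replicate noise while retaining enough points to average over it.

The Michaelis–Menten fit is Levenberg–Marquardt nonlinear least squares of
`v = vmax·S/(Km+S)` (via lmfit), started from vmax₀ = 1.5× the largest
observed rate and Km₀ = the substrate concentration nearest half-maximal
rate, run to a relative tolerance of 1e-10; negative parameter estimates
are flagged invalid rather than returned.

Derived quantities: `kcat = vmax/(E_total·f_active)` with the enzyme
preparation's active fraction from active-site titration (0.951 ± 0.143
for the reference preparation), and `kcat/Km` in mM⁻¹s⁻¹ (factor 1000 over
µM units). SEs propagate in quadrature over the vmax/Km SEs and the
active-fraction SD — a documented convention, since no propagation method
is standard for this assay. Human-facing reports round kcat to 2 decimals
and Km and efficiency to 2 significant figures, with the efficiency
computed from the *rounded* kcat to mirror the published-table convention;
raw values are always retained in the JSON. Note the hFX row of that table
(efficiency printed 160) is only reproducible pre-rounding (0.20/1.3 µM →
154); the self-consistent hHMCN1 and hLYPD6B rows are the reference cases.

## Synthetic data

Generators emit the exact formats the pipeline consumes plus a truth table
and a JSON manifest; all randomness flows from one integer seed and
regeneration is byte-identical.

- **Proteome**: uniform-composition background sequences (default 20
  proteins of 150–400 residues) with non-overlapping 12-residue planted
  slots: 5 legacy windows, 5 revised-only windows (ring closed, no C two
  residues after C4), 5 near-misses (acceptor Glu or aromatic Trp).
  Uniform composition makes accidental-motif statistics analytically
  checkable; accidental background sites are detected by scanning and
  reported in the manifest, not suppressed.
- **MS/MS**: charge-1 b/y ladders of random 8–16-mer peptides with one
  hydroxylation at a random position, Gaussian ppm jitter on m/z and
  Bernoulli peak dropout. No isotope envelopes, retention time or chimeric
  spectra.
- **LFQ pairs**: lognormal total abundance split exactly by the true
  occupancy, each channel multiplied by unit-mean lognormal noise with the
  requested CV.
- **Progress curves**: the noiseless integrated-MM solution plus additive
  Gaussian noise on % conversion, clipped to [0, 100].

These emulate the statistical structure each stage assumes, not real
acquisitions — passing tests demonstrate correctness of the algorithms
under the stated noise models, not performance on real proteomic data
(no FDR control, co-elution, or missing-value structure is simulated).

## Problem sizes

The analysis drivers and test suite use 20-protein proteomes, 100–500
spectra, 200 LFQ pairs, 6-concentration rate grids and 100-replicate noise
studies — sizes at which every stage's statistical checks (oracle
equivalence on 1,000 random sequences, localization soundness under 30 %
dropout, median-Km recovery at 5 % noise) are stable under reseeding while
the whole suite runs in minutes on one CPU.
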
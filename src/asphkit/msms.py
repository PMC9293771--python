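"""Modification-aware fragment masses, peak matching, hydroxylation-site
localization and label-free site-occupancy estimation.

A hydroxylation adds one oxygen to the peptide (monoisotopic +15.994915 Da,
the "~16 Da" shift seen in annotated MS/MS spectra).  Fragment b/y ions that
span the modified residue carry the shift; ions that do not are unmoved, so
the boundary between shifted and unshifted ions in the two series brackets
the modified residue.  Site occupancy is estimated from the intensities of
the hydroxylated and unmodified (base) forms of the same peptide, and is
defined only when the base peptide was detected.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

#: monoisotopic mass shift of hydroxylation (one oxygen), Da
HYDROXYLATION_DELTA = 15.994915
#: monoisotopic proton mass, Da
PROTON = 1.007276466812
#: monoisotopic mass of water, Da
WATER = _pmass.calculate_mass(formula="H2O")

#: monoisotopic residue (amino-acid minus water) masses, Da
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

#: fixed intact-mass offset of chloroacetyl/Cys thioether macrocyclization
#: (ring closure expels HCl), Da.  Cyclic assay peptides are handled at
#: intact-mass level only; their fragments are not predicted.
THIOETHER_CYCLIZATION_DELTA = -(
    _pmass.calculate_mass(formula="H") + _pmass.calculate_mass(formula="Cl")
)


class OccupancyUndefinedError(ValueError):
    """Both intensities are zero: the occupancy ratio is undefined."""


class BasePeptideNotDetected(ValueError):
    """Occupancy is only estimable when the unmodified base peptide was seen."""


class LocalizationError(ValueError):
    """Contradictory shifted/unshifted fragment evidence."""


@dataclasses.dataclass(frozen=True)
class Modification:
    position: int  # 1-based residue index within the peptide
    mass_delta: float = HYDROXYLATION_DELTA


@dataclasses.dataclass(frozen=True)
class Peptide:
    sequence: str
    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        unknown = set(self.sequence) - set(RESIDUE_MASS)
        if unknown:
            raise ValueError(f"unknown residue(s): {sorted(unknown)}")
        positions = [m.position for m in self.modifications]
        if any(p < 1 or p > len(self.sequence) for p in positions):
            raise ValueError("modification position outside peptide")
        if len(positions) != len(set(positions)):
            raise ValueError("more than one modification at a position")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" | "y"
    index: int  # 1..n-1
    charge: int
    mz: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}^{self.charge}+"


@dataclasses.dataclass(frozen=True)
class PeakMatch:
    ion: FragmentIon
    observed_mz: float
    ppm_error: float


@dataclasses.dataclass(frozen=True)
class SpectrumMatch:
    peptide: Peptide | None
    matched: tuple[PeakMatch, ...]
    unmatched_theoretical: tuple[FragmentIon, ...]


@dataclasses.dataclass(frozen=True)
class OccupancyEstimate:
    site: tuple[str, int]  # (accession, position)
    intensity_hydroxylated: float
    intensity_base: float

    @property
    def percent(self) -> float:
        return 100.0 * self.intensity_hydroxylated / (
            self.intensity_hydroxylated + self.intensity_base
        )


def monoisotopic_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    mass = WATER + sum(RESIDUE_MASS[aa] for aa in peptide.sequence)
    mass += sum(m.mass_delta for m in peptide.modifications)
    return mass


def theoretical_by_ions(peptide: Peptide, max_charge: int = 1) -> list[FragmentIon]:
    """All b_i / y_i ions (i = 1..n-1) at charges 1..max_charge.

    A fragment's mass includes the deltas of the modifications it spans:
    b_i covers residues 1..i, y_i covers residues n-i+1..n.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    delta_at = {m.position: m.mass_delta for m in peptide.modifications}

    # prefix[i] = sum of residue masses 1..i including spanned deltas
    prefix = [0.0]
    for i, aa in enumerate(peptide.sequence, start=1):
        prefix.append(prefix[-1] + RESIDUE_MASS[aa] + delta_at.get(i, 0.0))
    total = prefix[n]

    ions = []
    for i in range(1, n):
        b_neutral = prefix[i]  # residue sum of the N-terminal fragment
        y_neutral = total - prefix[i] + WATER
        for z in range(1, max_charge + 1):
            ions.append(FragmentIon("b", i, z, (b_neutral + z * PROTON) / z))
            ions.append(FragmentIon("y", n - i, z, (y_neutral + z * PROTON) / z))
    return sorted(ions, key=lambda f: (f.series, f.index, f.charge))


def match_peaks(
    peaks: Sequence[tuple[float, float]],
    ions: Sequence[FragmentIon],
    tol_ppm: float = 10.0,
    peptide: Peptide | None = None,
) -> SpectrumMatch:
    """Assign each theoretical ion to its nearest peak within ``tol_ppm``.

    One peak satisfies at most one ion; contested peaks go to the ion with the
    smallest absolute ppm error, ties broken toward the lower series index.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    candidates = []  # (|ppm|, series index, ion order, ion, peak idx, mz, ppm)
    for order, ion in enumerate(ions):
        for j, (mz, _intensity) in enumerate(peaks):
            ppm = (mz - ion.mz) / ion.mz * 1e6
            if abs(ppm) <= tol_ppm:
                candidates.append((abs(ppm), ion.index, order, ion, j, mz, ppm))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_peaks: set[int] = set()
    matched_ions: set[int] = set()
    matches = []
    for _appm, _idx, order, ion, j, mz, ppm in candidates:
        if j in used_peaks or order in matched_ions:
            continue
        used_peaks.add(j)
        matched_ions.add(order)
        matches.append(PeakMatch(ion, mz, ppm))
    unmatched = tuple(
        ion for order, ion in enumerate(ions) if order not in matched_ions
    )
    return SpectrumMatch(peptide, tuple(matches), unmatched)


def localize_shift(
    match_unshifted: SpectrumMatch,
    match_shifted: SpectrumMatch,
    delta: float = HYDROXYLATION_DELTA,
) -> tuple[int, int]:
    """Smallest residue interval consistent with which ions carry the shift.

    ``match_unshifted`` holds the observed peaks matched against the
    unmodified theoretical ladder; ``match_shifted`` against the same ladder
    offset by ``delta`` (each ion treated as spanning the modification).  An
    ion matched in the shifted ladder must span the site; one matched
    unshifted must not:

    * b_i shifted   -> site <= i;  b_i unshifted -> site >= i+1
    * y_i shifted   -> site >= n-i+1;  y_i unshifted -> site <= n-i

    Returns the (lo, hi) 1-based inclusive interval; raises
    :class:`LocalizationError` on contradictory evidence (an ion observed both
    shifted and unshifted, or an empty interval).
    """
    if match_unshifted.peptide is None or match_shifted.peptide is None:
        raise ValueError("localization requires the base peptide on both matches")
    if match_unshifted.peptide.sequence != match_shifted.peptide.sequence:
        raise ValueError("matches refer to different base sequences")
    n = len(match_unshifted.peptide)

    unshifted = {(m.ion.series, m.ion.index, m.ion.charge) for m in match_unshifted.matched}
    shifted = {(m.ion.series, m.ion.index, m.ion.charge) for m in match_shifted.matched}
    both = unshifted & shifted
    if both:
        raise LocalizationError(
            f"ion(s) observed both shifted and unshifted: {sorted(both)}"
        )

    lo, hi = 1, n
    for series, index, _z in unshifted:
        if series == "b":
            lo = max(lo, index + 1)
        else:
            hi = min(hi, n - index)
    for series, index, _z in shifted:
        if series == "b":
            hi = min(hi, index)
        else:
            lo = max(lo, n - index + 1)
    if lo > hi:
        raise LocalizationError(
            f"contradictory shift pattern: empty interval [{lo}, {hi}]"
        )
    return lo, hi


def localize_from_spectrum(
    sequence: str,
    peaks: Sequence[tuple[float, float]],
    tol_ppm: float = 10.0,
    max_charge: int = 1,
    delta: float = HYDROXYLATION_DELTA,
) -> tuple[tuple[int, int], int]:
    """Convenience wrapper: match a spectrum of a singly hydroxylated peptide
    against the unshifted and shifted theoretical ladders and localize.

    Returns ``((lo, hi), n_supporting_ions)``.
    """
    base = Peptide(sequence)
    ions = theoretical_by_ions(base, max_charge)
    shifted_ions = [
        FragmentIon(f.series, f.index, f.charge, f.mz + delta / f.charge)
        for f in ions
    ]

    # a peak explainable by ions of BOTH ladders is shift-ambiguous (exact
    # residue degeneracies exist, e.g. P+H2O = V+O, A+O = S, F+O = Y) and
    # cannot support any constraint — exclude it before matching
    def _explained(mz: float, ladder: Sequence[FragmentIon]) -> bool:
        return any(abs((mz - f.mz) / f.mz) * 1e6 <= tol_ppm for f in ladder)

    usable = [
        (mz, inten) for mz, inten in peaks
        if not (_explained(mz, ions) and _explained(mz, shifted_ions))
    ]

    m_plain = match_peaks(usable, ions, tol_ppm, peptide=base)
    m_shift = match_peaks(usable, shifted_ions, tol_ppm, peptide=base)

    # an ion matched in both ladders is an m/z coincidence (exact residue
    # degeneracies exist: V+O = P+H2O, A+O = S, F+O = Y); such an ion cannot
    # be assigned a shift state and contributes no constraint
    plain_by_key = {(m.ion.series, m.ion.index, m.ion.charge): m
                    for m in m_plain.matched}
    shift_by_key = {(m.ion.series, m.ion.index, m.ion.charge): m
                    for m in m_shift.matched}
    for key in set(plain_by_key) & set(shift_by_key):
        del plain_by_key[key], shift_by_key[key]
    m_plain = SpectrumMatch(base, tuple(plain_by_key.values()), m_plain.unmatched_theoretical)
    m_shift = SpectrumMatch(base, tuple(shift_by_key.values()), m_shift.unmatched_theoretical)

    interval = localize_shift(m_plain, m_shift, delta)
    return interval, len(m_plain.matched) + len(m_shift.matched)


def estimate_occupancy(
    intensity_hydroxylated: float,
    intensity_base: float | None,
    site: tuple[str, int] = ("", 0),
) -> OccupancyEstimate:
    """Site occupancy as 100 * Ih / (Ih + Ib).

    Follows the label-free quantitation convention that occupancy is computed
    only for sites where the unmodified base peptide was also detected: a
    missing base intensity raises :class:`BasePeptideNotDetected` (Ib = 0 with
    a detected base peptide is legitimate and yields 100%).
    """
    if intensity_base is None:
        raise BasePeptideNotDetected(f"site {site}: base peptide not detected")
    if intensity_hydroxylated < 0 or intensity_base < 0:
        raise ValueError("intensities must be >= 0")
    if intensity_hydroxylated == 0 and intensity_base == 0:
        raise OccupancyUndefinedError(f"site {site}: both intensities zero")
    return OccupancyEstimate(site, intensity_hydroxylated, intensity_base)


def occupancy_table(rows: Iterable[dict]) -> "pd.DataFrame":
    """Occupancy report from records with keys site, intensity_hydroxylated,
    intensity_base (None/NaN base -> flagged not estimable)."""
    import math

    import pandas as pd

    out = []
    for r in rows:
        ib = r.get("intensity_base")
        site = r["site"]
        if ib is None or (isinstance(ib, float) and math.isnan(ib)):
            out.append({"site": site, "percent": float("nan"),
                        "status": "base_not_detected"})
            continue
        try:
            est = estimate_occupancy(float(r["intensity_hydroxylated"]), float(ib),
                                     site=(str(site), 0))
            out.append({"site": site, "percent": est.percent, "status": "ok"})
        except OccupancyUndefinedError:
            out.append({"site": site, "percent": float("nan"),
                        "status": "undefined"})
    return pd.DataFrame(out, columns=["site", "percent", "status"])
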
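"""Theoretical fragment generation and greedy stub/backbone spectrum annotation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    H_MASS,
    PROTON_MASS,
    WATER,
    CrosslinkerDefinition,
    ElementalComposition,
    Peptide,
    peptide_mass,
)
from .spectra import Spectrum

__all__ = [
    "TheoreticalFragment",
    "PeakAnnotation",
    "AnnotatedSpectrum",
    "backbone_fragments",
    "stub_fragments",
    "annotate_spectrum",
    "stub_backbone_sums",
    "cleavage_efficiency",
]

BACKBONE_SERIES = ("a", "b", "y", "c", "x", "z")

_CO = ElementalComposition({"C": 1, "O": 1}).mass
_NH3 = ElementalComposition({"N": 1, "H": 3}).mass
_H2 = 2 * H_MASS
_WATER = WATER.mass


@dataclass(frozen=True)
class TheoreticalFragment:
    """A theoretical backbone or stub fragment of one peptide of a CSM.

    ``series`` is one of a/b/y/c/x/z or "stub"; ``index`` is the 1-based
    cleavage position counted from the relevant terminus for backbone ions,
    or the stub label for stub fragments.
    """

    series: str
    index: int | str
    peptide_id: str
    charge: int
    mz: float
    shift: int = 0


@dataclass(frozen=True)
class PeakAnnotation:
    fragment: TheoreticalFragment
    ppm_error: float


@dataclass(frozen=True)
class AnnotatedSpectrum:
    """A spectrum plus at most one annotation per peak (one peak per fragment)."""

    spectrum: Spectrum
    annotations: tuple[PeakAnnotation | None, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.annotations) != len(self.spectrum):
            raise ValueError("annotations must parallel the peak list")

    @property
    def n_annotated(self) -> int:
        return sum(1 for a in self.annotations if a is not None)


def _series_mz(series: str, prefix_mass: float, charge: int) -> float:
    """m/z for a backbone ion given the summed residue masses of its fragment."""
    if series == "b":
        neutral = prefix_mass
    elif series == "a":
        neutral = prefix_mass - _CO
    elif series == "c":
        neutral = prefix_mass + _NH3
    elif series == "y":
        neutral = prefix_mass + _WATER
    elif series == "z":
        # z-dot convention: z+1 radical (y - NH3 + H)
        neutral = prefix_mass + _WATER - _NH3 + H_MASS
    elif series == "x":
        neutral = prefix_mass + _WATER + _CO - _H2
    else:
        raise ValueError(f"unknown ion series {series!r}")
    return (neutral + charge * PROTON_MASS) / charge


def backbone_fragments(
    peptide: Peptide,
    series: Iterable[str] = ("a", "b", "y"),
    charges: Sequence[int] = (1,),
    peptide_id: str = "alpha",
    link_stub_mass: float | None = None,
) -> list[TheoreticalFragment]:
    """All backbone fragments of one peptide for the requested series/charges.

    When ``link_stub_mass`` is given and the peptide has a link site,
    fragments spanning the link site carry that stub mass (the residual
    crosslinker remnant); by default fragments are computed for the bare
    peptide.
    """
    series = tuple(series)
    bad = set(series) - set(BACKBONE_SERIES)
    if bad:
        raise ValueError(f"unknown ion series: {sorted(bad)}")
    residues = peptide.residue_masses()
    n = len(residues)
    prefix = np.cumsum(residues)
    total = prefix[-1]
    link = peptide.link_site
    out: list[TheoreticalFragment] = []
    for s in series:
        n_term = s in ("a", "b", "c")
        for idx in range(1, n):  # cleavage positions 1..n-1
            frag_sum = prefix[idx - 1] if n_term else total - prefix[n - idx - 1]
            if link_stub_mass is not None and link is not None:
                spans = link <= idx if n_term else link > n - idx
                if spans:
                    frag_sum += link_stub_mass
            for z in charges:
                out.append(
                    TheoreticalFragment(
                        series=s,
                        index=idx,
                        peptide_id=peptide_id,
                        charge=int(z),
                        mz=_series_mz(s, float(frag_sum), int(z)),
                    )
                )
    return out


def stub_fragments(
    peptide: Peptide,
    xl: CrosslinkerDefinition,
    shifts: Iterable[int] | None = None,
    charges: Sequence[int] = (1,),
    peptide_id: str = "alpha",
) -> list[TheoreticalFragment]:
    """Peptide+stub fragments: full cross product of labels x shifts x charges."""
    shifts = tuple(xl.hydrogen_shifts if shifts is None else shifts)
    pep_mass = peptide_mass(peptide)
    out: list[TheoreticalFragment] = []
    for label, comp in xl.stubs.items():
        for shift in shifts:
            neutral = pep_mass + comp.mass + shift * H_MASS
            for z in charges:
                out.append(
                    TheoreticalFragment(
                        series="stub",
                        index=label,
                        peptide_id=peptide_id,
                        charge=int(z),
                        mz=(neutral + z * PROTON_MASS) / z,
                        shift=shift,
                    )
                )
    return out


def annotate_spectrum(
    spectrum: Spectrum,
    csm: tuple[Peptide, Peptide | None, CrosslinkerDefinition],
    series: Iterable[str] = ("a", "b", "y"),
    tol_ppm: float = 10.0,
    charges: Sequence[int] = (1,),
    shifts: Iterable[int] | None = None,
) -> AnnotatedSpectrum:
    """Greedy one-to-one annotation of peaks with theoretical fragments.

    Candidate (peak, fragment) pairs within ``tol_ppm`` are sorted by
    absolute ppm error (ties: lower-m/z peak first) and assigned greedily so
    that each peak carries at most one annotation and each fragment is used
    at most once.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    alpha, beta, xl = csm
    fragments: list[TheoreticalFragment] = []
    for pep, pid in ((alpha, "alpha"), (beta, "beta")):
        if pep is None:
            continue
        fragments.extend(backbone_fragments(pep, series, charges, peptide_id=pid))
        fragments.extend(stub_fragments(pep, xl, shifts, charges, peptide_id=pid))

    mz = spectrum.mz
    candidates: list[tuple[float, int, int]] = []  # (|ppm|, peak_idx, frag_idx)
    t = tol_ppm * 1e-6
    for f_idx, frag in enumerate(fragments):
        lo = int(np.searchsorted(mz, frag.mz * (1 - t), side="left"))
        hi = int(np.searchsorted(mz, frag.mz * (1 + t), side="right"))
        for p_idx in range(lo, hi):
            ppm = (mz[p_idx] - frag.mz) / frag.mz * 1e6
            candidates.append((abs(ppm), p_idx, f_idx))
    candidates.sort()

    annotations: list[PeakAnnotation | None] = [None] * len(spectrum)
    used_frag = [False] * len(fragments)
    for _, p_idx, f_idx in candidates:
        if annotations[p_idx] is not None or used_frag[f_idx]:
            continue
        frag = fragments[f_idx]
        annotations[p_idx] = PeakAnnotation(
            fragment=frag, ppm_error=float((mz[p_idx] - frag.mz) / frag.mz * 1e6)
        )
        used_frag[f_idx] = True
    return AnnotatedSpectrum(spectrum=spectrum, annotations=tuple(annotations))


def stub_backbone_sums(annotated: AnnotatedSpectrum) -> tuple[float, float]:
    """Summed intensity of stub-annotated vs backbone-annotated peaks."""
    stub_sum = 0.0
    backbone_sum = 0.0
    for peak_intensity, ann in zip(annotated.spectrum.intensity, annotated.annotations):
        if ann is None:
            continue
        if ann.fragment.series == "stub":
            stub_sum += float(peak_intensity)
        else:
            backbone_sum += float(peak_intensity)
    return stub_sum, backbone_sum


def cleavage_efficiency(
    spectrum: Spectrum,
    precursor_window: float = 2.0,
    include_charge_reduced: bool = True,
) -> float:
    """Fraction of total ion current not remaining in surviving precursor species.

    Defined as 1 - (summed intensity within ``precursor_window`` of the
    precursor m/z, optionally including its charge-reduced species, divided
    by total spectrum intensity). An empty spectrum yields 0.0.
    """
    total = float(spectrum.intensity.sum()) if len(spectrum) else 0.0
    if total == 0.0:
        return 0.0
    targets = [spectrum.precursor_mz]
    z = spectrum.precursor_charge
    if include_charge_reduced and z is not None and z > 1:
        neutral = (spectrum.precursor_mz - PROTON_MASS) * z
        for z_red in range(1, z):
            targets.append((neutral + z_red * PROTON_MASS) / z_red)
    surviving = np.zeros(len(spectrum), dtype=bool)
    for target in targets:
        surviving |= np.abs(spectrum.mz - target) <= precursor_window
    return float(1.0 - spectrum.intensity[surviving].sum() / total)
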
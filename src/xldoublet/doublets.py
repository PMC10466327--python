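"""Signature stub-doublet detection and MS3 precursor trigger selection.

A doublet is a pair of peaks in one MS2 spectrum whose neutral mass
difference (at an assumed fragment charge) matches one of the crosslinker's
delta-mass variants within a ppm tolerance. Detected doublets are deduped
per m/z window and turned into an ordered MS3 trigger list, emulating the
acquisition logic post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np

from .chem import DeltaMassSet
from .spectra import RankedSpectrum, Spectrum, rank_peaks

__all__ = [
    "DoubletMatch",
    "Trigger",
    "TriggerList",
    "TriggerOutcome",
    "find_doublets",
    "trigger_mz",
    "dedupe_window",
    "select_ms3_precursors",
    "evaluate_triggers",
]


@dataclass(frozen=True)
class DoubletMatch:
    """One detected stub-pair: two peak indices, assumed charge and variant hit."""

    light_peak_index: int
    heavy_peak_index: int
    assumed_charge: int
    matched_variant: float
    ppm_error: float
    summed_intensity: float
    best_rank: int


@dataclass(frozen=True)
class Trigger:
    """An MS3 precursor selection derived from one doublet match."""

    precursor_mz: float
    charge: int
    source_match: DoubletMatch


@dataclass(frozen=True)
class TriggerList:
    """Ordered MS3 trigger selections (descending source-doublet intensity)."""

    triggers: tuple[Trigger, ...]

    def __len__(self) -> int:
        return len(self.triggers)

    def __iter__(self):
        return iter(self.triggers)


class _HasTrueStubMz(Protocol):
    true_stub_mz: dict[str, tuple[float, ...]]


@dataclass(frozen=True)
class TriggerOutcome:
    """Per-spectrum trigger evaluation against synthetic ground truth."""

    n_triggers: int
    alpha_triggered: bool
    beta_triggered: bool
    n_false_triggers: int


def _as_ranked(spectrum: Spectrum) -> RankedSpectrum:
    if isinstance(spectrum, RankedSpectrum):
        return spectrum
    return rank_peaks(spectrum)


def find_doublets(
    spectrum: Spectrum,
    deltas: DeltaMassSet,
    tol_ppm: float = 5.0,
    charges: Sequence[int] = (1,),
    max_rank: int | None = None,
) -> list[DoubletMatch]:
    """Find all peak pairs whose mass difference matches a delta variant.

    A pair (i, j) with mz_j > mz_i matches at assumed charge z when
    ``|(mz_j - mz_i) * z - delta| <= tol_ppm * 1e-6 * mz_j * z`` for some
    variant delta; both peaks are assumed to carry the same charge z. Each
    (i, j, z) is reported once, with the closest-matching variant. When
    ``max_rank`` is set, at least one peak of the pair must have an
    intensity rank <= max_rank.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not charges:
        raise ValueError("charges must be non-empty")
    ranked = _as_ranked(spectrum) if len(spectrum) else None
    mz = spectrum.mz
    if np.any(np.diff(mz) < 0):
        raise ValueError("spectrum peaks must be sorted by m/z")
    n = mz.size
    if n < 2:
        return []
    assert ranked is not None
    t = tol_ppm * 1e-6
    variants = np.asarray(deltas.variants, float)
    matches: list[DoubletMatch] = []
    for z in charges:
        if z <= 0:
            raise ValueError("assumed charges must be positive")
        seen: set[tuple[int, int]] = set()
        for i in range(n - 1):
            for delta in variants:
                center = mz[i] + delta / z
                lo = int(np.searchsorted(mz, center / (1.0 + t), side="left"))
                hi = int(np.searchsorted(mz, center / (1.0 - t), side="right"))
                for j in range(max(lo, i + 1), hi):
                    if (i, j) in seen:
                        continue
                    obs = (mz[j] - mz[i]) * z
                    best = variants[int(np.argmin(np.abs(variants - obs)))]
                    if abs(obs - best) <= t * mz[j] * z:
                        seen.add((i, j))
                        rank_best = int(min(ranked.ranks[i], ranked.ranks[j]))
                        if max_rank is not None and rank_best > max_rank:
                            continue
                        matches.append(
                            DoubletMatch(
                                light_peak_index=i,
                                heavy_peak_index=j,
                                assumed_charge=int(z),
                                matched_variant=float(best),
                                ppm_error=float((obs - best) / (mz[j] * z) * 1e6),
                                summed_intensity=float(
                                    spectrum.intensity[i] + spectrum.intensity[j]
                                ),
                                best_rank=rank_best,
                            )
                        )
    matches.sort(
        key=lambda m: (m.light_peak_index, m.heavy_peak_index, m.assumed_charge)
    )
    return matches


def trigger_mz(match: DoubletMatch, spectrum: Spectrum, species: str = "heavy") -> float:
    """The m/z that would be isolated for MS3 for this match."""
    if species == "heavy":
        return float(spectrum.mz[match.heavy_peak_index])
    if species == "light":
        return float(spectrum.mz[match.light_peak_index])
    raise ValueError(f"species must be 'heavy' or 'light', got {species!r}")


def _intensity_order(matches, spectrum, species):
    return sorted(
        matches,
        key=lambda m: (
            -m.summed_intensity,
            trigger_mz(m, spectrum, species),
            m.light_peak_index,
            m.assumed_charge,
        ),
    )


def dedupe_window(
    matches: Iterable[DoubletMatch],
    spectrum: Spectrum,
    window_mz: float = 1.5,
    trigger_species: str = "heavy",
) -> list[DoubletMatch]:
    """Greedy per-window dedup of doublet triggers.

    Matches are processed in descending summed intensity (ties: lower
    trigger m/z); a match survives only if its trigger m/z is farther than
    ``window_mz`` from every previously kept match's trigger m/z. This
    emulates the exclusion-list behaviour that prevents several MS3
    triggers landing on the same peptide doublet.
    """
    if window_mz < 0:
        raise ValueError("window_mz must be >= 0")
    kept: list[DoubletMatch] = []
    kept_mz: list[float] = []
    for match in _intensity_order(matches, spectrum, trigger_species):
        tmz = trigger_mz(match, spectrum, trigger_species)
        if all(abs(tmz - prev) > window_mz for prev in kept_mz):
            kept.append(match)
            kept_mz.append(tmz)
    return kept


def select_ms3_precursors(
    matches: Iterable[DoubletMatch],
    spectrum: Spectrum,
    max_triggers: int = 5,
    window_mz: float | None = 1.5,
    trigger_species: str = "heavy",
) -> TriggerList:
    """Turn doublet matches into an ordered, deduped, capped MS3 trigger list.

    The trigger precursor is the heavier doublet peak by default (it retains
    more of the linker), at the match's assumed charge.
    """
    if max_triggers < 1:
        raise ValueError("max_triggers must be >= 1")
    if window_mz:
        surviving = dedupe_window(matches, spectrum, window_mz, trigger_species)
    else:
        surviving = _intensity_order(matches, spectrum, trigger_species)
    triggers = tuple(
        Trigger(
            precursor_mz=trigger_mz(m, spectrum, trigger_species),
            charge=m.assumed_charge,
            source_match=m,
        )
        for m in surviving[:max_triggers]
    )
    return TriggerList(triggers=triggers)


def evaluate_triggers(
    triggers: TriggerList, truth: _HasTrueStubMz, tol_ppm: float = 5.0
) -> TriggerOutcome:
    """Score a trigger list against ground-truth stub m/z positions.

    A trigger counts for a peptide if its precursor m/z lies within
    ``tol_ppm`` of any of that peptide's true stub-fragment m/z; triggers
    matching neither peptide are false triggers.
    """
    alpha_mz = truth.true_stub_mz.get("alpha", ())
    beta_mz = truth.true_stub_mz.get("beta", ())
    t = tol_ppm * 1e-6

    def hits(target_list, mz):
        return any(abs(mz - target) <= t * target for target in target_list)

    alpha_hit = beta_hit = False
    n_false = 0
    for trig in triggers:
        a = hits(alpha_mz, trig.precursor_mz)
        b = hits(beta_mz, trig.precursor_mz)
        alpha_hit = alpha_hit or a
        beta_hit = beta_hit or b
        if not (a or b):
            n_false += 1
    return TriggerOutcome(
        n_triggers=len(triggers),
        alpha_triggered=alpha_hit,
        beta_triggered=beta_hit,
        n_false_triggers=n_false,
    )
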
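"""End-to-end per-spectrum processing: preprocessing, doublet detection,
MS3-trigger selection and annotation, folded into a :class:`CsmRecord`."""

from __future__ import annotations

from typing import Iterable, Sequence

from .annotate import annotate_spectrum, stub_backbone_sums
from .chem import CrosslinkerDefinition, doublet_delta_set
from .doublets import (
    DoubletMatch,
    evaluate_triggers,
    find_doublets,
    select_ms3_precursors,
)
from .metrics import CsmRecord
from .spectra import Spectrum, rank_peaks, remove_precursor
from .synthetic import SyntheticTruth

__all__ = ["assumed_charges", "attribute_matches", "process_spectrum", "process_dataset"]


def assumed_charges(precursor_charge: int | None) -> tuple[int, ...]:
    """Default assumed fragment charges: 1..(precursor charge - 1)."""
    if precursor_charge is None or precursor_charge <= 2:
        return (1,)
    return tuple(range(1, precursor_charge))


def attribute_matches(
    matches: Iterable[DoubletMatch],
    spectrum: Spectrum,
    truth: SyntheticTruth,
    tol_ppm: float = 5.0,
) -> dict[str, list[DoubletMatch]]:
    """Assign each detected doublet to a peptide when both of its peaks sit on
    that peptide's true stub positions."""
    t = tol_ppm * 1e-6
    out: dict[str, list[DoubletMatch]] = {"alpha": [], "beta": []}
    for match in matches:
        light = float(spectrum.mz[match.light_peak_index])
        heavy = float(spectrum.mz[match.heavy_peak_index])
        for pid, targets in truth.true_stub_mz.items():
            if any(abs(light - x) <= t * x for x in targets) and any(
                abs(heavy - x) <= t * x for x in targets
            ):
                out[pid].append(match)
    return out


def process_spectrum(
    spectrum: Spectrum,
    truth: SyntheticTruth,
    xl: CrosslinkerDefinition,
    tol_ppm: float = 5.0,
    shifts: Sequence[int] | None = None,
    window_mz: float | None = 1.5,
    max_triggers: int = 5,
    max_rank: int | None = None,
    precursor_window: float = 2.0,
    annotation_tol_ppm: float = 10.0,
    annotation_series: Sequence[str] = ("a", "b", "y"),
    eval_tol_ppm: float = 5.0,
) -> CsmRecord:
    """Run the full detection + trigger + annotation pipeline on one spectrum."""
    cleaned = remove_precursor(
        spectrum, precursor_window, include_charge_reduced=False
    )
    deltas = doublet_delta_set(xl, shifts)
    charges = assumed_charges(spectrum.precursor_charge)

    if len(cleaned) >= 2:
        ranked = rank_peaks(cleaned)
        matches = find_doublets(ranked, deltas, tol_ppm, charges, max_rank)
        triggers = select_ms3_precursors(matches, ranked, max_triggers, window_mz)
    else:
        ranked = cleaned
        matches = []
        triggers = select_ms3_precursors([], cleaned, max_triggers, window_mz)
    outcome = evaluate_triggers(triggers, truth, eval_tol_ppm)

    by_peptide = attribute_matches(matches, cleaned, truth, eval_tol_ppm)
    best_rank = {
        pid: (min(m.best_rank for m in ms) if ms else None)
        for pid, ms in by_peptide.items()
    }

    annotated = annotate_spectrum(
        cleaned,
        (truth.alpha, truth.beta, xl),
        series=annotation_series,
        tol_ppm=annotation_tol_ppm,
        charges=(1, 2),
    )
    stub_sum, backbone_sum = stub_backbone_sums(annotated)

    return CsmRecord(
        scan_id=spectrum.scan_id,
        stub_sum=stub_sum,
        backbone_sum=backbone_sum,
        doublet_alpha_found=bool(by_peptide["alpha"]),
        doublet_beta_found=bool(by_peptide["beta"]),
        best_rank_alpha=best_rank["alpha"],
        best_rank_beta=best_rank["beta"],
        n_ms3_triggered=outcome.n_triggers,
        alpha_triggered=outcome.alpha_triggered,
        beta_triggered=outcome.beta_triggered,
        class_label=truth.class_label,
    )


def process_dataset(
    spectra: Sequence[Spectrum],
    truths: Sequence[SyntheticTruth],
    xl: CrosslinkerDefinition,
    **kwargs,
) -> list[CsmRecord]:
    return [process_spectrum(s, t, xl, **kwargs) for s, t in zip(spectra, truths)]
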
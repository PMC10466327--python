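"""Seeded synthetic MS2 generator with per-peak ground truth.

Produces crosslinked, linear, and crosslinker-modified linear peptide
spectra whose statistical structure (stub/backbone intensity partition,
hydrogen-shift satellites, doublet dropout, chemical noise, ppm jitter) is
configurable, so detection, annotation and the dataset statistics can all
be exercised against known truth.

Idealizations (documented): noise and backbone peaks are rejected when they
would land within a guard tolerance of an existing peak or would form a
spurious doublet relation with one, so the ground truth stays unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import (
    H_MASS,
    PROTON_MASS,
    WATER,
    CrosslinkerDefinition,
    Peptide,
    RESIDUE_MASSES,
    doublet_delta_set,
    load_crosslinker,
    peptide_mass,
    stub_fragment_mz,
)
from .spectra import Spectrum, write_mgf

__all__ = [
    "GeneratorConfig",
    "PeakProvenance",
    "SyntheticTruth",
    "random_peptide",
    "compatible_peptide_pair",
    "generate_csm_spectrum",
    "generate_linear_spectrum",
    "generate_dataset",
]

_RESIDUES = sorted(RESIDUE_MASSES)

#: Guard tolerance (ppm) used when rejecting ambiguous peak placements.
GUARD_PPM = 25.0
#: Minimum m/z separation between the two peptides' stub peaks (Th), so the
#: per-window trigger dedup cannot merge the two peptides' doublets.
MIN_CROSS_STUB_SEPARATION = 4.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-spectrum generator; the seed fixes everything."""

    crosslinker: str = "UCCL"
    n_crosslinked: int = 100
    n_linear: int = 100
    n_xl_modified: int = 0
    peptide_length: tuple[int, int] = (6, 18)
    stub_to_backbone_log_ratio: tuple[float, float] = (np.log(5.3), 0.6)
    hydrogen_shift_probs: dict[int, float] = field(default_factory=lambda: {1: 0.3})
    doublet_dropout_prob: float = 0.0
    n_noise_peaks: int = 20
    noise_intensity: tuple[float, float] = (2.0, 1.0)
    #: sigma (ppm) of a per-spectrum calibration offset applied to all peaks;
    #: this is the error mode that median-mass-error recalibration corrects
    mz_jitter_ppm: float = 0.0
    #: sigma (ppm) of additional independent per-peak jitter (default off)
    mz_peak_jitter_ppm: float = 0.0
    scan_range: tuple[float, float] = (150.0, 1800.0)
    precursor_charges_csm: tuple[int, ...] = (3, 4, 5)
    precursor_charges_linear: tuple[int, ...] = (2, 3)
    stub_charge: int = 1
    backbone_keep_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peptide_length[0] < 5:
            raise ValueError("minimum peptide length is 5")
        if not 0.0 <= self.doublet_dropout_prob <= 1.0:
            raise ValueError("doublet_dropout_prob must be in [0, 1]")
        probs = list(self.hydrogen_shift_probs.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("hydrogen shift probabilities must be in [0, 1]")
        if sum(probs) > 1.0 + 1e-12:
            raise ValueError("hydrogen shift probabilities must sum to <= 1")
        if 0 in self.hydrogen_shift_probs:
            raise ValueError("shift 0 is always generated; only satellites take probs")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def load_xl(self) -> CrosslinkerDefinition:
        return load_crosslinker(self.crosslinker)


@dataclass(frozen=True)
class PeakProvenance:
    """Ground-truth origin of a single generated peak."""

    kind: str  # stub | backbone | noise | precursor
    peptide_id: str | None = None  # alpha | beta
    label: str | None = None  # stub label or series+index, e.g. "y3"
    shift: int = 0
    charge: int = 0
    theoretical_mz: float = 0.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-spectrum ground truth: class, peptides, per-peak provenance."""

    class_label: str  # crosslinked | linear | xl_modified
    alpha: Peptide
    beta: Peptide | None
    provenance: tuple[PeakProvenance, ...]
    true_stub_mz: dict[str, tuple[float, ...]]


def random_peptide(
    length_range: tuple[int, int], rng: np.random.Generator
) -> Peptide:
    """Uniform random peptide with one internal lysine designated as link site."""
    lo, hi = length_range
    if lo < 5:
        raise ValueError("minimum peptide length is 5")
    length = int(rng.integers(lo, hi + 1))
    seq = list(rng.choice(_RESIDUES, size=length))
    site = int(rng.integers(2, length))  # 1-based, strictly internal
    seq[site - 1] = "K"
    return Peptide(sequence="".join(seq), link_site=site)


# --- collision guards --------------------------------------------------------


def _guard_deltas(xl: CrosslinkerDefinition) -> np.ndarray:
    base = doublet_delta_set(xl, [0]).base_delta
    return np.array([base + k * H_MASS for k in range(-3, 4)])


def _conflicts(
    new_mz: float,
    placed: Sequence[float],
    guard_deltas: np.ndarray,
    guard_ppm: float = GUARD_PPM,
    charges: Sequence[int] = (1, 2, 3, 4),
) -> bool:
    """True if a peak at ``new_mz`` would be ambiguous against placed peaks."""
    if not len(placed):
        return False
    p = np.asarray(placed, dtype=float)
    heavier = np.maximum(p, new_mz)
    diff = np.abs(p - new_mz)
    if np.any(diff <= guard_ppm * 1e-6 * heavier):
        return True
    for z in charges:
        tol = guard_ppm * 1e-6 * heavier * z  # (n_placed,)
        gap = np.abs(diff[:, None] * z - guard_deltas[None, :])
        if np.any(gap <= tol[:, None]):
            return True
    return False


def compatible_peptide_pair(
    config: GeneratorConfig,
    xl: CrosslinkerDefinition,
    rng: np.random.Generator,
    max_attempts: int = 200,
) -> tuple[Peptide, Peptide]:
    """Draw a peptide pair whose stub peaks neither overlap nor form
    spurious cross-peptide doublet relations."""
    guard = _guard_deltas(xl)
    labels = xl.doublet_pair
    shifts = [0] + sorted(config.hydrogen_shift_probs)
    for _ in range(max_attempts):
        alpha = random_peptide(config.peptide_length, rng)
        beta = random_peptide(config.peptide_length, rng)
        a_mz = [
            stub_fragment_mz(alpha, xl, lab, s, config.stub_charge)
            for lab in labels
            for s in shifts
        ]
        b_mz = [
            stub_fragment_mz(beta, xl, lab, s, config.stub_charge)
            for lab in labels
            for s in shifts
        ]
        ok = True
        for am in a_mz:
            for bm in b_mz:
                if abs(am - bm) < MIN_CROSS_STUB_SEPARATION:
                    ok = False
                    break
                if _conflicts(am, [bm], guard):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return alpha, beta
    raise RuntimeError("could not draw a compatible peptide pair")


# --- spectrum assembly -------------------------------------------------------


def _lognormal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    return float(np.exp(rng.normal(mu, sigma)))


def _place_stub_peaks(peptide, peptide_id, xl, config, rng):
    """Stub doublet peaks (+ hydrogen-shift satellites) for one peptide.

    Returns (mz_list, provenance_list). Empty if the doublet drops out.
    """
    if rng.random() < config.doublet_dropout_prob:
        return [], []
    mzs, prov = [], []
    z = config.stub_charge
    for label in xl.doublet_pair:
        shifts = [0] + [
            s for s, p in sorted(config.hydrogen_shift_probs.items()) if rng.random() < p
        ]
        for shift in shifts:
            mz = stub_fragment_mz(peptide, xl, label, shift, z)
            mzs.append(mz)
            prov.append(
                PeakProvenance(
                    kind="stub",
                    peptide_id=peptide_id,
                    label=label,
                    shift=shift,
                    charge=z,
                    theoretical_mz=mz,
                )
            )
    return mzs, prov


def _place_backbone_peaks(peptide, peptide_id, config, rng, placed, guard):
    """b/y backbone peaks at 1+ within the scan range, guard-filtered."""
    residues = peptide.residue_masses()
    n = len(residues)
    prefix = np.cumsum(residues)
    total = prefix[-1]
    lo, hi = config.scan_range
    mzs, prov = [], []
    for series in ("b", "y"):
        for idx in range(1, n):
            if series == "b":
                neutral = prefix[idx - 1]
            else:
                neutral = total - prefix[n - idx - 1] + WATER.mass
            mz = neutral + PROTON_MASS
            if not (lo <= mz <= hi):
                continue
            if rng.random() > config.backbone_keep_prob:
                continue
            if _conflicts(mz, placed + mzs, guard):
                continue
            mzs.append(mz)
            prov.append(
                PeakProvenance(
                    kind="backbone",
                    peptide_id=peptide_id,
                    label=f"{series}{idx}",
                    charge=1,
                    theoretical_mz=mz,
                )
            )
    return mzs, prov


def _place_noise_peaks(config, rng, placed, guard):
    lo, hi = config.scan_range
    mzs, prov = [], []
    for _ in range(config.n_noise_peaks):
        for _attempt in range(100):
            mz = float(rng.uniform(lo, hi))
            if not _conflicts(mz, placed + mzs, guard):
                mzs.append(mz)
                prov.append(PeakProvenance(kind="noise", theoretical_mz=mz))
                break
    return mzs, prov


def _assemble(
    config,
    rng,
    stub_mzs,
    stub_prov,
    backbone_mzs,
    backbone_prov,
    precursor_mz,
    precursor_charge,
    scan_id,
    class_label,
    alpha,
    beta,
    guard,
):
    """Draw intensities, add noise + residual precursor, jitter, sort, wrap."""
    # raw log-normal intensities, then rescale the stub group so that
    # log(stub_sum / backbone_sum) equals the drawn partition exactly
    backbone_int = [_lognormal(rng, 4.0, 1.0) for _ in backbone_mzs]
    stub_int = [_lognormal(rng, 4.0, 1.0) for _ in stub_mzs]
    if stub_int and backbone_int:
        mu, sigma = config.stub_to_backbone_log_ratio
        ratio = float(np.exp(rng.normal(mu, sigma)))
        scale = ratio * sum(backbone_int) / sum(stub_int)
        stub_int = [x * scale for x in stub_int]

    noise_mzs, noise_prov = _place_noise_peaks(
        config, rng, list(stub_mzs) + list(backbone_mzs) + [precursor_mz], guard
    )
    noise_int = [
        _lognormal(rng, config.noise_intensity[0], config.noise_intensity[1])
        for _ in noise_mzs
    ]

    all_mz = list(stub_mzs) + list(backbone_mzs) + list(noise_mzs) + [precursor_mz]
    all_int = stub_int + backbone_int + noise_int + [
        _lognormal(rng, 6.0, 0.5)
    ]
    all_prov = (
        list(stub_prov)
        + list(backbone_prov)
        + list(noise_prov)
        + [
            PeakProvenance(
                kind="precursor",
                charge=precursor_charge,
                theoretical_mz=precursor_mz,
            )
        ]
    )

    eps = np.zeros(len(all_mz))
    if config.mz_jitter_ppm > 0:
        eps += float(rng.normal(0.0, config.mz_jitter_ppm))
    if config.mz_peak_jitter_ppm > 0:
        eps += rng.normal(0.0, config.mz_peak_jitter_ppm, size=len(all_mz))
    all_mz = [m * (1.0 + e * 1e-6) for m, e in zip(all_mz, eps)]

    # true stub positions are the observed (jittered) peak m/z: evaluation asks
    # whether a trigger landed on a stub peak of this spectrum
    n_stub = len(stub_mzs)
    observed_stub = list(zip(stub_prov, all_mz[:n_stub]))

    order = np.argsort(all_mz, kind="stable")
    spectrum = Spectrum(
        mz=np.asarray(all_mz)[order],
        intensity=np.asarray(all_int)[order],
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        scan_id=scan_id,
        ms_level=2,
        metadata={"CLASS": class_label},
    )
    true_stub_mz: dict[str, tuple[float, ...]] = {}
    for pid in ("alpha", "beta"):
        mz_list = tuple(m for p, m in observed_stub if p.peptide_id == pid)
        if mz_list:
            true_stub_mz[pid] = mz_list
    truth = SyntheticTruth(
        class_label=class_label,
        alpha=alpha,
        beta=beta,
        provenance=tuple(all_prov[i] for i in order),
        true_stub_mz=true_stub_mz,
    )
    return spectrum, truth


def generate_csm_spectrum(
    alpha: Peptide,
    beta: Peptide,
    xl: CrosslinkerDefinition,
    config: GeneratorConfig,
    rng: np.random.Generator,
    scan_id: str = "CSM_0",
) -> tuple[Spectrum, SyntheticTruth]:
    """One crosslinked-peptide MS2 spectrum with per-peak ground truth."""
    guard = _guard_deltas(xl)
    neutral = peptide_mass(alpha) + peptide_mass(beta) + xl.spacer.mass

    stub_mzs, stub_prov = [], []
    for pep, pid in ((alpha, "alpha"), (beta, "beta")):
        m, p = _place_stub_peaks(pep, pid, xl, config, rng)
        stub_mzs += m
        stub_prov += p

    # pick a precursor charge whose m/z is not on top of a stub peak, so
    # precursor removal cannot delete doublet evidence
    charges = list(config.precursor_charges_csm)
    rng.shuffle(charges)
    prec_z = charges[0]
    for z in charges:
        mz_candidate = (neutral + z * PROTON_MASS) / z
        if all(abs(mz_candidate - s) > 3.0 for s in stub_mzs):
            prec_z = z
            break
    prec_z = int(prec_z)
    prec_mz = (neutral + prec_z * PROTON_MASS) / prec_z

    backbone_mzs, backbone_prov = [], []
    for pep, pid in ((alpha, "alpha"), (beta, "beta")):
        m, p = _place_backbone_peaks(
            pep, pid, config, rng, stub_mzs + backbone_mzs + [prec_mz], guard
        )
        backbone_mzs += m
        backbone_prov += p

    return _assemble(
        config,
        rng,
        stub_mzs,
        stub_prov,
        backbone_mzs,
        backbone_prov,
        prec_mz,
        prec_z,
        scan_id,
        "crosslinked",
        alpha,
        beta,
        guard,
    )


def generate_linear_spectrum(
    peptide: Peptide,
    config: GeneratorConfig,
    rng: np.random.Generator,
    modified: bool = False,
    xl: CrosslinkerDefinition | None = None,
    scan_id: str = "LIN_0",
) -> tuple[Spectrum, SyntheticTruth]:
    """A linear-peptide MS2 spectrum; with ``modified``, a mono-link stub
    doublet is planted (the specificity challenge for MS3 triggering)."""
    xl = xl or config.load_xl()
    guard = _guard_deltas(xl)
    prec_z = int(rng.choice(config.precursor_charges_linear))
    neutral = peptide_mass(peptide)
    if modified:
        neutral += xl.spacer.mass + WATER.mass  # hydrolyzed mono-link
    prec_mz = (neutral + prec_z * PROTON_MASS) / prec_z

    stub_mzs: list[float] = []
    stub_prov: list[PeakProvenance] = []
    if modified:
        stub_mzs, stub_prov = _place_stub_peaks(peptide, "alpha", xl, config, rng)

    backbone_mzs, backbone_prov = _place_backbone_peaks(
        peptide, "alpha", config, rng, stub_mzs + [prec_mz], guard
    )
    return _assemble(
        config,
        rng,
        stub_mzs,
        stub_prov,
        backbone_mzs,
        backbone_prov,
        prec_mz,
        prec_z,
        scan_id,
        "xl_modified" if modified else "linear",
        peptide,
        None,
        guard,
    )


def generate_dataset(
    config: GeneratorConfig, out_prefix: str | None = None
) -> tuple[list[Spectrum], list[SyntheticTruth], pd.DataFrame]:
    """Generate the full mixed dataset; optionally write MGF + truth + CSM tables.

    Output files (when ``out_prefix`` given): ``<prefix>.mgf``,
    ``<prefix>.truth.tsv`` (long per-peak provenance), ``<prefix>.csms.tsv``.
    Fully reproducible from ``config.seed``.
    """
    rng = config.rng()
    xl = config.load_xl()
    spectra: list[Spectrum] = []
    truths: list[SyntheticTruth] = []

    for i in range(config.n_crosslinked):
        alpha, beta = compatible_peptide_pair(config, xl, rng)
        s, t = generate_csm_spectrum(alpha, beta, xl, config, rng, f"CSM_{i:06d}")
        spectra.append(s)
        truths.append(t)
    for i in range(config.n_linear):
        pep = random_peptide(config.peptide_length, rng)
        s, t = generate_linear_spectrum(pep, config, rng, False, xl, f"LIN_{i:06d}")
        spectra.append(s)
        truths.append(t)
    for i in range(config.n_xl_modified):
        pep = random_peptide(config.peptide_length, rng)
        s, t = generate_linear_spectrum(pep, config, rng, True, xl, f"MOD_{i:06d}")
        spectra.append(s)
        truths.append(t)

    csm_rows = []
    for s, t in zip(spectra, truths):
        csm_rows.append(
            {
                "scan_id": s.scan_id,
                "class": t.class_label,
                "peptide_alpha": t.alpha.sequence,
                "link_site_alpha": t.alpha.link_site or "",
                "peptide_beta": t.beta.sequence if t.beta else "",
                "link_site_beta": (t.beta.link_site or "") if t.beta else "",
                "precursor_charge": s.precursor_charge,
            }
        )
    csm_table = pd.DataFrame(
        csm_rows,
        columns=[
            "scan_id",
            "class",
            "peptide_alpha",
            "link_site_alpha",
            "peptide_beta",
            "link_site_beta",
            "precursor_charge",
        ],
    )

    if out_prefix is not None:
        write_mgf(spectra, f"{out_prefix}.mgf")
        truth_rows = []
        for s, t in zip(spectra, truths):
            for idx, (mz, prov) in enumerate(zip(s.mz, t.provenance)):
                truth_rows.append(
                    {
                        "scan_id": s.scan_id,
                        "peak_index": idx,
                        "mz": f"{mz:.6f}",
                        "kind": prov.kind,
                        "peptide_id": prov.peptide_id or "",
                        "label": prov.label or "",
                        "shift": prov.shift,
                        "charge": prov.charge,
                        "theoretical_mz": f"{prov.theoretical_mz:.6f}",
                    }
                )
        pd.DataFrame(truth_rows).to_csv(f"{out_prefix}.truth.tsv", sep="\t", index=False)
        csm_table.to_csv(f"{out_prefix}.csms.tsv", sep="\t", index=False)

    return spectra, truths, csm_table
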
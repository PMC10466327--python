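"""Centroided peak-list model, MGF reading/writing, and spectrum preprocessing.

Spectra are immutable: every operation returns a new :class:`Spectrum`.
Peaks are stored as parallel numpy arrays sorted by m/z.
"""

from __future__ import annotations

import gzip
import io
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import PROTON_MASS

__all__ = [
    "Spectrum",
    "RankedSpectrum",
    "MgfParseError",
    "read_mgf",
    "write_mgf",
    "remove_precursor",
    "rank_peaks",
    "median_ppm_error",
    "recalibrate",
]


class MgfParseError(ValueError):
    """Malformed MGF input; message names the offending line."""


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2/MS3 peak list with precursor metadata.

    Invariants enforced on construction: peaks sorted ascending by m/z,
    all m/z strictly positive, intensities finite and non-negative.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float
    precursor_charge: int | None = None
    scan_id: str = ""
    ms_level: int = 2
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size:
            if not np.all(np.isfinite(mz)) or not np.all(np.isfinite(inten)):
                raise ValueError("peaks must be finite")
            if np.any(mz <= 0):
                raise ValueError("all m/z values must be positive")
            if np.any(inten < 0):
                raise ValueError("intensities must be non-negative")
            order = np.argsort(mz, kind="stable")
            mz = mz[order]
            inten = inten[order]
        mz.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if self.precursor_charge is not None and self.precursor_charge <= 0:
            raise ValueError("precursor_charge must be positive or None")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def with_peaks(self, mz: Sequence[float], intensity: Sequence[float]) -> "Spectrum":
        return replace(self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))


@dataclass(frozen=True)
class RankedSpectrum(Spectrum):
    """A spectrum whose peaks carry intensity ranks (1 = most intense).

    Ties are broken by lower m/z; ranks are a permutation of 1..n.
    """

    ranks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        super().__post_init__()
        ranks = np.asarray(self.ranks, dtype=int)
        if ranks.shape != self.mz.shape:
            raise ValueError("ranks must parallel the peak arrays")
        if ranks.size and sorted(ranks.tolist()) != list(range(1, ranks.size + 1)):
            raise ValueError("ranks must be a permutation of 1..n_peaks")
        ranks.setflags(write=False)
        object.__setattr__(self, "ranks", ranks)


# --- MGF I/O -----------------------------------------------------------------

_KNOWN_HEADERS = {"TITLE", "PEPMASS", "CHARGE", "SCANS", "RTINSECONDS", "MSLEVEL"}


def _parse_charge(token: str) -> int:
    token = token.strip()
    if token.endswith("+") or token.endswith("-"):
        sign = -1 if token.endswith("-") else 1
        return sign * int(token[:-1])
    return int(token)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file (optionally gzip-compressed) into spectra.

    Recognized headers: TITLE, PEPMASS, CHARGE, SCANS, RTINSECONDS, MSLEVEL;
    unknown ``KEY=value`` headers are preserved in ``metadata``.
    """
    spectra: list[Spectrum] = []
    in_block = False
    mzs: list[float] = []
    intens: list[float] = []
    headers: dict[str, str] = {}

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfParseError(f"line {lineno}: nested BEGIN IONS")
                in_block = True
                mzs, intens, headers = [], [], {}
            elif line == "END IONS":
                if not in_block:
                    raise MgfParseError(f"line {lineno}: END IONS without BEGIN IONS")
                spectra.append(_finish_block(mzs, intens, headers, lineno))
                in_block = False
            elif in_block:
                if "=" in line and not line[0].isdigit():
                    key, _, value = line.partition("=")
                    headers[key.strip().upper()] = value.strip()
                else:
                    parts = line.split()
                    if len(parts) < 2:
                        raise MgfParseError(f"line {lineno}: malformed peak line {line!r}")
                    try:
                        mzs.append(float(parts[0]))
                        intens.append(float(parts[1]))
                    except ValueError as exc:
                        raise MgfParseError(
                            f"line {lineno}: malformed peak line {line!r}"
                        ) from exc
        if in_block:
            raise MgfParseError("unexpected end of file inside BEGIN IONS block")
    return spectra


def _finish_block(mzs, intens, headers, lineno) -> Spectrum:
    if "PEPMASS" not in headers:
        raise MgfParseError(f"block ending at line {lineno}: missing PEPMASS")
    pepmass = headers.pop("PEPMASS").split()
    precursor_mz = float(pepmass[0])
    charge = None
    if "CHARGE" in headers:
        charge = _parse_charge(headers.pop("CHARGE"))
        if charge <= 0:
            charge = None
    scan_id = headers.pop("SCANS", "") or headers.get("TITLE", "")
    ms_level = int(headers.pop("MSLEVEL", "2"))
    metadata = {k: v for k, v in headers.items()}
    if len(pepmass) > 1:
        metadata["PEPMASS_INTENSITY"] = pepmass[1]
    return Spectrum(
        mz=np.array(mzs, float),
        intensity=np.array(intens, float),
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        scan_id=scan_id,
        ms_level=ms_level,
        metadata=metadata,
    )


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra to MGF with a deterministic layout (round-trips read_mgf)."""
    path = str(path)
    opener = (lambda p: io.TextIOWrapper(gzip.open(p, "wb"))) if path.endswith(".gz") else open
    mode = {} if path.endswith(".gz") else {"mode": "w"}
    with opener(path, **mode) as fh:  # type: ignore[call-overload]
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            title = spec.metadata.get("TITLE", spec.scan_id)
            if title:
                fh.write(f"TITLE={title}\n")
            pep_int = spec.metadata.get("PEPMASS_INTENSITY")
            if pep_int is not None:
                fh.write(f"PEPMASS={spec.precursor_mz:.6f} {pep_int}\n")
            else:
                fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            if spec.precursor_charge is not None:
                fh.write(f"CHARGE={spec.precursor_charge}+\n")
            if spec.scan_id:
                fh.write(f"SCANS={spec.scan_id}\n")
            fh.write(f"MSLEVEL={spec.ms_level}\n")
            for key in sorted(spec.metadata):
                if key in ("TITLE", "PEPMASS_INTENSITY"):
                    continue
                fh.write(f"{key.upper()}={spec.metadata[key]}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f} {inten:.10g}\n")
            fh.write("END IONS\n")


# --- preprocessing -----------------------------------------------------------


def remove_precursor(
    spectrum: Spectrum,
    window_mz: float = 2.0,
    include_charge_reduced: bool = True,
) -> Spectrum:
    """Drop peaks within ``window_mz`` of the precursor m/z.

    When the precursor charge is known and ``include_charge_reduced`` is set,
    peaks at the charge-reduced precursor species (same neutral mass at every
    lower charge) are removed too.
    """
    if window_mz <= 0:
        raise ValueError("window_mz must be positive")
    targets = [spectrum.precursor_mz]
    z = spectrum.precursor_charge
    if include_charge_reduced and z is not None and z > 1:
        neutral = (spectrum.precursor_mz - PROTON_MASS) * z
        for z_red in range(1, z):
            targets.append((neutral + z_red * PROTON_MASS) / z_red)
    keep = np.ones(len(spectrum), dtype=bool)
    for target in targets:
        keep &= np.abs(spectrum.mz - target) > window_mz
    return spectrum.with_peaks(spectrum.mz[keep], spectrum.intensity[keep])


def rank_peaks(spectrum: Spectrum) -> RankedSpectrum:
    """Attach intensity ranks (1 = most intense; ties -> lower m/z first)."""
    if len(spectrum) == 0:
        raise ValueError("cannot rank an empty spectrum")
    # peaks are mz-sorted, so a stable descending-intensity sort breaks
    # intensity ties by lower m/z automatically
    order = np.argsort(-spectrum.intensity, kind="stable")
    ranks = np.empty(len(spectrum), dtype=int)
    ranks[order] = np.arange(1, len(spectrum) + 1)
    return RankedSpectrum(
        mz=spectrum.mz,
        intensity=spectrum.intensity,
        precursor_mz=spectrum.precursor_mz,
        precursor_charge=spectrum.precursor_charge,
        scan_id=spectrum.scan_id,
        ms_level=spectrum.ms_level,
        metadata=dict(spectrum.metadata),
        ranks=ranks,
    )


def median_ppm_error(matched: Sequence[tuple[float, float]]) -> float:
    """Median of 1e6 * (observed - theoretical) / theoretical over matches."""
    if not matched:
        raise ValueError("matched list must be non-empty")
    return statistics.median(1e6 * (obs - theo) / theo for obs, theo in matched)


def recalibrate(spectrum: Spectrum, ppm_offset: float) -> Spectrum:
    """Scale all fragment m/z and the precursor m/z by 1/(1 + ppm_offset*1e-6)."""
    if not np.isfinite(ppm_offset):
        raise ValueError("ppm_offset must be finite")
    factor = 1.0 / (1.0 + ppm_offset * 1e-6)
    return replace(
        spectrum,
        mz=spectrum.mz * factor,
        intensity=spectrum.intensity,
        precursor_mz=spectrum.precursor_mz * factor,
    )
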
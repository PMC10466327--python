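"""Dataset-level statistics: cleavage orthogonality, doublet prevalence and
rank curves, MS3-trigger sensitivity/specificity, and representative-spectrum
selection via the geometric median."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CsmRecord",
    "GeometricMedianError",
    "orthogonality_stats",
    "geometric_median",
    "representative_spectrum",
    "doublet_prevalence",
    "rank_cutoff_curve",
    "ms3_trigger_stats",
    "trigger_sensitivity",
    "bootstrap_median",
]


@dataclass(frozen=True)
class CsmRecord:
    """Per-spectrum quantities entering the dataset-level comparisons."""

    scan_id: str
    stub_sum: float = 0.0
    backbone_sum: float = 0.0
    doublet_alpha_found: bool = False
    doublet_beta_found: bool = False
    best_rank_alpha: int | None = None
    best_rank_beta: int | None = None
    n_ms3_triggered: int = 0
    alpha_triggered: bool = False
    beta_triggered: bool = False
    class_label: str = "crosslinked"


class GeometricMedianError(RuntimeError):
    """Weiszfeld iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: tuple[float, float]):
        super().__init__(message)
        self.last_iterate = last_iterate


def orthogonality_stats(records: Sequence[CsmRecord]) -> tuple[float, float]:
    """(median stub/backbone intensity ratio, fraction with stub > backbone).

    Records with zero backbone intensity are excluded from the median ratio
    (no finite ratio) but still count toward the stub>backbone fraction.
    """
    if not records:
        raise ValueError("records must be non-empty")
    ratios = [
        r.stub_sum / r.backbone_sum for r in records if r.backbone_sum > 0
    ]
    if not ratios:
        raise ValueError("no record has backbone_sum > 0; median ratio undefined")
    frac = sum(1 for r in records if r.stub_sum > r.backbone_sum) / len(records)
    return float(np.median(ratios)), frac


def geometric_median(
    points: Sequence[tuple[float, float]],
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> tuple[float, float]:
    """Weiszfeld iteration for the point minimizing summed Euclidean distance.

    Uses the Vardi-Zhang correction when an iterate coincides with a data
    point. Raises :class:`GeometricMedianError` on non-convergence.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("need at least one 2-D point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if pts.shape[0] == 1:
        return tuple(pts[0])
    x = pts.mean(axis=0)
    for _ in range(max_iter):
        dists = np.linalg.norm(pts - x, axis=1)
        on_point = dists < 1e-15
        if on_point.any():
            # Vardi-Zhang: treat the coincident point's pull separately
            far = ~on_point
            if not far.any():
                return tuple(x)
            w = 1.0 / dists[far]
            t_num = (pts[far] * w[:, None]).sum(axis=0)
            t_den = w.sum()
            t_point = t_num / t_den
            r_vec = ((pts[far] - x) * w[:, None]).sum(axis=0)
            r_norm = np.linalg.norm(r_vec)
            eta = float(on_point.sum())
            if r_norm <= eta:
                return tuple(x)
            gamma = min(1.0, eta / r_norm)
            x_new = (1.0 - gamma) * t_point + gamma * x
        else:
            w = 1.0 / dists
            x_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        step = np.linalg.norm(x_new - x)
        x = x_new
        if step < tol:
            return tuple(x)
    raise GeometricMedianError(
        f"Weiszfeld did not converge in {max_iter} iterations", tuple(x)
    )


def _log_points(records: Iterable[CsmRecord], log: bool = True):
    recs = [
        r
        for r in records
        if r.stub_sum > 0 and r.backbone_sum > 0
    ]
    if not recs:
        raise ValueError("no record with positive stub and backbone sums")
    if log:
        pts = [(math.log10(r.backbone_sum), math.log10(r.stub_sum)) for r in recs]
    else:
        pts = [(r.backbone_sum, r.stub_sum) for r in recs]
    return recs, pts


def representative_spectrum(records: Sequence[CsmRecord], log: bool = True) -> str:
    """Scan id whose intensity point is nearest the geometric median.

    Points are (log10 backbone_sum, log10 stub_sum) by default; ties resolve
    to the lower scan_id.
    """
    recs, pts = _log_points(records, log)
    gm = np.asarray(geometric_median(pts))
    dists = np.linalg.norm(np.asarray(pts) - gm, axis=1)
    best = min(range(len(recs)), key=lambda i: (dists[i], recs[i].scan_id))
    return recs[best].scan_id


def doublet_prevalence(records: Sequence[CsmRecord]) -> tuple[float, float]:
    """(fraction with at least one doublet found, fraction with both)."""
    if not records:
        raise ValueError("records must be non-empty")
    at_least_one = sum(
        1 for r in records if r.doublet_alpha_found or r.doublet_beta_found
    )
    both = sum(1 for r in records if r.doublet_alpha_found and r.doublet_beta_found)
    n = len(records)
    return at_least_one / n, both / n


def rank_cutoff_curve(
    records: Sequence[CsmRecord], cutoffs: Sequence[int] = (1, 5, 10, 20)
) -> pd.DataFrame:
    """Proportion of records whose doublets pass each intensity-rank cutoff.

    For each cutoff r: ``p_more_intense`` is the fraction whose better
    (lower-rank) doublet has rank <= r; ``p_both`` requires both doublets'
    ranks <= r. Records missing a doublet fail the corresponding column.
    """
    if not records:
        raise ValueError("records must be non-empty")
    n = len(records)
    rows = []
    for cutoff in cutoffs:
        more_intense = 0
        both = 0
        for r in records:
            ranks = [x for x in (r.best_rank_alpha, r.best_rank_beta) if x is not None]
            if ranks and min(ranks) <= cutoff:
                more_intense += 1
            if (
                r.best_rank_alpha is not None
                and r.best_rank_beta is not None
                and r.best_rank_alpha <= cutoff
                and r.best_rank_beta <= cutoff
            ):
                both += 1
        rows.append(
            {"cutoff": cutoff, "p_more_intense": more_intense / n, "p_both": both / n}
        )
    return pd.DataFrame(rows)


def ms3_trigger_stats(
    records_by_class: dict[str, Sequence[CsmRecord]],
) -> pd.DataFrame:
    """Mean MS3 triggers per MS2 and normal-approximation 0.95 CI, per class."""
    rows = []
    for label, records in records_by_class.items():
        if not records:
            raise ValueError(f"class {label!r} has no records")
        counts = np.array([r.n_ms3_triggered for r in records], dtype=float)
        mean = float(counts.mean())
        sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
        half = 1.96 * sd / math.sqrt(counts.size)
        rows.append(
            {
                "class": label,
                "mean_triggers": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "n": int(counts.size),
            }
        )
    return pd.DataFrame(rows)


def trigger_sensitivity(records: Sequence[CsmRecord]) -> tuple[float, float]:
    """(fraction with at least one peptide correctly triggered, fraction with both)."""
    if not records:
        raise ValueError("records must be non-empty")
    n = len(records)
    one = sum(1 for r in records if r.alpha_triggered or r.beta_triggered)
    both = sum(1 for r in records if r.alpha_triggered and r.beta_triggered)
    return one / n, both / n


def bootstrap_median(
    values: Sequence[float],
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> tuple[float, float, float, float]:
    """Bootstrap the median: returns (median, se, ci_low, ci_high)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("values must be non-empty")
    rng = rng or np.random.default_rng()
    medians = np.median(
        vals[rng.integers(0, vals.size, size=(n_boot, vals.size))], axis=1
    )
    lo, hi = np.quantile(medians, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return float(np.median(vals)), float(medians.std(ddof=1)), float(lo), float(hi)
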
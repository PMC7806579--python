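"""Pre-annotation spectrum cleanup: thresholds, deisotoping, monoisotopic checks.

The pipeline order is fixed — m/z window, then intensity thresholds, then
deisotoping — and every rule *flags* peaks rather than deleting them.  Only
singly charged envelopes are considered, so the isotope spacing is the plain
13C-12C difference of 1.003355 Da.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .chem import C13_SPACING
from .io import FLAG_ISOTOPE, FLAG_THRESHOLD, Peak, Spectrum

__all__ = ["FilterConfig", "threshold_filter", "deisotope", "validate_monoisotopic", "clean"]


@dataclass(frozen=True)
class FilterConfig:
    """Filtering parameters; defaults are the tool's standard operating point.

    ``abs_intensity_min`` is in cps, ``rel_intensity_min`` in percent of the
    base peak, ``isotope_ratio_range`` in percent of the envelope's
    monoisotopic peak, ``isotope_tolerance`` in Da (defaults to the annotation
    tolerance of 10 mmu).
    """

    abs_intensity_min: float = 500.0
    rel_intensity_min: float = 1.0
    mz_range: tuple[float, float] | None = None
    isotope_ratio_range: tuple[float, float] = (1.0, 100.0)
    isotope_tolerance: float = 0.010
    monoisotopic_validation: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.rel_intensity_min <= 100.0):
            raise ValueError("rel_intensity_min must be within [0, 100]")
        lo, hi = self.isotope_ratio_range
        if lo < 0 or hi < lo:
            raise ValueError("isotope_ratio_range must be an increasing interval >= 0")
        if self.mz_range is not None and self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range low bound must be below high bound")
        if self.isotope_tolerance <= 0:
            raise ValueError("isotope_tolerance must be positive")
        if self.abs_intensity_min < 0:
            raise ValueError("abs_intensity_min must be non-negative")


def threshold_filter(s: Spectrum, cfg: FilterConfig | None = None) -> Spectrum:
    """Flag peaks outside the m/z window or below the intensity thresholds.

    The relative threshold is computed against the base peak of the
    post-m/z-filter spectrum; applying the filter twice changes nothing.
    """
    cfg = cfg or FilterConfig()
    out = s.copy()
    in_window = []
    for p in out.peaks:
        if cfg.mz_range is not None and not (cfg.mz_range[0] <= p.mz <= cfg.mz_range[1]):
            p.flags.add(FLAG_THRESHOLD)
        elif p.retained:
            in_window.append(p)
    base = max((p.intensity for p in in_window), default=0.0)
    floor = max(cfg.abs_intensity_min, base * cfg.rel_intensity_min / 100.0)
    for p in in_window:
        if p.intensity < floor:
            p.flags.add(FLAG_THRESHOLD)
    if not out.retained:
        warnings.warn(f"spectrum {s.title!r} has no peaks left after thresholding")
    return out


def deisotope(s: Spectrum, cfg: FilterConfig | None = None) -> Spectrum:
    """Flag 13C isotope peaks of singly charged envelopes.

    Walking the retained peaks from light to heavy, each unclaimed peak starts
    an envelope; contiguous companions at ``+k * 1.003355`` Da (within the
    isotope tolerance) whose intensity ratio to the envelope's monoisotopic
    peak falls inside ``isotope_ratio_range`` are flagged.  A peak claimed as
    an isotope can never start an envelope of its own, which makes the walk
    deterministic.
    """
    cfg = cfg or FilterConfig()
    out = s.copy()
    peaks = out.retained
    lo, hi = cfg.isotope_ratio_range
    for i, head in enumerate(peaks):
        if FLAG_ISOTOPE in head.flags or head.intensity <= 0:
            continue
        k = 1
        while True:
            target = head.mz + k * C13_SPACING
            best = None
            for q in peaks:
                if q is head or FLAG_ISOTOPE in q.flags:
                    continue
                err = abs(q.mz - target)
                if err <= cfg.isotope_tolerance and (best is None or err < best[0]):
                    best = (err, q)
            if best is None:
                break
            ratio = 100.0 * best[1].intensity / head.intensity
            if lo <= ratio <= hi:
                best[1].flags.add(FLAG_ISOTOPE)
                k += 1
            else:
                break
    return out


def validate_monoisotopic(s: Spectrum, p: Peak, cfg: FilterConfig | None = None) -> bool:
    """True iff ``p`` cannot plausibly be the 13C isotope of a lighter peak.

    Checked on the pre-deisotoping view: a peak one isotope spacing below whose
    intensity would put ``p`` inside the isotope ratio window vetoes ``p`` as an
    [M+H]+ candidate.
    """
    cfg = cfg or FilterConfig()
    lo, hi = cfg.isotope_ratio_range
    for q in s.retained:
        if q is p:
            continue
        if abs((p.mz - q.mz) - C13_SPACING) <= cfg.isotope_tolerance and q.intensity > 0:
            ratio = 100.0 * p.intensity / q.intensity
            if lo <= ratio <= hi:
                return False
    return True


def clean(s: Spectrum, cfg: FilterConfig | None = None) -> Spectrum:
    """Full cleanup pipeline: m/z + intensity thresholds, then deisotoping."""
    cfg = cfg or FilterConfig()
    return deisotope(threshold_filter(s, cfg), cfg)
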
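"""Optical-fractionator stereology: total cell number and density.

Design-based stereology estimates a total object count from a systematic
sample of sections by scaling the summed counts by the inverses of the three
sampling fractions:

    N = [ sum(Q) * (t / h) * (1 / asf) * (1 / ssf) ] * 2

where Q are per-section object counts, t the section thickness, h the optical
dissector height, asf the area sampling fraction, ssf the section sampling
fraction, and the factor 2 converts the sectioned hemisphere into a bilateral
(whole-brain) total.

Density is reported against a Cavalieri-style reference volume reconstructed
from the sampled section areas: V = sum(area_i * t) / ssf.  The density
denominator is this package's own convention (the estimator literature leaves
it to the study design).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UM3_PER_MM3 = 1e9


@dataclass
class SectionCounts:
    """Per-section object counts with the fractionator sampling parameters.

    ``q``: object counts in the sampled sections (non-negative integers);
    ``t``: section thickness (um); ``h``: dissector height (um, 0 < h <= t);
    ``asf``/``ssf``: area and section sampling fractions in (0, 1];
    ``bilateral_factor``: 2 when one hemisphere was sectioned.
    """

    q: np.ndarray
    t: float
    h: float
    asf: float
    ssf: float
    bilateral_factor: float = 2.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q)
        if (self.q < 0).any() or not np.array_equal(self.q, self.q.astype(int)):
            raise ValueError("section counts must be non-negative integers")
        if not 0 < self.h <= self.t:
            raise ValueError("need 0 < h <= t")
        if not 0 < self.asf <= 1 or not 0 < self.ssf <= 1:
            raise ValueError("asf and ssf must lie in (0, 1]")


def estimate_total_cells(s: SectionCounts) -> float:
    """Fractionator estimate N = [sum(Q) * (t/h) * (1/asf) * (1/ssf)] * bilateral."""
    return float(
        s.q.sum() * (s.t / s.h) * (1.0 / s.asf) * (1.0 / s.ssf) * s.bilateral_factor
    )


def cell_density(
    n_total: float, section_areas_um2: np.ndarray, t_um: float, ssf: float
) -> float:
    """Cells per mm^3 against the Cavalieri volume of the sampled sections.

    V = (sum of sampled section areas * t) / ssf, converted from um^3 to mm^3.
    """
    areas = np.asarray(section_areas_um2, dtype=float)
    if (areas <= 0).any():
        raise ValueError("section areas must be positive")
    if not 0 < ssf <= 1:
        raise ValueError("ssf must lie in (0, 1]")
    volume_mm3 = areas.sum() * t_um / ssf / UM3_PER_MM3
    if volume_mm3 <= 0:
        raise ValueError("zero reference volume")
    return float(n_total / volume_mm3)
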
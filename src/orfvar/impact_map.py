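"""Sliding-window relative-impact profile along a genomic region.

The impact potential at position x is the arithmetic mean of the impact
codes (0-3) of all variants within x +- half_window (default 30 bp); empty
windows map to 0.  Profiles from different annotation strategies are made
comparable by dividing every profile by the maximum value reached across a
set of reference profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GenomicInterval

DEFAULT_HALF_WINDOW = 30


@dataclass
class ImpactProfile:
    region: GenomicInterval
    half_window: int
    values: np.ndarray
    normalization_reference: str = ""

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.region.start, self.region.end + 1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"position": self.positions,
                             "value": self.values})


def impact_profile(variant_impacts: list[tuple[int, int]],
                   region: GenomicInterval,
                   half_window: int = DEFAULT_HALF_WINDOW) -> ImpactProfile:
    """Windowed mean impact along ``region``.

    ``variant_impacts`` holds (genomic position, impact code 0-3), one
    entry per variant — the caller supplies each variant's maximal impact.
    Runs in O(region + variants) via prefix sums.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    L = region.length
    counts = np.zeros(L + 1)
    sums = np.zeros(L + 1)
    lo, hi = region.start, region.end
    for pos, impact in variant_impacts:
        if not 0 <= impact <= 3:
            raise ValueError(f"impact code {impact} outside 0..3")
        a = max(lo, pos - half_window) - lo
        b = min(hi, pos + half_window) - lo + 1
        if b <= 0 or a >= L:
            continue
        counts[a] += 1
        counts[b] -= 1
        sums[a] += impact
        sums[b] -= impact
    counts = np.cumsum(counts[:-1])
    sums = np.cumsum(sums[:-1])
    values = np.divide(sums, counts, out=np.zeros(L), where=counts > 0)
    return ImpactProfile(region=region, half_window=half_window,
                         values=values)


def normalize_profiles(target: ImpactProfile,
                       references: list[ImpactProfile],
                       reference_name: str = "references"
                       ) -> ImpactProfile:
    """Scale ``target`` by the maximum value across ``references``.

    A reference profile scaled by itself peaks at exactly 1; a target whose
    raw peak exceeds every reference peaks above 1.
    """
    if not references:
        raise ValueError("need at least one reference profile")
    for r in references:
        if r.region != target.region or r.half_window != target.half_window:
            raise ValueError("profiles must share region and half_window")
    ref_max = max(float(r.values.max()) for r in references)
    if ref_max <= 0:
        raise ValueError("all-zero reference profiles: scaling undefined")
    return ImpactProfile(region=target.region,
                         half_window=target.half_window,
                         values=target.values / ref_max,
                         normalization_reference=reference_name)
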
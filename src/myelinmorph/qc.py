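"""Multicriteria post-hoc screening of fiber records.

Automated segmentation produces spurious detections; before aggregation,
records are screened on three physiologically motivated rules:

* g-ratio strictly inside (0, 1) — values at or outside the bounds signal
  mis-segmented axon or myelin boundaries (g = 1 means zero myelin);
* axon diameter at least 0.335 µm — below two pixels at 0.166 µm/px a
  diameter is dominated by partial-volume effects;
* eccentricity at most 0.9 — downstream quantities assume near-circular
  cross-sections.

Boundary semantics are literal: a diameter of exactly 0.335 µm is kept
(only *below* is removed) and an eccentricity of exactly 0.9 is kept (only
*exceeding* is removed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from myelinmorph.morphometry import FiberRecord

REASON_G = "g_ratio"
REASON_DIAMETER = "diameter"
REASON_ECCENTRICITY = "eccentricity"
REASON_INVALID = "invalid"


@dataclass(frozen=True)
class QCPolicy:
    """Screening thresholds; defaults are the standard screen."""

    g_min: float = 0.0            # exclusive
    g_max: float = 1.0            # exclusive
    min_diameter: float = 0.335   # µm, inclusive (kept at the boundary)
    max_eccentricity: float = 0.9 # inclusive (kept at the boundary)

    def __post_init__(self) -> None:
        if not 0 <= self.g_min < self.g_max <= 1:
            raise ValueError("need 0 <= g_min < g_max <= 1")
        if self.min_diameter < 0:
            raise ValueError("min_diameter must be non-negative")
        if not 0 < self.max_eccentricity <= 1:
            raise ValueError("max_eccentricity must lie in (0, 1]")


@dataclass
class ScreenResult:
    """Partition of the input into kept records and removals with reasons."""

    kept: list[FiberRecord]
    removed: list[tuple[FiberRecord, tuple[str, ...]]]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)


def _violations(r: FiberRecord, policy: QCPolicy) -> tuple[str, ...]:
    metrics = (r.g_ratio, r.axon_diameter_um, r.eccentricity)
    if any(not math.isfinite(m) for m in metrics):
        return (REASON_INVALID,)
    reasons = []
    if not policy.g_min < r.g_ratio < policy.g_max:
        reasons.append(REASON_G)
    if r.axon_diameter_um < policy.min_diameter:
        reasons.append(REASON_DIAMETER)
    if r.eccentricity > policy.max_eccentricity:
        reasons.append(REASON_ECCENTRICITY)
    return tuple(reasons)


def screen(records: list[FiberRecord],
           policy: QCPolicy | None = None) -> ScreenResult:
    """Partition ``records`` into kept and removed-with-reasons.

    Order-preserving; every removed record is tagged with *all* rules it
    violates, and a record with any non-finite metric is removed with
    reason ``"invalid"``.  ``kept`` + ``removed`` always partitions the
    input, and screening the kept set again is a no-op.
    """
    policy = policy or QCPolicy()
    kept, removed = [], []
    for r in records:
        reasons = _violations(r, policy)
        if reasons:
            removed.append((r, reasons))
        else:
            kept.append(r)
    return ScreenResult(kept=kept, removed=removed)
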
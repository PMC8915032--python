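"""Synthetic network generator with case-study-like marginal ranges.

Generated networks emulate the *structure* of the bundled river-basin
dataset: a dozen-or-so sludge generators with moderate COD (tens of g/L),
near-neutral alkalinity and C/N below the digestion window, plus a handful
of industrial substrates with very high, widely spread COD and C/N (drawn
log-uniformly, matching their orders-of-magnitude spread) and low
alkalinity.  Receptor acceptance capacities are drawn so that total
available substrate exceeds total capacity by a factor of 1–4, keeping the
volume constraints active and the instance non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .network import CaseNetwork, ConstraintBounds, ObjectiveParams, Receptor, SubstrateSource

__all__ = ["SynthSpec", "DEFAULT_RANGES", "generate_network"]

# Envelopes read off the bundled case-study dataset columns.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "sludge_volume": (4400.0, 47000.0),
    "sludge_cod": (16900.0, 23400.0),
    "sludge_cn": (14.0, 21.0),
    "sludge_alk": (1800.0, 10100.0),
    "industrial_volume": (9000.0, 9000.0),
    "industrial_cod": (155900.0, 667400.0),
    "industrial_cn": (32.0, 33000.0),
    "industrial_alk": (20.0, 660.0),
    "toxicity": (0.01, 2.30),
    "distance_km": (5.0, 67.0),
}


@dataclass(frozen=True)
class SynthSpec:
    """Shape and envelopes of a synthetic network."""

    n_sludge: int = 12
    n_industrial: int = 7
    n_receptors: int = 3
    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_sludge, self.n_industrial, self.n_receptors) < 0:
            raise ValidationError("counts must be >= 0")
        if self.n_sludge + self.n_industrial == 0 or self.n_receptors == 0:
            raise ValidationError("need at least one generator and one receptor")
        merged = {**DEFAULT_RANGES, **self.ranges}
        unknown = set(self.ranges) - set(DEFAULT_RANGES)
        if unknown:
            raise ValidationError(f"unknown range key(s): {sorted(unknown)}")
        for key, (lo, hi) in merged.items():
            if not lo <= hi or lo <= 0:
                raise ValidationError(f"range {key!r} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        object.__setattr__(self, "ranges", merged)


def generate_network(
    spec: SynthSpec,
    bounds: ConstraintBounds | None = None,
    params: ObjectiveParams | None = None,
) -> CaseNetwork:
    """Draw a seeded, reproducible network within the spec's envelopes."""
    rng = np.random.default_rng(spec.seed)
    rr = spec.ranges
    rids = [f"R{i + 1}" for i in range(spec.n_receptors)]

    def uni(key: str) -> float:
        lo, hi = rr[key]
        return float(rng.uniform(lo, hi))

    def loguni(key: str) -> float:
        lo, hi = rr[key]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    sources: list[SubstrateSource] = []
    for i in range(spec.n_sludge):
        sources.append(
            SubstrateSource(
                id=f"W{i + 1}",
                kind="sludge",
                daily_volume=uni("sludge_volume"),
                cod=uni("sludge_cod"),
                cn_ratio=uni("sludge_cn"),
                alkalinity=uni("sludge_alk"),
                toxicity=uni("toxicity"),
                distance_km={rid: uni("distance_km") for rid in rids},
            )
        )
    for i in range(spec.n_industrial):
        sources.append(
            SubstrateSource(
                id=f"C{i + 1}",
                kind="industrial",
                daily_volume=uni("industrial_volume"),
                cod=loguni("industrial_cod"),
                cn_ratio=loguni("industrial_cn"),
                alkalinity=uni("industrial_alk"),
                toxicity=uni("toxicity"),
                distance_km={rid: uni("distance_km") for rid in rids},
            )
        )

    total_volume = sum(s.daily_volume for s in sources)
    total_cap = total_volume / rng.uniform(1.0, 4.0)
    weights = rng.uniform(0.5, 1.5, size=spec.n_receptors)
    caps = total_cap * weights / weights.sum()
    receptors = [
        Receptor(
            id=rid,
            max_external_volume=float(cap),
            own_cod=uni("sludge_cod"),
            own_cn=uni("sludge_cn"),
            own_alk=uni("sludge_alk"),
            own_tox=uni("toxicity"),
        )
        for rid, cap in zip(rids, caps)
    ]
    return CaseNetwork(
        sources=sources,
        receptors=receptors,
        bounds=bounds if bounds is not None else ConstraintBounds(),
        params=params if params is not None else ObjectiveParams(),
    )
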
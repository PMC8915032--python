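"""Quality coefficients, blend mass balance, cost index and feasibility.

The cost index scores an allocation ``x`` of quantised substrate volumes by
summing, over every active edge (generator w, receptor r), a normalised term

    (V_ws / V_w) * T_w * combine(quality_w, logistics_wr)

where ``quality_w = (F_w1 + F_w2 + F_w3) ** rho_q`` aggregates three
dimensionless substrate-quality coefficients (biogas potential from COD,
COD/TN adequacy, alkalinity adequacy), ``T_w`` is a toxicity coefficient, and
the logistics term scales with route length, transport cost rate and social
impact.  In the default *penalty* mode the logistics term is divided by a
fixed reference cost and subtracted (clamped at zero), so long routes
reduce, never increase, an edge's worth and uniformly longer networks score
worse; the *literal* mode adds the raw term instead.  The signed index B' carries the solver-dependent sign
convention K; the comparable index is B = |B'|.

Feasibility of an allocation is a mass-balance question: each receptor's
blended feed must respect its external-volume cap, the COD/TN window, the
alkalinity window and the toxicity ceiling, and no generator may ship more
than it produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, NamedTuple, Sequence

from .errors import ConfigurationError, ValidationError
from .network import (
    Allocation,
    CaseNetwork,
    ConstraintBounds,
    Receptor,
    SubstrateSource,
)

__all__ = [
    "QualityCoefficients",
    "BlendProfile",
    "Violation",
    "EvaluationResult",
    "quality_coefficients",
    "network_quality_coefficients",
    "edge_coefficients",
    "blend_profile",
    "cost_index",
    "check_feasibility",
    "biogas_estimate",
    "evaluate",
    "performance_summary",
    "digester_volume",
]

_REL_TOL = 1e-9  # slack applied to inclusive bounds so exact boundaries pass

DEFAULT_HRT_DAYS = 20.0


@dataclass(frozen=True)
class QualityCoefficients:
    """Dimensionless per-substrate coefficients: F_w1, F_w2, F_w3 and T_w."""

    f1: float  # biogas potential, from COD
    f2: float  # COD/TN adequacy
    f3: float  # alkalinity adequacy
    t: float   # toxicity attenuation

    @property
    def f_sum(self) -> float:
        return self.f1 + self.f2 + self.f3


def _trapezoid(x: float, lo: float, hi: float, shoulder: float) -> float:
    """Membership: 1 on [lo, hi], linear shoulders of width ``shoulder``, else 0."""
    if lo <= x <= hi:
        return 1.0
    if shoulder <= 0:
        return 0.0
    if lo - shoulder < x < lo:
        return (x - (lo - shoulder)) / shoulder
    if hi < x < hi + shoulder:
        return ((hi + shoulder) - x) / shoulder
    return 0.0


def quality_coefficients(
    source: SubstrateSource,
    bounds: ConstraintBounds,
    mode: str = "fallback",
    *,
    cod_ref: float | None = None,
    shoulder_frac: float = 0.25,
    equations: Mapping[str, Callable[[SubstrateSource, ConstraintBounds], float]] | None = None,
) -> QualityCoefficients:
    """Compute the four dimensionless coefficients for one substrate.

    The shipped ``fallback`` mode is a transparent stand-in family:

    * ``f1 = cod / cod_ref`` with ``cod_ref`` defaulting to the network's
      maximum COD (or the source's own COD when none is given),
    * ``f2`` / ``f3``: trapezoidal membership of C/N (resp. alkalinity) on
      its operational window, with linear shoulders of width
      ``shoulder_frac`` times the window width,
    * ``t = max(0, 1 - toxicity / tox_max)``.

    ``figure2`` mode runs user-supplied coefficient equations (callables for
    the keys ``f1, f2, f3, t``) and raises :class:`ConfigurationError` when
    they have not been provided.
    """
    if mode == "figure2":
        if not equations or set(equations) < {"f1", "f2", "f3", "t"}:
            raise ConfigurationError(
                "figure2 coefficient mode requires user-supplied equations for f1, f2, f3 and t"
            )
        return QualityCoefficients(
            f1=float(equations["f1"](source, bounds)),
            f2=float(equations["f2"](source, bounds)),
            f3=float(equations["f3"](source, bounds)),
            t=float(equations["t"](source, bounds)),
        )
    if mode != "fallback":
        raise ConfigurationError(f"unknown coefficient mode {mode!r}")
    ref = cod_ref if cod_ref is not None else source.cod
    if not ref > 0:
        raise ValidationError("cod_ref must be > 0")
    cn_w = bounds.cn_max - bounds.cn_min
    alk_w = bounds.alk_max - bounds.alk_min
    return QualityCoefficients(
        f1=source.cod / ref,
        f2=_trapezoid(source.cn_ratio, bounds.cn_min, bounds.cn_max, shoulder_frac * cn_w),
        f3=_trapezoid(source.alkalinity, bounds.alk_min, bounds.alk_max, shoulder_frac * alk_w),
        t=max(0.0, 1.0 - source.toxicity / bounds.tox_max),
    )


def network_quality_coefficients(net: CaseNetwork) -> dict[str, QualityCoefficients]:
    """Coefficients for every source, sharing the network-wide COD reference."""
    p = net.params
    cod_ref = p.cod_ref if p.cod_ref is not None else max(s.cod for s in net.sources)
    return {
        s.id: quality_coefficients(
            s, net.bounds, p.coefficient_mode, cod_ref=cod_ref, shoulder_frac=p.shoulder_frac
        )
        for s in net.sources
    }


def edge_coefficients(net: CaseNetwork) -> dict[tuple[str, str], float]:
    """Volume-independent per-edge factor c_wr of the cost index.

    An active edge contributes ``(V_ws / V_w) * c_wr`` to B', with
    ``c_wr = T_w * combine(quality_w, logistics_wr)`` as described in the
    module docstring.  In penalty mode every c_wr is >= 0.
    """
    p = net.params
    qcs = network_quality_coefficients(net)
    raw = {
        (s.id, rid): s.transport_cost_rate * s.distance_km[rid] * s.social_impact
        for s in net.sources
        for rid in net.receptor_ids
    }
    raw_max = max(raw.values(), default=0.0)
    ref = p.logistics_ref if p.logistics_ref is not None else raw_max
    coefs: dict[tuple[str, str], float] = {}
    for s in net.sources:
        q = qcs[s.id].f_sum
        quality = q**p.rho_q if p.quality_weight_mode == "exponent" else q * p.rho_q
        for rid in net.receptor_ids:
            if p.logistics_mode == "penalty":
                norm = raw[(s.id, rid)] / ref if ref > 0 else 0.0
                combine = max(0.0, quality - p.rho_x * norm)
            else:
                combine = quality + p.rho_x * raw[(s.id, rid)]
            coefs[(s.id, rid)] = qcs[s.id].t * combine
    return coefs


# ---------------------------------------------------------------------------
# Blend mass balance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlendProfile:
    """Mass-balance summary of one receptor's blended feed.

    Concentration fields are NaN (and ``defined`` is False) when the blend is
    empty.  ``cn_ratio`` is the ratio of total COD mass to total TN mass —
    never an average of per-source ratios.
    """

    receptor_id: str
    total_volume: float           # L/day
    cod_conc: float               # mg/L
    cod_mass: float               # kg COD/day
    tn_mass: float                # kg N/day
    cn_ratio: float               # dimensionless
    alkalinity: float             # mg CaCO3/L, volume-weighted
    toxicity: float               # mg Pb/L, volume-weighted
    defined: bool = True


def blend_profile(
    a: Allocation,
    receptor: Receptor,
    sources: Mapping[str, SubstrateSource] | Sequence[SubstrateSource],
    mixing: str = "external_only",
) -> BlendProfile:
    """Volume-weighted mass balance of everything routed to ``receptor``.

    COD mass is ``sum(v * cod) * 1e-6`` kg/day, TN per source is derived as
    COD over C/N before mixing, and the blend C/N is the COD-mass to TN-mass
    ratio.  Alkalinity and toxicity mix as volume-weighted mean
    concentrations.  ``mixing="with_base"`` co-mixes the receptor's own
    sludge stream at ``base_feed_volume`` with its own characterisation.
    """
    if not isinstance(sources, Mapping):
        sources = {s.id: s for s in sources}
    streams: list[tuple[float, float, float, float, float]] = []  # v, cod, cn, alk, tox
    for (sid, rid), v in a.volume.items():
        if rid != receptor.id or v == 0.0:
            continue
        s = sources[sid]
        streams.append((v, s.cod, s.cn_ratio, s.alkalinity, s.toxicity))
    if mixing == "with_base":
        if receptor.base_feed_volume is None:
            raise ValidationError(
                f"receptor {receptor.id!r}: mixing='with_base' requires base_feed_volume"
            )
        streams.append(
            (receptor.base_feed_volume, receptor.own_cod, receptor.own_cn, receptor.own_alk, receptor.own_tox)
        )
    elif mixing != "external_only":
        raise ConfigurationError(f"unknown mixing mode {mixing!r}")

    total_v = sum(v for v, *_ in streams)
    if total_v == 0.0:
        nan = float("nan")
        return BlendProfile(receptor.id, 0.0, nan, 0.0, 0.0, nan, nan, nan, defined=False)
    cod_mass = sum(v * cod for v, cod, *_ in streams) * 1e-6
    tn_mass = sum(v * cod / cn for v, cod, cn, *_ in streams) * 1e-6
    return BlendProfile(
        receptor_id=receptor.id,
        total_volume=total_v,
        cod_conc=cod_mass * 1e6 / total_v,
        cod_mass=cod_mass,
        tn_mass=tn_mass,
        cn_ratio=cod_mass / tn_mass if tn_mass > 0 else float("inf"),
        alkalinity=sum(v * alk for v, _, _, alk, _ in streams) / total_v,
        toxicity=sum(v * tox for v, *_, tox in streams) / total_v,
    )


# ---------------------------------------------------------------------------
# Cost index and feasibility
# ---------------------------------------------------------------------------

def cost_index(a: Allocation, net: CaseNetwork) -> tuple[float, float]:
    """Evaluate the cost index; returns ``(B', B)`` with ``B = |B'|``."""
    coefs = edge_coefficients(net)
    vmax = {s.id: s.daily_volume for s in net.sources}
    total = sum(
        (v / vmax[sid]) * coefs[(sid, rid)] for (sid, rid), v in a.volume.items() if v != 0.0
    )
    b_signed = net.params.K * total
    return b_signed, abs(b_signed)


class Violation(NamedTuple):
    """One violated restriction: where it happened, what was seen, the bound."""

    constraint: str
    where: str       # receptor id or source id
    observed: float
    bound: float

    @property
    def magnitude(self) -> float:
        """Violation size normalised by the bound (scale-free)."""
        return abs(self.observed - self.bound) / max(abs(self.bound), 1.0)


def check_feasibility(
    a: Allocation, net: CaseNetwork, mixing: str = "external_only"
) -> tuple[bool, list[Violation]]:
    """Check every operational restriction; returns (feasible, violations).

    Per receptor with non-zero intake: volume cap, C/N window, alkalinity
    window (all inclusive) and toxicity ceiling, evaluated on the blend mass
    balance.  Per source: total shipped volume at most the available volume.
    """
    b = net.bounds
    violations: list[Violation] = []
    smap = net.source_map()
    for r in net.receptors:
        prof = blend_profile(a, r, smap, mixing)
        if prof.total_volume == 0.0:
            continue
        if prof.total_volume > r.max_external_volume * (1 + _REL_TOL):
            violations.append(Violation("volume_max", r.id, prof.total_volume, r.max_external_volume))
        if prof.cn_ratio < b.cn_min * (1 - _REL_TOL):
            violations.append(Violation("cn_min", r.id, prof.cn_ratio, b.cn_min))
        if prof.cn_ratio > b.cn_max * (1 + _REL_TOL):
            violations.append(Violation("cn_max", r.id, prof.cn_ratio, b.cn_max))
        if prof.alkalinity < b.alk_min * (1 - _REL_TOL):
            violations.append(Violation("alk_min", r.id, prof.alkalinity, b.alk_min))
        if prof.alkalinity > b.alk_max * (1 + _REL_TOL):
            violations.append(Violation("alk_max", r.id, prof.alkalinity, b.alk_max))
        if prof.toxicity > b.tox_max * (1 + _REL_TOL):
            violations.append(Violation("tox_max", r.id, prof.toxicity, b.tox_max))
    for s in net.sources:
        tot = a.total_from_source(s.id)
        if tot > s.daily_volume * (1 + _REL_TOL):
            violations.append(Violation("source_volume", s.id, tot, s.daily_volume))
    return (not violations, violations)


def biogas_estimate(blends: Iterable[BlendProfile], yield_m3_per_kg: float = 0.268) -> float:
    """Daily biogas volume (Nm3/day) from the COD mass of each receptor blend."""
    if not yield_m3_per_kg > 0:
        raise ValidationError("biogas yield must be > 0")
    return sum(b.cod_mass for b in blends) * yield_m3_per_kg


def digester_volume(receptor: Receptor, hrt_days: float = DEFAULT_HRT_DAYS) -> tuple[float, bool]:
    """Digester working volume in m3 and whether it was derived.

    When the receptor does not state a digester volume, it is approximated as
    the hydraulic retention time times the plant's daily feed (external cap
    plus base feed), converted from litres to m3.
    """
    if receptor.digester_volume is not None:
        return receptor.digester_volume, False
    base = receptor.base_feed_volume or 0.0
    return (receptor.max_external_volume + base) * hrt_days / 1000.0, True


@dataclass
class EvaluationResult:
    """Full evaluation of one allocation against one network."""

    b_signed: float
    b_abs: float
    feasible: bool
    violations: list[Violation]
    blends: dict[str, BlendProfile]
    biogas_total: float                       # Nm3/day
    organic_load: dict[str, float]            # kg COD/(m3 day) per receptor
    avg_cn: float                             # volume-weighted over active receptors
    avg_alk: float
    organic_load_derived: bool = False        # True when digester volumes were approximated


def evaluate(
    a: Allocation, net: CaseNetwork, mixing: str = "external_only", hrt_days: float = DEFAULT_HRT_DAYS
) -> EvaluationResult:
    """Cost index, feasibility, blends and performance metrics in one pass."""
    b_signed, b_abs = cost_index(a, net)
    feasible, violations = check_feasibility(a, net, mixing)
    smap = net.source_map()
    blends = {r.id: blend_profile(a, r, smap, mixing) for r in net.receptors}
    biogas = biogas_estimate(blends.values(), net.params.biogas_yield)
    loads: dict[str, float] = {}
    derived_any = False
    for r in net.receptors:
        vol_m3, derived = digester_volume(r, hrt_days)
        derived_any = derived_any or derived
        loads[r.id] = blends[r.id].cod_mass / vol_m3
    active = [b for b in blends.values() if b.total_volume > 0]
    wsum = sum(b.total_volume for b in active)
    if wsum > 0:
        avg_cn = sum(b.cn_ratio * b.total_volume for b in active) / wsum
        avg_alk = sum(b.alkalinity * b.total_volume for b in active) / wsum
    else:
        avg_cn = avg_alk = float("nan")
    return EvaluationResult(
        b_signed=b_signed,
        b_abs=b_abs,
        feasible=feasible,
        violations=violations,
        blends=blends,
        biogas_total=biogas,
        organic_load=loads,
        avg_cn=avg_cn,
        avg_alk=avg_alk,
        organic_load_derived=derived_any,
    )


def performance_summary(ev: EvaluationResult, net: CaseNetwork) -> dict[str, object]:
    """Flatten an evaluation into the standard performance-metric record."""
    loads = list(ev.organic_load.values())
    avg_load = sum(loads) / len(loads) if loads else float("nan")
    rec = {
        "best_index_b": ev.b_abs,
        "feasible": ev.feasible,
        "total_biogas_nm3_d": ev.biogas_total,
        "avg_organic_load_kg_cod_m3_d": avg_load,
        "avg_cn_ratio": ev.avg_cn,
        "avg_alkalinity_mg_l": ev.avg_alk,
        "organic_load_approximate": ev.organic_load_derived,
    }
    for rid, load in ev.organic_load.items():
        rec[f"organic_load_{rid}"] = load
    return rec
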
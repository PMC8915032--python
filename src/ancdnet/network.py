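"""Domain model of a centralised anaerobic co-digestion (AnCD) network.

A network couples *substrate generators* (undigested sewage sludge from
wastewater treatment plants, plus industrial organic wastes) with *receptors*
(WWTPs that operate anaerobic digesters with spare capacity) over a complete
bipartite graph.  The decision to optimise is how many litres per day each
generator ships to each receptor, with shipped volumes quantised to multiples
of a quantum ``q`` (1000 L by default).

This module holds the domain types, the discretisation of shippable volumes,
readers for the delimited case datasets (the Besòs river-basin case study is
bundled), and plain-text serialisation of allocations.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import NetworkLoadError, ValidationError

__all__ = [
    "SubstrateSource",
    "Receptor",
    "ConstraintBounds",
    "ObjectiveParams",
    "CaseNetwork",
    "Allocation",
    "volume_options",
    "load_case_network",
    "load_baseline",
    "write_allocation",
    "read_allocation",
]

_KINDS = ("sludge", "industrial")


@dataclass
class SubstrateSource:
    """One waste generator: characterisation, daily volume and route data.

    Parameters
    ----------
    id : str
        Unique generator label (e.g. ``"W1"`` or ``"C3"``).
    kind : {"sludge", "industrial"}
        Undigested sewage sludge from a WWTP, or an industrial substrate.
    daily_volume : float
        Available volume V_w in L/day.
    cod : float
        Chemical oxygen demand in mg O2/L (proxy for organic content).
    cn_ratio : float
        COD:TN ratio (dimensionless); total nitrogen is derived as
        ``cod / cn_ratio``.
    alkalinity : float
        Buffering capacity in mg CaCO3/L.
    toxicity : float
        Heavy-metal toxicity proxy in mg Pb/L.
    distance_km : mapping of receptor id -> km
        Road distance of the route to each receptor in the network.
    transport_cost_rate : float, default 1.0
        Economic cost of the route in currency per km (X_w).
    social_impact : int, default 1
        Social impact class of the route, 1 (low) to 3 (high) (I_w).
    """

    id: str
    kind: str
    daily_volume: float
    cod: float
    cn_ratio: float
    alkalinity: float
    toxicity: float
    distance_km: Mapping[str, float] = field(default_factory=dict)
    transport_cost_rate: float = 1.0
    social_impact: int = 1

    def __post_init__(self) -> None:
        self.distance_km = dict(self.distance_km)
        if self.kind not in _KINDS:
            raise ValidationError(f"source {self.id!r}: kind must be one of {_KINDS}, got {self.kind!r}")
        if not self.daily_volume > 0:
            raise ValidationError(f"source {self.id!r}: daily_volume must be > 0, got {self.daily_volume}")
        if not self.cod > 0:
            raise ValidationError(f"source {self.id!r}: cod must be > 0, got {self.cod}")
        if not self.cn_ratio > 0:
            raise ValidationError(f"source {self.id!r}: cn_ratio must be > 0, got {self.cn_ratio}")
        if self.alkalinity < 0:
            raise ValidationError(f"source {self.id!r}: alkalinity must be >= 0, got {self.alkalinity}")
        if self.toxicity < 0:
            raise ValidationError(f"source {self.id!r}: toxicity must be >= 0, got {self.toxicity}")
        for rid, d in self.distance_km.items():
            if not d > 0:
                raise ValidationError(f"source {self.id!r}: distance to {rid!r} must be > 0, got {d}")
        if self.social_impact not in (1, 2, 3):
            raise ValidationError(f"source {self.id!r}: social_impact must be 1, 2 or 3, got {self.social_impact}")

    @property
    def tn(self) -> float:
        """Total nitrogen concentration in mg N/L, derived from COD and C/N."""
        return self.cod / self.cn_ratio


@dataclass
class Receptor:
    """One anaerobic-digestion plant accepting external substrates.

    ``max_external_volume`` is the daily volume of external substrate the
    plant can accept on top of its own sludge stream.  The plant's own-sludge
    characterisation is kept so blends can optionally include it
    (``mixing="with_base"``) when its flow ``base_feed_volume`` is known.
    """

    id: str
    max_external_volume: float
    own_cod: float
    own_cn: float
    own_alk: float
    own_tox: float
    base_feed_volume: float | None = None
    digester_volume: float | None = None

    def __post_init__(self) -> None:
        if not self.max_external_volume > 0:
            raise ValidationError(f"receptor {self.id!r}: max_external_volume must be > 0")
        for name in ("own_cod", "own_cn", "own_alk", "own_tox"):
            if getattr(self, name) < 0:
                raise ValidationError(f"receptor {self.id!r}: {name} must be >= 0")
        for name in ("base_feed_volume", "digester_volume"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"receptor {self.id!r}: {name} must be > 0 when given, got {v}")


@dataclass
class ConstraintBounds:
    """Operational bounds on each receptor's blended feed.

    Defaults are the anaerobic-digestion safe-operation windows used
    throughout: COD/TN ratio within [20, 60] (ammonia inhibition below,
    nitrogen starvation above), alkalinity within [2500, 6000] mg CaCO3/L
    (pH buffering), and lead toxicity at most 2.1 mg Pb/L.
    """

    cn_min: float = 20.0
    cn_max: float = 60.0
    alk_min: float = 2500.0
    alk_max: float = 6000.0
    tox_max: float = 2.1

    def __post_init__(self) -> None:
        if not self.cn_min < self.cn_max:
            raise ValidationError("cn_min must be < cn_max")
        if not self.alk_min < self.alk_max:
            raise ValidationError("alk_min must be < alk_max")
        if not self.tox_max > 0:
            raise ValidationError("tox_max must be > 0")


@dataclass
class ObjectiveParams:
    """Weights and modes of the quality-plus-logistics cost index.

    rho_q and rho_x (both 0.5 by default) balance the substrate-quality term
    against the transport-logistics term.  ``K`` is a sign convention only:
    maximising solvers use +1, minimising solvers -1; the reported index B is
    the absolute value either way.

    ``quality_weight_mode`` applies rho_q as an exponent on the summed quality
    coefficients (default) or as a plain multiplier.  ``logistics_mode``
    selects whether the normalised logistics term is subtracted as a penalty
    (default) or added literally.  In penalty mode the raw logistics cost
    ``X_w * d * I_w`` is divided by ``logistics_ref`` (a fixed reference
    scale, by default the cost of a 100 km unit-rate low-impact route) so
    that stretching every route genuinely degrades the index; setting
    ``logistics_ref=None`` normalises by the network's own largest edge cost
    instead (scale-free).  ``quantum`` is the volume discretisation step q in
    litres.  ``biogas_yield`` converts removed COD mass to biogas volume
    (m3 per kg COD).
    """

    rho_q: float = 0.5
    rho_x: float = 0.5
    K: int = 1
    quality_weight_mode: str = "exponent"
    logistics_mode: str = "penalty"
    logistics_ref: float | None = 100.0
    quantum: float = 1000.0
    biogas_yield: float = 0.268
    # fallback-coefficient knobs (see objective.quality_coefficients)
    coefficient_mode: str = "fallback"
    cod_ref: float | None = None
    shoulder_frac: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.rho_q <= 1) or not (0 < self.rho_x <= 1):
            raise ValidationError("rho_q and rho_x must lie in (0, 1]")
        if self.K not in (-1, 1):
            raise ValidationError("K must be -1 or +1")
        if self.quality_weight_mode not in ("exponent", "multiplier"):
            raise ValidationError(f"unknown quality_weight_mode {self.quality_weight_mode!r}")
        if self.logistics_mode not in ("penalty", "literal"):
            raise ValidationError(f"unknown logistics_mode {self.logistics_mode!r}")
        if self.coefficient_mode not in ("fallback", "figure2"):
            raise ValidationError(f"unknown coefficient_mode {self.coefficient_mode!r}")
        if not self.quantum > 0:
            raise ValidationError("quantum must be > 0")
        if self.logistics_ref is not None and not self.logistics_ref > 0:
            raise ValidationError("logistics_ref must be > 0 when given")
        if not self.biogas_yield > 0:
            raise ValidationError("biogas_yield must be > 0")
        if not 0 <= self.shoulder_frac:
            raise ValidationError("shoulder_frac must be >= 0")


@dataclass
class CaseNetwork:
    """A complete bipartite generator/receptor network plus problem settings."""

    sources: list[SubstrateSource]
    receptors: list[Receptor]
    bounds: ConstraintBounds = field(default_factory=ConstraintBounds)
    params: ObjectiveParams = field(default_factory=ObjectiveParams)

    def __post_init__(self) -> None:
        sids = [s.id for s in self.sources]
        rids = [r.id for r in self.receptors]
        for ids, what in ((sids, "source"), (rids, "receptor")):
            dup = {i for i in ids if ids.count(i) > 1}
            if dup:
                raise ValidationError(f"duplicate {what} id(s): {sorted(dup)}")
        if set(sids) & set(rids):
            raise ValidationError("source and receptor ids overlap")
        for s in self.sources:
            missing = [rid for rid in rids if rid not in s.distance_km]
            if missing:
                raise ValidationError(f"source {s.id!r}: missing distance to receptor(s) {missing}")

    # -- conveniences -----------------------------------------------------
    @property
    def source_ids(self) -> list[str]:
        return [s.id for s in self.sources]

    @property
    def receptor_ids(self) -> list[str]:
        return [r.id for r in self.receptors]

    @property
    def n_edges(self) -> int:
        return len(self.sources) * len(self.receptors)

    def edges(self) -> Iterator[tuple[str, str]]:
        """Edges in source-major order: (w0,r0), (w0,r1), ..., (w1,r0), ..."""
        for s in self.sources:
            for r in self.receptors:
                yield (s.id, r.id)

    def get_source(self, sid: str) -> SubstrateSource:
        for s in self.sources:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_receptor(self, rid: str) -> Receptor:
        for r in self.receptors:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def source_map(self) -> dict[str, SubstrateSource]:
        return {s.id: s for s in self.sources}


def volume_options(source: SubstrateSource, quantum: float) -> tuple[float, ...]:
    """Discrete volumes (L/day) that may be shipped from ``source`` per edge.

    Returns ``(0, q, 2q, ..., l_w*q)`` with ``l_w = floor(V_w / q)``; when the
    available volume V_w is not an exact multiple of the quantum, V_w itself
    is appended as a final partial step so full utilisation of the generator
    stays representable.  The result is strictly increasing and ends at V_w.
    """
    if not quantum > 0:
        raise ValidationError("quantum must be > 0")
    v_w = source.daily_volume
    if not v_w > 0:
        raise ValidationError(f"source {source.id!r}: daily_volume must be > 0")
    l_w = int(math.floor(v_w / quantum + 1e-9))
    opts = [i * quantum for i in range(l_w + 1)]
    if opts[-1] < v_w - 1e-9 * max(1.0, v_w):
        opts.append(v_w)
    else:
        opts[-1] = v_w  # absorb rounding: last multiple == V_w
    return tuple(opts)


@dataclass
class Allocation:
    """The decision variable: volume (L/day) shipped per (source, receptor).

    Zero entries are equivalent to absent entries; equality compares the
    non-zero maps only.
    """

    volume: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (sid, rid), v in self.volume.items():
            if v < 0:
                raise ValidationError(f"allocation ({sid}, {rid}): volume must be >= 0, got {v}")

    def get(self, sid: str, rid: str) -> float:
        return self.volume.get((sid, rid), 0.0)

    def nonzero(self) -> dict[tuple[str, str], float]:
        return {k: v for k, v in self.volume.items() if v != 0.0}

    def total_from_source(self, sid: str) -> float:
        return sum(v for (s, _), v in self.volume.items() if s == sid)

    def total_to_receptor(self, rid: str) -> float:
        return sum(v for (_, r), v in self.volume.items() if r == rid)

    @property
    def total_volume(self) -> float:
        return sum(self.volume.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Allocation):
            return NotImplemented
        return self.nonzero() == other.nonzero()

    def validate_against(self, net: CaseNetwork) -> None:
        """Check ids, option-set membership and per-source conservation."""
        sids = set(net.source_ids)
        rids = set(net.receptor_ids)
        opts = {s.id: volume_options(s, net.params.quantum) for s in net.sources}
        for (sid, rid), v in self.volume.items():
            if sid not in sids:
                raise ValidationError(f"allocation references unknown source {sid!r}")
            if rid not in rids:
                raise ValidationError(f"allocation references unknown receptor {rid!r}")
            if not any(math.isclose(v, o, rel_tol=1e-9, abs_tol=1e-6) for o in opts[sid]):
                raise ValidationError(
                    f"allocation ({sid}, {rid}): volume {v} is not in the discrete option set"
                )
        for s in net.sources:
            tot = self.total_from_source(s.id)
            if tot > s.daily_volume * (1 + 1e-9) + 1e-6:
                raise ValidationError(
                    f"source {s.id!r}: total allocated {tot} exceeds available {s.daily_volume}"
                )

    @classmethod
    def from_indices(cls, net: CaseNetwork, indices: Iterable[int]) -> "Allocation":
        """Build an allocation from per-edge option indices (edge order = ``net.edges()``)."""
        idx = list(indices)
        if len(idx) != net.n_edges:
            raise ValidationError(f"expected {net.n_edges} option indices, got {len(idx)}")
        opts = {s.id: volume_options(s, net.params.quantum) for s in net.sources}
        vol: dict[tuple[str, str], float] = {}
        for (sid, rid), i in zip(net.edges(), idx):
            v = opts[sid][i]
            if v:
                vol[(sid, rid)] = v
        return cls(vol)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_GEN_REQUIRED = ["id", "kind", "volume_l_per_day", "cod_mg_l", "cn_ratio", "alk_mg_l", "tox_mg_l"]
_REC_REQUIRED = ["id", "max_volume_l_per_day", "cod_mg_l", "cn_ratio", "alk_mg_l", "tox_mg_l"]


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    try:
        return pd.to_numeric(df[col])
    except (ValueError, TypeError) as exc:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.iloc[0]["id"] if len(bad) else "?"
        raise NetworkLoadError(f"{what}: non-numeric value in column {col!r} (row id {row!r})") from exc


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, skipinitialspace=True, float_precision="round_trip")
    except FileNotFoundError:
        raise NetworkLoadError(f"{what}: file not found: {path}")
    except Exception as exc:  # malformed CSV
        raise NetworkLoadError(f"{what}: cannot parse {path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    return df


def load_case_network(
    path: str | Path,
    bounds: ConstraintBounds | None = None,
    params: ObjectiveParams | None = None,
    *,
    receptors_path: str | Path | None = None,
) -> CaseNetwork:
    """Read a case dataset from delimited text into a validated network.

    Two dialects are accepted:

    * **two tables** — ``path`` holds one generator per row with columns
      ``id, kind, volume_l_per_day, cod_mg_l, cn_ratio, alk_mg_l, tox_mg_l``
      plus one ``dist_<receptor-id>_km`` column per receptor and optional
      ``x_cost_per_km`` / ``social_impact`` columns; ``receptors_path`` holds
      the receptor table (``id, max_volume_l_per_day, cod_mg_l, cn_ratio,
      alk_mg_l, tox_mg_l`` plus optional ``base_feed_l_per_day`` /
      ``digester_m3``).  When ``receptors_path`` is omitted, a sibling file
      named ``<stem>_receptors.csv`` is looked up.
    * **single table** — receptor rows appended to the generator table with
      ``kind == "receptor"`` (their ``volume_l_per_day`` column carries the
      maximum acceptable external volume and distance cells are empty).

    Row order is preserved.  Any missing column, non-numeric cell, duplicate
    id or missing distance raises :class:`NetworkLoadError` naming the row
    and column.
    """
    path = Path(path)
    gens = _read_table(path, "generator table")
    rec_df: pd.DataFrame | None = None

    if "kind" in gens.columns and (gens["kind"].astype(str).str.strip() == "receptor").any():
        mask = gens["kind"].astype(str).str.strip() == "receptor"
        rec_df = gens[mask].rename(columns={"volume_l_per_day": "max_volume_l_per_day"})
        gens = gens[~mask].reset_index(drop=True)
    elif receptors_path is not None:
        rec_df = _read_table(receptors_path, "receptor table")
    else:
        sibling = path.with_name(path.stem + "_receptors" + path.suffix)
        alt = path.with_name(path.stem.replace("_generators", "_receptors") + path.suffix)
        for cand in (alt, sibling):
            if cand != path and cand.exists():
                rec_df = _read_table(cand, "receptor table")
                break
        if rec_df is None:
            raise NetworkLoadError(
                f"no receptor table: pass receptors_path= or place {sibling.name} next to {path.name}"
            )

    for col in _GEN_REQUIRED:
        if col not in gens.columns:
            raise NetworkLoadError(f"generator table: missing column {col!r}")
    for col in _REC_REQUIRED:
        if col not in rec_df.columns:
            raise NetworkLoadError(f"receptor table: missing column {col!r}")

    rids = [str(x).strip() for x in rec_df["id"]]
    dist_cols = {rid: f"dist_{rid}_km" for rid in rids}
    for rid, col in dist_cols.items():
        if col not in gens.columns:
            raise NetworkLoadError(f"generator table: missing distance column {col!r} for receptor {rid!r}")

    for col in _GEN_REQUIRED[2:] + list(dist_cols.values()):
        gens[col] = _numeric(gens, col, "generator table")
    for col in _REC_REQUIRED[1:]:
        rec_df[col] = _numeric(rec_df, col, "receptor table")

    try:
        sources = []
        for _, row in gens.iterrows():
            dist = {rid: float(row[col]) for rid, col in dist_cols.items()}
            if any(pd.isna(v) for v in dist.values()):
                raise NetworkLoadError(f"generator table: missing distance for row id {row['id']!r}")
            sources.append(
                SubstrateSource(
                    id=str(row["id"]).strip(),
                    kind=str(row["kind"]).strip(),
                    daily_volume=float(row["volume_l_per_day"]),
                    cod=float(row["cod_mg_l"]),
                    cn_ratio=float(row["cn_ratio"]),
                    alkalinity=float(row["alk_mg_l"]),
                    toxicity=float(row["tox_mg_l"]),
                    distance_km=dist,
                    transport_cost_rate=float(row.get("x_cost_per_km", 1.0))
                    if "x_cost_per_km" in gens.columns and not pd.isna(row.get("x_cost_per_km"))
                    else 1.0,
                    social_impact=int(row.get("social_impact", 1))
                    if "social_impact" in gens.columns and not pd.isna(row.get("social_impact"))
                    else 1,
                )
            )
        receptors = []
        for _, row in rec_df.iterrows():
            def _opt(col: str) -> float | None:
                if col in rec_df.columns and not pd.isna(row.get(col)):
                    return float(row[col])
                return None

            receptors.append(
                Receptor(
                    id=str(row["id"]).strip(),
                    max_external_volume=float(row["max_volume_l_per_day"]),
                    own_cod=float(row["cod_mg_l"]),
                    own_cn=float(row["cn_ratio"]),
                    own_alk=float(row["alk_mg_l"]),
                    own_tox=float(row["tox_mg_l"]),
                    base_feed_volume=_opt("base_feed_l_per_day"),
                    digester_volume=_opt("digester_m3"),
                )
            )
        return CaseNetwork(
            sources=sources,
            receptors=receptors,
            bounds=bounds if bounds is not None else ConstraintBounds(),
            params=params if params is not None else ObjectiveParams(),
        )
    except ValidationError as exc:
        raise NetworkLoadError(str(exc)) from exc


def load_baseline(
    bounds: ConstraintBounds | None = None, params: ObjectiveParams | None = None
) -> CaseNetwork:
    """Load the bundled Besòs river-basin case study (19 generators, 3 receptors)."""
    data = importlib.resources.files("ancdnet") / "data"
    return load_case_network(
        Path(str(data / "besos_generators.csv")),
        bounds,
        params,
        receptors_path=Path(str(data / "besos_receptors.csv")),
    )


def write_network(net: CaseNetwork, generators_path: str | Path, receptors_path: str | Path) -> None:
    """Write a network back to the two-table CSV dialect (lossless)."""
    rows = []
    for s in net.sources:
        row = {
            "id": s.id,
            "kind": s.kind,
            "volume_l_per_day": s.daily_volume,
            "cod_mg_l": s.cod,
            "cn_ratio": s.cn_ratio,
            "alk_mg_l": s.alkalinity,
            "tox_mg_l": s.toxicity,
        }
        for rid in net.receptor_ids:
            row[f"dist_{rid}_km"] = s.distance_km[rid]
        row["x_cost_per_km"] = s.transport_cost_rate
        row["social_impact"] = s.social_impact
        rows.append(row)
    pd.DataFrame(rows).to_csv(generators_path, index=False, float_format="%.17g")
    rrows = []
    for r in net.receptors:
        rrow = {
            "id": r.id,
            "max_volume_l_per_day": r.max_external_volume,
            "cod_mg_l": r.own_cod,
            "cn_ratio": r.own_cn,
            "alk_mg_l": r.own_alk,
            "tox_mg_l": r.own_tox,
        }
        if r.base_feed_volume is not None:
            rrow["base_feed_l_per_day"] = r.base_feed_volume
        if r.digester_volume is not None:
            rrow["digester_m3"] = r.digester_volume
        rrows.append(rrow)
    pd.DataFrame(rrows).to_csv(receptors_path, index=False, float_format="%.17g")


def write_allocation(a: Allocation, path: str | Path, net: CaseNetwork) -> None:
    """Serialise an allocation to a JSON file, refusing invalid allocations."""
    a.validate_against(net)
    entries = [
        {"source": sid, "receptor": rid, "volume_l_per_day": v}
        for (sid, rid), v in sorted(a.volume.items())
    ]
    payload = {"format": "ancdnet-allocation", "version": 1, "entries": entries}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_allocation(path: str | Path, net: CaseNetwork) -> Allocation:
    """Read an allocation written by :func:`write_allocation` and validate it."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise NetworkLoadError(f"cannot read allocation file {path}: {exc}") from exc
    vol: dict[tuple[str, str], float] = {}
    for e in payload.get("entries", []):
        vol[(str(e["source"]), str(e["receptor"]))] = float(e["volume_l_per_day"])
    a = Allocation(vol)
    a.validate_against(net)
    return a
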
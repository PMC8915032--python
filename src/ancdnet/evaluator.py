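"""Vectorised batch evaluation of candidate allocations.

The metaheuristics evaluate whole populations per iteration; doing that
through the per-allocation public API would dominate run time.  This module
precomputes the network as flat arrays (edge order matching
``CaseNetwork.edges()``: source-major, so a population matrix of shape
(P, E) reshapes to (P, S, R)) and evaluates P candidates in a handful of
numpy operations.  Results agree with the readable single-allocation path in
:mod:`ancdnet.objective`; the test suite asserts the two routes match.

It also hosts the volume-repair decode used by the solvers: candidate
volumes are scaled down to satisfy the per-source availability and the
per-receptor acceptance caps, then snapped down onto the discrete option
grid.  Repair never increases any volume, is deterministic, and leaves
already-volume-feasible candidates untouched.
"""

from __future__ import annotations

import numpy as np

from .network import Allocation, CaseNetwork, volume_options
from .objective import edge_coefficients

__all__ = ["VectorEvaluator"]

_REL_TOL = 1e-9


class VectorEvaluator:
    """Precompiled view of a :class:`CaseNetwork` for population evaluation."""

    def __init__(self, net: CaseNetwork, mixing: str = "external_only"):
        self.net = net
        self.mixing = mixing
        S, R = len(net.sources), len(net.receptors)
        self.S, self.R, self.E = S, R, S * R

        opts = [np.asarray(volume_options(s, net.params.quantum), dtype=float) for s in net.sources]
        self.n_options_per_source = np.array([len(o) for o in opts])
        smax = int(self.n_options_per_source.max())
        # pad by repeating the last (largest) option so clipped indices stay valid
        self.option_values = np.stack(
            [np.pad(o, (0, smax - len(o)), mode="edge") for o in opts]
        )  # (S, smax)
        self.n_options = np.repeat(self.n_options_per_source, R)  # per edge (E,)
        self.edge_options = np.repeat(self.option_values, R, axis=0)  # (E, smax)

        self.v_max = np.array([s.daily_volume for s in net.sources])          # (S,)
        self.cod = np.array([s.cod for s in net.sources])                     # mg/L
        self.tn = np.array([s.cod / s.cn_ratio for s in net.sources])         # mg N/L
        self.alk = np.array([s.alkalinity for s in net.sources])
        self.tox = np.array([s.toxicity for s in net.sources])
        self.caps = np.array([r.max_external_volume for r in net.receptors])  # (R,)
        self.quantum = net.params.quantum

        coefs = edge_coefficients(net)
        c = np.array([coefs[e] for e in net.edges()])                          # (E,)
        self.edge_weight = (c / np.repeat(self.v_max, R)).reshape(S, R)        # term = v * weight

        b = net.bounds
        self.bounds = b
        if mixing == "with_base":
            bv = np.array([r.base_feed_volume or 0.0 for r in net.receptors])
            self.base_v = bv
            self.base_cod_mass = bv * np.array([r.own_cod for r in net.receptors]) * 1e-6
            own_cn = np.array([max(r.own_cn, 1e-300) for r in net.receptors])
            self.base_tn_mass = bv * np.array([r.own_cod for r in net.receptors]) / own_cn * 1e-6
            self.base_alk_v = bv * np.array([r.own_alk for r in net.receptors])
            self.base_tox_v = bv * np.array([r.own_tox for r in net.receptors])
        else:
            self.base_v = np.zeros(R)
            self.base_cod_mass = np.zeros(R)
            self.base_tn_mass = np.zeros(R)
            self.base_alk_v = np.zeros(R)
            self.base_tox_v = np.zeros(R)

    # -- genotype handling ------------------------------------------------
    def random_indices(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform random option-index matrix of shape (n, E)."""
        return (rng.random((n, self.E)) * self.n_options).astype(np.int64)

    def decode(self, indices: np.ndarray) -> np.ndarray:
        """Option indices (P, E) -> volumes (P, S, R)."""
        idx = np.minimum(np.atleast_2d(indices), self.n_options - 1)
        P = idx.shape[0]
        vol = self.edge_options[np.arange(self.E)[None, :], idx]
        return vol.reshape(P, self.S, self.R)

    def snap_down(self, vol: np.ndarray) -> np.ndarray:
        """Largest option value <= vol, per source (vol shape (P, S, R))."""
        vmax = self.v_max[None, :, None]
        grid = np.floor(vol / self.quantum + 1e-12) * self.quantum
        return np.where(vol >= vmax * (1 - 1e-12), vmax, np.minimum(grid, vmax))

    def repair(self, vol: np.ndarray) -> np.ndarray:
        """Scale volumes down to the volume constraints and re-grid them."""
        vol = vol.copy()
        s_tot = vol.sum(axis=2)  # (P, S)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(s_tot > self.v_max[None, :], self.v_max[None, :] / s_tot, 1.0)
        vol *= f[:, :, None]
        vol = self.snap_down(vol)
        r_tot = vol.sum(axis=1) + self.base_v[None, :]  # (P, R)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(r_tot > self.caps[None, :], self.caps[None, :] / r_tot, 1.0)
        vol *= g[:, None, :]
        return self.snap_down(vol)

    def volumes_to_indices(self, vol: np.ndarray) -> np.ndarray:
        """Volumes (S, R) -> option indices (E,), exact grid values assumed."""
        flat = vol.reshape(self.E)
        idx = np.empty(self.E, dtype=np.int64)
        for e in range(self.E):
            opts = self.edge_options[e, : self.n_options[e]]
            idx[e] = int(np.argmin(np.abs(opts - flat[e])))
        return idx

    def to_allocation(self, vol: np.ndarray) -> Allocation:
        """Volumes (S, R) -> public :class:`Allocation`."""
        volume: dict[tuple[str, str], float] = {}
        for i, s in enumerate(self.net.sources):
            for j, r in enumerate(self.net.receptors):
                v = float(vol[i, j])
                if v != 0.0:
                    volume[(s.id, r.id)] = v
        return Allocation(volume)

    def from_allocation(self, a: Allocation) -> np.ndarray:
        vol = np.zeros((self.S, self.R))
        sidx = {s.id: i for i, s in enumerate(self.net.sources)}
        ridx = {r.id: j for j, r in enumerate(self.net.receptors)}
        for (sid, rid), v in a.volume.items():
            vol[sidx[sid], ridx[rid]] = v
        return vol

    # -- batch evaluation -------------------------------------------------
    def evaluate(self, vol: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluate volumes (P, S, R): index, feasibility, violation mass.

        Returns arrays keyed ``b_abs``, ``feasible``, ``viol_sum`` (sum of
        bound-normalised violation magnitudes, for the linear penalty) and
        ``total_volume``.
        """
        b = self.bounds
        b_abs = np.abs(np.einsum("psr,sr->p", vol, self.edge_weight))

        s_tot = vol.sum(axis=2)                                  # (P, S)
        r_tot = vol.sum(axis=1) + self.base_v[None, :]           # (P, R)
        cod_mass = np.einsum("psr,s->pr", vol, self.cod) * 1e-6 + self.base_cod_mass
        tn_mass = np.einsum("psr,s->pr", vol, self.tn) * 1e-6 + self.base_tn_mass
        alk_v = np.einsum("psr,s->pr", vol, self.alk) + self.base_alk_v
        tox_v = np.einsum("psr,s->pr", vol, self.tox) + self.base_tox_v

        active = r_tot > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            cn = np.where(tn_mass > 0, cod_mass / np.where(tn_mass > 0, tn_mass, 1.0), np.inf)
            alk = np.where(active, alk_v / np.where(active, r_tot, 1.0), 0.0)
            tox = np.where(active, tox_v / np.where(active, r_tot, 1.0), 0.0)

        def _excess(obs: np.ndarray, bound: float, above: bool) -> np.ndarray:
            tol = abs(bound) * _REL_TOL
            d = (obs - bound - tol) if above else (bound - tol - obs)
            return np.maximum(d, 0.0) / max(abs(bound), 1.0)

        cap_exc = np.maximum(r_tot - self.caps[None, :] * (1 + _REL_TOL), 0.0) / self.caps[None, :]
        src_exc = np.maximum(s_tot - self.v_max[None, :] * (1 + _REL_TOL), 0.0) / self.v_max[None, :]
        cn_hi = np.where(active, _excess(cn, b.cn_max, True), 0.0)
        cn_lo = np.where(active, _excess(cn, b.cn_min, False), 0.0)
        alk_hi = np.where(active, _excess(alk, b.alk_max, True), 0.0)
        alk_lo = np.where(active, _excess(alk, b.alk_min, False), 0.0)
        tox_hi = np.where(active, _excess(tox, b.tox_max, True), 0.0)
        # infinite C/N (zero nitrogen): count as a pure cn_max violation of unit magnitude
        cn_hi = np.where(np.isinf(cn_hi), 1.0, cn_hi)

        viol = (
            cap_exc.sum(axis=1)
            + src_exc.sum(axis=1)
            + cn_hi.sum(axis=1)
            + cn_lo.sum(axis=1)
            + alk_hi.sum(axis=1)
            + alk_lo.sum(axis=1)
            + tox_hi.sum(axis=1)
        )
        feasible = viol == 0.0
        return {
            "b_abs": b_abs,
            "feasible": feasible,
            "viol_sum": viol,
            "total_volume": vol.sum(axis=(1, 2)),
        }

    def fitness(self, res: dict[str, np.ndarray], penalty: str, lam: float = 1.0) -> np.ndarray:
        """Penalty-adjusted fitness: death -> 0 when infeasible; linear ->
        ``max(0, b_abs - lam * viol_sum)``."""
        if penalty == "death":
            return np.where(res["feasible"], res["b_abs"], 0.0)
        return np.maximum(0.0, res["b_abs"] - lam * res["viol_sum"])
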
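"""Agent-based immune core: state container and the per-timestep update rule.

The simulated immune system lives on two toroidal 2-D grids (PERIPHERY
and WHITE_MATTER).  Individually tracked cell agents move, interact
through bit-string receptor binding, secrete and sense cytokine fields,
proliferate, die and are replenished by hematopoiesis with thymic
selection.  One timestep is one simulated day.

Phase order within a step is fixed:

    movement (incl. periphery -> white-matter migration)
    -> receptor-mediated interactions (presentation, activation,
       suppression, viral clearance, autoimmune attack)
    -> secretion
    -> cytokine diffusion and decay
    -> class switch and duplication
    -> aging and death (incl. drug-induced depletion, remyelination)
    -> hematopoiesis

All stochastic draws come from ``state.rng`` and nothing else, so a
(seed, params) pair fully determines the trajectory.
"""

from __future__ import annotations

import numpy as np

from .agents import AgentPool, CellState, CellType, Compartment, Isotype, LYMPHOCYTES, T_LINEAGES
from .params import EngineParams
from .receptors import binds_many, near_complement, random_receptors, thymic_selection

__all__ = ["SimState", "make_initial_state", "step", "hematopoiesis", "run_steps",
           "TRAJ_COLUMNS", "counts_by_lineage_comp"]

# cytokine species indices
IL2, IFNG, TGFB = 0, 1, 2

# enum values hoisted to plain ints for the hot loop
_B, _TH, _TREG, _CTL, _NK, _APC, _PLASMA = (int(c) for c in CellType)
_RESTING, _ACTIVATED, _DUPLICATING, _ANERGIC = (
    int(CellState.RESTING), int(CellState.ACTIVATED),
    int(CellState.DUPLICATING), int(CellState.ANERGIC))
_P, _WM = int(Compartment.PERIPHERY), int(Compartment.WHITE_MATTER)

#: Column order of the per-step trajectory record.
TRAJ_COLUMNS = ("oligo", "kills", "B", "TH", "IL2", "IFNG", "TGFB", "IgM", "IgG", "IgA")

_N_TYPES = len(CellType)
_N_STATES = len(CellState)


def _neighbor_table(side: int) -> np.ndarray:
    """(side*side, 4) int16 table of torus neighbours (N, S, W, E)."""
    n = side * side
    idx = np.arange(n)
    r, c = idx // side, idx % side
    out = np.empty((n, 4), dtype=np.int16)
    out[:, 0] = ((r - 1) % side) * side + c
    out[:, 1] = ((r + 1) % side) * side + c
    out[:, 2] = r * side + (c - 1) % side
    out[:, 3] = r * side + (c + 1) % side
    return out


class SimState:
    """Full simulation state of one digital patient.

    Attributes are mutated in place by :func:`step`; the same object is
    returned for chaining.  ``modifiers`` holds the per-step treatment
    multipliers (all neutral in a treatment-naive run).
    """

    def __init__(self, params: EngineParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.time = 0
        self.pool = AgentPool()
        self.nbr = _neighbor_table(params.grid_side)
        ns_ = params.n_sites
        self._cyt_nbr = np.concatenate(
            [self.nbr.astype(np.int64), self.nbr.astype(np.int64) + ns_])
        ns = params.n_sites
        self.cyt = np.zeros((3, 2 * ns), dtype=np.float64)  # species x (comp*ns + site)
        self.ab_titer = np.zeros(3, dtype=np.float64)       # IgM, IgG, IgA
        # oligodendrocytes (white matter)
        self.oligo_site = np.zeros(params.n_oligo, dtype=np.int16)
        self.oligo_alive = np.ones(params.n_oligo, dtype=bool)
        self.oligo_per_site = np.bincount(
            self.oligo_site, minlength=ns).astype(np.int32)
        # pathology scalars
        self.viral_load = 0.0
        self.viral_antigen: int | None = None
        self.debris = 0.0
        self.ebv_fired = False
        self.kills_this_step = 0
        self.hematopoiesis_enabled = True
        # treatment modifiers, neutral by default
        self.modifiers = {
            "mig_factor": 1.0,        # natalizumab: scales periphery->WM migration
            "act_factor": 1.0,        # IFNb-1a: scales lymphocyte activation
            "dup_factor": 1.0,        # IFNb-1a: scales duplication
            "dup_factor_activated": 1.0,  # teriflunomide: duplication of activated cells
            "tgfb_factor": 1.0,       # IFNb-1a: scales TGF-b secretion
            "b_kill_prob": 0.0,       # ocrelizumab: per-step B depletion probability
        }
        # bookkeeping of the last executed step: (cell type, compartment) ints
        self.log_births = np.zeros((_N_TYPES, 2), dtype=np.int64)
        self.log_deaths = np.zeros((_N_TYPES, 2), dtype=np.int64)
        self.log_emigration = np.zeros((_N_TYPES, 2), dtype=np.int64)
        self.log_immigration = np.zeros((_N_TYPES, 2), dtype=np.int64)
        self.log_switch_out = np.zeros((_N_TYPES, 2), dtype=np.int64)
        self.log_switch_in = np.zeros((_N_TYPES, 2), dtype=np.int64)
        # per-state death probability table
        self._death_table = self._build_death_table(params)

    @staticmethod
    def _build_death_table(p: EngineParams) -> np.ndarray:
        t = np.zeros((_N_TYPES, _N_STATES), dtype=np.float64)
        t[:, CellState.RESTING] = p.death_resting
        t[:, CellState.ACTIVATED] = p.death_activated
        t[:, CellState.DUPLICATING] = p.death_activated
        t[:, CellState.ANERGIC] = p.death_anergic
        t[CellType.PLASMA, CellState.RESTING] = p.death_plasma
        return t

    # -- helpers ----------------------------------------------------------

    def flatpos(self, idx: np.ndarray) -> np.ndarray:
        """Flat (compartment, site) position index into cytokine rows."""
        return self.pool.comp[idx].astype(np.int64) * self.params.n_sites + self.pool.site[idx]

    def observables(self) -> dict[str, float]:
        counts = np.bincount(self.pool.ctype[self.pool.alive], minlength=_N_TYPES)
        return {
            "oligo": int(self.oligo_alive.sum()),
            "kills": self.kills_this_step,
            "B": int(counts[CellType.B]),
            "TH": int(counts[CellType.TH]),
            "IL2": float(self.cyt[IL2].sum()),
            "IFNG": float(self.cyt[IFNG].sum()),
            "TGFB": float(self.cyt[TGFB].sum()),
            "IgM": float(self.ab_titer[Isotype.IGM]),
            "IgG": float(self.ab_titer[Isotype.IGG]),
            "IgA": float(self.ab_titer[Isotype.IGA]),
        }

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable snapshot (alive agents only)."""
        pool = self.pool
        idx = np.flatnonzero(pool.alive)
        return {
            "time": self.time,
            "params": self.params.as_dict(),
            "rng_state": self.rng.bit_generator.state,
            "pool_capacity": pool.cap,
            "pool_free": pool._free[: pool._nfree].tolist(),
            "agents": {
                "slot": idx.tolist(),
                "agent_id": pool.agent_id[idx].tolist(),
                "ctype": pool.ctype[idx].tolist(),
                "state": pool.state[idx].tolist(),
                "comp": pool.comp[idx].tolist(),
                "site": pool.site[idx].tolist(),
                "receptor": pool.receptor[idx].tolist(),
                "age": pool.age[idx].tolist(),
                "act_age": pool.act_age[idx].tolist(),
                "isotype": pool.isotype[idx].tolist(),
            },
            "next_agent_id": pool._next_id,
            "cytokines": self.cyt.tolist(),
            "ab_titer": self.ab_titer.tolist(),
            "oligo_site": self.oligo_site.tolist(),
            "oligo_alive": self.oligo_alive.tolist(),
            "viral_load": self.viral_load,
            "viral_antigen": self.viral_antigen,
            "debris": self.debris,
            "ebv_fired": self.ebv_fired,
            "hematopoiesis_enabled": self.hematopoiesis_enabled,
            "modifiers": dict(self.modifiers),
        }

    @classmethod
    def from_dict(cls, snap: dict) -> "SimState":
        params = EngineParams(snap["params"])
        rng = np.random.default_rng()
        rng.bit_generator.state = snap["rng_state"]
        st = cls(params, rng)
        st.time = snap["time"]
        ag = snap["agents"]
        pool = st.pool
        if snap["pool_capacity"] > pool.cap:
            pool._grow(snap["pool_capacity"] - pool.cap)
        # restore the exact slot layout: vectorised updates iterate slots in
        # index order, so layout is part of the reproducibility contract
        slots = np.asarray(ag["slot"], dtype=np.int64)
        pool.alive[:] = False
        pool.alive[slots] = True
        pool.agent_id[slots] = ag["agent_id"]
        pool.ctype[slots] = np.asarray(ag["ctype"], dtype=np.int8)
        pool.state[slots] = np.asarray(ag["state"], dtype=np.int8)
        pool.comp[slots] = np.asarray(ag["comp"], dtype=np.int8)
        pool.site[slots] = np.asarray(ag["site"], dtype=np.int16)
        pool.receptor[slots] = np.asarray(ag["receptor"], dtype=np.uint64)
        pool.age[slots] = np.asarray(ag["age"], dtype=np.int32)
        pool.act_age[slots] = np.asarray(ag["act_age"], dtype=np.int32)
        pool.isotype[slots] = np.asarray(ag["isotype"], dtype=np.int8)
        free = np.asarray(snap["pool_free"], dtype=np.int64)
        pool._free = free.copy()
        pool._nfree = len(free)
        pool._next_id = snap["next_agent_id"]
        st.cyt = np.asarray(snap["cytokines"], dtype=np.float64)
        st.ab_titer = np.asarray(snap["ab_titer"], dtype=np.float64)
        st.oligo_site = np.asarray(snap["oligo_site"], dtype=np.int16)
        st.oligo_alive = np.asarray(snap["oligo_alive"], dtype=bool)
        st.oligo_per_site = np.bincount(
            st.oligo_site[st.oligo_alive], minlength=params.n_sites
        ).astype(np.int32)
        st.viral_load = snap["viral_load"]
        st.viral_antigen = snap["viral_antigen"]
        st.debris = snap["debris"]
        st.ebv_fired = snap["ebv_fired"]
        st.hematopoiesis_enabled = snap["hematopoiesis_enabled"]
        st.modifiers.update(snap["modifiers"])
        st._refresh_binding()
        return st

    def _refresh_binding(self) -> None:
        """Recompute cached antigen-binding flags for all alive agents."""
        p = self.params
        idx = np.flatnonzero(self.pool.alive)
        rec = self.pool.receptor[idx]
        self.pool.binds_self[idx] = binds_many(rec, p.self_antigen, p.receptor_length,
                                               p.bind_threshold)
        if self.viral_antigen is not None:
            self.pool.binds_viral[idx] = binds_many(rec, self.viral_antigen,
                                                    p.receptor_length, p.bind_threshold)


def _setpoints(p: EngineParams) -> np.ndarray:
    sp = np.zeros(_N_TYPES, dtype=np.float64)
    sp[CellType.B] = p.setpoint_B
    sp[CellType.TH] = p.setpoint_TH
    sp[CellType.TREG] = p.setpoint_TREG
    sp[CellType.CTL] = p.setpoint_CTL
    sp[CellType.NK] = p.setpoint_NK
    sp[CellType.APC] = p.setpoint_APC
    return sp


def _draw_receptors(state: SimState, ctype: int, n: int) -> np.ndarray:
    """Birth receptors: uniform repertoire with an autoreactive bias for
    B/TH/CTL, then thymic negative selection for T lineages (rejected
    receptors are resampled so the requested cohort size is preserved)."""
    p = state.params
    rng = state.rng
    if ctype in (CellType.NK, CellType.APC):
        return np.zeros(n, dtype=np.uint64)
    out = np.empty(n, dtype=np.uint64)
    need = n
    while need > 0:
        rec = random_receptors(rng, need, p.receptor_length)
        if ctype in (CellType.B, CellType.TH, CellType.CTL) and p.p_auto > 0:
            bias = rng.random(need) < p.p_auto
            nb = int(bias.sum())
            if nb:
                rec[bias] = near_complement(rng, p.self_antigen, p.receptor_length, nb)
        if ctype in T_LINEAGES:
            ok = thymic_selection(rec, [p.self_antigen], p.receptor_length,
                                  p.neg_threshold)
            rec = rec[ok]
        got = len(rec)
        out[n - need : n - need + got] = rec
        need -= got
    return out


def _spawn_cohort(state: SimState, ctype: int, n: int, comp: int,
                  state_enum: int = CellState.RESTING,
                  ages: np.ndarray | int = 0) -> np.ndarray:
    p = state.params
    sites = state.rng.integers(0, p.n_sites, size=n).astype(np.int16)
    rec = _draw_receptors(state, ctype, n)
    slots = state.pool.spawn(ctype=ctype, comp=comp, site=sites, receptor=rec,
                             state=state_enum, age=ages)
    state.pool.binds_self[slots] = binds_many(rec, p.self_antigen, p.receptor_length,
                                              p.bind_threshold)
    if state.viral_antigen is not None:
        state.pool.binds_viral[slots] = binds_many(rec, state.viral_antigen,
                                                   p.receptor_length, p.bind_threshold)
    return slots


def make_initial_state(params: EngineParams, rng: np.random.Generator | int) -> SimState:
    """Immune system at its homeostatic set-points, no pathology yet."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    st = SimState(params, rng)
    sp = _setpoints(params)
    for ct in LYMPHOCYTES:
        n = int(sp[ct])
        if n:
            ages = rng.geometric(params.death_resting, size=n).astype(np.int32)
            _spawn_cohort(st, ct, n, Compartment.PERIPHERY, ages=ages)
    st.oligo_site = rng.integers(0, params.n_sites, size=params.n_oligo).astype(np.int16)
    st.oligo_alive = np.ones(params.n_oligo, dtype=bool)
    st.oligo_per_site = np.bincount(st.oligo_site, minlength=params.n_sites).astype(np.int32)
    return st


def counts_by_lineage_comp(pool: AgentPool) -> np.ndarray:
    """(n_types, 2) alive-agent counts, for conservation bookkeeping."""
    idx = np.flatnonzero(pool.alive)
    flat = pool.ctype[idx].astype(np.int64) * 2 + pool.comp[idx]
    return np.bincount(flat, minlength=_N_TYPES * 2).reshape(_N_TYPES, 2)


# ---------------------------------------------------------------------------
# step phases
# ---------------------------------------------------------------------------


def _phase_movement(state: SimState) -> None:
    p, pool, rng = state.params, state.pool, state.rng
    idx = np.flatnonzero(pool.alive)
    if len(idx) == 0:
        return
    pool.site[idx] = state.nbr[pool.site[idx], rng.integers(0, 4, size=len(idx))]
    # activated effector migration into the white matter
    st = pool.state
    active = (st == _ACTIVATED) | (st == _DUPLICATING)
    if not active.any():
        return
    eff = (active & pool.alive & (pool.comp == _P)
           & ((pool.ctype == _TH) | (pool.ctype == _CTL)))
    eff_idx = np.flatnonzero(eff)
    if len(eff_idx) == 0:
        return
    pm = p.p_mig_eff * state.modifiers["mig_factor"]
    go = eff_idx[rng.random(len(eff_idx)) < pm]
    if len(go) == 0:
        return
    np.add.at(state.log_emigration, (pool.ctype[go], 0), 1)
    pool.comp[go] = _WM
    pool.site[go] = rng.integers(0, p.n_sites, size=len(go)).astype(np.int16)
    np.add.at(state.log_immigration, (pool.ctype[go], 1), 1)


def _gate(vals: np.ndarray, K: float, floor: float) -> np.ndarray:
    return floor + (1.0 - floor) * vals / (vals + K)


def _phase_interactions(state: SimState) -> None:
    from .pathology import autoimmune_attack  # late import avoids a cycle

    p, pool, rng = state.params, state.pool, state.rng
    ns = p.n_sites
    sites_viral = sites_self = None
    apc_idx = None
    if state.viral_load >= 0.5 or state.debris > 0.05:
        apc_idx = np.flatnonzero(pool.alive & (pool.ctype == _APC) & (pool.comp == _P))
    if state.viral_load >= 0.5 and len(apc_idx):
        pv = p.p_present_viral_max * state.viral_load / (state.viral_load + p.viral_present_K)
        pres = apc_idx[rng.random(len(apc_idx)) < pv]
        if len(pres):
            sites_viral = np.zeros(ns, dtype=bool)
            sites_viral[pool.site[pres]] = True
    if state.debris > 0.05 and len(apc_idx):
        dh = state.debris ** p.debris_hill
        ps = p.p_present_self_max * dh / (dh + p.debris_K ** p.debris_hill)
        pres = apc_idx[rng.random(len(apc_idx)) < ps]
        if len(pres):
            sites_self = np.zeros(ns, dtype=bool)
            sites_self[pool.site[pres]] = True

    act_factor = state.modifiers["act_factor"]
    il2_row = state.cyt[IL2]
    resting_p = None
    if sites_viral is not None or sites_self is not None:
        resting_p = pool.alive & (pool.state == _RESTING) & (pool.comp == _P)

        def cognate_mask(ct: int) -> np.ndarray:
            base = resting_p & (pool.ctype == ct)
            m = np.zeros(pool.cap, dtype=bool)
            if sites_viral is not None:
                m |= base & pool.binds_viral & sites_viral[pool.site]
            if sites_self is not None:
                m |= base & pool.binds_self & sites_self[pool.site]
            return m

        # TH and CTL activation, gated by local IL-2
        for ct, pact in ((_TH, p.p_act_th), (_CTL, p.p_act_ctl)):
            cand = np.flatnonzero(cognate_mask(ct))
            if len(cand) == 0:
                continue
            gate = _gate(il2_row[pool.site[cand]], p.il2_K, p.il2_gate_floor)
            hit = cand[rng.random(len(cand)) < pact * act_factor * gate]
            pool.state[hit] = _ACTIVATED
            pool.act_age[hit] = 0
        # bystander TREG activation at any presenting site
        pres_any = np.zeros(ns, dtype=bool)
        if sites_viral is not None:
            pres_any |= sites_viral
        if sites_self is not None:
            pres_any |= sites_self
        tr = np.flatnonzero(resting_p & (pool.ctype == _TREG) & pres_any[pool.site])
        if len(tr):
            hit = tr[rng.random(len(tr)) < p.p_act_treg]
            pool.state[hit] = _ACTIVATED
            pool.act_age[hit] = 0
        # B activation requires cognate antigen plus available T-cell help
        # (licensing is compartment-wide: T-B collaboration in lymphoid
        # tissue is efficient once helper clones are activated)
        mb = cognate_mask(_B)
        if mb.any():
            th_act = (pool.alive & (pool.ctype == _TH) & (pool.state == _ACTIVATED)
                      & (pool.comp == _P))
            if th_act.any():
                cand = np.flatnonzero(mb)
                hit = cand[rng.random(len(cand)) < p.p_act_b * act_factor]
                pool.state[hit] = _ACTIVATED
                pool.act_age[hit] = 0

    # regulatory suppression, gated by local TGF-beta
    treg_act = np.flatnonzero(pool.alive & (pool.ctype == _TREG)
                              & (pool.state == _ACTIVATED) & (pool.comp == _P))
    if len(treg_act):
        treg_sites = np.zeros(ns, dtype=bool)
        treg_sites[pool.site[treg_act]] = True
        tgt = (pool.alive & (pool.comp == _P)
               & ((pool.state == _ACTIVATED) | (pool.state == _DUPLICATING))
               & ((pool.ctype == _TH) | (pool.ctype == _CTL) | (pool.ctype == _B))
               & treg_sites[pool.site])
        tgt_idx = np.flatnonzero(tgt)
        if len(tgt_idx):
            gate = _gate(state.cyt[TGFB][pool.site[tgt_idx]], p.tgfb_K, p.tgfb_gate_floor)
            hit = tgt_idx[rng.random(len(tgt_idx)) < p.p_sup * gate]
            pool.state[hit] = _ANERGIC

    # viral replication and clearance
    if state.viral_load > 0.0:
        n_eff = int((pool.alive & pool.binds_viral
                     & ((pool.state == _ACTIVATED)
                        | (pool.state == _DUPLICATING))).sum())
        n_nk = int((pool.alive & (pool.ctype == _NK) & (pool.comp == _P)).sum())
        ab_clear = p.viral_clear_ab * float(state.ab_titer.sum())
        state.viral_load *= p.viral_growth * np.exp(
            -(p.viral_clear_eff * n_eff + p.viral_clear_nk * n_nk + ab_clear))
        state.viral_load = min(state.viral_load, p.viral_cap)
        if state.viral_load < 0.01:
            state.viral_load = 0.0

    autoimmune_attack(state)


def _phase_secretion(state: SimState) -> None:
    p, pool = state.params, state.pool
    act = pool.alive & (pool.state == _ACTIVATED)
    if act.any():
        th = np.flatnonzero(act & (pool.ctype == _TH))
        if len(th):
            fp = state.flatpos(th)
            np.add.at(state.cyt[IL2], fp, p.secrete_il2_th)
            np.add.at(state.cyt[IFNG], fp, p.secrete_ifng_th)
        ctl = np.flatnonzero(act & (pool.ctype == _CTL))
        if len(ctl):
            np.add.at(state.cyt[IFNG], state.flatpos(ctl), p.secrete_ifng_ctl)
        treg = np.flatnonzero(act & (pool.ctype == _TREG))
        if len(treg):
            amt = p.secrete_tgfb_treg * state.modifiers["tgfb_factor"]
            np.add.at(state.cyt[TGFB], state.flatpos(treg), amt)
    plasma = np.flatnonzero(pool.alive & (pool.ctype == _PLASMA))
    if len(plasma):
        np.add.at(state.ab_titer, pool.isotype[plasma], p.secrete_ab_plasma)
    state.ab_titer *= p.ab_decay


def _phase_cytokine_field(state: SimState) -> None:
    p = state.params
    if state.cyt.max() < 1e-9:
        if state.cyt.any():
            state.cyt[:] = 0.0
        return
    # mass-conserving nearest-neighbour diffusion on each torus, then decay
    A = state.cyt
    d = p.cytokine_diffusion
    nb = A[:, state._cyt_nbr].sum(axis=2)
    state.cyt = p.cytokine_decay * ((1.0 - d) * A + (d / 4.0) * nb)


_DUP_P = {_B: "p_dup_b", _TH: "p_dup_th", _TREG: "p_dup_treg", _CTL: "p_dup_ctl"}


def _phase_duplication(state: SimState) -> None:
    p, pool, rng = state.params, state.pool, state.rng
    st = pool.state
    any_act = (pool.alive & ((st == _ACTIVATED) | (st == _DUPLICATING))).any()
    if not any_act:
        return
    # class switch of activated B cells into antibody-secreting plasma cells
    bact = np.flatnonzero(pool.alive & (pool.ctype == _B) & (st == _ACTIVATED))
    if len(bact):
        sw = bact[rng.random(len(bact)) < p.p_switch_plasma]
        if len(sw):
            np.add.at(state.log_switch_out, (pool.ctype[sw], pool.comp[sw]), 1)
            pool.ctype[sw] = _PLASMA
            pool.state[sw] = _RESTING
            pool.isotype[sw] = rng.choice(3, size=len(sw), p=p.isotype_probs)
            np.add.at(state.log_switch_in, (pool.ctype[sw], pool.comp[sw]), 1)
    # cells committed last step divide now
    dup = np.flatnonzero(pool.alive & (pool.state == _DUPLICATING))
    if len(dup):
        slots = pool.spawn(ctype=pool.ctype[dup], comp=pool.comp[dup],
                           site=pool.site[dup], receptor=pool.receptor[dup],
                           state=_ACTIVATED)
        pool.binds_self[slots] = pool.binds_self[dup]
        pool.binds_viral[slots] = pool.binds_viral[dup]
        pool.act_age[slots] = pool.act_age[dup]
        np.add.at(state.log_births, (pool.ctype[slots], pool.comp[slots]), 1)
        pool.state[dup] = _ACTIVATED
    # activated lymphocytes commit to division while inside the clonal
    # expansion window, subject to lineage crowding
    counts = np.bincount(pool.ctype[pool.alive], minlength=_N_TYPES)
    sp = _setpoints(p)
    df = state.modifiers["dup_factor"] * state.modifiers["dup_factor_activated"]
    expandable = (pool.alive & (pool.state == _ACTIVATED)
                  & (pool.act_age <= p.dup_window))
    if not expandable.any():
        return
    for ct, pname in _DUP_P.items():
        cand = np.flatnonzero(expandable & (pool.ctype == ct))
        if len(cand) == 0:
            continue
        crowd = max(0.0, 1.0 - counts[ct] / (p.crowd_cap_mult * sp[ct]))
        prob = getattr(p, pname) * crowd * df
        if prob <= 0.0:
            continue
        hit = cand[rng.random(len(cand)) < prob]
        pool.state[hit] = _DUPLICATING


def _phase_death(state: SimState) -> None:
    p, pool, rng = state.params, state.pool, state.rng
    idx = np.flatnonzero(pool.alive)
    if len(idx) == 0:
        return
    pool.age[idx] += 1
    act = (pool.state[idx] == _ACTIVATED) | (pool.state[idx] == _DUPLICATING)
    pool.act_age[idx[act]] += 1
    probs = state._death_table[pool.ctype[idx], pool.state[idx]]
    # tissue-infiltrated effectors burn out faster
    in_wm_act = act & (pool.comp[idx] == _WM)
    if in_wm_act.any():
        probs = probs.copy()
        probs[in_wm_act] = p.death_activated_wm
    bk = state.modifiers["b_kill_prob"]
    if bk > 0.0:
        probs = probs.copy()
        isb = pool.ctype[idx] == _B
        probs[isb] = 1.0 - (1.0 - probs[isb]) * (1.0 - bk)
    dead = idx[rng.random(len(idx)) < probs]
    if len(dead):
        np.add.at(state.log_deaths, (pool.ctype[dead], pool.comp[dead]), 1)
        pool.kill(dead)
    # oligodendrocyte repopulation toward baseline (remyelination)
    dead_ol = np.flatnonzero(~state.oligo_alive)
    if len(dead_ol):
        back = dead_ol[rng.random(len(dead_ol)) < p.p_remyelinate]
        if len(back):
            state.oligo_alive[back] = True
            np.add.at(state.oligo_per_site, state.oligo_site[back], 1)


def hematopoiesis(state: SimState) -> SimState:
    """Bone-marrow/thymus replenishment of resting lineages.

    Birth numbers are Poisson with mean ``death_resting * set-point`` per
    lineage, which balances resting turnover exactly at the homeostatic
    set-point; new receptors are uniform draws (with the configured
    autoreactive bias) and T lineages pass thymic negative selection.
    """
    p, rng = state.params, state.rng
    sp = _setpoints(p)
    rates = p.death_resting * sp[list(LYMPHOCYTES)]
    births = rng.poisson(rates)
    total = int(births.sum())
    if total == 0:
        return state
    ctypes = np.repeat(np.array(LYMPHOCYTES, dtype=np.int8), births)
    rec = random_receptors(rng, total, p.receptor_length)
    # autoreactive bias of the B/TH/CTL repertoires
    if p.p_auto > 0:
        eligible = (ctypes == _B) | (ctypes == _TH) | (ctypes == _CTL)
        bias = eligible & (rng.random(total) < p.p_auto)
        nb = int(bias.sum())
        if nb:
            rec[bias] = near_complement(rng, p.self_antigen, p.receptor_length, nb)
    # thymic negative selection: rejected T-lineage receptors are never born
    is_t = (ctypes == _TH) | (ctypes == _TREG) | (ctypes == _CTL)
    keep = np.ones(total, dtype=bool)
    if is_t.any():
        keep[is_t] = thymic_selection(rec[is_t], [p.self_antigen],
                                      p.receptor_length, p.neg_threshold)
    ctypes, rec = ctypes[keep], rec[keep]
    if len(ctypes) == 0:
        return state
    sites = rng.integers(0, p.n_sites, size=len(ctypes)).astype(np.int16)
    slots = state.pool.spawn(ctype=ctypes, comp=_P, site=sites, receptor=rec)
    state.pool.binds_self[slots] = binds_many(rec, p.self_antigen,
                                              p.receptor_length, p.bind_threshold)
    if state.viral_antigen is not None:
        state.pool.binds_viral[slots] = binds_many(rec, state.viral_antigen,
                                                   p.receptor_length, p.bind_threshold)
    np.add.at(state.log_births, (ctypes, np.zeros(len(ctypes), dtype=np.int8)), 1)
    return state


def step(state: SimState) -> SimState:
    """Advance the simulation by one timestep (one day, in place)."""
    for log in (state.log_births, state.log_deaths, state.log_emigration,
                state.log_immigration, state.log_switch_out, state.log_switch_in):
        log[:] = 0
    state.kills_this_step = 0
    _phase_movement(state)
    _phase_interactions(state)
    _phase_secretion(state)
    _phase_cytokine_field(state)
    _phase_duplication(state)
    _phase_death(state)
    if state.hematopoiesis_enabled:
        hematopoiesis(state)
    state.time += 1
    return state


def run_steps(state: SimState, n_steps: int,
              hook=None) -> np.ndarray:
    """Run ``n_steps`` timesteps, recording one trajectory row per step.

    ``hook(state, i)`` is called before each step (used by the treatment
    layer to refresh drug-effect modifiers).  Returns an array of shape
    ``(n_steps, len(TRAJ_COLUMNS))`` in :data:`TRAJ_COLUMNS` order.
    """
    traj = np.empty((n_steps, len(TRAJ_COLUMNS)), dtype=np.float64)
    pool = state.pool
    for i in range(n_steps):
        if hook is not None:
            hook(state, i)
        step(state)
        counts = np.bincount(pool.ctype[pool.alive], minlength=_N_TYPES)
        row = traj[i]
        row[0] = state.oligo_per_site.sum()
        row[1] = state.kills_this_step
        row[2] = counts[_B]
        row[3] = counts[_TH]
        row[4] = state.cyt[IL2].sum()
        row[5] = state.cyt[IFNG].sum()
        row[6] = state.cyt[TGFB].sum()
        row[7] = state.ab_titer[0]
        row[8] = state.ab_titer[1]
        row[9] = state.ab_titer[2]
    return traj
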
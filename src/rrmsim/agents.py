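"""Cell agents stored as structure-of-arrays pools.

Each immune cell is an individually tracked agent with a type, an
activation state, a compartment + grid-site position, a bit-string
receptor and an age.  For speed the population lives in a fixed-capacity
pool of parallel numpy columns with an ``alive`` mask; births reuse free
slots and deaths simply clear the mask, so per-step updates are pure
vector operations.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = ["CellType", "CellState", "Isotype", "Compartment", "AgentPool", "LYMPHOCYTES"]


class CellType(IntEnum):
    B = 0
    TH = 1      # CD4 helper T cell
    TREG = 2
    CTL = 3     # CD8 cytotoxic T cell
    NK = 4
    APC = 5
    PLASMA = 6


class CellState(IntEnum):
    RESTING = 0
    ACTIVATED = 1
    DUPLICATING = 2
    ANERGIC = 3
    DEAD = 4


class Isotype(IntEnum):
    NONE = -1
    IGM = 0
    IGG = 1
    IGA = 2


class Compartment(IntEnum):
    PERIPHERY = 0
    WHITE_MATTER = 1


#: Lineages replenished by hematopoiesis (PLASMA arises by class switch only).
LYMPHOCYTES = (CellType.B, CellType.TH, CellType.TREG, CellType.CTL, CellType.NK, CellType.APC)

#: T lineages subject to thymic negative selection.
T_LINEAGES = (CellType.TH, CellType.TREG, CellType.CTL)


class AgentPool:
    """Fixed-capacity structure-of-arrays store for immune agents."""

    __slots__ = (
        "cap", "alive", "agent_id", "ctype", "state", "comp", "site",
        "receptor", "age", "act_age", "isotype", "binds_self", "binds_viral",
        "_next_id", "_free", "_nfree",
    )

    def __init__(self, capacity: int = 2048):
        self.cap = capacity
        self.alive = np.zeros(capacity, dtype=bool)
        self.agent_id = np.zeros(capacity, dtype=np.int64)
        self.ctype = np.zeros(capacity, dtype=np.int8)
        self.state = np.zeros(capacity, dtype=np.int8)
        self.comp = np.zeros(capacity, dtype=np.int8)
        self.site = np.zeros(capacity, dtype=np.int16)
        self.receptor = np.zeros(capacity, dtype=np.uint64)
        self.age = np.zeros(capacity, dtype=np.int32)
        self.act_age = np.zeros(capacity, dtype=np.int32)
        self.isotype = np.full(capacity, Isotype.NONE, dtype=np.int8)
        # binding of the (fixed) self / viral epitopes, precomputed at birth
        self.binds_self = np.zeros(capacity, dtype=bool)
        self.binds_viral = np.zeros(capacity, dtype=bool)
        self._next_id = 0
        self._free = np.arange(capacity - 1, -1, -1, dtype=np.int64)
        self._nfree = capacity

    # -- slot management ------------------------------------------------

    def _take_slots(self, n: int) -> np.ndarray:
        if n > self._nfree:
            self._grow(max(self.cap, n))
        slots = self._free[self._nfree - n : self._nfree].copy()
        self._nfree -= n
        return slots

    def _grow(self, extra: int) -> None:
        old = self.cap
        new_cap = old + extra
        for name in ("alive", "agent_id", "ctype", "state", "comp", "site",
                     "receptor", "age", "act_age", "isotype",
                     "binds_self", "binds_viral"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[:old] = arr
            if name == "isotype":
                grown[old:] = Isotype.NONE
            setattr(self, name, grown)
        fresh = np.arange(new_cap - 1, old - 1, -1, dtype=np.int64)
        self._free = np.concatenate([fresh, self._free[: self._nfree]])
        self._nfree += extra
        self.cap = new_cap

    # -- births and deaths ----------------------------------------------

    def spawn(
        self,
        ctype: int | np.ndarray,
        comp: int | np.ndarray,
        site: np.ndarray,
        receptor: np.ndarray,
        state: int = CellState.RESTING,
        age: int | np.ndarray = 0,
        isotype: int | np.ndarray = Isotype.NONE,
    ) -> np.ndarray:
        """Create agents; returns the slot indices used."""
        n = len(site)
        if n == 0:
            return np.empty(0, dtype=np.int64)
        slots = self._take_slots(n)
        self.alive[slots] = True
        self.agent_id[slots] = np.arange(self._next_id, self._next_id + n)
        self._next_id += n
        self.ctype[slots] = ctype
        self.state[slots] = state
        self.comp[slots] = comp
        self.site[slots] = site
        self.receptor[slots] = receptor
        self.age[slots] = age
        self.act_age[slots] = 0
        self.isotype[slots] = isotype
        self.binds_self[slots] = False
        self.binds_viral[slots] = False
        return slots

    def kill(self, slots: np.ndarray) -> None:
        """Remove agents immediately (DEAD agents never persist a step)."""
        if len(slots) == 0:
            return
        self.alive[slots] = False
        if self._nfree + len(slots) > len(self._free):
            self._free = np.concatenate([self._free[: self._nfree], slots])
            self._nfree = len(self._free)
        else:
            self._free[self._nfree : self._nfree + len(slots)] = slots
            self._nfree += len(slots)

    # -- queries ---------------------------------------------------------

    def mask(self, ctype: int | None = None, state: int | None = None,
             comp: int | None = None) -> np.ndarray:
        m = self.alive.copy()
        if ctype is not None:
            m &= self.ctype == ctype
        if state is not None:
            m &= self.state == state
        if comp is not None:
            m &= self.comp == comp
        return m

    def count(self, ctype: int | None = None, state: int | None = None,
              comp: int | None = None) -> int:
        return int(self.mask(ctype, state, comp).sum())

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())
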
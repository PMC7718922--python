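"""caDNAno strand-diagram parsing and design-level analysis.

A multilayer DNA origami is specified in caDNAno as a set of virtual
helices on a honeycomb or square lattice, each carrying a scaffold lane
and a staple lane of slots.  Every slot stores 5'/3' neighbour pointers,
an insertion count (``loop``) and a deletion flag (``skip``).  This
module reads the 2.x "vstrands" JSON dialect into a validated
:class:`LatticeDesign` and derives the design-level quantities the
mechanics of the object depend on: crossovers (single vs. double),
nicks and gaps, and the helical twist density imposed by the lattice
connectivity.

The lattice connectivity allocates a fixed rotation per slot: honeycomb
designs repeat every 21 slots over two helical turns (10.5 bp/turn) and
square-lattice designs every 32 slots over three turns (32/3 ≈ 10.67
bp/turn).  Insertions and deletions change the number of actual base
pairs packed into those turns, which is how designers tune global twist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "Helix",
    "Strand",
    "Crossover",
    "NickSite",
    "Gap",
    "LatticeDesign",
    "parse_cadnano",
    "to_cadnano_json",
    "enumerate_crossovers",
    "find_nicks",
    "find_gaps",
    "imposed_twist_density",
    "design_report",
    "LATTICE_BP_PER_TURN",
]

#: Rotation the lattice connectivity allocates per design slot, as base
#: pairs per turn.  Fixed by the lattice repeat geometry: 21 slots / 2
#: turns (honeycomb) and 32 slots / 3 turns (square); not configurable.
LATTICE_BP_PER_TURN = {"honeycomb": 21.0 / 2.0, "square": 32.0 / 3.0}

SCAFFOLD = "scaffold"
STAPLE = "staple"
_LANES = {SCAFFOLD: "scaf", STAPLE: "stap"}


class DesignError(ValueError):
    """Raised for malformed or inconsistent strand diagrams."""


@dataclass(frozen=True)
class Helix:
    num: int
    row: int
    col: int


@dataclass
class Strand:
    """One strand traversal, 5'→3', as (helix num, slot index) steps."""

    kind: str
    path: list[tuple[int, int]]
    circular: bool = False

    def __len__(self) -> int:  # number of slots traversed
        return len(self.path)


@dataclass(frozen=True)
class Crossover:
    """An inter-helix junction.

    ``arity`` is ``"double"`` when a reciprocal strand crossing of the
    same kind exists within one slot of this one (the two crossings are
    merged into a single record), else ``"single"``.
    """

    helices: tuple[int, int]
    slot: int
    kind: str
    arity: str


@dataclass(frozen=True)
class NickSite:
    """A backbone discontinuity between abutting termini on one lane,
    with the complementary strand continuous across the same boundary.
    ``slot`` is the boundary: the nick lies between ``slot-1`` and
    ``slot``."""

    helix: int
    slot: int
    kind: str


@dataclass(frozen=True)
class Gap:
    """A maximal unpaired stretch (one lane occupied, the other not)
    flanked by paired slots; slots ``start``..``end`` inclusive."""

    helix: int
    start: int
    end: int
    kind: str  # the lane that is *present* over the gap


@dataclass
class LatticeDesign:
    """Parsed strand diagram: helices on a lattice plus lane arrays.

    Lane arrays are kept verbatim (caDNAno pointer quadruples) so that
    serialisation round-trips bit-exactly; strand traversals are
    derived and validated at parse time.
    """

    lattice: str
    helices: list[Helix]
    scaf: dict[int, np.ndarray]  # helix num -> (n_slots, 4) int32
    stap: dict[int, np.ndarray]
    loop: dict[int, np.ndarray]  # insertion counts per slot
    skip: dict[int, np.ndarray]  # deletion flags (bool) per slot
    strands: list[Strand] = field(default_factory=list)
    sequences: dict[int, str] | None = None
    name: str = "design"

    # -- basic accessors -------------------------------------------------
    @property
    def n_slots(self) -> int:
        return max(len(a) for a in self.scaf.values())

    def helix(self, num: int) -> Helix:
        for h in self.helices:
            if h.num == num:
                return h
        raise KeyError(num)

    def occupied(self, helix: int, kind: str) -> np.ndarray:
        """Boolean per-slot occupancy of one lane."""
        lane = self.scaf if kind == SCAFFOLD else self.stap
        return (lane[helix] != -1).any(axis=1)

    def paired(self, helix: int) -> np.ndarray:
        """Slots carrying one base pair: both lanes occupied, not deleted."""
        return (
            self.occupied(helix, SCAFFOLD)
            & self.occupied(helix, STAPLE)
            & ~self.skip[helix]
        )

    def lattice_neighbors(self, num: int) -> list[int]:
        h = self.helix(num)
        out = []
        for other in self.helices:
            if other.num != num and _adjacent(self.lattice, h, other):
                out.append(other.num)
        return out


# -- lattice adjacency ---------------------------------------------------

def _adjacent(lattice: str, a: Helix, b: Helix) -> bool:
    dr, dc = b.row - a.row, b.col - a.col
    if lattice == "square":
        return abs(dr) + abs(dc) == 1
    if lattice == "honeycomb":
        if dr == 0 and abs(dc) == 1:
            return True
        # vertical neighbour exists on one side only, set by slot parity
        if dc == 0 and abs(dr) == 1:
            down = (a.row + a.col) % 2 == 0
            return dr == (1 if down else -1)
        return False
    raise DesignError(f"unknown lattice {lattice!r}")


def _max_degree(lattice: str) -> int:
    return 3 if lattice == "honeycomb" else 4


# -- parsing -------------------------------------------------------------

def parse_cadnano(
    json_text: str,
    sequences: Mapping[int, str] | None = None,
    lattice: str | None = None,
) -> LatticeDesign:
    """Parse a caDNAno 2.x ("vstrands") JSON document.

    Parameters
    ----------
    json_text:
        The JSON text of the design.
    sequences:
        Optional mapping of strand index to base string, attached as-is.
    lattice:
        ``"honeycomb"`` or ``"square"``.  If omitted, the lattice is
        inferred from the crossover connectivity: if every inter-helix
        strand jump joins honeycomb-adjacent helices the design is taken
        as honeycomb, else square is tried.  Ambiguous designs (no
        inter-helix jumps) require the explicit flag.
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise DesignError(f"malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "vstrands" not in doc:
        raise DesignError("not a caDNAno 2.x document (missing 'vstrands')")

    helices: list[Helix] = []
    scaf: dict[int, np.ndarray] = {}
    stap: dict[int, np.ndarray] = {}
    loop: dict[int, np.ndarray] = {}
    skip: dict[int, np.ndarray] = {}
    for vh in doc["vstrands"]:
        num = int(vh["num"])
        helices.append(Helix(num, int(vh["row"]), int(vh["col"])))
        scaf[num] = np.asarray(vh["scaf"], dtype=np.int32).reshape(-1, 4)
        stap[num] = np.asarray(vh["stap"], dtype=np.int32).reshape(-1, 4)
        n = len(scaf[num])
        loop[num] = np.asarray(vh.get("loop", [0] * n), dtype=np.int32)
        skip[num] = np.asarray(vh.get("skip", [0] * n), dtype=np.int32) != 0
    if len({h.num for h in helices}) != len(helices):
        raise DesignError("duplicate helix numbers")

    design = LatticeDesign(
        lattice=lattice or "square",  # provisional, fixed below
        helices=helices,
        scaf=scaf,
        stap=stap,
        loop=loop,
        skip=skip,
        sequences=dict(sequences) if sequences else None,
        name=str(doc.get("name", "design")),
    )
    design.strands = _trace_strands(design)

    if lattice is None:
        design.lattice = _infer_lattice(design)
    else:
        if lattice not in LATTICE_BP_PER_TURN:
            raise DesignError(f"unknown lattice {lattice!r}")
        design.lattice = lattice
    _validate(design)
    return design


def _jumps(design: LatticeDesign) -> list[tuple[int, int, int, str]]:
    """All inter-helix strand steps as (helix_a, helix_b, slot, kind)."""
    out = []
    for strand in design.strands:
        steps = list(zip(strand.path, strand.path[1:]))
        if strand.circular:
            steps.append((strand.path[-1], strand.path[0]))
        for (h1, s1), (h2, s2) in steps:
            if h1 != h2:
                if s1 != s2:
                    raise DesignError(
                        f"crossover changes slot index: ({h1},{s1})->({h2},{s2})"
                    )
                out.append((h1, h2, s1, strand.kind))
    return out


def _infer_lattice(design: LatticeDesign) -> str:
    jumps = _jumps(design)
    if not jumps:
        raise DesignError(
            "cannot infer lattice for a design with no crossovers; "
            "pass lattice= explicitly"
        )
    by = {h.num: h for h in design.helices}
    for lat in ("honeycomb", "square"):
        if all(_adjacent(lat, by[a], by[b]) for a, b, _, _ in jumps):
            return lat
    raise DesignError("crossover connectivity fits neither lattice")


def _trace_strands(design: LatticeDesign) -> list[Strand]:
    strands: list[Strand] = []
    for kind, lane_name in _LANES.items():
        lanes = design.scaf if kind == SCAFFOLD else design.stap
        occupied: set[tuple[int, int]] = set()
        for h, arr in lanes.items():
            for s in np.nonzero((arr != -1).any(axis=1))[0]:
                occupied.add((h, int(s)))

        def ptr(h: int, s: int, end: str) -> tuple[int, int] | None:
            row = lanes[h][s]
            a, b = (row[0], row[1]) if end == "5" else (row[2], row[3])
            if a == -1 and b == -1:
                return None
            return int(a), int(b)

        def check_recip(cur, nxt):
            if nxt not in occupied:
                raise DesignError(
                    f"{kind} 3' pointer at {cur} targets unoccupied slot {nxt}"
                )
            back = ptr(*nxt, "5")
            if back != cur:
                raise DesignError(
                    f"dangling {kind} pointer: {cur} -> {nxt} not reciprocated"
                )

        visited: set[tuple[int, int]] = set()
        # linear strands first: walk from 5' ends
        for start in sorted(occupied):
            if ptr(*start, "5") is not None or ptr(*start, "3") is None:
                continue
            path = [start]
            visited.add(start)
            cur = start
            while (nxt := ptr(*cur, "3")) is not None:
                check_recip(cur, nxt)
                if nxt in visited:
                    raise DesignError(f"{kind} strand revisits slot {nxt}")
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            strands.append(Strand(kind, path))
        # remaining occupied slots belong to circular strands
        for start in sorted(occupied - visited):
            if start in visited:
                continue
            path = [start]
            visited.add(start)
            cur = start
            while True:
                nxt = ptr(*cur, "3")
                if nxt is None:
                    raise DesignError(
                        f"{kind} slot {cur} reachable only mid-strand yet "
                        "has no 3' pointer"
                    )
                check_recip(cur, nxt)
                if nxt == start:
                    break
                if nxt in visited:
                    raise DesignError(f"{kind} strand revisits slot {nxt}")
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            strands.append(Strand(kind, path, circular=True))
    return strands


def _validate(design: LatticeDesign) -> None:
    by = {h.num: h for h in design.helices}
    maxdeg = _max_degree(design.lattice)
    for h in design.helices:
        deg = len(design.lattice_neighbors(h.num))
        if deg > maxdeg:
            raise DesignError(
                f"helix {h.num} has {deg} lattice neighbours "
                f"(max {maxdeg} on {design.lattice})"
            )
    for a, b, slot, kind in _jumps(design):
        if not _adjacent(design.lattice, by[a], by[b]):
            raise DesignError(
                f"{kind} crossover {a}->{b} at slot {slot} joins "
                f"non-neighbour helices on the {design.lattice} lattice"
            )


def to_cadnano_json(design: LatticeDesign) -> str:
    """Serialise back to caDNAno 2.x JSON (round-trips with parse)."""
    vstrands = []
    for h in design.helices:
        vstrands.append(
            {
                "num": h.num,
                "row": h.row,
                "col": h.col,
                "scaf": design.scaf[h.num].tolist(),
                "stap": design.stap[h.num].tolist(),
                "loop": design.loop[h.num].tolist(),
                "skip": (-design.skip[h.num].astype(int)).tolist(),
                "stap_colors": [],
            }
        )
    return json.dumps({"name": design.name, "vstrands": vstrands})


# -- crossovers ----------------------------------------------------------

def enumerate_crossovers(design: LatticeDesign) -> list[Crossover]:
    """Report every inter-helix strand junction exactly once.

    Two crossings of the same kind between the same helix pair at
    adjacent slots (reciprocal strand exchange) are merged into one
    ``double`` crossover; an unpartnered crossing is ``single``.
    """
    groups: dict[tuple[tuple[int, int], str], list[int]] = {}
    for a, b, slot, kind in _jumps(design):
        key = (tuple(sorted((a, b))), kind)
        groups.setdefault(key, []).append(slot)
    out: list[Crossover] = []
    for (pair, kind), slots in groups.items():
        slots = sorted(slots)
        i = 0
        while i < len(slots):
            if i + 1 < len(slots) and slots[i + 1] - slots[i] <= 1:
                out.append(Crossover(pair, slots[i], kind, "double"))
                i += 2
            else:
                out.append(Crossover(pair, slots[i], kind, "single"))
                i += 1
    out.sort(key=lambda c: (c.helices, c.slot, c.kind))
    return out


# -- nicks and gaps ------------------------------------------------------

def _lane_connected(design: LatticeDesign, helix: int, kind: str) -> np.ndarray:
    """conn[s] True when slot s and s+1 on this helix are joined by a
    backbone bond of the given lane (in either strand direction)."""
    lanes = design.scaf if kind == SCAFFOLD else design.stap
    arr = lanes[helix]
    n = len(arr)
    conn = np.zeros(n, dtype=bool)
    for s in range(n - 1):
        r = arr[s]
        if (r[0] == helix and r[1] == s + 1) or (r[2] == helix and r[3] == s + 1):
            conn[s] = True
    return conn


def find_nicks(design: LatticeDesign) -> list[NickSite]:
    """Backbone discontinuities between abutting strand termini on one
    lane of an intact duplex.  A lane that merely leaves the helix
    through a crossover is covalently continuous, not nicked; an
    unpaired stretch is a gap (see :func:`find_gaps`), never a nick."""
    nicks: list[NickSite] = []

    def is_terminus(arr: np.ndarray, s: int) -> bool:
        return (arr[s, 0] == -1 and arr[s, 1] == -1) or (
            arr[s, 2] == -1 and arr[s, 3] == -1
        )

    for h in design.helices:
        paired = design.paired(h.num)
        for kind, other in ((STAPLE, SCAFFOLD), (SCAFFOLD, STAPLE)):
            lanes = design.scaf if kind == SCAFFOLD else design.stap
            arr = lanes[h.num]
            conn = _lane_connected(design, h.num, kind)
            conn_other = _lane_connected(design, h.num, other)
            occ = design.occupied(h.num, kind)
            for s in range(len(occ) - 1):
                if (
                    occ[s]
                    and occ[s + 1]
                    and not conn[s]
                    and conn_other[s]
                    and paired[s]
                    and paired[s + 1]
                    and is_terminus(arr, s)
                    and is_terminus(arr, s + 1)
                ):
                    nicks.append(NickSite(h.num, s + 1, kind))
    nicks.sort(key=lambda n: (n.helix, n.slot, n.kind))
    return nicks


def find_gaps(design: LatticeDesign) -> list[Gap]:
    """Maximal unpaired stretches flanked by paired slots."""
    gaps: list[Gap] = []
    for h in design.helices:
        occ_sc = design.occupied(h.num, SCAFFOLD)
        occ_st = design.occupied(h.num, STAPLE)
        single = occ_sc ^ occ_st
        paired = occ_sc & occ_st
        n = len(single)
        s = 0
        while s < n:
            if single[s]:
                e = s
                while e + 1 < n and single[e + 1]:
                    e += 1
                if s > 0 and e < n - 1 and paired[s - 1] and paired[e + 1]:
                    kind = SCAFFOLD if occ_sc[s] else STAPLE
                    gaps.append(Gap(h.num, s, e, kind))
                s = e + 1
            else:
                s += 1
    return gaps


# -- imposed twist density ----------------------------------------------

def segment_table(design: LatticeDesign) -> pd.DataFrame:
    """Per-helix crossover-bounded segment breakdown.

    Each segment of ``n`` design slots contributes ``n - deletions +
    insertions`` actual base pairs and ``n / rho_L`` design turns, where
    ``rho_L`` is the per-slot rotation allocated by the lattice repeat.
    """
    rho = LATTICE_BP_PER_TURN[design.lattice]
    xo_slots: dict[int, set[int]] = {h.num: set() for h in design.helices}
    for a, b, slot, _ in _jumps(design):
        xo_slots[a].add(slot)
        xo_slots[b].add(slot)
    rows = []
    for h in design.helices:
        occ = design.occupied(h.num, SCAFFOLD) & design.occupied(h.num, STAPLE)
        idx = np.nonzero(occ)[0]
        if idx.size == 0:
            continue
        # contiguous occupied runs, each split at crossover slots
        runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
        for run in runs:
            bounds = sorted(x for x in xo_slots[h.num] if run[0] < x <= run[-1])
            starts = [int(run[0])] + bounds
            ends = bounds + [int(run[-1]) + 1]
            for s, e in zip(starts, ends):
                if e <= s:
                    continue
                sl = slice(s, e)
                n = e - s
                dele = int(design.skip[h.num][sl].sum())
                ins = int(design.loop[h.num][sl].sum())
                rows.append(
                    {
                        "helix": h.num,
                        "start": s,
                        "end": e - 1,
                        "slots": n,
                        "deletions": dele,
                        "insertions": ins,
                        "bp": n - dele + ins,
                        "turns": n / rho,
                    }
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["bp_per_turn"] = df["bp"] / df["turns"]
    return df


def imposed_twist_density(design: LatticeDesign) -> tuple[float, pd.DataFrame]:
    """Base pairs per turn imposed by the design connectivity.

    Returns the aggregate density ``sum(bp) / sum(turns)`` over all
    crossover-bounded duplex segments, plus the per-segment table.
    10.5 means twist-neutral B-DNA; larger values (e.g. 10.67 for
    default square-lattice spacing) underwind the helices and build up
    right-handed global twist.
    """
    df = segment_table(design)
    if df.empty or df["bp"].sum() <= 0:
        raise DesignError("design has no paired slots")
    density = float(df["bp"].sum() / df["turns"].sum())
    return density, df


# -- report --------------------------------------------------------------

def design_report(design: LatticeDesign) -> dict:
    """JSON-ready summary: helix table, crossovers, nicks, gaps, twist."""
    density, table = imposed_twist_density(design)
    return {
        "name": design.name,
        "lattice": design.lattice,
        "n_helices": len(design.helices),
        "n_slots": design.n_slots,
        "helices": [
            {"num": h.num, "row": h.row, "col": h.col} for h in design.helices
        ],
        "strands": {
            "scaffold": sum(1 for s in design.strands if s.kind == SCAFFOLD),
            "staple": sum(1 for s in design.strands if s.kind == STAPLE),
        },
        "crossovers": [
            {
                "helices": list(c.helices),
                "slot": c.slot,
                "kind": c.kind,
                "arity": c.arity,
            }
            for c in enumerate_crossovers(design)
        ],
        "nicks": [
            {"helix": n.helix, "slot": n.slot, "kind": n.kind}
            for n in find_nicks(design)
        ],
        "gaps": [
            {"helix": g.helix, "start": g.start, "end": g.end, "kind": g.kind}
            for g in find_gaps(design)
        ],
        "imposed_twist_density_bp_per_turn": density,
        "segments": table.to_dict(orient="records"),
    }
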
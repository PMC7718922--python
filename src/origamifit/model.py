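"""Idealized coarse-grained model building and helical-property analysis.

Each nucleotide is represented by two pseudo-atom beads: P at the
backbone-phosphate radius and B at the base centroid.  Helices are laid
out on the design lattice with canonical B-form geometry (3.4 Å rise,
per-slot twist of 360°/rho_L where rho_L is the lattice's base pairs per
turn, right-handed).  This idealized model is the starting point of the
flexible fit and, with injected deformations, the ground truth of the
synthetic test fixtures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .design import LATTICE_BP_PER_TURN, SCAFFOLD, STAPLE, LatticeDesign

__all__ = [
    "GeometryParams",
    "BeadModel",
    "HelicalProperties",
    "build_ideal_model",
    "helical_properties",
    "apply_deformation",
    "write_model",
    "read_model",
]

P_BEAD, B_BEAD = 0, 1


@dataclass(frozen=True)
class GeometryParams:
    """Idealized B-form geometry of the coarse-grained model.

    rise:            axial rise per base pair, Å
    r_p:             P-bead radius from the helix axis, Å
    r_b:             B-bead radius from the helix axis, Å
    strand_phase:    angular offset between the two strands' P beads,
                     degrees (the minor/major-groove asymmetry)
    inter_helix:     lattice spacing between adjacent helix axes, Å

    The two B beads of a Watson–Crick pair sit diametrically across the
    helix axis (each base reaches from its backbone toward the axis), so
    the pair's B-bead midpoint lies exactly on the axis — the anchor the
    helical-property and twist measurements rely on.
    """

    rise: float = 3.4
    r_p: float = 9.0
    r_b: float = 3.0
    strand_phase: float = 154.0
    inter_helix: float = 25.0


def lattice_xy(lattice: str, row: int, col: int, spacing: float) -> tuple[float, float]:
    """In-plane helix-axis position for a lattice site.

    The honeycomb convention matches the parity rule used for adjacency:
    a helix with even row+col has its vertical neighbour at row+1.
    """
    if lattice == "square":
        return col * spacing, row * spacing
    x = col * spacing * math.sqrt(3.0) / 2.0
    y = row * spacing * 1.5 - ((row + col) % 2) * spacing * 0.5
    return x, y


@dataclass
class BeadModel:
    """Coarse-grained coordinates with design-index annotations.

    Bead arrays are indexed by bead id; nucleotide arrays by nucleotide
    id.  ``nuc_pair`` holds the Watson–Crick partner (or -1) and is
    symmetric.  ``nuc_axial`` is the axial base-pair coordinate in units
    of base pairs along the nucleotide's helix (fractional positions are
    possible only through file round-trips; the builder assigns
    integers, with deletions omitted and insertions taking full steps).
    """

    coords: np.ndarray  # (n_beads, 3) float64, Å
    bead_kind: np.ndarray  # (n_beads,) uint8: 0=P, 1=B
    bead_nuc: np.ndarray  # (n_beads,) int32 bead -> nucleotide
    nuc_strand: np.ndarray  # (n_nuc,) int32
    nuc_helix: np.ndarray  # (n_nuc,) int32 (-1 unknown)
    nuc_slot: np.ndarray  # (n_nuc,) int32
    nuc_sub: np.ndarray  # (n_nuc,) int32 insertion sub-index
    nuc_pair: np.ndarray  # (n_nuc,) int32 partner nucleotide or -1
    nuc_p: np.ndarray  # (n_nuc,) int32 nucleotide -> P bead
    nuc_b: np.ndarray  # (n_nuc,) int32 nucleotide -> B bead
    nuc_axial: np.ndarray  # (n_nuc,) float64
    nuc_base: list[str] = field(default_factory=list)
    strand_kind: list[str] = field(default_factory=list)  # per strand id
    params: GeometryParams = field(default_factory=GeometryParams)
    design: LatticeDesign | None = None
    # construction frame: exact bundle axis through frame_origin; None
    # means "estimate by PCA" (e.g. after bending or a bare file read)
    frame_origin: np.ndarray | None = None
    frame_axis: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_nucleotides(self) -> int:
        return len(self.nuc_strand)

    def copy(self) -> "BeadModel":
        return replace(self, coords=self.coords.copy())

    def axis_frame(self) -> tuple[np.ndarray, np.ndarray]:
        """(origin, unit axis) of the bundle: the stored construction
        frame when available, otherwise the PCA principal axis."""
        if self.frame_origin is not None and self.frame_axis is not None:
            return self.frame_origin, self.frame_axis
        return self.coords.mean(axis=0), _principal_axis(self.coords)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite bead coordinates")
        p = self.nuc_pair
        has = p >= 0
        if not np.all(p[p[has]] == np.nonzero(has)[0]):
            raise ValueError("base pairing is not symmetric")

    # -- selection helpers ----------------------------------------------
    def nucleotides_for(self, selection) -> np.ndarray:
        """Nucleotide ids for a ``{helix: (lo, hi) | None}`` selection
        (hi inclusive; None selects the whole helix)."""
        masks = []
        for helix, rng in dict(selection).items():
            m = self.nuc_helix == helix
            if rng is not None:
                lo, hi = rng
                m &= (self.nuc_slot >= lo) & (self.nuc_slot <= hi)
            masks.append(m)
        if not masks:
            return np.empty(0, dtype=np.int64)
        return np.nonzero(np.logical_or.reduce(masks))[0]

    def beads_for_nucleotides(self, nuc_ids: np.ndarray) -> np.ndarray:
        return np.concatenate([self.nuc_p[nuc_ids], self.nuc_b[nuc_ids]])

    def pair_centroids(self, helix: int) -> tuple[np.ndarray, np.ndarray]:
        """(axial keys, centroids) of base pairs on one helix, ordered
        by axial coordinate; each centroid is the midpoint of the two
        partner B beads, which the ideal geometry places on the helix
        axis."""
        nucs = np.nonzero((self.nuc_helix == helix) & (self.nuc_pair >= 0))[0]
        nucs = nucs[nucs < self.nuc_pair[nucs]]
        if nucs.size == 0:
            return np.empty(0), np.empty((0, 3))
        order = np.argsort(self.nuc_axial[nucs], kind="stable")
        nucs = nucs[order]
        partners = self.nuc_pair[nucs]
        cen = 0.5 * (
            self.coords[self.nuc_b[nucs]] + self.coords[self.nuc_b[partners]]
        )
        return self.nuc_axial[nucs], cen

    def pair_pp_axes(self, helix: int) -> np.ndarray:
        """Per base pair, the P→P vector (scaffold P to partner P)."""
        nucs = np.nonzero((self.nuc_helix == helix) & (self.nuc_pair >= 0))[0]
        nucs = nucs[nucs < self.nuc_pair[nucs]]
        order = np.argsort(self.nuc_axial[nucs], kind="stable")
        nucs = nucs[order]
        partners = self.nuc_pair[nucs]
        return self.coords[self.nuc_p[partners]] - self.coords[self.nuc_p[nucs]]


# -- construction --------------------------------------------------------

def build_ideal_model(
    design: LatticeDesign, params: GeometryParams | None = None
) -> BeadModel:
    """Lay the design out with idealized B-form geometry.

    Helix axes run along +z at their lattice positions.  Along each
    helix, base pairs stack at the rise with a per-step twist of
    360/rho_L degrees (right-handed: the phase angle grows with +z).
    Deleted slots are omitted; inserted bases take full axial steps.
    """
    params = params or GeometryParams()
    rho = LATTICE_BP_PER_TURN[design.lattice]
    omega = math.radians(360.0 / rho)
    phase = math.radians(params.strand_phase)

    # axial coordinate per (helix, slot, sub): deletions omitted,
    # insertions appended after their slot, each a full step
    axial: dict[tuple[int, int, int], float] = {}
    for h in design.helices:
        occ = design.occupied(h.num, SCAFFOLD) | design.occupied(h.num, STAPLE)
        u = 0.0
        for s in np.nonzero(occ)[0]:
            s = int(s)
            if design.skip[h.num][s]:
                continue
            axial[(h.num, s, 0)] = u
            u += 1.0
            for j in range(int(design.loop[h.num][s])):
                axial[(h.num, s, j + 1)] = u
                u += 1.0

    helix_xy = {
        h.num: lattice_xy(design.lattice, h.row, h.col, params.inter_helix)
        for h in design.helices
    }

    coords: list[np.ndarray] = []
    bead_kind: list[int] = []
    bead_nuc: list[int] = []
    nuc_strand: list[int] = []
    nuc_helix: list[int] = []
    nuc_slot: list[int] = []
    nuc_sub: list[int] = []
    nuc_axial: list[float] = []
    nuc_base: list[str] = []
    nuc_p: list[int] = []
    nuc_b: list[int] = []
    nuc_of: dict[tuple[int, int, int, str], int] = {}
    strand_kind = [s.kind for s in design.strands]

    for sid, strand in enumerate(design.strands):
        seq = (design.sequences or {}).get(sid)
        pos_in_strand = 0
        for h, s in strand.path:
            if design.skip[h][s]:
                continue
            for sub in range(int(design.loop[h][s]) + 1):
                u = axial[(h, s, sub)]
                nid = len(nuc_strand)
                nuc_of[(h, s, sub, strand.kind)] = nid
                nuc_strand.append(sid)
                nuc_helix.append(h)
                nuc_slot.append(s)
                nuc_sub.append(sub)
                nuc_axial.append(u)
                base = "N"
                if seq and pos_in_strand < len(seq):
                    base = seq[pos_in_strand]
                nuc_base.append(base)
                pos_in_strand += 1

                x0, y0 = helix_xy[h]
                z = u * params.rise
                phi = u * omega if strand.kind == SCAFFOLD else u * omega + phase
                psi = u * omega + phase / 2.0  # base-pair axis
                bphi = psi if strand.kind == SCAFFOLD else psi + math.pi
                pb = len(coords)
                coords.append(
                    np.array(
                        [x0 + params.r_p * math.cos(phi),
                         y0 + params.r_p * math.sin(phi), z]
                    )
                )
                bead_kind.append(P_BEAD)
                bead_nuc.append(nid)
                bb = len(coords)
                coords.append(
                    np.array(
                        [x0 + params.r_b * math.cos(bphi),
                         y0 + params.r_b * math.sin(bphi), z]
                    )
                )
                bead_kind.append(B_BEAD)
                bead_nuc.append(nid)
                nuc_p.append(pb)
                nuc_b.append(bb)

    n_nuc = len(nuc_strand)
    nuc_pair = np.full(n_nuc, -1, dtype=np.int32)
    for (h, s, sub, kind), nid in nuc_of.items():
        if kind == SCAFFOLD:
            partner = nuc_of.get((h, s, sub, STAPLE))
            if partner is not None:
                nuc_pair[nid] = partner
                nuc_pair[partner] = nid

    model = BeadModel(
        coords=np.asarray(coords).reshape(-1, 3) if coords else np.empty((0, 3)),
        frame_origin=(
            np.asarray(coords).reshape(-1, 3).mean(axis=0)
            if coords else np.zeros(3)
        ),
        frame_axis=np.array([0.0, 0.0, 1.0]),
        bead_kind=np.asarray(bead_kind, dtype=np.uint8),
        bead_nuc=np.asarray(bead_nuc, dtype=np.int32),
        nuc_strand=np.asarray(nuc_strand, dtype=np.int32),
        nuc_helix=np.asarray(nuc_helix, dtype=np.int32),
        nuc_slot=np.asarray(nuc_slot, dtype=np.int32),
        nuc_sub=np.asarray(nuc_sub, dtype=np.int32),
        nuc_pair=nuc_pair,
        nuc_p=np.asarray(nuc_p, dtype=np.int32),
        nuc_b=np.asarray(nuc_b, dtype=np.int32),
        nuc_axial=np.asarray(nuc_axial, dtype=np.float64),
        nuc_base=nuc_base,
        strand_kind=strand_kind,
        params=params,
        design=design,
    )
    model.validate()
    return model


# -- helical properties --------------------------------------------------

@dataclass
class HelicalProperties:
    """Per base-pair-step rise, local twist and base-pair normal,
    grouped by helix."""

    helix: np.ndarray  # (n_steps,) helix num per step
    rise: np.ndarray  # Å
    twist: np.ndarray  # degrees, in (-180, 180]
    normal: np.ndarray  # (n_steps, 3) unit step directions

    def summary(self) -> dict:
        return {
            "mean_rise": float(np.mean(self.rise)),
            "mean_twist": float(np.mean(self.twist)),
            "std_rise": float(np.std(self.rise)),
            "std_twist": float(np.std(self.twist)),
        }


def _principal_axis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    # orient along increasing extent for reproducibility
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def helical_properties(model: BeadModel) -> HelicalProperties:
    """Rise, local twist and base-pair orientation per step.

    The rise is the distance between consecutive base-pair centroids
    projected on the local step direction; the twist is the signed angle
    between consecutive P–P base-pair axes about that direction.
    """
    hel, rises, twists, normals = [], [], [], []
    for h in np.unique(model.nuc_helix):
        _, cen = model.pair_centroids(int(h))
        if len(cen) < 2:
            continue
        axes = model.pair_pp_axes(int(h))
        steps = np.diff(cen, axis=0)
        norm = np.linalg.norm(steps, axis=1)
        ndir = steps / norm[:, None]
        for i in range(len(steps)):
            n = ndir[i]
            a = axes[i] - np.dot(axes[i], n) * n
            b = axes[i + 1] - np.dot(axes[i + 1], n) * n
            ang = math.degrees(
                math.atan2(float(np.dot(np.cross(a, b), n)), float(np.dot(a, b)))
            )
            hel.append(int(h))
            rises.append(float(norm[i]))
            twists.append(ang)
            normals.append(n)
    if not rises:
        raise ValueError("model has fewer than 2 consecutive base pairs")
    return HelicalProperties(
        helix=np.asarray(hel),
        rise=np.asarray(rises),
        twist=np.asarray(twists),
        normal=np.asarray(normals),
    )


# -- deformation ---------------------------------------------------------

def apply_deformation(
    model: BeadModel, global_twist: float = 0.0, curvature: float = 0.0
) -> BeadModel:
    """Inject a global twist (degrees per base pair) and/or a circular-
    arc curvature (1/Å) about the model's principal axis.

    Each cross-sectional plane at axial coordinate z rotates rigidly by
    ``global_twist * z / rise``; curvature then maps the straight axis
    onto an arc of radius 1/curvature, carrying each section rigidly.
    Intra-section distances are preserved exactly.
    """
    if not (math.isfinite(global_twist) and math.isfinite(curvature)):
        raise ValueError("non-finite deformation parameters")
    out = model.copy()
    if model.n_beads == 0 or (global_twist == 0.0 and curvature == 0.0):
        return out

    centroid, axis = model.axis_frame()
    # frame with e3 = principal axis
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(tmp, axis)) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tmp, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    R = np.stack([e1, e2, axis])  # world -> local

    local = (model.coords - centroid) @ R.T
    x, y, z = local[:, 0].copy(), local[:, 1].copy(), local[:, 2].copy()

    if global_twist != 0.0:
        alpha = np.radians(global_twist) * z / model.params.rise
        ca, sa = np.cos(alpha), np.sin(alpha)
        x, y = ca * x - sa * y, sa * x + ca * y

    if curvature != 0.0:
        # bend onto an arc of radius 1/curvature, centre of curvature at
        # local (-r, 0, 0): each section plane rotates rigidly by z*kappa
        r = 1.0 / curvature
        theta = z * curvature
        ct, st = np.cos(theta), np.sin(theta)
        x, z = (r + x) * ct - r, (r + x) * st
        out.frame_origin = out.frame_axis = None  # axis is now an arc
    out.coords = np.stack([x, y, z], axis=1) @ R + centroid
    return out


# -- file I/O ------------------------------------------------------------

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def write_model(model: BeadModel, path: str | Path, sidecar: bool = True) -> None:
    """Write pseudo-atoms as PDB: P beads as phosphorus, B beads as
    carbon; one chain per strand; residue number = slot index + 1.

    A JSON sidecar (``<path>.json``) maps atom serials to design
    indices and records base pairing, so that reads recover the full
    annotation; without it reads are tolerant but unannotated.
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = "origamifit-model"
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    mdl = gemmi.Model("1")
    serial = 0
    serial_meta: dict[str, list] = {}
    order = np.lexsort((model.nuc_sub, model.nuc_slot, model.nuc_strand))
    for sid in np.unique(model.nuc_strand[order]):
        chain = gemmi.Chain(_CHAIN_IDS[int(sid) % len(_CHAIN_IDS)])
        nucs = order[model.nuc_strand[order] == sid]
        for nid in nucs:
            res = gemmi.Residue()
            res.name = "DN"
            res.seqid = gemmi.SeqId(int(model.nuc_slot[nid]) + 1, " ")
            for bead, name, elem in (
                (model.nuc_p[nid], "P", "P"),
                (model.nuc_b[nid], "C1", "C"),
            ):
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element(elem)
                xyz = model.coords[bead]
                a.pos = gemmi.Position(*xyz)
                a.occ = 1.0
                a.b_iso = 0.0
                serial += 1
                a.serial = serial
                res.add_atom(a)
                serial_meta[str(serial)] = [
                    int(model.nuc_helix[nid]),
                    int(model.nuc_slot[nid]),
                    int(model.nuc_sub[nid]),
                    int(sid),
                    name,
                    int(nid),
                ]
            chain.add_residue(res)
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.write_pdb(str(path))
    if sidecar:
        meta = {
            "serials": serial_meta,
            "pairs": model.nuc_pair.tolist(),
            "strand_kind": list(model.strand_kind),
            "params": vars(model.params),
            "frame": (
                None
                if model.frame_origin is None
                else {
                    "origin": model.frame_origin.tolist(),
                    "axis": model.frame_axis.tolist(),
                }
            ),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta))


def read_model(path: str | Path) -> BeadModel:
    """Read a pseudo-atom PDB written by :func:`write_model`.

    With the sidecar present, design indices and pairing are restored;
    without it, chains become strands, residue numbers become slots,
    helices are unknown (-1) and pairing is marked absent.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    meta = None
    side = Path(str(path) + ".json")
    if side.exists():
        meta = json.loads(side.read_text())

    coords, bead_kind, bead_nuc = [], [], []
    nuc_strand, nuc_helix, nuc_slot, nuc_sub = [], [], [], []
    nuc_p, nuc_b, nuc_axial = [], [], []
    strand_kind: list[str] = []
    old_ids: list[int] = []  # original nucleotide ids from the sidecar
    serial = 0
    # atoms are written P-then-B per nucleotide; group by that pattern
    # rather than by residue, since files from other tools may merge
    # same-numbered residues
    for mdl in st:
        for ci, chain in enumerate(mdl):
            for res in chain:
                for atom in res:
                    serial += 1
                    is_p = atom.element.name == "P"
                    if is_p:
                        nid = len(nuc_strand)
                        nuc_strand.append(ci)
                        nuc_helix.append(-1)
                        nuc_slot.append(res.seqid.num - 1)
                        nuc_sub.append(0)
                        nuc_p.append(-1)
                        nuc_b.append(-1)
                        old_ids.append(-1)
                    elif not nuc_strand or nuc_b[-1] != -1:
                        raise ValueError(
                            "malformed pseudo-atom file: B bead without a "
                            "preceding P bead"
                        )
                    nid = len(nuc_strand) - 1
                    if meta and str(serial) in meta["serials"]:
                        helix, slot, sub, sid, _, old_id = meta["serials"][
                            str(serial)
                        ]
                        nuc_helix[nid] = helix
                        nuc_slot[nid] = slot
                        nuc_sub[nid] = sub
                        nuc_strand[nid] = sid
                        old_ids[nid] = old_id
                    bid = len(coords)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    bead_kind.append(P_BEAD if is_p else B_BEAD)
                    bead_nuc.append(nid)
                    if is_p:
                        nuc_p[nid] = bid
                    else:
                        nuc_b[nid] = bid
        break  # first model only
    if any(b < 0 for b in nuc_b) or any(pp < 0 for pp in nuc_p):
        raise ValueError("a nucleotide is missing its P or B bead")
    nuc_axial = [float(s0 + su) for s0, su in zip(nuc_slot, nuc_sub)]
    n_nuc = len(nuc_strand)
    frame = None
    if meta and len(meta.get("pairs", [])) == n_nuc and -1 not in old_ids:
        # pairs are stored in the writer's original nucleotide ids;
        # remap through the serial sidecar to this read order
        old_to_new = {o: n for n, o in enumerate(old_ids)}
        pairs_old = meta["pairs"]
        nuc_pair = np.array(
            [
                old_to_new.get(pairs_old[o], -1) if pairs_old[o] >= 0 else -1
                for o in old_ids
            ],
            dtype=np.int32,
        )
        strand_kind = list(meta.get("strand_kind", []))
        params = GeometryParams(**meta["params"])
        frame = meta.get("frame")
    else:
        nuc_pair = np.full(n_nuc, -1, dtype=np.int32)
        params = GeometryParams()
    model = BeadModel(
        coords=np.asarray(coords, dtype=np.float64).reshape(-1, 3),
        bead_kind=np.asarray(bead_kind, dtype=np.uint8),
        bead_nuc=np.asarray(bead_nuc, dtype=np.int32),
        nuc_strand=np.asarray(nuc_strand, dtype=np.int32),
        nuc_helix=np.asarray(nuc_helix, dtype=np.int32),
        nuc_slot=np.asarray(nuc_slot, dtype=np.int32),
        nuc_sub=np.asarray(nuc_sub, dtype=np.int32),
        nuc_pair=nuc_pair,
        nuc_p=np.asarray(nuc_p, dtype=np.int32),
        nuc_b=np.asarray(nuc_b, dtype=np.int32),
        nuc_axial=np.asarray(nuc_axial, dtype=np.float64),
        nuc_base=["N"] * n_nuc,
        strand_kind=strand_kind,
        params=params,
        frame_origin=np.asarray(frame["origin"]) if frame else None,
        frame_axis=np.asarray(frame["axis"]) if frame else None,
    )
    model.validate()
    return model
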
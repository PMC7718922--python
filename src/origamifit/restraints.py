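"""Tagged harmonic elastic network and soft excluded volume.

The network holds the coarse-grained model near its idealized geometry
with three restraint classes that the fitting protocol relieves in
sequence: long-range *interhelical* bonds (crossover backbone bonds plus
inter-duplex pairs near crossovers), short-range *intrahelical* bonds
(pairs within one duplex), and *basepair* bonds joining Watson–Crick
partners.  Rest lengths come from the ideal model, so the network energy
of the idealized structure is exactly zero.

A single soft repulsion replaces non-bonded interactions, truncated with
a smooth switching function (switch-on 8 Å, cutoff 10 Å); pairs within
three covalent bonds of each other are excluded so the repulsion never
fights the network at rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .design import LatticeDesign
from .model import BeadModel

__all__ = [
    "CLASSES",
    "NetworkParams",
    "RestraintSet",
    "build_elastic_network",
    "energy_and_forces",
    "excluded_volume_forces",
]

INTERHELICAL, INTRAHELICAL, BASEPAIR = 0, 1, 2
CLASSES = {"interhelical": INTERHELICAL, "intrahelical": INTRAHELICAL,
           "basepair": BASEPAIR}
CLASS_NAMES = {v: k for k, v in CLASSES.items()}
ALL_CLASSES = frozenset(CLASSES)


@dataclass(frozen=True)
class NetworkParams:
    """Stiffnesses (kcal/mol/Å²), capture radii (Å) and excluded-volume
    parameters.  These are declared defaults of this package, not
    published force-field constants."""

    k_basepair: float = 5.0
    k_intrahelical: float = 1.0
    k_interhelical: float = 0.5
    d_intra: float = 10.0
    d_inter: float = 15.0
    sigma_ev: float = 4.0
    k_ev: float = 5.0
    switch_on: float = 8.0
    cutoff: float = 10.0


@dataclass
class RestraintSet:
    """Harmonic bonds (i, j, r0, k, class) plus excluded-volume terms."""

    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray
    k: np.ndarray
    cls: np.ndarray  # int8 class codes
    params: NetworkParams = field(default_factory=NetworkParams)
    exclusions: np.ndarray | None = None  # (m, 2) sorted pairs, 1-2/1-3/1-4

    @property
    def n_bonds(self) -> int:
        return len(self.i)

    def validate(self) -> None:
        if np.any(self.i == self.j):
            raise ValueError("bond with identical endpoints")
        if np.any(self.r0 <= 0):
            raise ValueError("non-positive rest length")
        pairs = np.stack([np.minimum(self.i, self.j),
                          np.maximum(self.i, self.j)], axis=1)
        if len(np.unique(pairs, axis=0)) != len(pairs):
            raise ValueError("duplicate bond pair")

    def class_mask(self, active: set[str] | frozenset[str]) -> np.ndarray:
        codes = {CLASSES[c] for c in active}
        return np.isin(self.cls, list(codes))

    # -- serialisation ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "i": self.i,
                "j": self.j,
                "r0": self.r0,
                "k": self.k,
                "class": [CLASS_NAMES[int(c)] for c in self.cls],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 params: NetworkParams | None = None) -> "RestraintSet":
        df = pd.read_csv(path, sep="\t")
        rs = cls(
            i=df["i"].to_numpy(np.int32),
            j=df["j"].to_numpy(np.int32),
            r0=df["r0"].to_numpy(float),
            k=df["k"].to_numpy(float),
            cls=np.array([CLASSES[c] for c in df["class"]], dtype=np.int8),
            params=params or NetworkParams(),
        )
        rs.validate()
        return rs


def _backbone_bonds(model: BeadModel) -> list[tuple[int, int]]:
    """Consecutive P-bead pairs along each strand (covalent backbone)."""
    out = []
    for sid in np.unique(model.nuc_strand):
        nucs = np.nonzero(model.nuc_strand == sid)[0]
        # nucleotides were appended in 5'->3' order at build time
        for a, b in zip(nucs[:-1], nucs[1:]):
            out.append((int(model.nuc_p[a]), int(model.nuc_p[b])))
    return out


def build_elastic_network(
    model: BeadModel,
    design: LatticeDesign | None = None,
    params: NetworkParams | None = None,
) -> RestraintSet:
    """Build the three-class network in the context of the strand diagram.

    * basepair: one bond per Watson–Crick pair between partner B beads;
    * intrahelical: covalent backbone bonds within a helix plus all
      same-helix bead pairs closer than ``d_intra`` in the input model
      (nick-adjacent backbone pairs stay connected only through the
      generic distance terms of the surrounding duplex, never through a
      covalent bond — nicks are physically discontinuous);
    * interhelical: covalent crossover backbone bonds plus inter-helix
      bead pairs within ``d_inter`` of each other near crossover slots.

    Rest lengths are the input-model distances.
    """
    params = params or NetworkParams()
    design = design or model.design
    coords = model.coords
    helix_of_bead = model.nuc_helix[model.bead_nuc]

    bonds: dict[tuple[int, int], tuple[float, int]] = {}

    def add(i: int, j: int, k: float, cls: int, keep_existing: bool = True):
        key = (i, j) if i < j else (j, i)
        if keep_existing and key in bonds:
            return
        bonds[key] = (k, cls)

    # covalent backbone: intrahelical within a helix, interhelical across
    backbone = _backbone_bonds(model)
    for i, j in backbone:
        same = helix_of_bead[i] == helix_of_bead[j]
        add(i, j,
            params.k_intrahelical if same else params.k_interhelical,
            INTRAHELICAL if same else INTERHELICAL,
            keep_existing=False)

    # Watson-Crick pairs between partner B beads
    nucs = np.nonzero(model.nuc_pair >= 0)[0]
    nucs = nucs[nucs < model.nuc_pair[nucs]]
    for n in nucs:
        add(int(model.nuc_b[n]), int(model.nuc_b[model.nuc_pair[n]]),
            params.k_basepair, BASEPAIR, keep_existing=False)

    # intrahelical distance pairs within one duplex
    for h in np.unique(model.nuc_helix):
        beads = np.nonzero(helix_of_bead == h)[0]
        if beads.size < 2:
            continue
        tree = cKDTree(coords[beads])
        for a, b in tree.query_pairs(params.d_intra):
            add(int(beads[a]), int(beads[b]), params.k_intrahelical,
                INTRAHELICAL)

    # interhelical pairs near crossovers
    if design is not None:
        from .design import enumerate_crossovers

        window = int(np.ceil(params.d_inter / model.params.rise))
        for xo in enumerate_crossovers(design):
            h1, h2 = xo.helices
            near1 = np.nonzero(
                (model.nuc_helix == h1)
                & (np.abs(model.nuc_slot - xo.slot) <= window)
            )[0]
            near2 = np.nonzero(
                (model.nuc_helix == h2)
                & (np.abs(model.nuc_slot - xo.slot) <= window)
            )[0]
            if near1.size == 0 or near2.size == 0:
                continue
            b1 = model.beads_for_nucleotides(near1)
            b2 = model.beads_for_nucleotides(near2)
            d = np.linalg.norm(
                coords[b1][:, None, :] - coords[b2][None, :, :], axis=2
            )
            for a, b in zip(*np.nonzero(d <= params.d_inter)):
                add(int(b1[a]), int(b2[b]), params.k_interhelical,
                    INTERHELICAL)

    # nicks are physically discontinuous: no direct P-P term across the
    # boundary in any class (the surrounding duplex still holds it)
    if design is not None:
        from .design import find_nicks

        kind_of_nuc = [model.strand_kind[s] for s in model.nuc_strand]
        for nick in find_nicks(design):
            before = [
                n for n in range(model.n_nucleotides)
                if model.nuc_helix[n] == nick.helix
                and model.nuc_slot[n] == nick.slot - 1
                and kind_of_nuc[n] == nick.kind
            ]
            after = [
                n for n in range(model.n_nucleotides)
                if model.nuc_helix[n] == nick.helix
                and model.nuc_slot[n] == nick.slot
                and kind_of_nuc[n] == nick.kind
            ]
            for a in before:
                for b in after:
                    i, j = int(model.nuc_p[a]), int(model.nuc_p[b])
                    bonds.pop((i, j) if i < j else (j, i), None)

    keys = np.array(sorted(bonds), dtype=np.int32).reshape(-1, 2)
    kv = np.array([bonds[tuple(k)] for k in keys])
    i, j = keys[:, 0], keys[:, 1]
    r0 = np.linalg.norm(coords[i] - coords[j], axis=1)

    # excluded-volume exclusions: 1-2/1-3/1-4 bonded pairs plus any pair
    # already inside sigma_ev in the ideal geometry — those contacts are
    # part of the rest state and are held by the network, so the
    # repulsion must not fight them
    excl = {tuple(p) for p in _bonded_exclusions(model, backbone)}
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(params.sigma_ev):
        excl.add((min(a, b), max(a, b)))
    exclusions = (
        np.array(sorted(excl), dtype=np.int32)
        if excl else np.empty((0, 2), dtype=np.int32)
    )

    rs = RestraintSet(
        i=i,
        j=j,
        r0=r0,
        k=kv[:, 0].astype(float),
        cls=kv[:, 1].astype(np.int8),
        params=params,
        exclusions=exclusions,
    )
    rs.validate()
    return rs


def _bonded_exclusions(model: BeadModel,
                       backbone: list[tuple[int, int]]) -> np.ndarray:
    """1-2, 1-3 and 1-4 pairs of the covalent graph (backbone P-P,
    intra-nucleotide P-B, Watson-Crick B-B)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import dijkstra

    n = model.n_beads
    edges = list(backbone)
    edges += [
        (int(model.nuc_p[k]), int(model.nuc_b[k]))
        for k in range(model.n_nucleotides)
    ]
    paired = np.nonzero(model.nuc_pair >= 0)[0]
    paired = paired[paired < model.nuc_pair[paired]]
    edges += [
        (int(model.nuc_b[k]), int(model.nuc_b[model.nuc_pair[k]]))
        for k in paired
    ]
    if not edges:
        return np.empty((0, 2), dtype=np.int32)
    e = np.asarray(edges)
    g = sp.csr_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    g = g + g.T
    dist = dijkstra(g, unweighted=True, limit=3)
    a, b = np.nonzero(np.isfinite(dist) & (dist > 0))
    keep = a < b
    return np.stack([a[keep], b[keep]], axis=1).astype(np.int32)


# -- energies and forces -------------------------------------------------

def _bond_energy_forces(coords, rs: RestraintSet, mask) -> tuple[float, np.ndarray]:
    forces = np.zeros_like(coords)
    i, j = rs.i[mask], rs.j[mask]
    if len(i) == 0:
        return 0.0, forces
    d = coords[i] - coords[j]
    r = np.linalg.norm(d, axis=1)
    dr = r - rs.r0[mask]
    k = rs.k[mask]
    energy = float(np.sum(0.5 * k * dr * dr))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, d / np.maximum(r, 1e-300)[:, None], 0.0)
    f = -(k * dr)[:, None] * unit  # force on bead i; -f on bead j
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return energy, forces


def _switch(r: np.ndarray, r_on: float, r_off: float) -> tuple[np.ndarray, np.ndarray]:
    """Raised-cosine switching function S(r) and dS/dr: 1 below r_on,
    0 beyond r_off."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    t = (r[mid] - r_on) / (r_off - r_on)
    s[mid] = 0.5 * (1.0 + np.cos(np.pi * t))
    ds[mid] = -0.5 * np.pi * np.sin(np.pi * t) / (r_off - r_on)
    s[r >= r_off] = 0.0
    return s, ds


def _ev_pairs(coords: np.ndarray, cutoff: float,
              exclusions: np.ndarray | None) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if exclusions is not None and len(exclusions) and len(pairs):
        n = len(coords)
        excl = set(map(tuple, exclusions))
        keep = [tuple(p) not in excl for p in pairs]
        pairs = pairs[np.asarray(keep, dtype=bool)]
    return pairs


def excluded_volume_forces(
    model_or_coords,
    params: NetworkParams | None = None,
    exclusions: np.ndarray | None = None,
    pairs: np.ndarray | None = None,
    brute_force: bool = False,
) -> tuple[float, np.ndarray]:
    """Soft repulsion ``1/2 k_ev (sigma - r)^2`` for r < sigma, modulated
    by the smooth switch (8→10 Å); bonded 1-2/1-3/1-4 pairs excluded.

    The neighbour-search result is exactly the all-pairs brute force
    (``brute_force=True`` evaluates that reference path).
    """
    params = params or NetworkParams()
    coords = getattr(model_or_coords, "coords", model_or_coords)
    n = len(coords)
    forces = np.zeros_like(coords)
    if n < 2:
        return 0.0, forces
    if pairs is None:
        if brute_force:
            a, b = np.triu_indices(n, k=1)
            pairs = np.stack([a, b], axis=1)
            if exclusions is not None and len(exclusions):
                excl = set(map(tuple, exclusions))
                keep = [tuple(p) not in excl for p in pairs]
                pairs = pairs[np.asarray(keep, dtype=bool)]
        else:
            pairs = _ev_pairs(coords, params.cutoff, exclusions)
    if len(pairs) == 0:
        return 0.0, forces
    i, j = pairs[:, 0], pairs[:, 1]
    d = coords[i] - coords[j]
    r = np.linalg.norm(d, axis=1)
    active = r < min(params.sigma_ev, params.cutoff)
    if not np.any(active):
        return 0.0, forces
    i, j, d, r = i[active], j[active], d[active], r[active]
    u = 0.5 * params.k_ev * (params.sigma_ev - r) ** 2
    du = -params.k_ev * (params.sigma_ev - r)
    s, ds = _switch(r, params.switch_on, params.cutoff)
    energy = float(np.sum(u * s))
    dtot = du * s + u * ds
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, d / np.maximum(r, 1e-300)[:, None], 0.0)
    f = -dtot[:, None] * unit
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return energy, forces


def energy_and_forces(
    model_or_coords,
    restraints: RestraintSet,
    active_classes: set[str] | frozenset[str] = ALL_CLASSES,
    include_excluded_volume: bool = True,
    ev_pairs: np.ndarray | None = None,
    breakdown_terms: bool = False,
) -> tuple[float, np.ndarray, dict[str, float]]:
    """Total energy, exact negative-gradient forces, and (on request) a
    per-class breakdown.  Bonds in inactive classes contribute nothing."""
    coords = getattr(model_or_coords, "coords", model_or_coords)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    mask = restraints.class_mask(active_classes)
    e_bonds, forces = _bond_energy_forces(coords, restraints, mask)
    breakdown = {}
    if breakdown_terms:
        for name in active_classes:
            m = restraints.class_mask({name})
            e, _ = _bond_energy_forces(coords, restraints, m)
            breakdown[name] = e
    e_ev = 0.0
    if include_excluded_volume:
        e_ev, f_ev = excluded_volume_forces(
            coords, restraints.params, restraints.exclusions, pairs=ev_pairs
        )
        forces += f_ev
    breakdown["excluded_volume"] = e_ev
    return e_bonds + e_ev, forces, breakdown


class NeighborList:
    """Verlet-style pair list for the excluded volume with a skin;
    rebuilt when any bead has moved more than half the skin."""

    def __init__(self, params: NetworkParams,
                 exclusions: np.ndarray | None, skin: float = 2.0):
        self.params = params
        self.exclusions = exclusions
        self.skin = skin
        self._ref: np.ndarray | None = None
        self.pairs: np.ndarray | None = None

    def get(self, coords: np.ndarray) -> np.ndarray:
        if (
            self._ref is None
            or np.max(np.sum((coords - self._ref) ** 2, axis=1))
            > (0.5 * self.skin) ** 2
        ):
            self.pairs = _ev_pairs(
                coords, self.params.cutoff + self.skin, self.exclusions
            )
            self._ref = coords.copy()
        return self.pairs
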
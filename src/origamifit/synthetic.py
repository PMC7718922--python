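"""Synthetic designs, ground-truth models and simulated density maps.

The generators emulate the object classes multilayer-origami studies
work with — duplexes, two-helix junction fixtures, honeycomb six-helix
tubes, square-lattice 2x2 / 4x4 blocks, and a two-domain tower — as
syntactically valid caDNAno 2.x JSON, then derive deformed ground-truth
bead models and Gaussian-simulated maps with optional voxel noise and
half-map pairs.

All randomness flows from one seed through ``numpy.random.SeedSequence``
substreams so half maps and any downstream dynamics draw independent,
reproducible noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import density as _density
from . import model as _model
from .design import LatticeDesign, parse_cadnano

__all__ = ["FixtureSpec", "Dataset", "make_design", "make_dataset"]

KINDS = (
    "duplex",
    "two_helix",
    "six_helix_tube",
    "block_2x2",
    "block_4x4",
    "multi_domain_tower",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parametric description of one synthetic fixture.

    noise is the voxel-noise standard deviation relative to the RMS map
    density; twist is in degrees per base pair, curvature in 1/Å.
    """

    kind: str = "six_helix_tube"
    length: int = 64
    lattice: str | None = None  # default chosen by kind
    crossover_spacing: int | None = None  # default 7 (honeycomb) / 8 (square)
    deletion_every: int = 0  # one skip every n slots (0 = none)
    insertion_every: int = 0
    nick_every: int | None = None  # staple cut period (None = 2*spacing)
    twist: float = 0.0
    curvature: float = 0.0
    resolution: float = 10.0
    voxel_size: float = 2.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.noise > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise > 0")
        if self.length < 8:
            raise ValueError("length must be at least 8 slots")

    @property
    def lattice_(self) -> str:
        if self.lattice is not None:
            return self.lattice
        return "honeycomb" if self.kind in ("duplex", "two_helix",
                                            "six_helix_tube") else "square"

    @property
    def spacing_(self) -> int:
        if self.crossover_spacing is not None:
            return self.crossover_spacing
        return 7 if self.lattice_ == "honeycomb" else 8


# -- lattice layouts -----------------------------------------------------

def _helix_layout(spec: FixtureSpec):
    """(path of (row, col), ring?) for each fixture kind.

    The honeycomb six-helix tube is the hexagonal ring of mutually
    adjacent sites; square blocks are serpentine rasters (the 2x2 one
    closes into a ring).
    """
    kind = spec.kind
    if kind == "duplex":
        return [(0, 0)], False
    if kind == "two_helix":
        return [(0, 0), (0, 1)], True
    if kind == "six_helix_tube":
        if spec.lattice_ != "honeycomb":
            raise ValueError("six_helix_tube requires the honeycomb lattice")
        return [(0, 0), (1, 0), (1, 1), (1, 2), (0, 2), (0, 1)], True
    if kind in ("block_2x2", "block_4x4"):
        n = 2 if kind == "block_2x2" else 4
        if spec.lattice_ != "square":
            raise ValueError(f"{kind} requires the square lattice")
        path = []
        for r in range(n):
            cols = range(n) if r % 2 == 0 else range(n - 1, -1, -1)
            path += [(r, c) for c in cols]
        return path, (n == 2)
    if kind == "multi_domain_tower":
        if spec.lattice_ != "square":
            raise ValueError("multi_domain_tower requires the square lattice")
        return None, False  # handled specially
    raise ValueError(kind)


class _Builder:
    """Accumulates caDNAno lane arrays and performs pointer surgery."""

    def __init__(self, n_slots: int):
        self.n = n_slots
        self.helices: list[tuple[int, int, int]] = []  # num, row, col
        self.scaf: dict[int, np.ndarray] = {}
        self.stap: dict[int, np.ndarray] = {}
        self.loop: dict[int, np.ndarray] = {}
        self.skip: dict[int, np.ndarray] = {}
        self.scaf_dir: dict[int, int] = {}
        self.range_: dict[int, tuple[int, int]] = {}

    def add_helix(self, num, row, col, lo, hi, scaf_dir):
        self.helices.append((num, row, col))
        self.scaf[num] = np.full((self.n, 4), -1, dtype=np.int64)
        self.stap[num] = np.full((self.n, 4), -1, dtype=np.int64)
        self.loop[num] = np.zeros(self.n, dtype=np.int64)
        self.skip[num] = np.zeros(self.n, dtype=np.int64)
        self.scaf_dir[num] = scaf_dir
        self.range_[num] = (lo, hi)
        # continuous lanes over [lo, hi): scaffold along scaf_dir,
        # staple antiparallel
        for lane, d in ((self.scaf, scaf_dir), (self.stap, -scaf_dir)):
            arr = lane[num]
            for s in range(lo, hi):
                prev, nxt = s - d, s + d
                if lo <= prev < hi:
                    arr[s, 0], arr[s, 1] = num, prev
                if lo <= nxt < hi:
                    arr[s, 2], arr[s, 3] = num, nxt

    def connect_scaf(self, a, sa, b, sb):
        self.scaf[a][sa, 2], self.scaf[a][sa, 3] = b, sb
        self.scaf[b][sb, 0], self.scaf[b][sb, 1] = a, sa

    def stap_double_crossover(self, a, b, q):
        """Reciprocal staple exchange between helices a and b at slots
        (q, q + stap_dir(a))."""
        da = -self.scaf_dir[a]
        q2 = q + da
        self.stap[a][q, 2], self.stap[a][q, 3] = b, q
        self.stap[b][q, 0], self.stap[b][q, 1] = a, q
        self.stap[b][q2, 2], self.stap[b][q2, 3] = a, q2
        self.stap[a][q2, 0], self.stap[a][q2, 1] = b, q2

    def cut_stap(self, h, s1, s2):
        """Remove the staple backbone connection between adjacent slots."""
        for x, y in ((s1, s2), (s2, s1)):
            r = self.stap[h][x]
            if r[2] == h and r[3] == y:
                r[2] = r[3] = -1
            if r[0] == h and r[1] == y:
                r[0] = r[1] = -1

    def to_json(self, name: str) -> str:
        vstrands = []
        for num, row, col in self.helices:
            vstrands.append(
                {
                    "num": num,
                    "row": row,
                    "col": col,
                    "scaf": self.scaf[num].tolist(),
                    "stap": self.stap[num].tolist(),
                    "loop": self.loop[num].tolist(),
                    "skip": self.skip[num].tolist(),
                    "stap_colors": [],
                }
            )
        return json.dumps({"name": name, "vstrands": vstrands})


def _route_bundle(b: _Builder, path, ring: bool, lo: int, hi: int,
                  spacing: int, nick_every: int, num0: int = 0,
                  dir0: int = 1):
    """Serpentine scaffold + staple double crossovers for one bundle."""
    m = len(path)
    for i, (r, c) in enumerate(path):
        b.add_helix(num0 + i, r, c, lo, hi, dir0 * (1 if i % 2 == 0 else -1))

    # scaffold crossovers at range ends between consecutive helices
    for i in range(m - 1):
        a, c = num0 + i, num0 + i + 1
        s = hi - 1 if b.scaf_dir[a] > 0 else lo
        b.connect_scaf(a, s, c, s)
    if ring and m >= 2:
        a, c = num0 + m - 1, num0
        s = hi - 1 if b.scaf_dir[a] > 0 else lo
        b.connect_scaf(a, s, c, s)

    # staple double crossovers: pair j at slots == (j % 2) * spacing
    # (mod 2*spacing), kept clear of the range ends
    n_pairs = m - 1 + (1 if ring and m > 2 else 0)
    for j in range(n_pairs):
        a, c = num0 + j, num0 + (j + 1) % m
        parity = j % 2
        q = lo + parity * spacing
        while q < lo + 2:
            q += 2 * spacing
        while q + 1 <= hi - 3:
            b.stap_double_crossover(a, c, q)
            q += 2 * spacing

    # staple nicks away from crossover slots
    if nick_every > 0 and m >= 1:
        offset = max(2, spacing // 2)
        for i in range(m):
            h = num0 + i
            for s in range(lo + offset, hi - 1, nick_every):
                if (s - lo) % (2 * spacing) in (0, 1, spacing, spacing + 1):
                    continue
                b.cut_stap(h, s, s + 1)


def make_design(spec: FixtureSpec) -> tuple[str, LatticeDesign]:
    """Build the caDNAno JSON for a fixture and parse it back.

    The returned design always satisfies the parser's invariants; the
    JSON text is what a designer's file would contain.
    """
    L = spec.length
    spacing = spec.spacing_
    nick_every = spec.nick_every if spec.nick_every is not None else 2 * spacing
    b = _Builder(L)

    if spec.kind == "multi_domain_tower":
        # 2x2 domain over the full length, 4x4 skirt over the second half
        path1 = [(0, 0), (0, 1), (1, 1), (1, 0)]
        _route_bundle(b, path1, True, 0, L, spacing, nick_every, num0=0)
        rest = [
            (0, 2), (0, 3), (1, 3), (1, 2), (2, 2), (2, 3), (3, 3), (3, 2),
            (3, 1), (3, 0), (2, 0), (2, 1),
        ]
        _route_bundle(b, rest, False, L // 2, L, spacing, nick_every, num0=4)
    else:
        path, ring = _helix_layout(spec)
        _route_bundle(b, path, ring, 0, L, spacing, nick_every)

    for num, _, _ in b.helices:
        lo, hi = b.range_[num]
        if spec.deletion_every > 0:
            for s in range(lo + spec.deletion_every - 1, hi,
                           spec.deletion_every):
                b.skip[num][s] = -1
        if spec.insertion_every > 0:
            for s in range(lo + spec.insertion_every - 1, hi,
                           spec.insertion_every):
                b.loop[num][s] = 1

    text = b.to_json(f"synthetic-{spec.kind}")
    design = parse_cadnano(text, lattice=spec.lattice_)
    return text, design


# -- datasets ------------------------------------------------------------

@dataclass
class Dataset:
    """A complete synthetic study: design, ground truth, and maps."""

    spec: FixtureSpec
    json_text: str
    design: LatticeDesign
    truth: "_model.BeadModel"
    dmap: "_density.DensityMap"
    half1: "_density.DensityMap"
    half2: "_density.DensityMap"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "design.json").write_text(self.json_text)
        _model.write_model(self.truth, outdir / "truth.pdb")
        _density.write_map(self.dmap, outdir / "map.mrc")
        _density.write_map(self.half1, outdir / "half1.mrc")
        _density.write_map(self.half2, outdir / "half2.mrc")
        (outdir / "spec.json").write_text(json.dumps(asdict(self.spec)))


def make_dataset(spec: FixtureSpec) -> Dataset:
    """Design → ideal model → injected deformation → simulated map and
    seeded half-map noise realisations."""
    text, design = make_design(spec)
    ideal = _model.build_ideal_model(design)
    truth = _model.apply_deformation(ideal, spec.twist, spec.curvature)
    dmap = _density.simulate_map(truth, spec.resolution, spec.voxel_size)
    if spec.noise > 0:
        rms = float(np.sqrt(np.mean(dmap.values ** 2)))
        streams = np.random.SeedSequence(spec.seed).spawn(2)
        halves = []
        for ss in streams:
            rng = np.random.default_rng(ss)
            noisy = dmap.copy()
            noisy.values = dmap.values + spec.noise * rms * rng.standard_normal(
                dmap.shape
            )
            halves.append(noisy)
        half1, half2 = halves
    else:
        half1, half2 = dmap.copy(), dmap.copy()
    return Dataset(spec, text, design, truth, dmap, half1, half2)
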
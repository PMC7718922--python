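"""Global-twist mechanics of multilayer DNA origami.

Multilayer bundles built with default square-lattice crossover spacing
(10.67 bp/turn) underwind their helices relative to B-DNA (10.5
bp/turn), producing right-handed internal torques and a global twist
whose magnitude falls with the cross-section's torsional stiffness —
the polar moment of inertia J of the helix bundle.  This module
measures the global twist from a bead model or directly from a density
map, computes J from a cross-section, and turns the two into an
empirical design-correction guide: the insertion/deletion density that
returns the imposed twist density to 10.5 bp/turn, optionally refined
against a user-supplied calibration table of (J, imposed density,
observed twist) points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .density import DensityMap, normalized_values
from .design import LATTICE_BP_PER_TURN, LatticeDesign, imposed_twist_density
from .model import BeadModel, lattice_xy

__all__ = [
    "TwistProfile",
    "CrossSection",
    "measure_twist_model",
    "measure_twist_map",
    "polar_moment",
    "cross_section_from_design",
    "twist_correction_guide",
]


@dataclass
class TwistProfile:
    """Cross-section rotation along the bundle axis.

    Angles are unwrapped and relative to the reference section; the
    slope is the fitted global twist in degrees per base pair, with
    positive sign meaning right-handed (matching B-DNA helicity).
    """

    axial: np.ndarray  # axial coordinate, Å
    bp_index: np.ndarray  # axial coordinate, base pairs
    angle: np.ndarray  # degrees, unwrapped
    slope: float  # degrees per base pair
    slope_stderr: float
    handedness: int  # +1 right-handed, -1 left-handed
    low_confidence: bool = False

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"axial_A": self.axial, "bp": self.bp_index,
             "angle_deg": self.angle}
        ).to_csv(path, index=False)


@dataclass
class CrossSection:
    """Helix-axis positions in a section plane (nm) and the disc radius
    used for the polar moment (nm)."""

    positions: np.ndarray  # (n, 2) nm
    r_h: float = 1.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if len(self.positions) < 1 or not np.all(np.isfinite(self.positions)):
            raise ValueError("cross-section needs >= 1 finite helix position")


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    sxx = float(np.sum(xm * xm))
    slope = float(np.sum(xm * ym) / sxx)
    resid = ym - slope * xm
    dof = max(len(x) - 2, 1)
    stderr = math.sqrt(float(np.sum(resid ** 2)) / dof / sxx)
    return slope, stderr


def _basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(tmp, axis))) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tmp, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _kabsch2d(ref: np.ndarray, cur: np.ndarray) -> float:
    """Least-squares in-plane rotation angle (degrees) mapping ref→cur,
    after centering both point sets."""
    a = ref - ref.mean(axis=0)
    b = cur - cur.mean(axis=0)
    num = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    den = float(np.sum(a[:, 0] * b[:, 0] + a[:, 1] * b[:, 1]))
    return math.degrees(math.atan2(num, den))


def measure_twist_model(model: BeadModel, min_sections: int = 10) -> TwistProfile:
    """Global twist of a bead model about its bundle axis.

    Per design slot, each helix contributes the centroid of its base
    pair; the in-plane rotation of these helix centres relative to the
    reference section (the first one carrying the fullest helix
    complement, registered on the shared helix subset elsewhere) is
    fitted against the axial base-pair index by ordinary least squares.
    """
    origin, axis = model.axis_frame()
    e1, e2 = _basis(axis)

    sections: dict[float, dict[int, np.ndarray]] = {}
    for h in np.unique(model.nuc_helix):
        keys, cen = model.pair_centroids(int(h))
        for k, c in zip(keys, cen):
            sections.setdefault(float(k), {})[int(h)] = c
    keys = sorted(sections)
    if len(keys) < min_sections:
        raise ValueError(
            f"model spans only {len(keys)} base-pair sections "
            f"(need >= {min_sections})"
        )

    full = max(len(sections[k]) for k in keys)
    ref_key = next(k for k in keys if len(sections[k]) == full)
    ref = sections[ref_key]

    bp_idx, axial, angles = [], [], []
    low_confidence = False
    for k in keys:
        sec = sections[k]
        shared = sorted(set(sec) & set(ref))
        if len(shared) < 2:
            low_confidence = True
            continue
        pts_ref = np.array(
            [[np.dot(ref[h] - origin, e1), np.dot(ref[h] - origin, e2)]
             for h in shared]
        )
        pts = np.array(
            [[np.dot(sec[h] - origin, e1), np.dot(sec[h] - origin, e2)]
             for h in shared]
        )
        spread = pts_ref - pts_ref.mean(axis=0)
        if np.linalg.matrix_rank(spread, tol=1e-6) < 1 or (
            np.linalg.norm(spread, axis=1).max() < 1e-6
        ):
            low_confidence = True
            continue
        z = float(np.mean([np.dot(sec[h] - origin, axis) for h in shared]))
        bp_idx.append(k)
        axial.append(z)
        angles.append(_kabsch2d(pts_ref, pts))
    if len(bp_idx) < min_sections:
        raise ValueError("too few usable cross-sections")

    angles = np.unwrap(np.asarray(angles), period=360.0)
    bp_idx = np.asarray(bp_idx)
    slope, stderr = _ols_slope(bp_idx, angles)
    return TwistProfile(
        axial=np.asarray(axial),
        bp_index=bp_idx,
        angle=angles,
        slope=slope,
        slope_stderr=stderr,
        handedness=1 if slope >= 0 else -1,
        low_confidence=low_confidence,
    )


# -- map-based twist -----------------------------------------------------

def _rot_correlation_angle(ref_polar: np.ndarray, cur_polar: np.ndarray,
                           dtheta: float, window: float) -> float:
    """Rotation (degrees) maximising the circular cross-correlation of
    two polar images P(r, theta), searched within +/- window degrees
    with parabolic sub-sample refinement."""
    fa = np.fft.fft(ref_polar, axis=1)
    fb = np.fft.fft(cur_polar, axis=1)
    corr = np.fft.ifft(fb * np.conj(fa), axis=1).real.sum(axis=0)
    n = corr.size
    lags = np.arange(n)
    lags[lags > n // 2] -= n
    angs = lags * dtheta
    ok = np.abs(angs) <= window
    idx = np.argmax(np.where(ok, corr, -np.inf))
    best = corr[idx]
    prev = corr[(idx - 1) % n]
    nxt = corr[(idx + 1) % n]
    denom = prev - 2.0 * best + nxt
    frac = 0.0 if denom == 0 else 0.5 * (prev - nxt) / denom
    return float(angs[idx] + frac * dtheta)


def measure_twist_map(
    dmap: DensityMap,
    axis: np.ndarray | str = "auto",
    slab_thickness: float = 10.0,
    rise: float = 3.4,
    anisotropy_min: float = 1.5,
    search_window: float = 30.0,
    n_theta: int = 720,
) -> TwistProfile:
    """Global twist straight from a density map.

    The map is sliced into axial slabs; each slab's in-plane density
    image is resampled to polar coordinates about the axis, and the
    rotation between consecutive slabs is found by maximising the
    rotational cross-correlation (restricted to ``search_window``
    degrees, below the first symmetry replica of typical bundle
    cross-sections).  Cumulative rotations are fitted against the axial
    base-pair coordinate.
    """
    rho = normalized_values(dmap)
    w = rho.ravel()
    if w.sum() <= 0:
        raise ValueError("map has no positive density")
    pts = dmap.grid_points()
    wn = w / w.sum()
    c = wn @ pts
    d = pts - c
    cov = (d * wn[:, None]).T @ d
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if isinstance(axis, str):
        if math.sqrt(vals[0] / max(vals[1], 1e-30)) < anisotropy_min:
            raise ValueError(
                "map is not elongated enough for a twist axis "
                f"(anisotropy < {anisotropy_min})"
            )
        ax = vecs[:, 0]
    else:
        ax = np.asarray(axis, float)
        ax = ax / np.linalg.norm(ax)
    e1, e2 = _basis(ax)

    t = d @ ax
    u, v = d @ e1, d @ e2
    n_slabs = max(int(np.ceil((t.max() - t.min()) / slab_thickness)), 2)
    edges = np.linspace(t.min() - 1e-9, t.max() + 1e-9, n_slabs + 1)
    rmax = float(np.sqrt(u ** 2 + v ** 2).max())
    nbin = max(int(2 * rmax / dmap.voxel_size), 8)
    extent = [-rmax, rmax]

    # per-slab in-plane images on a common grid
    images, centers, masses = [], [], []
    for i in range(n_slabs):
        sel = (t >= edges[i]) & (t < edges[i + 1])
        img, _, _ = np.histogram2d(
            u[sel], v[sel], bins=nbin, range=[extent, extent],
            weights=w[sel],
        )
        images.append(img)
        centers.append(0.5 * (edges[i] + edges[i + 1]))
        masses.append(img.sum())
    masses = np.asarray(masses)
    keep = masses > 0.25 * masses.max()

    # polar resampling about the axis
    dtheta = 360.0 / n_theta
    thetas = np.radians(np.arange(n_theta) * dtheta)
    radii = np.linspace(2.0, rmax * 0.95, max(nbin // 2, 8))
    px = (radii[:, None] * np.cos(thetas)[None, :] + rmax) / (2 * rmax) * nbin
    py = (radii[:, None] * np.sin(thetas)[None, :] + rmax) / (2 * rmax) * nbin
    polar = {}
    for i in np.nonzero(keep)[0]:
        polar[i] = ndimage.map_coordinates(
            images[i], [px, py], order=1, mode="constant"
        ) * radii[:, None]

    idxs = sorted(polar)
    if len(idxs) < 3:
        raise ValueError("too few populated slabs along the axis")
    angles = [0.0]
    for a, b in zip(idxs[:-1], idxs[1:]):
        inc = _rot_correlation_angle(polar[a], polar[b], dtheta,
                                     search_window)
        angles.append(angles[-1] + inc)
    axial = np.array([centers[i] for i in idxs])
    angles = np.asarray(angles)
    bp = axial / rise
    slope, stderr = _ols_slope(bp, angles)
    return TwistProfile(
        axial=axial,
        bp_index=bp,
        angle=angles,
        slope=slope,
        slope_stderr=stderr,
        handedness=1 if slope >= 0 else -1,
    )


# -- polar moment and the correction guide -------------------------------

def polar_moment(cross_section: CrossSection) -> float:
    """Polar moment of inertia J (nm^4) of the helix bundle: each helix
    a solid disc of radius r_h, moved off the section centroid via the
    parallel-axis theorem: J = sum(pi r^4 / 2 + pi r^2 d^2)."""
    pos = cross_section.positions
    r = cross_section.r_h
    d2 = np.sum((pos - pos.mean(axis=0)) ** 2, axis=1)
    return float(len(pos) * math.pi * r ** 4 / 2.0
                 + math.pi * r ** 2 * np.sum(d2))


def cross_section_from_design(
    design: LatticeDesign, inter_helix_nm: float = 2.5, r_h: float = 1.0
) -> CrossSection:
    """The planned cross-section: helix lattice positions in nm."""
    pos = np.array(
        [lattice_xy(design.lattice, h.row, h.col, inter_helix_nm)
         for h in design.helices]
    )
    return CrossSection(pos, r_h=r_h)


TARGET_DENSITY = 10.5  # twist-neutral B-DNA, bp per turn


def twist_correction_guide(
    design: LatticeDesign,
    calibration: pd.DataFrame | None = None,
    inter_helix_nm: float = 2.5,
    r_h: float = 1.0,
) -> dict:
    """Recommend the indel density that removes the imposed twist.

    With net insertions-per-slot delta, the imposed density is
    ``rho_L * (1 + delta)``; solving for 10.5 bp/turn gives the
    recommended change relative to the design's current indel content
    (for default square-lattice spacing: 1 deletion per 64 slots).  A
    calibration table with columns ``polar_moment_nm4``,
    ``imposed_density_bp_per_turn`` and ``observed_twist_deg_per_bp``
    (the shape of published per-object scatter data) adds an
    interpolated expected residual twist at this design's (J, density).
    """
    density, table = imposed_twist_density(design)
    rho = LATTICE_BP_PER_TURN[design.lattice]
    slots = int(table["slots"].sum())
    delta_now = float(
        (table["insertions"].sum() - table["deletions"].sum()) / slots
    )
    delta_target = TARGET_DENSITY / rho - 1.0
    change = delta_target - delta_now
    repeat = 21 if design.lattice == "honeycomb" else 32
    if abs(change) < 1e-9:
        status = "no_change"
    elif change < 0:
        status = "add_deletions"
    else:
        status = "add_insertions_or_remove_deletions"
    J = polar_moment(cross_section_from_design(design, inter_helix_nm, r_h))
    out = {
        "lattice": design.lattice,
        "polar_moment_nm4": J,
        "imposed_density_bp_per_turn": density,
        "target_density_bp_per_turn": TARGET_DENSITY,
        "current_net_indels_per_slot": delta_now,
        "recommended_net_indels_per_slot": change,
        "recommended_net_indels_per_repeat": change * repeat,
        "resulting_density_bp_per_turn": rho * (1.0 + delta_now + change),
        "status": status,
    }
    if calibration is not None:
        out["expected_residual_twist_deg_per_bp"] = _interp_calibration(
            calibration, J, density
        )
    return out


def _interp_calibration(table: pd.DataFrame, J: float,
                        density: float) -> float:
    from scipy.interpolate import griddata

    pts = table[
        ["polar_moment_nm4", "imposed_density_bp_per_turn"]
    ].to_numpy(float)
    vals = table["observed_twist_deg_per_bp"].to_numpy(float)
    # scale axes to comparable ranges before interpolating
    scale = np.maximum(pts.max(axis=0) - pts.min(axis=0), 1e-12)
    q = np.array([[J, density]]) / scale
    res = griddata(pts / scale, vals, q, method="linear")
    if np.isnan(res[0]):
        res = griddata(pts / scale, vals, q, method="nearest")
    return float(res[0])
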
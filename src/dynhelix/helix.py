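"""Helical-lattice geometry: axis fit, diameter, pitch, helix angle, tetramer Rg.

The axis is seeded with the principal direction of the monomer centers of
mass and refined by least squares so that the radial distances of the centers
about the axis have minimal variance.  With monomers ordered along the
helical path, the axial coordinate and the unwrapped azimuth are each fitted
linearly against the path index, giving the rise per monomer and the
azimuthal step; from these

* ``pitch = rise_per_monomer * monomers_per_turn`` (axial rise per full turn),
* ``helix_angle = arctan(rise / (radius * azimuthal_step))`` — the pitch angle
  between the local helical path and the plane normal to the axis, consistent
  with the few-degree values such assemblies show.

The diameter is twice the mean radial distance of monomer centers (an outer
envelope diameter over all particles is reported alongside).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError
from .geometry import radius_of_gyration
from .structures import OligomerFrame, Trajectory, WindowSpec, select_window
from .topology import AssemblyTopology, _azimuth_basis, _monomer_com

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HelixParams:
    axis_point: np.ndarray
    axis_direction: np.ndarray
    diameter_A: float
    outer_diameter_A: float
    pitch_A: float
    helix_angle_deg: float
    rise_per_monomer_A: float
    monomers_per_turn: float


def fit_axis(frame: OligomerFrame, topology: AssemblyTopology | None = None):
    """(axis_point, unit axis_direction) minimizing radial-distance variance."""
    coms = np.array([_monomer_com(m) for m in frame.monomers])
    if len(coms) < 8:
        raise DegenerateGeometryError("axis fit needs >= 8 monomers")
    center = coms.mean(axis=0)
    rel = coms - center
    cov = rel.T @ rel
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, -1]
    # collinear monomer centers carry no radial information
    if evals[1] < 1e-9 * evals[2]:
        raise DegenerateGeometryError("monomer centers are collinear; no cylinder axis")

    def spherical(d):
        theta = np.arccos(np.clip(d[2], -1, 1))
        phi = np.arctan2(d[1], d[0])
        return theta, phi

    def unit(theta, phi):
        return np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )

    def residuals(p):
        theta, phi, ox, oy = p
        d = unit(theta, phi)
        u, v = _azimuth_basis(d)
        point = center + ox * u + oy * v
        r = rel + center - point
        radial = r - np.outer(r @ d, d)
        dist = np.linalg.norm(radial, axis=1)
        return dist - dist.mean()

    # seed with each principal direction; a flat ring's best axis is the
    # smallest-eigenvalue direction, a tall helix's the largest
    best = None
    for seed in (evecs[:, 2], evecs[:, 1], evecs[:, 0]):
        theta0, phi0 = spherical(seed)
        sol = least_squares(residuals, x0=[theta0, phi0, 0.0, 0.0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    theta, phi, ox, oy = best.x
    d = unit(theta, phi)
    u, v = _azimuth_basis(d)
    point = center + ox * u + oy * v
    # canonical orientation for determinism: positive largest |component|
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    return point, d


def _cylindrical(coms: np.ndarray, point: np.ndarray, direction: np.ndarray):
    u, v = _azimuth_basis(direction)
    rel = coms - point
    axial = rel @ direction
    radial_vec = rel - np.outer(axial, direction)
    radius = np.linalg.norm(radial_vec, axis=1)
    azimuth = np.arctan2(radial_vec @ v, radial_vec @ u)
    return radius, azimuth, axial


def _unwrap_along_order(azimuth: np.ndarray) -> np.ndarray:
    """Monotone unwrapped azimuth along the given order (steps folded to [0, 2pi))."""
    steps = np.diff(azimuth) % (2 * np.pi)
    return np.concatenate(([0.0], np.cumsum(steps)))


def helix_params(frame: OligomerFrame, topology: AssemblyTopology) -> HelixParams:
    """Fit diameter, pitch and helix angle of one frame.

    Invariant under rigid-body transforms and under reversal of the axis
    direction; requires a successful axis fit.
    """
    point, direction = fit_axis(frame)
    order = topology.chain_order
    by_id = {m.monomer_id: m for m in frame.monomers}
    coms = np.array([_monomer_com(by_id[mid]) for mid in order])
    radius, azimuth, axial = _cylindrical(coms, point, direction)

    idx = np.arange(len(order))
    rise = np.polyfit(idx, axial, 1)[0]
    if rise < 0:  # measure along the winding direction
        direction = -direction
        radius, azimuth, axial = _cylindrical(coms, point, direction)
        rise = np.polyfit(idx, axial, 1)[0]
    unwrapped = _unwrap_along_order(azimuth)
    steps = np.diff(unwrapped)
    if np.any(steps <= 0) or np.any(steps >= np.pi):
        log.warning("non-monotone azimuth along path; re-ordering by axial position")
        reorder = np.argsort(axial, kind="stable")
        radius, azimuth, axial = radius[reorder], azimuth[reorder], axial[reorder]
        rise = np.polyfit(idx, axial, 1)[0]
        unwrapped = _unwrap_along_order(azimuth)
    dtheta = np.polyfit(idx, unwrapped, 1)[0]
    if dtheta <= 0:
        raise DegenerateGeometryError("azimuth does not advance along the path")

    mean_radius = float(radius.mean())
    monomers_per_turn = 2 * np.pi / dtheta
    pitch = rise * monomers_per_turn
    helix_angle = float(np.degrees(np.arctan2(abs(rise), mean_radius * dtheta)))

    outer = 0.0
    for m in frame.monomers:
        rel = m.coords - point
        ax = rel @ direction
        rad = np.linalg.norm(rel - np.outer(ax, direction), axis=1)
        outer = max(outer, float(rad.max()))

    return HelixParams(
        axis_point=point,
        axis_direction=direction,
        diameter_A=2 * mean_radius,
        outer_diameter_A=2 * outer,
        pitch_A=float(pitch),
        helix_angle_deg=helix_angle,
        rise_per_monomer_A=float(rise),
        monomers_per_turn=float(monomers_per_turn),
    )


def helix_params_series(
    trajectory: Trajectory,
    topology: AssemblyTopology,
    window: WindowSpec | None = None,
) -> pd.DataFrame:
    """helix_params for each (windowed) frame, one row per frame."""
    traj = select_window(trajectory, window) if window is not None else trajectory
    rows = []
    for frame in traj.frames:
        p = helix_params(frame, topology)
        rows.append(
            (
                frame.frame_index,
                p.diameter_A,
                p.outer_diameter_A,
                p.pitch_A,
                p.helix_angle_deg,
                p.rise_per_monomer_A,
                p.monomers_per_turn,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "frame_index",
            "diameter_A",
            "outer_diameter_A",
            "pitch_A",
            "helix_angle_deg",
            "rise_per_monomer_A",
            "monomers_per_turn",
        ],
    )


def tetramer_rg_series(
    trajectory: Trajectory,
    topology: AssemblyTopology,
    window: WindowSpec | None = None,
) -> pd.DataFrame:
    """Radius of gyration of each tetramer per frame plus window means.

    Window means carry ``frame_index == -1``.
    """
    traj = select_window(trajectory, window) if window is not None else trajectory
    tetramers: dict[int, list[str]] = {}
    for mid, tet in topology.tetramer_of.items():
        tetramers.setdefault(tet, []).append(mid)
    rows = []
    for frame in traj.frames:
        for tet in sorted(tetramers):
            coords = np.concatenate(
                [frame.monomer(mid).coords for mid in sorted(tetramers[tet])]
            )
            rows.append((tet, frame.frame_index, radius_of_gyration(coords)))
    df = pd.DataFrame(rows, columns=["tetramer", "frame_index", "rg_A"])
    means = df.groupby("tetramer", sort=True)["rg_A"].mean().reset_index()
    means.insert(1, "frame_index", -1)
    return pd.concat([df, means], ignore_index=True)
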
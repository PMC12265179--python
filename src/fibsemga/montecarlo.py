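"""Event-by-event electron transport through a voxelized specimen.

Single-scattering Monte Carlo in the CASINO lineage: elastic deflections are
discrete events sampled from the screened-Rutherford cross section, energy is
lost continuously along each flight segment at the Joy-Luo stopping power, and
electrons are tracked until they exit the block, fall below the 50 eV floor,
or leave the grid laterally/below.  An energy-selective backscatter (ESB)
filter accepts electrons that exit back through the entrance surface (z = 0)
with at least the grid voltage of kinetic energy.

Geometry convention: z >= 0 points into the block, the surface plane is z = 0
and everything above it is vacuum; voxel [i, j, k] spans the half-open box
[i*dx, (i+1)*dx) x [j*dy, (j+1)*dy) x [k*dz, (k+1)*dz).

The transport loop is vectorised over electrons; free-flight lengths are
sampled as s = -lambda ln(1-u) and truncated at voxel boundaries (the
exponential is memoryless, so resampling in the next voxel is exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .materials import Material
from .electron_physics import (
    DEFAULT_SCREENING_EXPONENT,
    SCREENING_PREFACTOR,
    elastic_sigma,
    inverse_mean_free_path,
    stopping_power,
)

STATUS_BACKSCATTERED = 0
STATUS_ABSORBED = 1
STATUS_TRANSMITTED = 2
STATUS_ESCAPED_SIDE = 3

_STATUS_NAMES = {
    STATUS_BACKSCATTERED: "backscattered",
    STATUS_ABSORBED: "absorbed",
    STATUS_TRANSMITTED: "transmitted",
    STATUS_ESCAPED_SIDE: "escaped-side",
}

_NUDGE = 1e-6  # nm pushed across a voxel boundary after truncation
_MAX_SEGMENTS = 100_000


class GeometryError(ValueError):
    """Beam or feature placed outside the specimen grid."""


@dataclass
class SpecimenModel:
    """Voxelized specimen: voxel -> material-id map plus a material table."""

    voxel_size: tuple[float, float, float]  # nm per axis
    material_ids: np.ndarray  # (nx, ny, nz) integer ids into `materials`
    materials: Sequence[Material]
    name: str = "specimen"

    def __post_init__(self) -> None:
        self.material_ids = np.ascontiguousarray(self.material_ids, dtype=np.int16)
        if self.material_ids.ndim != 3:
            raise GeometryError("material_ids must be a 3-D array")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        if any(v <= 0 for v in vs):
            raise GeometryError("voxel size must be > 0 on every axis")
        self.voxel_size = vs
        if self.material_ids.size == 0:
            raise GeometryError("empty specimen grid")
        if self.material_ids.min() < 0 or self.material_ids.max() >= len(self.materials):
            raise GeometryError("voxel references a material id outside the table")

    @classmethod
    def bulk(
        cls,
        material: Material,
        size: tuple[float, float, float] = (400.0, 400.0, 300.0),
    ) -> "SpecimenModel":
        """A homogeneous block represented as a single large voxel."""
        ids = np.zeros((1, 1, 1), dtype=np.int16)
        return cls(voxel_size=size, material_ids=ids, materials=[material],
                   name=f"bulk:{material.name}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_ids.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (nm) along each axis."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def without_top_slices(self, k: int) -> "SpecimenModel":
        """The specimen after ablating the top k voxel layers (fresh surface at z=0)."""
        if k < 0 or k >= self.shape[2]:
            raise GeometryError(f"cannot remove {k} of {self.shape[2]} z-layers")
        return SpecimenModel(
            voxel_size=self.voxel_size,
            material_ids=self.material_ids[:, :, k:],
            materials=self.materials,
            name=f"{self.name}[-{k} slices]",
        )


@dataclass(frozen=True)
class BeamConfig:
    """Primary beam: landing point on the surface, energy, tracking floor."""

    energy: float = 1.5  # keV
    position: tuple[float, float] = (0.0, 0.0)  # nm, on z = 0
    termination_energy: float = 0.05  # keV

    def __post_init__(self) -> None:
        if not self.energy > self.termination_energy > 0:
            raise ValueError("require energy > termination energy > 0")


@dataclass(frozen=True)
class ESBFilter:
    """Energy-selective backscatter grid: accept exit energy >= grid voltage."""

    grid_voltage_ev: float = 700.0

    def __post_init__(self) -> None:
        if self.grid_voltage_ev < 0:
            raise ValueError("grid voltage must be >= 0")

    def accepts(self, exit_energy_kev: np.ndarray) -> np.ndarray:
        return exit_energy_kev >= self.grid_voltage_ev * 1e-3


@dataclass
class TrajectoryBatch:
    """Columnar record of per-electron fates."""

    status: np.ndarray        # int codes, see STATUS_*
    exit_energy: np.ndarray   # keV, NaN when absorbed
    max_depth: np.ndarray     # nm
    n_elastic: np.ndarray     # elastic events
    path_length: np.ndarray   # nm
    energy_loss: np.ndarray   # keV deposited along the path
    beam_energy: float

    @property
    def n(self) -> int:
        return self.status.size

    def backscattered(self, esb: "ESBFilter | None" = None) -> np.ndarray:
        mask = self.status == STATUS_BACKSCATTERED
        if esb is not None:
            mask &= self.accepts_safe(esb)
        return mask

    def accepts_safe(self, esb: "ESBFilter") -> np.ndarray:
        e = np.where(np.isnan(self.exit_energy), -1.0, self.exit_energy)
        return esb.accepts(e)


@dataclass(frozen=True)
class TrajectoryOutcome:
    """A single electron's fate (scalar view of one TrajectoryBatch row)."""

    status: str
    exit_energy: float | None
    max_depth: float
    n_elastic: int
    path_length: float


class _MaterialTables:
    """Per-material energy-gridded physics tables for the transport loop."""

    def __init__(self, material: Material, e_max: float,
                 exponent: float = DEFAULT_SCREENING_EXPONENT) -> None:
        self.Z = material.composition.atomic_numbers
        self.n_i = material.element_number_densities()
        self.exponent = exponent
        from .electron_physics import E_MAX, E_MIN

        self.e_grid = np.geomspace(E_MIN, min(e_max * 1.05, E_MAX), 256)
        self.inv_mfp = inverse_mean_free_path(material, self.e_grid, exponent)
        self.stop = stopping_power(material, self.e_grid)
        # per-element cumulative selection probability n_i sigma_i / sum
        partial = self.n_i[:, None] * elastic_sigma(self.Z[:, None], self.e_grid[None, :], exponent)
        self.cum_prob = np.cumsum(partial, axis=0) / partial.sum(axis=0)

    def lookup(self, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.interp(E, self.e_grid, self.inv_mfp),
            np.interp(E, self.e_grid, self.stop),
        )

    def sample_element_Z(self, E: np.ndarray, u: np.ndarray) -> np.ndarray:
        idx = np.zeros(E.shape, dtype=np.int64)
        acc = np.zeros(E.shape)
        for j in range(len(self.Z) - 1):
            acc = np.interp(E, self.e_grid, self.cum_prob[j])
            idx = np.where((u >= acc) & (idx == j), j + 1, idx)
        return self.Z[idx]


def _rotate_directions(d: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Deflect unit vectors d by polar angle theta, azimuth phi (vectorised)."""
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    near_pole = np.abs(dz) > 0.999999
    # general rotation
    denom = np.sqrt(np.maximum(1.0 - dz**2, 1e-30))
    nx = st * (dx * dz * cp - dy * sp) / denom + dx * ct
    ny = st * (dy * dz * cp + dx * sp) / denom + dy * ct
    nz = -denom * st * cp + dz * ct
    # beam along +/- z: rotate about the pole directly
    px = st * cp
    py = st * sp
    pz = np.sign(dz) * ct
    out = np.empty_like(d)
    out[:, 0] = np.where(near_pole, px, nx)
    out[:, 1] = np.where(near_pole, py, ny)
    out[:, 2] = np.where(near_pole, pz, nz)
    norm = np.sqrt((out**2).sum(axis=1))
    return out / norm[:, None]


def transport_batch(
    specimen: SpecimenModel,
    beam: BeamConfig,
    n: int,
    rng: np.random.Generator,
    exponent: float = DEFAULT_SCREENING_EXPONENT,
) -> TrajectoryBatch:
    """Trace ``n`` electrons from the beam landing point; return their fates."""
    if n < 1:
        raise ValueError("need at least one trajectory")
    x0, y0 = beam.position
    landings = np.broadcast_to([x0, y0], (n, 2))
    return transport_positions(
        specimen, landings, beam.energy, beam.termination_energy, rng, exponent
    )


def transport_positions(
    specimen: SpecimenModel,
    landings: np.ndarray,
    energy: float = 1.5,
    termination_energy: float = 0.05,
    rng: np.random.Generator | None = None,
    exponent: float = DEFAULT_SCREENING_EXPONENT,
    tracking_floor_kev: float | None = None,
) -> TrajectoryBatch:
    """Trace one electron per row of ``landings`` (x, y on the surface, nm).

    This is the vectorised core: all electrons advance together regardless of
    where they landed, so rastering many pixels in one call amortises the
    stepping overhead.

    ``tracking_floor_kev`` abandons electrons (as absorbed) once their energy
    drops below it.  With an ESB filter of grid voltage V, electrons below
    V can never be accepted, so setting the floor to V leaves every
    filter-accepted count unchanged while skipping the sub-threshold random
    walk; unfiltered backscatter counts are undercounted in that case.
    """
    rng = rng if rng is not None else np.random.default_rng()
    landings = np.asarray(landings, dtype=float).reshape(-1, 2)
    n = len(landings)
    ext = specimen.extent
    if np.any(landings[:, 0] < 0) or np.any(landings[:, 0] >= ext[0]) or        np.any(landings[:, 1] < 0) or np.any(landings[:, 1] >= ext[1]):
        raise GeometryError(f"beam landing outside grid extent {ext[:2]}")
    beam = BeamConfig(energy=energy, termination_energy=termination_energy)
    e_floor = max(termination_energy, tracking_floor_kev or 0.0)

    tables = [_MaterialTables(m, beam.energy, exponent) for m in specimen.materials]
    ids = specimen.material_ids
    vs = np.asarray(specimen.voxel_size)
    shape = np.asarray(specimen.shape)

    pos = np.empty((n, 3))
    pos[:, :2] = landings
    pos[:, 2] = 0.0
    dirs = np.zeros((n, 3))
    dirs[:, 2] = 1.0
    E = np.full(n, beam.energy)
    loss = np.zeros(n)
    max_depth = np.zeros(n)
    n_el = np.zeros(n, dtype=np.int64)
    path = np.zeros(n)
    status = np.full(n, -1, dtype=np.int8)
    exit_E = np.full(n, np.nan)

    alive = np.arange(n)
    for _ in range(_MAX_SEGMENTS):
        if alive.size == 0:
            break
        p = pos[alive]
        d = dirs[alive]
        e = E[alive]

        vox = np.floor(p / vs).astype(np.int64)
        vox = np.clip(vox, 0, shape - 1)  # guard fp edge landings
        mid = ids[vox[:, 0], vox[:, 1], vox[:, 2]]

        inv_mfp = np.empty(alive.size)
        stop = np.empty(alive.size)
        for m, tab in enumerate(tables):
            sel = mid == m
            if sel.any():
                inv_mfp[sel], stop[sel] = tab.lookup(e[sel])

        s_free = -np.log1p(-rng.random(alive.size)) / inv_mfp

        # distance to the nearest voxel boundary along the flight direction
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = vox * vs
            hi = (vox + 1) * vs
            t_axis = np.where(d > 0, (hi - p) / d, np.where(d < 0, (lo - p) / d, np.inf))
        t_bound = np.maximum(t_axis.min(axis=1), 0.0)

        scatter = s_free < t_bound
        step = np.where(scatter, s_free, t_bound + _NUDGE)

        p_new = p + d * step[:, None]
        de = stop * step
        e_new = e - de

        pos[alive] = p_new
        E[alive] = e_new
        loss[alive] += de
        path[alive] += step
        max_depth[alive] = np.maximum(max_depth[alive], p_new[:, 2])

        # classify exits / termination
        out_top = p_new[:, 2] < 0.0
        out_bottom = p_new[:, 2] >= shape[2] * vs[2]
        out_side = (
            (p_new[:, 0] < 0.0)
            | (p_new[:, 0] >= shape[0] * vs[0])
            | (p_new[:, 1] < 0.0)
            | (p_new[:, 1] >= shape[1] * vs[1])
        )
        dead_E = e_new < e_floor

        idx = alive
        bs = out_top & ~dead_E
        status[idx[bs]] = STATUS_BACKSCATTERED
        exit_E[idx[bs]] = e_new[bs]
        tr = out_bottom & ~out_top & ~dead_E
        status[idx[tr]] = STATUS_TRANSMITTED
        exit_E[idx[tr]] = e_new[tr]
        sd = out_side & ~out_top & ~out_bottom & ~dead_E
        status[idx[sd]] = STATUS_ESCAPED_SIDE
        exit_E[idx[sd]] = e_new[sd]
        ab = dead_E & ~(out_top | out_bottom | out_side)
        # electrons dropping below the floor while exiting count as their exit
        ab |= dead_E & (out_top | out_bottom | out_side)
        status[idx[ab & ~(out_top | out_bottom | out_side)]] = STATUS_ABSORBED
        low_exit = dead_E & (out_top | out_bottom | out_side)
        status[idx[low_exit & out_top]] = STATUS_BACKSCATTERED
        status[idx[low_exit & out_bottom & ~out_top]] = STATUS_TRANSMITTED
        status[idx[low_exit & out_side & ~out_top & ~out_bottom]] = STATUS_ESCAPED_SIDE
        exit_E[idx[low_exit]] = e_new[low_exit]

        finished = out_top | out_bottom | out_side | dead_E

        # elastic deflection for electrons that scattered and survived
        sc = scatter & ~finished
        if sc.any():
            sub = idx[sc]
            e_sc = e_new[sc]
            mid_sc = mid[sc]
            zsel = np.empty(sub.size)
            u_el = rng.random(sub.size)
            for m, tab in enumerate(tables):
                selm = mid_sc == m
                if selm.any():
                    zsel[selm] = tab.sample_element_Z(e_sc[selm], u_el[selm])
            a = SCREENING_PREFACTOR * zsel**exponent / e_sc
            u = rng.random(sub.size)
            ct = 1.0 - 2.0 * a * u / (1.0 + a - u)
            theta = np.arccos(np.clip(ct, -1.0, 1.0))
            phi = rng.random(sub.size) * 2.0 * np.pi
            dirs[sub] = _rotate_directions(dirs[sub], theta, phi)
            n_el[sub] += 1

        alive = idx[~finished]
    else:  # pragma: no cover - safety valve
        status[alive] = STATUS_ABSORBED

    return TrajectoryBatch(
        status=status,
        exit_energy=exit_E,
        max_depth=max_depth,
        n_elastic=n_el,
        path_length=path,
        energy_loss=loss,
        beam_energy=beam.energy,
    )


def simulate_trajectory(
    specimen: SpecimenModel, beam: BeamConfig, rng: np.random.Generator
) -> TrajectoryOutcome:
    """Trace one electron and return its fate."""
    batch = transport_batch(specimen, beam, 1, rng)
    st = int(batch.status[0])
    ee = float(batch.exit_energy[0])
    return TrajectoryOutcome(
        status=_STATUS_NAMES[st],
        exit_energy=None if np.isnan(ee) else ee,
        max_depth=float(batch.max_depth[0]),
        n_elastic=int(batch.n_elastic[0]),
        path_length=float(batch.path_length[0]),
    )


def bse_yield(
    specimen: SpecimenModel,
    beam: BeamConfig,
    n: int,
    esb: ESBFilter | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Accepted-backscatter yield estimate and its binomial standard error."""
    rng = rng if rng is not None else np.random.default_rng()
    batch = transport_batch(specimen, beam, n, rng)
    p = float(batch.backscattered(esb).mean())
    se = float(np.sqrt(p * (1.0 - p) / n))
    return p, se


def depth_response(
    material: Material,
    beam: BeamConfig,
    n: int,
    esb: ESBFilter | None = None,
    rng: np.random.Generator | None = None,
    bin_width: float = 5.0,
    max_depth: float = 50.0,
    bulk_size: tuple[float, float, float] = (400.0, 400.0, 300.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram of maximum depth reached by accepted backscattered electrons.

    Returns (counts, bin_edges, accepted_depths).  Counts sum to the number
    of accepted electrons with max depth below ``max_depth``; the raw depths
    are returned as well for quantile work.
    """
    rng = rng if rng is not None else np.random.default_rng()
    spec = SpecimenModel.bulk(material, bulk_size)
    centred = BeamConfig(
        energy=beam.energy,
        position=(bulk_size[0] / 2.0, bulk_size[1] / 2.0),
        termination_energy=beam.termination_energy,
    )
    batch = transport_batch(spec, centred, n, rng)
    depths = batch.max_depth[batch.backscattered(esb)]
    edges = np.arange(0.0, max_depth + bin_width, bin_width)
    counts, _ = np.histogram(depths, bins=edges)
    return counts, edges, depths
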
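"""Generators for every input the pipeline consumes.

No measured data ship with the package: voxel phantoms (stain squares at
stepped depths, a stained synaptic vesicle), block-face HAADF line profiles
with the characteristic asymmetric peak (sharp onset, exponential decay into
the block, plateau baseline, Poisson noise), and core-loss EELS spectra
(power-law background plus sawtooth edges) are all synthesised with known
ground truth so every downstream stage has a parameter-recovery test.

Each generator is deterministic under a fixed seed and emits its ground truth
alongside the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .materials import Material, implant_gallium, preset, stain_with
from .montecarlo import GeometryError, SpecimenModel


def _implant(material: Material, ga_fraction: float, mode: str) -> Material:
    if ga_fraction == 0.0:
        return material
    if mode == "auto":
        mode = (
            "replace_carbon"
            if material.composition.fraction_of("C") >= ga_fraction
            else "additive"
        )
    return implant_gallium(material, ga_fraction, mode=mode)


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthStepPhantomSpec:
    """Stain squares buried at stepped depths below the block face.

    The default places five 5-nm-thick squares of 3 at.% Pb-stained resin at
    depths 0-5, 5-10, 10-15, 15-20 and 20-25 nm, one square per depth, spaced
    along x.  ``ga_fraction`` implants the whole phantom (matrix and stain)
    uniformly over its depth extent.
    """

    layer_depths: tuple[tuple[float, float], ...] = (
        (0.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, 25.0),
    )
    stain_element: str = "Pb"
    stain_fraction: float = 0.03
    square_size: float = 30.0  # nm
    square_spacing: float = 30.0  # nm gap between squares
    margin: float = 75.0  # nm of bare matrix around the feature row; any
    # electron that can still clear a 700 eV exit filter travels < ~70 nm of
    # path at 1.5 keV, so this margin keeps detectable paths off the grid edge
    depth_extent: float = 60.0  # nm of block; the same energy-loss bound keeps
    # every filter-accepted electron above ~35 nm depth
    voxel_size: float = 3.0  # nm, lateral
    voxel_z: float = 2.5  # nm along depth (resolves the 5-nm layer boundaries)
    ga_fraction: float = 0.0
    ga_mode: str = "auto"  # replace_carbon | additive | auto

    def __post_init__(self) -> None:
        depths = sorted(self.layer_depths)
        for (a0, b0), (a1, _) in zip(depths, depths[1:]):
            if a1 < b0 - 1e-9:
                raise ValueError("layer depth intervals overlap")
        if any(b <= a for a, b in depths):
            raise ValueError("layer intervals must have positive thickness")


@dataclass(frozen=True)
class VesiclePhantomSpec:
    """A stained spherical shell (synaptic vesicle model) buried in resin."""

    outer_diameter: float = 40.0  # nm
    membrane_thickness: float = 5.0  # nm
    stain_element: str = "Pb"
    stain_fraction: float = 0.03
    center_depth: float = 35.0  # nm below the surface
    lateral_extent: float = 201.0  # nm (x and y); keeps filter-detectable
    # backscatter paths (< ~70 nm at 1.5 keV) clear of the grid edges
    depth_extent: float = 90.0  # nm
    voxel_size: float = 3.0  # nm
    ga_fraction: float = 0.0
    ga_mode: str = "auto"

    def __post_init__(self) -> None:
        if not 0 < self.membrane_thickness < self.outer_diameter / 2.0:
            raise ValueError("membrane thickness must be < outer radius")


def _snap(value: float, step: float, what: str) -> int:
    n = value / step
    if abs(n - round(n)) > 1e-9:
        warnings.warn(f"{what} {value} nm is not a voxel multiple; snapped")
    return max(1, round(n))


def make_depth_step_phantom(spec: DepthStepPhantomSpec) -> SpecimenModel:
    """Voxelize the depth-step phantom; materials are exactly {matrix, stained}."""
    vs = spec.voxel_size
    vz = spec.voxel_z
    sq = _snap(spec.square_size, vs, "square size")
    gap = _snap(spec.square_spacing, vs, "square spacing")
    mar = _snap(spec.margin, vs, "margin")
    nz = _snap(spec.depth_extent, vz, "depth extent")
    n_layers = len(spec.layer_depths)
    nx = 2 * mar + n_layers * sq + (n_layers - 1) * gap
    ny = 2 * mar + sq

    ids = np.zeros((nx, ny, nz), dtype=np.int16)
    y0, y1 = mar, mar + sq
    for i, (top, bottom) in enumerate(spec.layer_depths):
        x0 = mar + i * (sq + gap)
        k0 = _snap(top, vz, "layer top") if top else 0
        k1 = _snap(bottom, vz, "layer bottom")
        if bottom > spec.depth_extent:
            raise GeometryError("stain layer extends below the phantom")
        ids[x0 : x0 + sq, y0:y1, k0:k1] = 1

    matrix = _implant(preset("epon_araldite"), spec.ga_fraction, spec.ga_mode)
    stained = _implant(
        stain_with(preset("epon_araldite"), spec.stain_element, spec.stain_fraction),
        spec.ga_fraction,
        spec.ga_mode,
    )
    return SpecimenModel(
        voxel_size=(vs, vs, vz),
        material_ids=ids,
        materials=[matrix, stained],
        name=f"depth-step(ga={spec.ga_fraction:g})",
    )


def feature_footprints(spec: DepthStepPhantomSpec) -> list[tuple[float, float, float, float]]:
    """Lateral (x0, x1, y0, y1) extents (nm) of each stain square, shallow first."""
    vs = spec.voxel_size
    sq = _snap(spec.square_size, vs, "square size") * vs
    gap = _snap(spec.square_spacing, vs, "square spacing") * vs
    mar = _snap(spec.margin, vs, "margin") * vs
    out = []
    for i in range(len(spec.layer_depths)):
        x0 = mar + i * (sq + gap)
        out.append((x0, x0 + sq, mar, mar + sq))
    return out


def make_vesicle_phantom(spec: VesiclePhantomSpec) -> SpecimenModel:
    """Voxelize the vesicle: a voxel is membrane iff its centre's distance to the
    vesicle centre lies in (r_outer - thickness, r_outer]."""
    vs = spec.voxel_size
    nx = ny = _snap(spec.lateral_extent, vs, "lateral extent")
    nz = _snap(spec.depth_extent, vs, "depth extent")
    r_out = spec.outer_diameter / 2.0
    cx = cy = nx * vs / 2.0
    cz = spec.center_depth
    if cz - r_out < 0 or cz + r_out > nz * vs:
        raise GeometryError("vesicle extends outside the block")
    if cx - r_out < 0 or cx + r_out > nx * vs:
        raise GeometryError("vesicle extends outside the lateral grid")

    centers = (np.arange(nx) + 0.5) * vs
    zc = (np.arange(nz) + 0.5) * vs
    dx2 = (centers - cx)[:, None, None] ** 2
    dy2 = (centers - cy)[None, :, None] ** 2
    dz2 = (zc - cz)[None, None, :] ** 2
    dist = np.sqrt(dx2 + dy2 + dz2)
    shell = (dist > r_out - spec.membrane_thickness) & (dist <= r_out)
    ids = shell.astype(np.int16)

    matrix = _implant(preset("epon_araldite"), spec.ga_fraction, spec.ga_mode)
    if spec.stain_fraction > 0:
        membrane = _implant(
            stain_with(preset("epon_araldite"), spec.stain_element, spec.stain_fraction),
            spec.ga_fraction,
            spec.ga_mode,
        )
    else:
        membrane = matrix
    return SpecimenModel(
        voxel_size=(vs, vs, vs),
        material_ids=ids,
        materials=[matrix, membrane],
        name=f"vesicle(depth={spec.center_depth:g},ga={spec.ga_fraction:g})",
    )


# ---------------------------------------------------------------------------
# HAADF block-face line profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HAADFProfileSpec:
    """Asymmetric block-face peak: vacuum, sharp onset, exponential decay, plateau.

    The noiseless model is ``plateau * (1 + (R - 1) * g(x))`` inside the block
    and zero in vacuum, where g rises from 0 to 1 over ``onset_width`` as a
    cubic smoothstep and then decays as exp(-(x - x_peak)/decay_length); the
    profile maximum over the plateau equals the jump-ratio target R exactly.
    """

    plateau: float = 1.0e4  # counts
    jump_ratio: float = 3.9
    onset_width: float = 6.0  # nm
    decay_length: float = 50.0  # nm
    extent: float = 600.0  # nm total length; keep >> interface + 5 decay
    # lengths so the interior plateau is genuinely tail-free
    interface: float = 100.0  # nm position of the vacuum/block interface
    step: float = 2.0  # nm sampling
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if self.jump_ratio < 1.0:
            raise ValueError("jump ratio target must be >= 1")
        if min(self.onset_width, self.decay_length, self.step, self.extent) <= 0:
            raise ValueError("all widths must be > 0")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def haadf_profile_model(spec: HAADFProfileSpec, positions: np.ndarray) -> np.ndarray:
    """Noiseless expected counts at ``positions`` (nm)."""
    x = np.asarray(positions, dtype=float)
    xi = x - spec.interface
    rise = _smoothstep(xi / spec.onset_width)
    tail = np.exp(-np.maximum(xi - spec.onset_width, 0.0) / spec.decay_length)
    g = rise * tail
    signal = spec.plateau * (1.0 + (spec.jump_ratio - 1.0) * g)
    return np.where(xi < 0.0, 0.0, signal)


def synth_haadf_profile(
    spec: HAADFProfileSpec, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate a noisy line profile; returns (table, ground-truth sidecar).

    The sampling grid is aligned so the peak position (interface + onset
    width) is hit exactly, making the noiseless max/plateau equal R.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(np.floor(spec.extent / spec.step)) + 1
    offset = spec.interface % spec.step  # align grid with the interface
    positions = offset + np.arange(n) * spec.step
    positions = positions[positions <= spec.extent]
    expected = haadf_profile_model(spec, positions)
    counts = rng.poisson(expected).astype(float) if spec.poisson_noise else expected
    table = pd.DataFrame({"position_nm": positions, "intensity": counts})
    truth = {
        "jump_ratio": spec.jump_ratio,
        "plateau": spec.plateau,
        "onset_width_nm": spec.onset_width,
        "decay_length_nm": spec.decay_length,
        "interface_nm": spec.interface,
        "peak_position_nm": spec.interface + spec.onset_width,
    }
    return table, truth


# ---------------------------------------------------------------------------
# EELS spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EELSEdgeSpec:
    element: str
    onset_ev: float
    integral: float  # background-subtracted counts in the 100 eV post-onset window


@dataclass(frozen=True)
class EELSSpectrumSpec:
    """Power-law background plus sawtooth core-loss edges.

    Each edge is a step at its onset with an (E/onset)^-s tail (s = 3),
    normalised so the channel-sum integral over ``window_ev`` past the onset
    equals the requested integral exactly on noiseless data.
    """

    energy_start: float = 200.0  # eV
    energy_stop: float = 1600.0  # eV
    dispersion: float = 1.0  # eV/channel
    background_amplitude: float = 2.8e11  # counts at 1 eV (power-law A); with
    # r = 3 this puts ~1.2e4 counts/channel under the C K edge, the scale of a
    # few-hundred-nm^2 STEM-EELS region at ~1 nA and ~0.1 s/pixel
    background_exponent: float = 3.0  # r in A * E^-r
    edges: tuple[EELSEdgeSpec, ...] = ()
    window_ev: float = 100.0
    tail_exponent: float = 3.0
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if self.background_exponent <= 0:
            raise ValueError("power-law exponent must be > 0")
        for e in self.edges:
            if not self.energy_start < e.onset_ev < self.energy_stop:
                raise ValueError(f"edge onset {e.onset_ev} outside energy range")
            if e.integral < 0:
                raise ValueError("edge integral must be >= 0")
        onsets = sorted(e.onset_ev for e in self.edges)
        for a, b in zip(onsets, onsets[1:]):
            if b < a + self.window_ev:
                warnings.warn("edge integration windows overlap")


def eels_energy_axis(spec: EELSSpectrumSpec) -> np.ndarray:
    n = int(round((spec.energy_stop - spec.energy_start) / spec.dispersion)) + 1
    return spec.energy_start + np.arange(n) * spec.dispersion


def eels_model(spec: EELSSpectrumSpec, energy: np.ndarray | None = None) -> np.ndarray:
    """Noiseless expected counts per channel."""
    E = eels_energy_axis(spec) if energy is None else np.asarray(energy, dtype=float)
    counts = spec.background_amplitude * E ** (-spec.background_exponent)
    for edge in spec.edges:
        shape = np.where(E >= edge.onset_ev, (E / edge.onset_ev) ** (-spec.tail_exponent), 0.0)
        win = (E >= edge.onset_ev) & (E < edge.onset_ev + spec.window_ev)
        norm = shape[win].sum() * spec.dispersion
        counts = counts + edge.integral * shape / norm
    return counts


def synth_eels_spectrum(
    spec: EELSSpectrumSpec, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, dict]:
    """Generate a noisy spectrum; returns (table, ground-truth sidecar)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    E = eels_energy_axis(spec)
    expected = eels_model(spec, E)
    counts = rng.poisson(expected).astype(float) if spec.poisson_noise else expected
    table = pd.DataFrame({"energy_ev": E, "counts": counts})
    truth = {
        "background_amplitude": spec.background_amplitude,
        "background_exponent": spec.background_exponent,
        "window_ev": spec.window_ev,
        "edges": [asdict(e) for e in spec.edges],
    }
    return table, truth


#: default edge onsets (eV); the Ga L2,3 onset is configurable near 1115-1140
C_K_ONSET = 284.0
O_K_ONSET = 532.0
GA_L23_ONSET = 1115.0


def eels_sample_spec(
    ga_c_ratio: float,
    sigma_c: float = 1.0,
    sigma_o_over_c: float = 0.271,
    sigma_ga_over_o: float = 0.85,
    carbon_counts: float = 4.0e5,
    ga_onset_ev: float = GA_L23_ONSET,
    **kwargs,
) -> EELSSpectrumSpec:
    """Spectrum of a Ga-implanted carbon matrix with a known Ga:C atomic ratio.

    Edge integrals are N_element * sigma_effective scaled to ``carbon_counts``
    for the C K edge, so the quantifier should recover ``ga_c_ratio``.
    """
    sigma_ga = sigma_ga_over_o * sigma_o_over_c * sigma_c
    edges = (
        EELSEdgeSpec("C", C_K_ONSET, carbon_counts),
        EELSEdgeSpec("Ga", ga_onset_ev, carbon_counts * ga_c_ratio * sigma_ga / sigma_c),
    )
    return EELSSpectrumSpec(edges=edges, **kwargs)


def eels_reference_spec(
    sigma_o: float = 0.271,
    sigma_ga_over_o: float = 0.85,
    oxygen_counts: float = 4.0e6,
    ga_onset_ev: float = GA_L23_ONSET,
    **kwargs,
) -> EELSSpectrumSpec:
    """Ga2O3 reference spectrum (N_Ga/N_O = 2/3) for k-factor calibration."""
    edges = (
        EELSEdgeSpec("O", O_K_ONSET, oxygen_counts),
        EELSEdgeSpec(
            "Ga", ga_onset_ev, oxygen_counts * (2.0 / 3.0) * sigma_ga_over_o
        ),
    )
    return EELSSpectrumSpec(edges=edges, **kwargs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_profile(table: pd.DataFrame, truth: dict, path: str | Path) -> None:
    """Two-column CSV plus a JSON ground-truth sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))


def write_phantom(specimen: SpecimenModel, path: str | Path) -> None:
    """Voxel grid to HDF5 (ids + voxel size + material summaries)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("material_ids", data=specimen.material_ids)
        fh.attrs["voxel_size_nm"] = specimen.voxel_size
        fh.attrs["name"] = specimen.name
        for i, m in enumerate(specimen.materials):
            grp = fh.create_group(f"materials/{i}")
            grp.attrs["name"] = m.name
            grp.attrs["mass_density"] = m.mass_density
            for s, f in m.composition.as_dict().items():
                grp.attrs[f"f_{s}"] = f
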
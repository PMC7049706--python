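"""Synthetic smFISH fields with exact ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a field of tens of cells imaged as a DAPI z-stack plus one or two
RNA-FISH channels, with 0.25 um optical sections covering the full nuclear
depth (~10 um). Interphase nuclei are rendered large, dim and smooth; mitotic
nuclei smaller, brighter and coarser-textured (condensed chromatin).
Occasional micronuclei sit near their parent nucleus. FISH speckles are
anisotropic Gaussian puncta placed in the nuclear or cytoplasmic compartment
with a controllable cytoplasmic fraction; a WT-like population has a low
fraction and a SINE-deletion-like population an elevated one. A linear
background gradient, Poisson shot noise and Gaussian read noise are added
last.

Every generated field comes with a :class:`GroundTruth`: per-nucleus and
per-speckle truth tables plus true label volumes, so each pipeline stage can
be scored against known answers.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack import ImageStack
from .territories import tessellate_cells

INTERPHASE = "interphase"
MITOTIC = "mitotic"
NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"


class PlacementWarning(UserWarning):
    """Emitted when fewer objects could be placed than requested."""


@dataclass
class FieldParams:
    """Parameters of one simulated field.

    Defaults describe the acquisition geometry of the emulated experiment
    (0.25 um z-sections over ~10 um of depth, sub-diffraction-scale xy
    pixels) and a WT-like localization regime (5% cytoplasmic speckles).

    Attributes
    ----------
    image_shape
        ``(n_z, n_y, n_x)`` voxel counts.
    voxel_size
        ``(z, y, x)`` voxel edge lengths in micrometres.
    n_cells
        Number of main nuclei to place.
    mitotic_fraction
        Probability that a cell is mitotic.
    micronucleus_rate
        Poisson mean of micronuclei per cell.
    speckles_per_cell
        Per FISH channel, ``(mean, dispersion)`` of an over-dispersed count
        law: counts are gamma-Poisson with variance ``mean + d * mean**2``
        (``d = 0`` recovers Poisson).
    cytoplasmic_fraction
        Per channel, probability a speckle is placed in the cytoplasm.
    speckle_sigma
        Per channel, Gaussian widths ``(z, y, x)`` in micrometres.
    speckle_amplitude
        Per channel, peak intensity above background.
    nucleus_radius_interphase, nucleus_radius_mitotic
        Mean in-plane radii in micrometres; mitotic must be smaller.
    dapi_gain_mitotic
        Multiplier (> 1) on mitotic DAPI intensity.
    texture_granularity_mitotic
        Relative amplitude of the band-limited multiplicative chromatin
        texture applied to mitotic nuclei.
    background_offset, background_gradient_amplitude
        Flat baseline and peak-to-trough amplitude of a linear shading
        gradient, in intensity units.
    poisson_scaling
        Photon-count scaling of the shot-noise model; ``None`` disables
        Poisson noise (useful for noiseless renders).
    read_noise_sigma
        Additive Gaussian read noise; 0 disables.
    """

    image_shape: tuple[int, int, int] = (41, 256, 256)
    voxel_size: tuple[float, float, float] = (0.25, 0.26, 0.26)
    n_cells: int = 10
    mitotic_fraction: float = 0.15
    micronucleus_rate: float = 0.1
    speckles_per_cell: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"malat1": (8.0, 0.15)}
    )
    cytoplasmic_fraction: dict[str, float] = field(default_factory=lambda: {"malat1": 0.05})
    speckle_sigma: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"malat1": (0.40, 0.25, 0.25)}
    )
    speckle_amplitude: dict[str, float] = field(default_factory=lambda: {"malat1": 150.0})
    nucleus_radius_interphase: float = 3.6
    nucleus_radius_mitotic: float = 2.2
    dapi_amplitude: float = 120.0
    dapi_gain_mitotic: float = 2.0
    texture_granularity_mitotic: float = 0.4
    texture_scale_um: float = 0.5
    background_offset: float = 20.0
    background_gradient_amplitude: float = 8.0
    poisson_scaling: float | None = 1.0
    read_noise_sigma: float = 2.0
    radius_jitter: float = 0.08
    nucleus_separation_um: float = 0.8
    micronucleus_radius_um: float = 0.8
    speckle_min_separation_um: tuple[float, float, float] = (2.2, 1.7, 1.7)
    cytoplasm_reach_um: float = 4.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.image_shape) != 3 or any(int(s) <= 0 for s in self.image_shape):
            raise ValueError(f"image_shape must be 3 positive ints, got {self.image_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.mitotic_fraction <= 1.0:
            raise ValueError("mitotic_fraction must lie in [0, 1]")
        if self.micronucleus_rate < 0:
            raise ValueError("micronucleus_rate must be >= 0")
        if not self.nucleus_radius_mitotic < self.nucleus_radius_interphase:
            raise ValueError("mitotic nuclei must be smaller than interphase nuclei")
        if self.dapi_gain_mitotic <= 1.0:
            raise ValueError("dapi_gain_mitotic must exceed 1")
        for ch, frac in self.cytoplasmic_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"cytoplasmic_fraction[{ch!r}] must lie in [0, 1]")
        for ch, (mean, disp) in self.speckles_per_cell.items():
            if mean < 0 or disp < 0:
                raise ValueError(f"speckles_per_cell[{ch!r}] must be non-negative")
        for ch, sig in self.speckle_sigma.items():
            if any(s <= 0 for s in sig):
                raise ValueError(f"speckle_sigma[{ch!r}] widths must be positive")
        for ch, amp in self.speckle_amplitude.items():
            if amp <= 0:
                raise ValueError(f"speckle_amplitude[{ch!r}] must be positive")
        if set(self.speckles_per_cell) != set(self.cytoplasmic_fraction) or set(
            self.speckles_per_cell
        ) != set(self.speckle_sigma) or set(self.speckles_per_cell) != set(
            self.speckle_amplitude
        ):
            raise ValueError("per-channel parameter dicts must share one channel set")

    @property
    def fish_channels(self) -> list[str]:
        return list(self.speckles_per_cell)

    def params_hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    """Truth tables and label volumes for one generated field.

    ``nucleus_table`` columns: nucleus_id, centroid_z/y/x (voxel coords),
    radius_um, phase, is_micronucleus, parent_cell.
    ``speckle_table`` columns: channel, speckle_id, centroid_z/y/x,
    compartment, cell_id.
    ``nucleus_labels`` labels main nuclei only (micronuclei are table rows);
    ``cell_labels`` is the true territory map from the true nucleus masks.
    """

    nucleus_table: pd.DataFrame
    speckle_table: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    params: FieldParams
    seed: int


def _negbin_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Gamma-Poisson draw with var = mean + dispersion * mean**2."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return int(rng.poisson(lam))


def _place_nuclei(params: FieldParams, rng: np.random.Generator) -> list[dict]:
    """Rejection-sample non-overlapping nucleus centres and radii."""
    nz, ny, nx = params.image_shape
    pz, py, px = params.voxel_size
    sep_px = params.nucleus_separation_um / py
    depth_um = nz * pz
    placed: list[dict] = []
    n_mitotic = rng.binomial(params.n_cells, params.mitotic_fraction)
    phases = [MITOTIC] * n_mitotic + [INTERPHASE] * (params.n_cells - n_mitotic)
    attempts_per_cell = 400
    for phase in phases:
        base_r = (
            params.nucleus_radius_mitotic if phase == MITOTIC else params.nucleus_radius_interphase
        )
        ok = False
        for _ in range(attempts_per_cell):
            r_um = base_r * (1.0 + rng.uniform(-params.radius_jitter, params.radius_jitter))
            r_px = r_um / py
            if 2 * r_px + 2 >= min(ny, nx):
                continue
            cy = rng.uniform(r_px + 1, ny - r_px - 2)
            cx = rng.uniform(r_px + 1, nx - r_px - 2)
            if all(
                np.hypot(cy - o["cy"], cx - o["cx"]) >= r_px + o["r_px"] + sep_px for o in placed
            ):
                zc_um = depth_um / 2 + rng.uniform(-1.0, 1.0)
                z_r_um = min(r_um, zc_um - 0.3, depth_um - zc_um - 0.3)
                placed.append(
                    dict(
                        cy=cy,
                        cx=cx,
                        cz=zc_um / pz,
                        r_px=r_px,
                        r_um=r_um,
                        z_r=max(z_r_um, 0.5) / pz,
                        phase=phase,
                    )
                )
                ok = True
                break
        if not ok:
            break
    if len(placed) < params.n_cells:
        warnings.warn(
            f"could only place {len(placed)} of {params.n_cells} nuclei at the "
            "requested minimum separation; truth tables reflect the placed count",
            PlacementWarning,
            stacklevel=3,
        )
    return placed


def _ellipsoid_profile(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    edge_softness: float = 0.08,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Soft-edged ellipsoid intensity profile on its local bounding box."""
    nz, ny, nx = shape
    cz, cy, cx = center
    rz, ry, rx = radii
    z0, z1 = max(int(cz - rz - 2), 0), min(int(cz + rz + 3), nz)
    y0, y1 = max(int(cy - ry - 2), 0), min(int(cy + ry + 3), ny)
    x0, x1 = max(int(cx - rx - 2), 0), min(int(cx + rx + 3), nx)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    r = np.sqrt(((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    profile = 1.0 / (1.0 + np.exp((r - 1.0) / edge_softness))
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), profile


def _add_gaussian_spot(
    volume: np.ndarray,
    center: tuple[float, float, float],
    sigma_vox: tuple[float, float, float],
    amplitude: float,
) -> None:
    nz, ny, nx = volume.shape
    cz, cy, cx = center
    sz, sy, sx = sigma_vox
    z0, z1 = max(int(cz - 4 * sz), 0), min(int(cz + 4 * sz) + 2, nz)
    y0, y1 = max(int(cy - 4 * sy), 0), min(int(cy + 4 * sy) + 2, ny)
    x0, x1 = max(int(cx - 4 * sx), 0), min(int(cx + 4 * sx) + 2, nx)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    volume[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * (((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)
    )


def _resolvable(
    pos: tuple[float, float, float],
    existing: list[tuple[float, float, float]],
    sep_vox: tuple[float, float, float],
) -> bool:
    """True if ``pos`` clears the anisotropic resolvability ellipsoid.

    Two diffraction-limited puncta closer than the optical resolution (which
    is coarser axially than laterally) are one object to any detector, so
    truth entities are kept at least one resolution ellipsoid apart.
    """
    return all(
        sum(((a - b) / s) ** 2 for a, b, s in zip(pos, q, sep_vox)) >= 1.0 for q in existing
    )


def _sample_nuclear_position(
    rng: np.random.Generator,
    nuc: dict,
    existing: list[tuple[float, float, float]],
    sep_vox: tuple[float, float, float],
) -> tuple[float, float, float] | None:
    """Uniform draw inside 0.85x the nucleus ellipsoid, respecting separation."""
    for _ in range(80):
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) > 1.0:
            continue
        u *= 0.85
        pos = (
            nuc["cz"] + u[0] * nuc["z_r"],
            nuc["cy"] + u[1] * nuc["r_px"],
            nuc["cx"] + u[2] * nuc["r_px"],
        )
        if _resolvable(pos, existing, sep_vox):
            return pos
    return None


def generate_field(params: FieldParams, seed: int) -> tuple[ImageStack, GroundTruth]:
    """Render one field and its ground truth.

    Identical ``(params, seed)`` pairs yield bit-identical stacks and truth
    tables. Nuclei are soft-edged ellipsoids placed without overlap; mitotic
    nuclei get a brighter mean and a multiplicative band-limited texture;
    speckles are anisotropic Gaussians at the truth centroids; a background
    gradient and Poisson + Gaussian noise are applied last.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    nz, ny, nx = (int(s) for s in params.image_shape)
    pz, py, px = params.voxel_size
    shape = (nz, ny, nx)

    nuclei = _place_nuclei(params, rng)

    # --- DAPI render and truth nucleus label map (2D projection geometry) ---
    dapi = np.zeros(shape, dtype=np.float64)
    nucleus_labels = np.zeros((ny, nx), dtype=np.int32)
    nucleus_rows: list[dict] = []
    yy2, xx2 = np.mgrid[0:ny, 0:nx]
    for i, nuc in enumerate(nuclei, start=1):
        amp = params.dapi_amplitude
        if nuc["phase"] == MITOTIC:
            amp *= params.dapi_gain_mitotic
        box, profile = _ellipsoid_profile(
            shape, (nuc["cz"], nuc["cy"], nuc["cx"]), (nuc["z_r"], nuc["r_px"], nuc["r_px"])
        )
        if nuc["phase"] == MITOTIC:
            tex_sigma = params.texture_scale_um / py
            noise = ndimage.gaussian_filter(rng.standard_normal(profile.shape), tex_sigma)
            noise /= max(noise.std(), 1e-9)
            texture = np.clip(1.0 + params.texture_granularity_mitotic * noise, 0.15, None)
            dapi[box] += amp * profile * texture
        else:
            dapi[box] += amp * profile
        mask2d = ((yy2 - nuc["cy"]) ** 2 + (xx2 - nuc["cx"]) ** 2) <= nuc["r_px"] ** 2
        nucleus_labels[mask2d & (nucleus_labels == 0)] = i
        nucleus_rows.append(
            dict(
                nucleus_id=i,
                centroid_z=nuc["cz"],
                centroid_y=nuc["cy"],
                centroid_x=nuc["cx"],
                radius_um=nuc["r_um"],
                phase=nuc["phase"],
                is_micronucleus=False,
                parent_cell=0,
            )
        )

    # --- micronuclei: small DAPI bodies just outside their parent nucleus ---
    next_id = len(nuclei) + 1
    for i, nuc in enumerate(nuclei, start=1):
        n_micro = rng.poisson(params.micronucleus_rate)
        for _ in range(n_micro):
            mr_um = params.micronucleus_radius_um * (1.0 + rng.uniform(-0.2, 0.2))
            mr_px = mr_um / py
            placed_ok = False
            for _ in range(60):
                theta = rng.uniform(0, 2 * np.pi)
                dist = nuc["r_px"] + mr_px + rng.uniform(2.0, 10.0)
                my = nuc["cy"] + dist * np.sin(theta)
                mx = nuc["cx"] + dist * np.cos(theta)
                if not (mr_px + 1 < my < ny - mr_px - 2 and mr_px + 1 < mx < nx - mr_px - 2):
                    continue
                if any(
                    np.hypot(my - o["cy"], mx - o["cx"]) < o["r_px"] + mr_px + 2 for o in nuclei
                ):
                    continue
                placed_ok = True
                break
            if not placed_ok:
                continue
            mz = nuc["cz"] + rng.uniform(-2.0, 2.0)
            box, profile = _ellipsoid_profile(
                shape, (mz, my, mx), (mr_um / pz, mr_px, mr_px)
            )
            dapi[box] += params.dapi_amplitude * profile
            nucleus_rows.append(
                dict(
                    nucleus_id=next_id,
                    centroid_z=mz,
                    centroid_y=my,
                    centroid_x=mx,
                    radius_um=mr_um,
                    phase=nuc["phase"],
                    is_micronucleus=True,
                    parent_cell=i,
                )
            )
            next_id += 1

    # --- true cell territories from the true nucleus masks ---
    if nucleus_labels.max() > 0:
        cell_labels = tessellate_cells(nucleus_labels)
    else:
        cell_labels = np.zeros_like(nucleus_labels)

    # pixels eligible for cytoplasmic speckles: in a territory, outside every
    # nucleus, within reach of the nucleus boundary, clear of the field border
    reach_px = params.cytoplasm_reach_um / py
    outside = nucleus_labels == 0
    dist_to_nucleus = ndimage.distance_transform_edt(outside)
    cyto_ok = (
        (cell_labels > 0)
        & outside
        & (dist_to_nucleus > 1.5)
        & (dist_to_nucleus <= reach_px)
        & (yy2 > 2)
        & (yy2 < ny - 3)
        & (xx2 > 2)
        & (xx2 < nx - 3)
    )

    # --- speckles ---
    fish = {ch: np.zeros(shape, dtype=np.float64) for ch in params.fish_channels}
    speckle_rows: list[dict] = []
    for ch in params.fish_channels:
        mean, disp = params.speckles_per_cell[ch]
        frac = params.cytoplasmic_fraction[ch]
        sigma_vox = tuple(
            s / v for s, v in zip(params.speckle_sigma[ch], params.voxel_size)
        )
        amp = params.speckle_amplitude[ch]
        sep_vox = tuple(
            s / v for s, v in zip(params.speckle_min_separation_um, params.voxel_size)
        )
        sid = 1
        for i, nuc in enumerate(nuclei, start=1):
            n_speckles = _negbin_count(rng, mean, disp)
            cell_cyto = np.argwhere(cyto_ok & (cell_labels == i))
            cell_positions: list[tuple[float, float, float]] = []
            for _ in range(n_speckles):
                cytoplasmic = rng.uniform() < frac
                pos: tuple[float, float, float] | None = None
                if cytoplasmic and len(cell_cyto):
                    for _ in range(60):
                        yx = cell_cyto[rng.integers(len(cell_cyto))]
                        cand = (
                            float(np.clip(nuc["cz"] + rng.uniform(-6.0, 6.0), 1, nz - 2)),
                            float(yx[0]) + rng.uniform(-0.3, 0.3),
                            float(yx[1]) + rng.uniform(-0.3, 0.3),
                        )
                        if _resolvable(cand, cell_positions, sep_vox):
                            pos = cand
                            break
                    compartment = CYTOPLASMIC
                else:
                    pos = _sample_nuclear_position(rng, nuc, cell_positions, sep_vox)
                    compartment = NUCLEAR
                if pos is None:
                    continue  # crowded cell: drop rather than violate separation
                cell_positions.append(pos)
                _add_gaussian_spot(fish[ch], pos, sigma_vox, amp)
                speckle_rows.append(
                    dict(
                        channel=ch,
                        speckle_id=sid,
                        centroid_z=pos[0],
                        centroid_y=pos[1],
                        centroid_x=pos[2],
                        compartment=compartment,
                        cell_id=i,
                    )
                )
                sid += 1

    # --- background, gradient, noise ---
    gradient = params.background_gradient_amplitude * (
        0.5 * (yy2 / max(ny - 1, 1) + xx2 / max(nx - 1, 1))
    )
    background = params.background_offset + gradient  # (ny, nx), broadcast over z
    channels: dict[str, np.ndarray] = {}
    for name, clean in [("dapi", dapi)] + [(ch, fish[ch]) for ch in params.fish_channels]:
        noiseless = clean + background[None, :, :]
        noisy = noiseless
        if params.poisson_scaling is not None and params.poisson_scaling > 0:
            noisy = rng.poisson(noiseless * params.poisson_scaling) / params.poisson_scaling
        if params.read_noise_sigma > 0:
            noisy = noisy + rng.normal(0.0, params.read_noise_sigma, size=shape)
        channels[name] = np.clip(noisy, 0.0, None).astype(np.float32)

    stack = ImageStack(
        channels=channels,
        voxel_size=params.voxel_size,
        provenance=f"speckquant-sim:{params.params_hash()}:seed={seed}",
    )
    nucleus_table = pd.DataFrame(
        nucleus_rows,
        columns=[
            "nucleus_id",
            "centroid_z",
            "centroid_y",
            "centroid_x",
            "radius_um",
            "phase",
            "is_micronucleus",
            "parent_cell",
        ],
    )
    speckle_table = pd.DataFrame(
        speckle_rows,
        columns=[
            "channel",
            "speckle_id",
            "centroid_z",
            "centroid_y",
            "centroid_x",
            "compartment",
            "cell_id",
        ],
    )
    truth = GroundTruth(
        nucleus_table=nucleus_table,
        speckle_table=speckle_table,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        params=params,
        seed=int(seed),
    )
    return stack, truth


@dataclass
class FieldRealization:
    """One generated field tagged with its cohort group and derived seed."""

    group: str
    field_index: int
    seed: int
    stack: ImageStack
    truth: GroundTruth


def generate_cohort(
    params_a: FieldParams,
    params_b: FieldParams,
    n_fields: int,
    seed: int,
    group_names: tuple[str, str] = ("a", "b"),
) -> tuple[list[FieldRealization], list[FieldRealization]]:
    """Generate two groups of fields with per-field seeds derived from ``seed``.

    The two groups share nothing but the seed stream, so with
    ``params_a == params_b`` they are null replicates of one condition.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_fields) % (2**31)
    groups: tuple[list[FieldRealization], list[FieldRealization]] = ([], [])
    for g, (name, params) in enumerate(zip(group_names, (params_a, params_b))):
        for i in range(n_fields):
            s = int(child_seeds[g * n_fields + i])
            stack, truth = generate_field(params, s)
            groups[g].append(
                FieldRealization(group=name, field_index=i, seed=s, stack=stack, truth=truth)
            )
    return groups


def sample_cell_counts(
    params: FieldParams, n_cells: int, seed: int, channel: str | None = None
) -> pd.DataFrame:
    """Draw per-cell (nuclear, cytoplasmic) speckle counts from the count law.

    Bypasses image rendering: totals are gamma-Poisson with the channel's
    (mean, dispersion) and the cytoplasmic count is binomial with the
    channel's cytoplasmic fraction. Used for statistics-stage calibration
    where thousands of cells are needed.
    """
    channel = channel or params.fish_channels[0]
    mean, disp = params.speckles_per_cell[channel]
    frac = params.cytoplasmic_fraction[channel]
    rng = np.random.default_rng(seed)
    rows = []
    for cid in range(1, n_cells + 1):
        total = _negbin_count(rng, mean, disp)
        n_cyto = int(rng.binomial(total, frac)) if total else 0
        rows.append(
            dict(cell_id=cid, channel=channel, n_nuclear=total - n_cyto, n_cytoplasmic=n_cyto)
        )
    return pd.DataFrame(rows)
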
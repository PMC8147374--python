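"""Seeded synthetic CBCT phantoms of mandible-like shapes.

The phantom geometry mimics the gross anatomy the segmentation target
presents to a slice-sweeping network: a horseshoe (half-torus) body in
the lower axial slices, two posterior rami rising as tapered cylinders,
and condylar/coronoid ellipsoidal processes at the top.  Intensities
emulate CBCT: a soft-tissue background, brighter bone on the mask, and
Gaussian acquisition noise, optionally corrupted by very bright metal
inserts along the superior dental-arch rim with alternating bright/dark
streaks radiating through them (an image-space emulation of the
reconstruction artifacts braces produce, not a physical projection
simulation).

Every draw is deterministic given its seed; a population of phantoms
shares the template but draws its own geometric parameters, giving a
coherent family of shapes with realistic inter-subject variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, Volume

__all__ = [
    "PhantomParams",
    "make_mandible_phantom",
    "add_metal_artifacts",
    "make_population",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity distributions for one phantom family.

    Lengths are in mm; intensities in arbitrary CBCT-like units ordered
    soft tissue < bone < metal.  The default grid (96 x 96 x 64 voxels at
    0.4 mm) matches the finest spacing of clinical dental CBCT while
    staying small enough for CPU experiments.
    """

    shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    # horseshoe body (half torus, opening towards +y); spreads are
    # calibrated so that a population stays coherent (pairwise Dice
    # after rigid alignment within [0.5, 0.95]) yet clearly varying
    arch_radius_mm: tuple[float, float] = (11.0, 0.5)  # mean, sd
    arch_thickness_mm: tuple[float, float] = (3.2, 0.2)
    # rami: tapered vertical cylinders at the arch ends
    ramus_height_mm: tuple[float, float] = (12.0, 0.7)
    ramus_radius_mm: tuple[float, float] = (2.6, 0.15)
    ramus_tilt_deg: tuple[float, float] = (8.0, 1.5)
    # condyle / coronoid bumps on top of each ramus
    condyle_scale_mm: tuple[float, float] = (3.0, 0.25)
    coronoid_scale_mm: tuple[float, float] = (2.0, 0.2)
    # intensities
    soft_tissue: float = 120.0
    bone: float = 420.0
    noise_sd: float = 40.0
    smooth_sigma_vox: float = 0.6
    # metal corruption
    metal_intensity: float = 1500.0
    n_inserts: int = 4
    insert_radius_mm: float = 1.2
    n_streaks_per_insert: int = 6
    streak_amplitude: float = 220.0

    def grid_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


def _coords_mm(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _draw(rng, pair):
    return float(rng.normal(pair[0], pair[1]))


def make_mandible_phantom(
    p: PhantomParams, seed: int
) -> tuple[Volume, BinaryMask]:
    """One paired (intensity volume, ground-truth mask) draw."""
    rng = np.random.default_rng(seed)
    X, Y, Z = _coords_mm(p.shape, p.spacing)
    ext = p.grid_mm()
    cx, cy = ext[0] / 2, ext[1] * 0.45
    z_body = ext[2] * 0.3

    R = _draw(rng, p.arch_radius_mm)
    thick = max(1.0, _draw(rng, p.arch_thickness_mm))
    if 2 * (R + thick) > min(ext[0], ext[1]) or z_body + _draw(rng, (0, 0)) > ext[2]:
        raise ValueError("grid too small to contain the phantom shape")

    # half-torus body: ring in the axial plane, open towards posterior (+y)
    rho = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    torus = np.sqrt((rho - R) ** 2 + (Z - z_body) ** 2) < thick
    body = torus & (Y < cy + R * 0.55)

    mask = body
    ramus_h = _draw(rng, p.ramus_height_mm)
    for side in (-1, 1):
        # ramus base sits at the arch end on this side
        bx = cx + side * R
        by = cy + R * 0.45
        tilt = np.deg2rad(_draw(rng, p.ramus_tilt_deg)) * side
        rr = max(1.0, _draw(rng, p.ramus_radius_mm))
        zz = np.clip((Z - z_body) / max(ramus_h, 1e-6), 0, 1)
        axis_x = bx + np.tan(tilt) * (Z - z_body)
        taper = rr * (1.0 - 0.35 * zz)
        ram = (
            (np.sqrt((X - axis_x) ** 2 + (Y - by) ** 2) < taper)
            & (Z >= z_body)
            & (Z <= z_body + ramus_h)
        )
        mask = mask | ram
        # condyle (posterior bump) and coronoid (anterior, smaller)
        topx = bx + np.tan(tilt) * ramus_h
        topz = z_body + ramus_h
        cs = max(0.8, _draw(rng, p.condyle_scale_mm))
        ks = max(0.6, _draw(rng, p.coronoid_scale_mm))
        cond = (
            ((X - topx) / cs) ** 2
            + ((Y - (by + cs * 0.8)) / cs) ** 2
            + ((Z - topz) / (cs * 1.2)) ** 2
        ) < 1.0
        coro = (
            ((X - topx) / ks) ** 2
            + ((Y - (by - ks * 1.4)) / ks) ** 2
            + ((Z - topz) / (ks * 1.5)) ** 2
        ) < 1.0
        mask = mask | cond | coro

    if not mask.any():
        raise ValueError("grid too small to contain the phantom shape")

    vol = np.full(p.shape, p.soft_tissue, dtype=np.float32)
    vol[mask] = p.bone
    if p.smooth_sigma_vox > 0:
        vol = ndimage.gaussian_filter(vol, p.smooth_sigma_vox)
    vol = vol + rng.normal(0.0, p.noise_sd, p.shape).astype(np.float32)

    return (
        Volume(vol.astype(np.float32), p.spacing),
        BinaryMask(mask.astype(np.uint8), p.spacing),
    )


def add_metal_artifacts(
    v: Volume, mask: BinaryMask, p: PhantomParams, seed: int
) -> Volume:
    """Bright dental-arch inserts plus radiating streaks and local blur."""
    if p.n_inserts == 0:
        return Volume(v.data.copy(), v.spacing, v.origin)
    rng = np.random.default_rng(seed)
    data = v.data.astype(np.float32).copy()
    sp = np.asarray(v.spacing)

    # candidate sites: top rim of the mask's anterior arch
    fg = np.argwhere(mask.data > 0)
    if len(fg) == 0:
        return Volume(data, v.spacing, v.origin)
    ymed = np.median(fg[:, 1])
    anterior = fg[fg[:, 1] <= ymed]
    zcut = np.percentile(anterior[:, 2], 75)
    rim = anterior[anterior[:, 2] >= zcut]
    if len(rim) == 0:
        rim = anterior
    sites = rim[rng.choice(len(rim), size=min(p.n_inserts, len(rim)), replace=False)]

    X, Y, Z = _coords_mm(v.data.shape, v.spacing)
    blur_roi = np.zeros(v.data.shape, dtype=bool)
    for sx, sy, sz in sites:
        c = np.array([sx, sy, sz]) * sp
        d2 = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        insert = d2 < p.insert_radius_mm**2
        data[insert] = p.metal_intensity
        # in-plane streaks through the insert, alternating bright/dark
        zi = int(sz)
        zlo, zhi = max(0, zi - 2), min(v.data.shape[2], zi + 3)
        xx, yy = X[:, :, 0], Y[:, :, 0]
        for k in range(p.n_streaks_per_insert):
            theta = rng.uniform(0, np.pi)
            amp = p.streak_amplitude * (1 if k % 2 == 0 else -1) * rng.uniform(0.6, 1.0)
            # signed distance to the line through c with direction theta
            dline = -(xx - c[0]) * np.sin(theta) + (yy - c[1]) * np.cos(theta)
            profile = amp * np.exp(-(dline**2) / (2 * (0.5**2)))
            along = (xx - c[0]) * np.cos(theta) + (yy - c[1]) * np.sin(theta)
            falloff = np.exp(-np.abs(along) / 25.0)
            data[:, :, zlo:zhi] += (profile * falloff)[:, :, None]
        blur_roi |= d2 < (6.0) ** 2
    # local blur around the inserts
    blurred = ndimage.gaussian_filter(data, 1.0)
    data[blur_roi] = blurred[blur_roi]
    return Volume(data, v.spacing, v.origin)


def make_population(n: int, p: PhantomParams, seed: int) -> list[BinaryMask]:
    """``n`` independent shape draws from the phantom family."""
    if n < 2:
        raise ValueError("a population needs n >= 2 shapes")
    ss = np.random.SeedSequence(seed).spawn(n)
    masks = []
    for child in ss:
        sub = int(child.generate_state(1)[0] % (2**31))
        _, m = make_mandible_phantom(p, sub)
        masks.append(m)
    return masks
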
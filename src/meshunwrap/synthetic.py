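"""Seeded synthetic cell-shape fixtures with planted protrusions.

Fixtures emulate the three canonical protrusion motifs: hemispherical
bleb-like bumps, elongated lamellipodium-like ridges, and thin tall
filopodium-like spikes, planted at rejection-sampled non-overlapping
locations on an icosphere of base radius R (default 32 voxels) and
displacing the surface radially.  Every fixture carries per-vertex
ground-truth instance labels (0 = cortex), a matched filled binary volume
and a cortical-shell intensity volume.  All randomness flows through one
seeded generator, so the same spec reproduces bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .mesh import SurfaceMesh
from .volumes import BinaryVolume, voxelize

MOTIFS = ("bleb", "bump", "ridge", "spike", "mixed")


@dataclass
class FixtureSpec:
    radius: float = 32.0
    motif: str = "bleb"
    count: int = 10
    amplitude: float = 0.2          # fraction of R
    width: float = 0.25             # angular width (radians)
    seed: int = 0
    subdivisions: int = 4
    amplitude_spread: float = 0.0   # relative jitter of amplitudes
    width_span: float = 1.0         # max/min ratio of log-uniform widths
    self_similar: bool = False      # scale amplitude with width (hemispheres)
    n_holes: int = 0
    n_handles: int = 0

    def __post_init__(self) -> None:
        if self.radius < 16:
            raise ValueError("base radius must be >= 16 voxels")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")


@dataclass
class Fixture:
    mesh: SurfaceMesh
    truth: np.ndarray               # per-vertex instance labels, 0 = cortex
    binary: Optional[BinaryVolume]
    intensity: Optional[np.ndarray]
    spec: FixtureSpec
    centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _sample_centers(rng: np.random.Generator, k: int,
                    separations: np.ndarray) -> np.ndarray:
    """Unit directions with pairwise angle >= the sum of the two motifs'
    separation radii (rejection sampling, widest motifs placed first)."""
    seps = np.asarray(separations, dtype=float)
    order = np.argsort(seps)[::-1]
    centers = np.zeros((k, 3))
    placed: list[int] = []
    for idx in order:
        ok = False
        for _ in range(10_000):
            c = rng.normal(size=3)
            c /= np.linalg.norm(c)
            if all(np.arccos(np.clip(c @ centers[j], -1, 1))
                   >= seps[idx] + seps[j] for j in placed):
                centers[idx] = c
                placed.append(idx)
                ok = True
                break
        if not ok:
            # near the packing limit greedy rejection is fragile: fall
            # back to a randomly rotated Fibonacci lattice, the standard
            # quasi-uniform spherical arrangement
            fib = _fibonacci_sphere(k)
            rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            fib = fib @ rot.T
            ang = np.arccos(np.clip(fib @ fib.T, -1, 1))
            np.fill_diagonal(ang, np.inf)
            if (ang >= seps[:, None] + seps[None, :]).all():
                return fib
            raise RuntimeError(
                f"could not place {k} non-overlapping motifs "
                f"after 10k rejections")
    return centers


def _fibonacci_sphere(k: int) -> np.ndarray:
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def _motif_displacement(motif: str, dirs: np.ndarray, center: np.ndarray,
                        width: float, rng: np.random.Generator) -> np.ndarray:
    """Radial displacement profile (unitless, max 1) of one planted motif."""
    ang = np.arccos(np.clip(dirs @ center, -1.0, 1.0))
    if motif == "bump":
        # smooth Gaussian bump (gentle cortical undulation)
        return np.exp(-((ang / width) ** 2))
    if motif == "bleb":
        # flattened hemispherical cap: near-constant height with a sharp
        # neck at angular radius `width`, like a retraction-stage bleb
        return np.sqrt(np.clip(1.0 - (ang / width) ** 8, 0.0, None))
    if motif == "spike":
        return np.sqrt(np.clip(1.0 - (ang / (0.35 * width)) ** 8, 0.0, None))
    if motif == "ridge":
        # elongated Gaussian along a random tangent great circle
        t = rng.normal(size=3)
        t -= (t @ center) * center
        t /= np.linalg.norm(t)
        along = dirs @ t
        across2 = np.clip(ang ** 2 - np.arcsin(np.clip(along, -1, 1)) ** 2,
                          0.0, None)
        return (np.exp(-across2 / (0.3 * width) ** 2)
                * np.exp(-((ang / (2.5 * width)) ** 2)))
    raise ValueError(motif)


def make_fixture(spec: FixtureSpec, with_volumes: bool = True) -> Fixture:
    """Generate a seeded fixture mesh (+ binary and intensity volumes)."""
    rng = np.random.default_rng(spec.seed)
    ico = trimesh.creation.icosphere(spec.subdivisions)
    dirs = np.asarray(ico.vertices)
    faces = np.asarray(ico.faces)
    R = spec.radius

    disp = np.zeros(len(dirs))
    labels = np.zeros(len(dirs), dtype=np.int64)
    centers = np.zeros((0, 3))
    amps = np.zeros(0)
    if spec.count > 0:
        span = max(spec.width_span, 1.0)
        widths = spec.width * np.exp(
            rng.uniform(-0.5, 0.5, spec.count) * np.log(span))
        centers = _sample_centers(rng, spec.count, 1.6 * widths)
        amps = spec.amplitude * (
            1.0 + spec.amplitude_spread * rng.uniform(-1, 1, spec.count))
        if spec.self_similar:
            amps = amps * widths / spec.width
        per_motif = np.zeros((spec.count, len(dirs)))
        eff_amp = np.zeros(spec.count)
        for i, c in enumerate(centers):
            motif = spec.motif if spec.motif != "mixed" else \
                ("bleb", "ridge", "spike")[i % 3]
            eff_amp[i] = amps[i] * (3.0 if motif == "spike" else 1.0)
            per_motif[i] = eff_amp[i] * _motif_displacement(
                motif, dirs, c, widths[i], rng)
        disp = per_motif.sum(axis=0)
        best = per_motif.argmax(axis=0)
        peak = per_motif.max(axis=0)
        labels = np.where(peak > 0.5 * eff_amp[best], best + 1, 0)

    vertices = R * (1.0 + disp)[:, None] * dirs
    # center inside a positive voxel frame
    offset = -vertices.min(axis=0) + 8.0
    vertices = vertices + offset
    mesh = SurfaceMesh(vertices, faces)
    fixture = Fixture(mesh, labels, None, None, spec, centers, amps)
    if spec.n_holes or spec.n_handles:
        fixture.mesh = punch_defects(mesh, spec.n_holes, spec.n_handles,
                                     spec.seed)
        fixture.truth = labels  # labels refer to the intact mesh vertices
    if with_volumes:
        binary = voxelize(fixture.mesh, dilation_radius=3)
        fixture.binary = binary
        from scipy import ndimage

        edt_in = ndimage.distance_transform_edt(binary.data)
        edt_out = ndimage.distance_transform_edt(~binary.data)
        shell = (edt_in <= 2) & binary.data | (edt_out <= 2) & ~binary.data
        fixture.intensity = shell.astype(np.float32)
    return fixture


def punch_defects(mesh: SurfaceMesh, n_holes: int = 0, n_handles: int = 0,
                  seed: int = 0) -> SurfaceMesh:
    """Plant topological defects: remove face patches (holes) and glue thin
    triangular-prism bridges between nearby faces (handles)."""
    rng = np.random.default_rng(seed)
    v = mesh.vertices.copy()
    f = mesh.faces.copy()

    keep = np.ones(len(f), dtype=bool)
    adjacency = None
    for _ in range(int(n_holes)):
        fi = int(rng.integers(len(f)))
        if adjacency is None:
            tm = trimesh.Trimesh(v, f, process=False)
            adjacency = tm.face_adjacency
        patch = {fi}
        for a, b in adjacency:
            if a == fi or b == fi:
                patch.update((int(a), int(b)))
        keep[list(patch)] = False
    faces_out = [f[keep]]
    verts_out = [v]
    n = len(v)

    for _ in range(int(n_handles)):
        # pick two kept faces facing each other across the interior
        fi = int(rng.integers(len(f)))
        c = v[f].mean(axis=1)
        d = np.linalg.norm(c - c[fi], axis=1)
        order = np.argsort(d)
        target = int(order[len(order) // 2])   # a mid-distance face
        tri_a = f[fi]
        tri_b = f[target]
        # prism: connect corresponding corners with side quads (two tris)
        for k in range(3):
            a0, a1 = tri_a[k], tri_a[(k + 1) % 3]
            b0, b1 = tri_b[k], tri_b[(k + 1) % 3]
            faces_out.append(np.array([[a0, a1, b0], [b0, a1, b1]]))
        # remove the end faces so the tube is open into the surface
        mask = np.ones(len(faces_out[0]), dtype=bool)
        for idx, tri in enumerate(faces_out[0]):
            if set(tri) == set(tri_a) or set(tri) == set(tri_b):
                mask[idx] = False
        faces_out[0] = faces_out[0][mask]

    out = SurfaceMesh(np.concatenate(verts_out),
                      np.concatenate(faces_out), mesh.representation_tag)
    return out
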
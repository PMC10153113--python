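"""Topographic (d, u, v) coordinate space built by normal propagation.

The (u, v)-parameterized reference surface is propagated along the unit
gradient of the signed distance function of the reference volume in
equidistant steps of ``alpha`` voxels, outward (d > 0) until the input
surface is fully enclosed and inward (d < 0) for ``Din`` steps.  The
result is a lookup volume (d, v, u) -> (x, y, z): trilinear resampling of
any Cartesian volume through this lookup yields its topographic
counterpart, and topographic coordinates map back to Cartesian space by
interpolating the lookup itself.

Array axis order of topographic volumes is (d, v, u) with d ascending from
-Din (deepest) to +Dout; the reference shell sits at index Din.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .mesh import SurfaceMesh
from .volumes import BinaryVolume, mesh_from_volume

log = logging.getLogger(__name__)


@dataclass
class SignedDistanceVolume:
    """Euclidean signed distance, positive inside the object (voxels)."""

    data: np.ndarray
    origin: np.ndarray

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        coords = (np.asarray(points, float) - self.origin).T
        return ndimage.map_coordinates(self.data, coords, order=order,
                                       mode="nearest")


@dataclass
class TopographicSpace:
    lookup: np.ndarray            # (D, N, ncol, 3) -> cartesian coordinates
    alpha: float
    d_in: int
    d_out: int
    origin: np.ndarray            # origin of the cartesian frame used

    @property
    def n_steps(self) -> int:
        return self.lookup.shape[0]

    @property
    def reference_index(self) -> int:
        return self.d_in

    def differential_volume(self) -> np.ndarray:
        """|dV/du x dV/dv . dV/dd| per voxel of the lookup."""
        core = self.lookup[:, :, :-1]
        du = np.gradient(core, axis=2)
        dv = np.gradient(core, axis=1)
        dd = np.gradient(core, axis=0)
        dVol = np.abs(np.einsum("dvci,dvci->dvc", np.cross(du, dv), dd))
        return np.concatenate([dVol, dVol[:, :, :1]], axis=2)


def signed_distance(volume: BinaryVolume) -> SignedDistanceVolume:
    """EDT of the background minus EDT of the foreground: positive inside."""
    fg = volume.data
    if not fg.any():
        raise ValueError("empty foreground")
    if fg.all():
        raise ValueError("all-foreground grid has no defined surface")
    inside = ndimage.distance_transform_edt(fg)
    outside = ndimage.distance_transform_edt(~fg)
    return SignedDistanceVolume(inside - outside, volume.origin)


def _smooth_shell(shell: np.ndarray, window: int = 5) -> np.ndarray:
    """Separable box smoothing of shell coordinate images (wrap in u)."""
    out = np.empty_like(shell)
    for k in range(3):
        tmp = ndimage.uniform_filter1d(shell[..., k], window, axis=1,
                                       mode="wrap")
        out[..., k] = ndimage.uniform_filter1d(tmp, window, axis=0,
                                               mode="nearest")
    return out


def build_topographic_space(uv, sdf: SignedDistanceVolume, alpha: float = 0.5,
                            d_in: int = 40,
                            d_out: Optional[int] = None,
                            enclose: Optional[SurfaceMesh] = None,
                            smooth_window: int = 5,
                            max_steps: int = 400) -> TopographicSpace:
    """Propagate the (u, v) reference shell to build the (d, u, v) lookup.

    ``d_out=None`` (auto) chooses the outward step count so that the mesh
    given in ``enclose`` (typically the input Cartesian surface) is fully
    contained; without an enclosing mesh it defaults to ``d_in``.
    Explicit Euler steps of ``alpha`` voxels along the unit SDF gradient,
    with per-step box smoothing of the shell coordinate images.
    """
    shell0 = np.asarray(uv.coordinates, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if d_out is None:
        if enclose is not None:
            outside = -sdf.sample(enclose.vertices)
            d_out = int(np.ceil(max(float(outside.max()), 0.0) / max(alpha, 1e-6))) + 4
        else:
            d_out = d_in
    d_out = int(d_out)
    if max(d_in, d_out) > max_steps:
        raise ValueError("step count exceeds max_steps; increase alpha")

    grad = np.stack(np.gradient(sdf.data))
    norm = np.maximum(np.linalg.norm(grad, axis=0), 1e-12)
    unit = grad / norm              # points inward (phi positive inside)

    def step(shell: np.ndarray, direction: float) -> np.ndarray:
        if alpha == 0.0:
            return shell
        coords = (shell.reshape(-1, 3) - sdf.origin).T
        g = np.stack([ndimage.map_coordinates(unit[k], coords, order=1,
                                              mode="nearest")
                      for k in range(3)], axis=1)
        gn = g / np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-12)
        new = shell + direction * alpha * (-gn.reshape(shell.shape))
        if smooth_window > 1:
            new = _smooth_shell(new, smooth_window)
            new[:, -1] = new[:, 0]
        return new

    shells_out = []
    s = shell0
    for _ in range(d_out):
        s = step(s, +1.0)
        shells_out.append(s)
    shells_in = []
    s = shell0
    for _ in range(d_in):
        s = step(s, -1.0)
        shells_in.append(s)
    lookup = np.stack(shells_in[::-1] + [shell0] + shells_out, axis=0)
    # guard against out-of-grid shells
    lo = lookup.reshape(-1, 3).min(axis=0) - sdf.origin
    hi = lookup.reshape(-1, 3).max(axis=0) - sdf.origin
    if (lo < -2).any() or (hi > np.asarray(sdf.data.shape) + 1).any():
        log.warning("topographic shells extend beyond the SDF grid; "
                    "consider more padding")
    return TopographicSpace(lookup, alpha, d_in, d_out, sdf.origin)


def resample_volume(space: TopographicSpace, intensity: np.ndarray,
                    origin: Optional[np.ndarray] = None, order: int = 1,
                    fill: float = 0.0) -> np.ndarray:
    """Trilinear resampling of a Cartesian volume into topographic space."""
    origin = space.origin if origin is None else np.asarray(origin, float)
    coords = (space.lookup.reshape(-1, 3) - origin).T
    out = ndimage.map_coordinates(np.asarray(intensity, float), coords,
                                  order=order, mode="constant", cval=fill)
    return out.reshape(space.lookup.shape[:3])


def topographic_mesh(topo_binary: np.ndarray, remesh_fraction: float = 0.5,
                     gaussian_sigma: float = 1.0, seed: int = 0) -> SurfaceMesh:
    """Surface-mesh the topographic binary volume (largest component)."""
    if not np.asarray(topo_binary).any():
        raise ValueError("empty topographic binary")
    # no padding: foreground reaching the array boundary stays open, so the
    # mesh is the topographic height sheet, not a closed box
    vol = BinaryVolume(np.asarray(topo_binary, bool),
                       origin=np.zeros(3))
    mesh = mesh_from_volume(vol, isovalue=0.5,
                            remesh_fraction=remesh_fraction,
                            gaussian_sigma=gaussian_sigma, seed=seed)
    mesh.representation_tag = "topographic"
    return mesh


def topo_to_cartesian(space: TopographicSpace, coords_or_mesh,
                      strict: bool = False):
    """Map (d, v, u) topographic coordinates back to Cartesian space.

    Accepts an (n, 3) coordinate array (indices into the lookup volume) or
    a topographic SurfaceMesh, whose face list is preserved.
    """
    if isinstance(coords_or_mesh, SurfaceMesh):
        pts = coords_or_mesh.vertices
    else:
        pts = np.asarray(coords_or_mesh, dtype=float)
    shape = np.asarray(space.lookup.shape[:3])
    low = (pts < -0.5).any() or (pts > shape - 0.5).any()
    if low:
        n_out = int(((pts < 0) | (pts > shape - 1)).any(axis=1).sum())
        if strict:
            raise ValueError(f"{n_out} coordinates outside the (d,u,v) domain")
        log.warning("%d coordinates clamped to the (d,u,v) domain", n_out)
    clamped = np.clip(pts, 0, shape - 1)
    cart = np.stack([ndimage.map_coordinates(space.lookup[..., k],
                                             clamped.T, order=1,
                                             mode="nearest")
                     for k in range(3)], axis=1)
    if isinstance(coords_or_mesh, SurfaceMesh):
        out = coords_or_mesh.copy(vertices=cart)
        out.representation_tag = "cartesian"
        return out
    return cart
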
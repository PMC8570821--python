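"""Ensemble analysis: superposition, essential-dynamics PCA, KDE maps, angles.

These tools map where an ensemble travelled.  PCA of superposed Cα
coordinates yields the essential subspace; projections of conformers onto
the leading components, or low-dimensional reaction coordinates such as
inter-domain angles, are turned into population landscapes by Gaussian
kernel density estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .ensemble import Ensemble
from .errors import AnalysisError, ContractError, SelectionError
from .geometry import superpose_onto
from .structure_io import Structure, select


# ---------------------------------------------------------------------------
# Superposition


def superpose(
    mobile: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Kabsch-fit ``mobile`` onto ``reference`` using the masked atoms.

    The transformation is estimated on the masked atoms and applied to all
    atoms; the returned RMSD is over the masked atoms.  Proper rotations
    only (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ContractError("mobile and reference must have the same shape")
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ContractError("superposition needs at least 3 selected atoms")
    rot, cm, cr, rmsd = superpose_onto(mobile[mask], reference[mask])
    moved = (mobile - cm) @ rot.T + cr
    return moved, rmsd


# ---------------------------------------------------------------------------
# Essential-dynamics PCA


@dataclass
class PcModel:
    """Principal components of superposed (masked) coordinate fluctuations."""

    mean_coords: np.ndarray   # (n_sel, 3) Å
    components: np.ndarray    # (p, 3 n_sel) orthonormal rows
    variances: np.ndarray     # (p,) non-increasing


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for k in range(out.shape[0]):
        idx = int(np.argmax(np.abs(out[k])))
        if out[k, idx] < 0:
            out[k] = -out[k]
    return out


def _masked_coords(ensemble, mask) -> np.ndarray:
    coords = ensemble.coords if isinstance(ensemble, Ensemble) else np.asarray(ensemble, float)
    if coords.ndim != 3:
        raise ContractError("expected an Ensemble or an (M, N, 3) array")
    if mask is None:
        return coords
    return coords[:, np.asarray(mask, dtype=bool), :]


def _align_to_mean(x: np.ndarray, max_iter: int = 100, tol: float = 1e-6):
    """Iteratively superpose all conformers onto their running mean."""
    reference = x[0] - x[0].mean(axis=0)

    def align_all(ref):
        aligned = np.empty_like(x)
        for m in range(x.shape[0]):
            rot, cm, cr, _ = superpose_onto(x[m], ref, check_collinear=False)
            aligned[m] = (x[m] - cm) @ rot.T + cr
        return aligned

    for _ in range(max_iter):
        aligned = align_all(reference)
        mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((mean - reference) ** 2, axis=1))))
        reference = mean
        if shift < tol:
            break
    # final pass against the converged reference, so downstream projection
    # (which superposes onto exactly this mean) sees the same deviations
    return align_all(reference), reference


def ensemble_pca(ensemble, mask: np.ndarray | None = None, p: int = 2) -> PcModel:
    """PCA of the masked-coordinate covariance after iterative superposition.

    Conformers are superposed onto the running mean until the mean shifts by
    less than 1e-6 Å (RMS); the covariance of the flattened deviations is
    then eigen-decomposed and the top-``p`` components returned.  Variances
    use the sample (M-1) normalization.  Component signs follow the
    convention that the largest-magnitude entry is positive.
    """
    x = _masked_coords(ensemble, mask)
    m = x.shape[0]
    if m <= p:
        raise ContractError(f"PCA with p={p} components needs at least {p + 1} conformers")
    aligned, mean = _align_to_mean(x)
    flat = (aligned - mean).reshape(m, -1)
    _, svals, vt = np.linalg.svd(flat, full_matrices=False)
    variances = svals**2 / (m - 1)
    n_dof = flat.shape[1]
    if p > len(variances):
        pad = p - len(variances)
        vt = np.vstack([vt, np.zeros((pad, n_dof))])
        variances = np.concatenate([variances, np.zeros(pad)])
    return PcModel(
        mean_coords=mean,
        components=_fix_component_signs(vt[:p]),
        variances=variances[:p].copy(),
    )


def project(ensemble, pc_model: PcModel, mask: np.ndarray | None = None) -> np.ndarray:
    """Project conformers onto the model's components → (M, p) coordinates."""
    x = _masked_coords(ensemble, mask)
    n_sel = pc_model.mean_coords.shape[0]
    if x.shape[1] != n_sel:
        raise ContractError(
            f"ensemble selects {x.shape[1]} atoms but the PC model was built "
            f"on {n_sel}"
        )
    out = np.empty((x.shape[0], pc_model.components.shape[0]))
    for m in range(x.shape[0]):
        rot, cm, cr, _ = superpose_onto(x[m], pc_model.mean_coords, check_collinear=False)
        dev = ((x[m] - cm) @ rot.T + cr - pc_model.mean_coords).ravel()
        out[m] = pc_model.components @ dev
    return out


# ---------------------------------------------------------------------------
# KDE population maps


@dataclass
class GridSpec:
    """Evaluation grid for 2-D density maps.

    Limits default to the data range padded by ``pad`` kernel standard
    deviations per axis, wide enough for the map to integrate to 1.
    """

    nx: int = 120
    ny: int = 120
    xlim: tuple | None = None
    ylim: tuple | None = None
    pad: float = 4.0


@dataclass
class DensityMap:
    grid_x: np.ndarray        # (nx,) axis vector
    grid_y: np.ndarray        # (ny,)
    density: np.ndarray       # (nx, ny), density[i, j] at (grid_x[i], grid_y[j])
    bandwidth: np.ndarray     # 2×2 kernel covariance

    def integral(self) -> float:
        dx = float(self.grid_x[1] - self.grid_x[0])
        dy = float(self.grid_y[1] - self.grid_y[0])
        return float(self.density.sum() * dx * dy)


def kde_map(
    points: np.ndarray,
    grid_spec: GridSpec | None = None,
    bandwidth: np.ndarray | float | None = None,
) -> DensityMap:
    """Gaussian-kernel density estimate of 2-D points on a regular grid.

    The kernel covariance follows Scott's rule from the sample covariance by
    default; ``bandwidth`` overrides it with an explicit kernel covariance
    (2×2 matrix, or a scalar variance applied isotropically), which makes the
    estimate independent of the sample size.  A dimension with zero variance
    makes the kernel singular and raises an :class:`AnalysisError`
    suggesting jitter or a 1-D treatment.
    """
    grid_spec = grid_spec or GridSpec()
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ContractError("points must be (M, 2)")
    if points.shape[0] < 2:
        raise ContractError("KDE needs at least 2 points")
    if np.allclose(points.std(axis=0), 0.0):
        raise AnalysisError("all points identical; no density to estimate")

    if bandwidth is None:
        try:
            kde = gaussian_kde(points.T, bw_method="scott")
            kernel_cov = np.asarray(kde.covariance, dtype=float)
        except np.linalg.LinAlgError as exc:
            raise AnalysisError(
                "degenerate (zero-variance) dimension; jitter the points or "
                "use a 1-D density instead"
            ) from exc
        evaluate = kde
    else:
        kernel_cov = np.asarray(bandwidth, dtype=float)
        if kernel_cov.ndim == 0:
            kernel_cov = float(kernel_cov) * np.eye(2)
        try:
            prec = np.linalg.inv(kernel_cov)
            norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(kernel_cov)))
        except np.linalg.LinAlgError as exc:
            raise AnalysisError("kernel covariance must be invertible") from exc
        if norm <= 0 or not np.isfinite(norm):
            raise AnalysisError("kernel covariance must be positive definite")

        def evaluate(grid_pts):
            diff = grid_pts.T[:, None, :] - points[None, :, :]
            quad = np.einsum("gmi,ij,gmj->gm", diff, prec, diff)
            return norm * np.exp(-0.5 * quad).mean(axis=1)

    sd = np.sqrt(np.diag(kernel_cov))
    xlim = grid_spec.xlim or (
        points[:, 0].min() - grid_spec.pad * sd[0],
        points[:, 0].max() + grid_spec.pad * sd[0],
    )
    ylim = grid_spec.ylim or (
        points[:, 1].min() - grid_spec.pad * sd[1],
        points[:, 1].max() + grid_spec.pad * sd[1],
    )
    gx = np.linspace(*xlim, grid_spec.nx)
    gy = np.linspace(*ylim, grid_spec.ny)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    density = evaluate(np.vstack([xx.ravel(), yy.ravel()])).reshape(
        grid_spec.nx, grid_spec.ny
    )
    return DensityMap(grid_x=gx, grid_y=gy, density=density, bandwidth=kernel_cov)


def save_density_map(dmap: DensityMap, path) -> None:
    """Write a density map as a delimited grid (first row/column are axes)."""
    out = np.zeros((len(dmap.grid_x) + 1, len(dmap.grid_y) + 1))
    out[0, 1:] = dmap.grid_y
    out[1:, 0] = dmap.grid_x
    out[1:, 1:] = dmap.density
    np.savetxt(path, out, fmt="%.8g", delimiter="\t")


# ---------------------------------------------------------------------------
# Inter-domain angles


@dataclass
class AngleSpec:
    """Three atom selections defining an inter-domain angle at a vertex.

    The angle is measured at the centroid of ``vertex_group`` between the
    centroids of ``group_a`` and ``group_b`` (e.g. LID–CORE–NMP style
    reaction coordinates for two-domain enzymes).
    """

    group_a: str
    vertex_group: str
    group_b: str

    def masks(self, structure: Structure) -> tuple:
        masks = tuple(
            select(structure, expr)
            for expr in (self.group_a, self.vertex_group, self.group_b)
        )
        for expr, mask in zip((self.group_a, self.vertex_group, self.group_b), masks):
            if not mask.any():
                raise SelectionError(f"angle selection {expr!r} selects no atoms")
        a, v, b = masks
        if (a & v).any() or (a & b).any() or (v & b).any():
            raise SelectionError("angle selections must be pairwise disjoint")
        return masks


def interdomain_angle(coords: np.ndarray, spec: AngleSpec, structure: Structure) -> float:
    """Angle in degrees at the vertex centroid, in [0, 180]."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (structure.n_atoms, 3):
        raise ContractError("coords must match the structure atom count")
    mask_a, mask_v, mask_b = spec.masks(structure)
    a = coords[mask_a].mean(axis=0)
    v = coords[mask_v].mean(axis=0)
    b = coords[mask_b].mean(axis=0)
    u1, u2 = a - v, b - v
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise AnalysisError("a group centroid coincides with the vertex centroid")
    cosang = np.clip(float(u1 @ u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angle_trace(ensemble: Ensemble, spec: AngleSpec, structure: Structure) -> np.ndarray:
    """Per-conformer inter-domain angle (degrees)."""
    return np.array(
        [interdomain_angle(ensemble.coords[m], spec, structure) for m in range(len(ensemble))]
    )


def save_table(values: np.ndarray, path, header: str = "") -> None:
    """Write projections or angle traces as a delimited text table."""
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.8g",
               delimiter="\t", header=header)
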
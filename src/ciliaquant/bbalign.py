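"""Basal-body alignment scoring via minimum enclosing ellipses.

Basal bodies anchored in well-aligned rows produce elongated stained ROIs;
scattered basal bodies produce compact ones.  Each ROI (a connected component
of above-threshold pixels inside one cell) is summarised by its minimum-area
enclosing ellipse (the Löwner–John ellipse of the ROI's pixel-corner points):

* eccentricity = sqrt(a^2 - b^2) / a — the focal-point separation over the
  major-axis length;
* Mm ratio = a / b — the major over minor semi-axis, >= 1, larger for more
  elongated (more aligned) ROIs.

Per-cell means of both metrics are compared between groups (e.g. control vs
knockdown) with a Welch two-tailed t-test.

The ellipse is fitted to the four corner points of every member pixel rather
than to pixel centers: pixels have extent, so a single-pixel ROI yields a
finite circle (Mm ratio 1) and a one-pixel-wide row yields a valid thin
ellipse instead of a degenerate zero-area one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .errors import InputError, NumericalError
from .movieio import CellMaskImage, ChannelImage

log = logging.getLogger(__name__)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class BBRoi:
    """A connected basal-body ROI: member pixel coordinates inside one cell."""

    roi_id: int
    cell_id: int
    pixels: np.ndarray  # (n, 2) array of (row, col)


@dataclass
class RoiEllipse:
    """Minimum enclosing ellipse of one ROI with its elongation metrics."""

    roi_id: int
    cell_id: int
    center: tuple[float, float]  # (x, y)
    a: float  # semi-major, pixels
    b: float  # semi-minor, pixels
    orientation: float  # radians in (-pi/2, pi/2]
    eccentricity: float
    mm_ratio: float
    n_pixels: int


@dataclass
class CellAlignment:
    """Per-cell alignment summary: unweighted means over the cell's ROIs."""

    cell_id: int
    mean_eccentricity: float
    mean_mm_ratio: float
    n_rois: int
    group_label: str = ""


# ---------------------------------------------------------------------------
# Minimum-volume enclosing ellipse (Khachiyan / Wolfe–Atwood iteration)
# ---------------------------------------------------------------------------

def min_enclosing_ellipse(
    points: np.ndarray, tol: float = 1e-7, max_iter: int = 10000
) -> tuple[tuple[float, float], float, float, float]:
    """Minimum-area ellipse containing all 2-D points (Löwner–John).

    Solves the dual D-optimal design problem with Khachiyan's barycentric
    update accelerated by Wolfe–Atwood away steps, to relative tolerance
    ``tol`` on the optimality conditions.  The fitted ellipse is then scaled
    minimally so every point is contained exactly (within floating error),
    which preserves the axis ratio.

    Returns ``(center, a, b, orientation)`` with ``a >= b > 0`` and
    orientation of the major axis in (-pi/2, pi/2].  Degenerate inputs
    (fewer than 3 affinely independent points) raise ``NumericalError``.
    """
    P_raw = np.asarray(points, dtype=float)
    if P_raw.ndim != 2 or P_raw.shape[1] != 2 or P_raw.shape[0] < 1:
        raise InputError("points must be an (n, 2) array with n >= 1")
    # Work in centred, unit-scale coordinates: the lifted design matrix is
    # badly conditioned for absolute image coordinates (hundreds of pixels).
    shift = P_raw.mean(axis=0)
    spread = np.sqrt(((P_raw - shift) ** 2).sum(axis=1).mean())
    scale = spread if spread > 0 else 1.0
    P = (P_raw - shift) / scale
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)])  # (n, 3)

    u = np.full(n, 1.0 / n)
    converged = False
    best_gap = np.inf
    best_u = u.copy()
    stall = 0
    for it in range(max_iter):
        X = Q.T @ (Q * u[:, None])  # (3, 3)
        try:
            Xinv = np.linalg.inv(X)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"degenerate point set (rank-deficient after {it} iterations)"
            ) from exc
        M = np.einsum("ij,jk,ik->i", Q, Xinv, Q)
        j_plus = int(np.argmax(M))
        kappa_plus = M[j_plus]
        support = u > 1e-12
        m_support = np.where(support, M, np.inf)
        j_minus = int(np.argmin(m_support))
        kappa_minus = m_support[j_minus]
        gap = max(kappa_plus - (d + 1), (d + 1) - kappa_minus)
        if gap <= (d + 1) * tol:
            converged = True
            break
        # Exact-line-search steps shrink with the gap; once improvements fall
        # below floating-point noise the iterate random-walks on a plateau
        # near machine accuracy.  Accept the best iterate at that point.
        if gap < best_gap * (1 - 1e-3):
            best_gap = gap
            best_u = u.copy()
            stall = 0
        else:
            stall += 1
            if stall > 500 and best_gap < 1e-4:
                u = best_u
                converged = True
                break
        if kappa_plus - (d + 1) >= (d + 1) - kappa_minus:
            # Forward (Frank-Wolfe) step towards the worst-contained point.
            step = (kappa_plus - d - 1) / ((d + 1) * (kappa_plus - 1))
            u *= 1 - step
            u[j_plus] += step
        else:
            # Away step shrinking the weight of an over-weighted point; for
            # kappa_minus near 1 the unconstrained step diverges, so fall
            # back to dropping the point entirely.
            if kappa_minus <= 1:
                step = u[j_minus] / (1 - u[j_minus])
            else:
                step = (d + 1 - kappa_minus) / ((d + 1) * (kappa_minus - 1))
                step = min(step, u[j_minus] / (1 - u[j_minus]))
            u *= 1 + step
            u[j_minus] = max(u[j_minus] - step, 0.0)
            u /= u.sum()
    if not converged:
        raise NumericalError(
            f"minimum-enclosing-ellipse iteration did not converge in {max_iter} steps"
        )

    c = P.T @ u
    cov = P.T @ (P * u[:, None]) - np.outer(c, c)
    try:
        A = np.linalg.inv(cov) / d
    except np.linalg.LinAlgError as exc:
        raise NumericalError("degenerate (collinear) point set") from exc
    # Scale so the farthest point sits exactly on the boundary.
    diff = P - c
    dev = np.einsum("ij,jk,ik->i", diff, A, diff).max()
    if dev <= 0:
        raise NumericalError("degenerate point set (all points coincide)")
    A /= dev
    eigvals, eigvecs = np.linalg.eigh(A)
    if eigvals[0] <= 0:
        raise NumericalError("degenerate (collinear) point set")
    a = scale / np.sqrt(eigvals[0])  # smallest eigenvalue -> major axis
    b = scale / np.sqrt(eigvals[1])
    c = shift + scale * c
    v = eigvecs[:, 0]
    orientation = float(np.arctan2(v[1], v[0]))
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    return (float(c[0]), float(c[1])), float(a), float(b), orientation


def ellipse_metrics(a: float, b: float) -> tuple[float, float]:
    """Eccentricity and Mm ratio of an ellipse with semi-axes a >= b > 0.

    Eccentricity is the focal separation over the major-axis length,
    ``sqrt(a^2 - b^2) / a``; the Mm ratio is ``a / b``.
    """
    if b <= 0:
        raise InputError("semi-minor axis must be > 0")
    if a < b:
        raise InputError(f"require a >= b, got a={a}, b={b}")
    ecc = float(np.sqrt(a**2 - b**2) / a)
    return ecc, float(a / b)


# ---------------------------------------------------------------------------
# Segmentation and per-cell aggregation
# ---------------------------------------------------------------------------

def segment_bb_rois(
    img: ChannelImage,
    mask: CellMaskImage,
    threshold: str | float = "otsu",
    min_area: int = 3,
) -> list[BBRoi]:
    """Segment basal-body ROIs within each masked cell.

    The threshold is computed per cell (Otsu on the cell's own pixels) or
    given as a fixed intensity.  Above-threshold pixels are grouped by
    8-connectivity inside the cell's mask (components straddling a cell
    border are clipped by the mask), and components smaller than ``min_area``
    pixels are dropped.
    """
    if img.shape != mask.shape:
        raise InputError(f"image shape {img.shape} != mask shape {mask.shape}")
    cell_ids = mask.cell_ids
    if cell_ids.size == 0:
        raise InputError("cell mask contains no cells")
    rois: list[BBRoi] = []
    for cell_id in cell_ids:
        cell_mask = mask.labels == cell_id
        values = img.pixels[cell_mask]
        if threshold == "otsu":
            if np.ptp(values) == 0:
                continue  # flat cell: nothing to segment
            t = threshold_otsu(values)
        else:
            t = float(threshold)
        fg = (img.pixels > t) & cell_mask
        labels, n_comp = ndimage.label(fg, structure=_EIGHT_CONN)
        for k in range(1, n_comp + 1):
            coords = np.argwhere(labels == k)
            if len(coords) < min_area:
                continue
            rois.append(BBRoi(roi_id=len(rois), cell_id=int(cell_id), pixels=coords))
    return rois


def _pixel_corner_points(pixels: np.ndarray) -> np.ndarray:
    """Unique (x, y) corner points of a set of (row, col) pixels."""
    r = pixels[:, 0]
    c = pixels[:, 1]
    corners = np.concatenate(
        [
            np.column_stack([c, r]),
            np.column_stack([c + 1, r]),
            np.column_stack([c, r + 1]),
            np.column_stack([c + 1, r + 1]),
        ]
    )
    return np.unique(corners, axis=0).astype(float)


def fit_roi_ellipse(roi: BBRoi) -> RoiEllipse:
    """Fit the minimum enclosing ellipse to one ROI's pixel corners."""
    corners = _pixel_corner_points(roi.pixels)
    center, a, b, orientation = min_enclosing_ellipse(corners)
    ecc, mm = ellipse_metrics(a, b)
    return RoiEllipse(
        roi_id=roi.roi_id,
        cell_id=roi.cell_id,
        center=center,
        a=a,
        b=b,
        orientation=orientation,
        eccentricity=ecc,
        mm_ratio=mm,
        n_pixels=len(roi.pixels),
    )


def aggregate_cells(
    ellipses: list[RoiEllipse], mask: CellMaskImage, group_label: str = ""
) -> list[CellAlignment]:
    """Unweighted per-cell means of eccentricity and Mm ratio.

    Cells present in the mask but without any ROI are omitted (logged).
    """
    by_cell: dict[int, list[RoiEllipse]] = {}
    for e in ellipses:
        by_cell.setdefault(e.cell_id, []).append(e)
    out: list[CellAlignment] = []
    for cell_id in mask.cell_ids:
        cell_ellipses = by_cell.get(int(cell_id))
        if not cell_ellipses:
            log.info("cell %d has no ROIs; omitted from per-cell table", cell_id)
            continue
        out.append(
            CellAlignment(
                cell_id=int(cell_id),
                mean_eccentricity=float(np.mean([e.eccentricity for e in cell_ellipses])),
                mean_mm_ratio=float(np.mean([e.mm_ratio for e in cell_ellipses])),
                n_rois=len(cell_ellipses),
                group_label=group_label,
            )
        )
    return out


def analyze_image(
    img: ChannelImage,
    mask: CellMaskImage,
    threshold: str | float = "otsu",
    min_area: int = 3,
    group_label: str = "",
) -> tuple[list[RoiEllipse], list[CellAlignment]]:
    """Segment, fit and aggregate in one call."""
    rois = segment_bb_rois(img, mask, threshold=threshold, min_area=min_area)
    ellipses = [fit_roi_ellipse(r) for r in rois]
    cells = aggregate_cells(ellipses, mask, group_label=group_label)
    return ellipses, cells


def compare_groups(
    cells_a: list[CellAlignment], cells_b: list[CellAlignment]
) -> dict:
    """Welch two-tailed t-test between groups on per-cell means.

    Tested separately for the Mm ratio and the eccentricity.  Returns group
    means, t statistics, two-tailed p-values and group sizes.
    """
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise InputError(
            f"need >= 2 cells per group, got {len(cells_a)} and {len(cells_b)}"
        )
    out: dict[str, dict] = {}
    for metric, attr in (("mm_ratio", "mean_mm_ratio"), ("eccentricity", "mean_eccentricity")):
        a = np.array([getattr(c, attr) for c in cells_a])
        b = np.array([getattr(c, attr) for c in cells_b])
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out[metric] = {
            "t_statistic": float(t),
            "p_value": float(p),
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "n_a": int(a.size),
            "n_b": int(b.size),
        }
    return out
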
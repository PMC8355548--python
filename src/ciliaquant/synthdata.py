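"""Seeded synthetic inputs with known ground truth for every analysis stage.

Each generator emulates one acquisition used by the quantification pipelines:

* ``make_movie`` — beads attached to beating cilia, seen as oscillating
  Gaussian blobs on a constant (optionally tilted) background, sampled at a
  known frame rate.  Dark-on-bright by default, as magnetic beads appear in
  brightfield.
* ``make_bb_image`` — basal-body staining inside labelled cells: aligned
  cells carry parallel rows of overlapping blobs (elongated ROIs), non-aligned
  cells carry compact scattered clusters.
* ``make_coloc_pair`` — red/green spot images with a controlled fraction of
  green spots sitting exactly on red spots (the co-occupancy ground truth).
* ``make_counts`` — a negative-binomial genes x cells matrix with two latent
  groups: Jam3-positive cells and Jam3-negative cells in which deuterosomal
  markers are up-regulated by a known fold change.

All generators are deterministic: identical parameters and seed give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .movieio import CellMaskImage, ChannelImage, Movie
from .scmarkers import ExpressionMatrix

# Default marker panels: canonical deuterosomal-stage and mature-MCC genes.
DEFAULT_DEUTERO_MARKERS = ("Ccno", "Cdc20b", "Deup1", "Foxn4", "Mcidas")
DEFAULT_MATURE_MARKERS = ("Tmem212", "Fam183b", "Dnali1", "Tppp3", "Sntn")


# ---------------------------------------------------------------------------
# Bead movies
# ---------------------------------------------------------------------------

@dataclass
class SynthMovieParams:
    """Parameters of the synthetic bead-beating movie.

    ``f_true`` may be a scalar (all beads share it) or one value per bead.
    ``bead_contrast`` is signed: negative renders dark beads on the bright
    background (the default, matching beads in brightfield).  The per-bead
    signal-to-noise ratio is ``|bead_contrast| / noise_sd`` (10 by default).
    """

    n_beads: int = 10
    f_true: float | list[float] = 15.0
    amplitude: float = 3.0
    direction: list[float] | None = None
    bead_radius: float = 2.0
    bead_contrast: float = -50.0
    noise_sd: float = 5.0
    drift: tuple[float, float] = (0.0, 0.0)
    fps: float = 120.0
    duration: float = 20.0
    frame_shape: tuple[int, int] = (128, 128)
    background: float = 100.0
    background_gradient: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def frequencies(self) -> np.ndarray:
        f = np.asarray(self.f_true, dtype=float)
        if f.ndim == 0:
            f = np.full(self.n_beads, float(f))
        if f.shape != (self.n_beads,):
            raise ParameterError(f"f_true must be scalar or length {self.n_beads}")
        return f

    def validate(self) -> None:
        if self.n_beads < 1:
            raise ParameterError("n_beads must be >= 1")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.bead_radius <= 0:
            raise ParameterError("bead_radius must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.fps <= 0 or self.duration <= 0:
            raise ParameterError("fps and duration must be > 0")
        f = self.frequencies()
        if np.any(f <= 0) or np.any(f >= self.fps / 2):
            raise ParameterError(
                f"bead frequencies must lie in (0, fps/2)=(0, {self.fps / 2}) Hz"
            )


def _place_centers(
    rng: np.random.Generator,
    n: int,
    frame_shape: tuple[int, int],
    margin: float,
    min_sep: float,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample ``n`` points with pairwise separation >= min_sep."""
    h, w = frame_shape
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ParameterError("frame too small for the requested margin")
    centers: list[np.ndarray] = []
    for _ in range(max_attempts):
        cand = np.array([
            rng.uniform(margin, w - margin),
            rng.uniform(margin, h - margin),
        ])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
            if len(centers) == n:
                return np.array(centers)
    raise ParameterError(
        f"could not place {n} objects with separation {min_sep:.1f} px "
        f"in a {w}x{h} frame"
    )


def _add_gaussian_blob(
    frame: np.ndarray, cx: float, cy: float, sigma: float, amplitude: float
) -> None:
    """Add a 2-D Gaussian in-place, evaluated on a local 5-sigma window."""
    h, w = frame.shape
    r = int(np.ceil(5 * sigma))
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2))
    frame[y0:y1, x0:x1] += amplitude * g


def make_movie(p: SynthMovieParams) -> tuple[Movie, pd.DataFrame]:
    """Render a bead movie and return it with its per-bead ground truth.

    Bead ``i``'s center at frame ``t`` is
    ``rest_i + drift * t + amplitude * sin(2 pi f_i t / fps + phi_i) * (cos th_i, sin th_i)``.
    Beads are Gaussian blobs of sd ``bead_radius`` added onto the background;
    i.i.d. Gaussian pixel noise of sd ``noise_sd`` is added per frame.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    freqs = p.frequencies()
    n_frames = int(round(p.fps * p.duration))
    h, w = p.frame_shape

    # Rest positions: keep the whole oscillation (and drift) path inside the
    # frame and keep paths from colliding, not just rest points.
    drift_span = float(np.hypot(*p.drift)) * n_frames
    margin = p.amplitude + 5 * p.bead_radius + drift_span
    min_sep = 4 * p.bead_radius + 2 * p.amplitude
    rest = _place_centers(rng, p.n_beads, p.frame_shape, margin, min_sep)

    if p.direction is None:
        theta = rng.uniform(0, 2 * np.pi, size=p.n_beads)
    else:
        theta = np.asarray(p.direction, dtype=float)
        if theta.shape != (p.n_beads,):
            raise ParameterError(f"direction must have length {p.n_beads}")
    phase = rng.uniform(0, 2 * np.pi, size=p.n_beads)

    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    base = (
        p.background
        + p.background_gradient[0] * xx
        + p.background_gradient[1] * yy
    ).astype(np.float32) * np.ones((h, w), dtype=np.float32)

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    t_idx = np.arange(n_frames)
    osc = p.amplitude * np.sin(
        2 * np.pi * freqs[None, :] * t_idx[:, None] / p.fps + phase[None, :]
    )  # (T, n_beads)
    for t in range(n_frames):
        frame = base.astype(np.float64)
        for i in range(p.n_beads):
            cx = rest[i, 0] + p.drift[0] * t + osc[t, i] * np.cos(theta[i])
            cy = rest[i, 1] + p.drift[1] * t + osc[t, i] * np.sin(theta[i])
            _add_gaussian_blob(frame, cx, cy, p.bead_radius, p.bead_contrast)
        frames[t] = frame.astype(np.float32)
    if p.noise_sd > 0:
        frames += rng.normal(0, p.noise_sd, size=frames.shape).astype(np.float32)

    truth = pd.DataFrame(
        {
            "bead_id": np.arange(p.n_beads),
            "f_true": freqs,
            "x_rest": rest[:, 0],
            "y_rest": rest[:, 1],
            "direction": theta,
            "phase": phase,
            "amplitude": p.amplitude,
        }
    )
    return Movie(frames, fps=p.fps), truth


# ---------------------------------------------------------------------------
# Basal-body images
# ---------------------------------------------------------------------------

@dataclass
class SynthBBParams:
    """Parameters of the synthetic basal-body staining image.

    Aligned cells carry ``rows_per_cell`` parallel rows of ``bbs_per_row``
    blobs whose along-row spacing makes neighbouring blobs merge into one
    elongated connected component after thresholding; perpendicular jitter is
    ``row_spread``.  Non-aligned cells carry the same number of blobs grouped
    into ``rows_per_cell`` compact isotropic clusters.
    """

    n_cells: int = 40
    frac_aligned: float = 0.5
    rows_per_cell: int = 3
    bbs_per_row: int = 8
    row_spread: float = 0.7
    blob_sigma: float = 1.5
    blob_amplitude: float = 150.0
    noise_sd: float = 2.0
    cell_radius: float = 26.0
    frame_shape: tuple[int, int] = (512, 512)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.frac_aligned <= 1:
            raise ParameterError("frac_aligned must be in [0, 1]")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if min(self.rows_per_cell, self.bbs_per_row) < 1:
            raise ParameterError("rows_per_cell and bbs_per_row must be >= 1")
        if self.row_spread < 0 or self.blob_sigma <= 0:
            raise ParameterError("row_spread >= 0 and blob_sigma > 0 required")


def make_bb_image(p: SynthBBParams) -> tuple[ChannelImage, CellMaskImage, pd.DataFrame]:
    """Render a basal-body image, its cell label mask and per-cell truth."""
    p.validate()
    rng = np.random.default_rng(p.seed)
    h, w = p.frame_shape

    # Non-overlapping cells on a jittered grid.
    pitch = int(np.ceil(2 * p.cell_radius + 6))
    cols = w // pitch
    rows = h // pitch
    if cols * rows < p.n_cells:
        raise ParameterError(
            f"cannot place {p.n_cells} non-overlapping cells of radius "
            f"{p.cell_radius} in a {w}x{h} frame"
        )
    slots = [(r, c) for r in range(rows) for c in range(cols)]
    chosen = [slots[i] for i in rng.choice(len(slots), size=p.n_cells, replace=False)]
    centers = np.array(
        [((c + 0.5) * pitch, (r + 0.5) * pitch) for r, c in chosen]
    )  # (x, y)

    n_aligned = int(round(p.frac_aligned * p.n_cells))
    aligned_flags = np.zeros(p.n_cells, dtype=bool)
    aligned_flags[rng.permutation(p.n_cells)[:n_aligned]] = True

    img = np.zeros((h, w), dtype=float)
    mask = np.zeros((h, w), dtype=np.int32)
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]

    row_pitch = max(5.0, 5 * p.blob_sigma)  # separation between parallel rows
    along_spacing = 2.0 * p.blob_sigma  # neighbours merge after threshold
    for k in range(p.n_cells):
        cx, cy = centers[k]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= p.cell_radius**2
        mask[inside] = k + 1
        if aligned_flags[k]:
            phi = rng.uniform(0, np.pi)
            u = np.array([np.cos(phi), np.sin(phi)])  # along-row direction
            v = np.array([-np.sin(phi), np.cos(phi)])  # across rows
            offsets = (np.arange(p.rows_per_cell) - (p.rows_per_cell - 1) / 2) * row_pitch
            for off in offsets:
                for j in range(p.bbs_per_row):
                    s = (j - (p.bbs_per_row - 1) / 2) * along_spacing
                    jitter = rng.normal(0, p.row_spread)
                    pos = np.array([cx, cy]) + s * u + (off + jitter) * v
                    _add_gaussian_blob(img, pos[0], pos[1], p.blob_sigma, p.blob_amplitude)
        else:
            # Same blob budget, grouped into compact isotropic clusters.
            cluster_sd = 2.5 * p.blob_sigma
            cluster_centers = _place_centers_in_disk(
                rng, p.rows_per_cell, (cx, cy), p.cell_radius - 3 * cluster_sd,
                min_sep=4 * cluster_sd,
            )
            for cc in cluster_centers:
                for _ in range(p.bbs_per_row):
                    pos = cc + rng.normal(0, cluster_sd, size=2)
                    _add_gaussian_blob(img, pos[0], pos[1], p.blob_sigma, p.blob_amplitude)
    if p.noise_sd > 0:
        img += rng.normal(0, p.noise_sd, size=img.shape)
    img = np.clip(img, 0, None)

    truth = pd.DataFrame(
        {"cell_id": np.arange(1, p.n_cells + 1), "aligned": aligned_flags}
    )
    return ChannelImage(img, "basal_bodies"), CellMaskImage(mask), truth


def _place_centers_in_disk(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    radius: float,
    min_sep: float,
    max_attempts: int = 5000,
) -> np.ndarray:
    """Rejection-sample ``n`` points inside a disk with pairwise min_sep."""
    radius = max(radius, 1.0)
    pts: list[np.ndarray] = []
    for _ in range(max_attempts):
        r = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        cand = np.array(center) + r * np.array([np.cos(a), np.sin(a)])
        if all(np.hypot(*(cand - q)) >= min_sep for q in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    # Fall back to relaxed separation rather than failing: cluster overlap
    # only makes the non-aligned ROI more compact, never elongated.
    while len(pts) < n:
        r = radius * np.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * np.pi)
        pts.append(np.array(center) + r * np.array([np.cos(a), np.sin(a)]))
    return np.array(pts)


# ---------------------------------------------------------------------------
# Co-localization image pairs
# ---------------------------------------------------------------------------

@dataclass
class SynthColocParams:
    """Parameters of the synthetic red/green spot-image pair."""

    n_spots_red: int = 200
    n_spots_green: int = 200
    co_occupancy: float = 0.5
    spot_sigma: float = 2.0
    spot_amplitude: float = 100.0
    noise_sd: float = 2.0
    frame_shape: tuple[int, int] = (256, 256)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.co_occupancy <= 1:
            raise ParameterError("co_occupancy must be in [0, 1]")
        if min(self.n_spots_red, self.n_spots_green) < 1:
            raise ParameterError("spot counts must be >= 1")
        if self.spot_sigma <= 0:
            raise ParameterError("spot_sigma must be > 0")


def make_coloc_pair(
    p: SynthColocParams,
) -> tuple[ChannelImage, ChannelImage, dict]:
    """Render a red/green pair with a known green-on-red co-occupancy.

    ``round(co_occupancy * n_spots_green)`` green spots are centred exactly on
    randomly chosen red spots; the remaining green spots are placed at least
    ``4 * spot_sigma`` away from every red spot so they contribute no overlap.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    h, w = p.frame_shape
    margin = 4 * p.spot_sigma

    red_pos = _place_centers(
        rng, p.n_spots_red, p.frame_shape, margin, min_sep=4 * p.spot_sigma
    )
    n_co = int(round(p.co_occupancy * p.n_spots_green))
    co_idx = rng.choice(p.n_spots_red, size=n_co, replace=n_co > p.n_spots_red)
    green_pos = [red_pos[i] for i in co_idx]

    n_free = p.n_spots_green - n_co
    attempts = 0
    while len(green_pos) < p.n_spots_green:
        cand = np.array([
            rng.uniform(margin, w - margin),
            rng.uniform(margin, h - margin),
        ])
        d_red = np.min(np.hypot(*(red_pos - cand).T))
        if d_red >= 4 * p.spot_sigma:
            green_pos.append(cand)
        attempts += 1
        if attempts > 200 * max(n_free, 1):
            raise ParameterError(
                "frame too crowded to place non-co-occupied green spots"
            )
    green_pos = np.array(green_pos)

    red = np.zeros((h, w), dtype=float)
    green = np.zeros((h, w), dtype=float)
    for x, y in red_pos:
        _add_gaussian_blob(red, x, y, p.spot_sigma, p.spot_amplitude)
    for x, y in green_pos:
        _add_gaussian_blob(green, x, y, p.spot_sigma, p.spot_amplitude)
    if p.noise_sd > 0:
        red += rng.normal(0, p.noise_sd, size=red.shape)
        green += rng.normal(0, p.noise_sd, size=green.shape)
    red = np.clip(red, 0, None)
    green = np.clip(green, 0, None)

    truth = {"co_occupancy": p.co_occupancy, "n_green_on_red": n_co}
    return ChannelImage(red, "red"), ChannelImage(green, "green"), truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class SynthCountsParams:
    """Parameters of the synthetic multiciliated-cell count matrix.

    Counts follow a gamma-Poisson (negative binomial) model with dispersion
    0.3.  A fraction ``frac_jam3_pos`` of cells is Jam3-positive (>= 1 Jam3
    read); deuterosomal marker means are multiplied by ``effect_deutero`` in
    Jam3-*negative* cells, mature markers and the reference gene Foxj1 are
    identically distributed in both groups.
    """

    n_genes: int = 2000
    n_cells: int = 500
    frac_jam3_pos: float = 0.5
    marker_genes_deutero: tuple[str, ...] = DEFAULT_DEUTERO_MARKERS
    marker_genes_mature: tuple[str, ...] = DEFAULT_MATURE_MARKERS
    effect_deutero: float = 3.0
    depth_mean: float = 5000.0
    dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        deutero = set(self.marker_genes_deutero)
        mature = set(self.marker_genes_mature)
        if not deutero or not mature:
            raise ParameterError("marker lists must be non-empty")
        if deutero & mature:
            raise ParameterError(f"marker lists overlap: {sorted(deutero & mature)}")
        if "Jam3" in deutero | mature:
            raise ParameterError("marker lists must not contain the split gene Jam3")
        if not 0 <= self.frac_jam3_pos <= 1:
            raise ParameterError("frac_jam3_pos must be in [0, 1]")
        if self.effect_deutero <= 0:
            raise ParameterError("effect_deutero must be > 0")
        n_special = 2 + len(deutero) + len(mature)
        if self.n_genes < n_special:
            raise ParameterError(f"n_genes must be >= {n_special}")


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * np.maximum(mean, 1e-12))
    return rng.poisson(lam)


def make_counts(p: SynthCountsParams) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a count matrix and return it with per-cell group ground truth."""
    p.validate()
    rng = np.random.default_rng(p.seed)

    deutero = list(p.marker_genes_deutero)
    mature = list(p.marker_genes_mature)
    special = ["Jam3", "Foxj1"] + deutero + mature
    n_filler = p.n_genes - len(special)
    fillers = [f"Gene{i:04d}" for i in range(n_filler)]
    gene_ids = special + fillers

    # Relative abundance: markers and Foxj1 at the filler median, so the
    # marker panels are a realistically tiny fraction of each cell's library
    # (a large marker share would leak the deuterosomal effect into every
    # other gene's CPM through the library-size normalisation).
    weights = np.empty(p.n_genes)
    weights[: len(special)] = 1.0
    weights[len(special):] = rng.lognormal(0.0, 1.0, size=n_filler)
    weights /= weights.sum()

    positive = rng.uniform(size=p.n_cells) < p.frac_jam3_pos

    mu = p.depth_mean * weights[:, None] * np.ones(p.n_cells)[None, :]
    d_idx = [gene_ids.index(g) for g in deutero]
    mu[np.ix_(d_idx, np.flatnonzero(~positive))] *= p.effect_deutero

    counts = _nb_sample(rng, mu, p.dispersion)

    # Jam3 row is set by group membership: negatives have zero reads,
    # positives at least one (1 + Poisson keeps the conditional mean realistic).
    jam3 = np.zeros(p.n_cells, dtype=np.int64)
    jam3[positive] = 1 + rng.poisson(2.0, size=int(positive.sum()))
    counts[gene_ids.index("Jam3")] = jam3

    cell_ids = [f"cell{i:04d}" for i in range(p.n_cells)]
    matrix = ExpressionMatrix(counts.astype(np.int64), gene_ids, cell_ids)
    truth = pd.DataFrame(
        {"cell_id": cell_ids, "group": np.where(positive, "jam3_pos", "jam3_neg")}
    )
    return matrix, truth
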
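"""Seeded synthetic smFISH fields with full ground truth.

Generates four-channel z-stacks that mimic the acquisition geometry of the
yeast osmotic-stress data set — interleaved TMR/CY5/DAPI/widefield planes,
200 nm z-spacing, 2048x2048 pixels at full scale — together with the exact
geometry and spot bookkeeping needed to test every pipeline stage:

* cells are non-overlapping ellipses kept clear of the image border (border
  cells can be planted deliberately to exercise the border filter);
* each cell contains one ellipsoidal nucleus rendered into the DAPI channel
  with a per-cell peak intensity, its half-maximum surface coinciding with
  the true nucleus boundary;
* the widefield channel renders a bright cell interior with a dark ridge
  between touching cells, as background-subtracted transmitted light does;
* single molecules are 3D Gaussian spots at the PSF scale, drawn per cell
  from a Poisson or two-state (bursting) count model, split between nucleus
  and cytoplasm by a nuclear fraction, and placed with a minimum pairwise
  separation so resolvable scenes stay resolvable;
* noise is signal-dependent (Poisson counting noise on signal plus camera
  offset) with additive Gaussian read noise; the spot amplitude is set from
  the requested peak-signal to background-noise ratio (SNR).

Everything is deterministic given the seed.

The default test geometry (12 x 256 x 256) is a downscaled stand-in for the
full acquisition geometry (25 x 2048 x 2048), which remains available via
:meth:`SceneSpec.full_geometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .stack_io import DEFAULT_CHANNEL_ORDER, ExperimentManifest, ImageStack

__all__ = [
    "SpotModel",
    "SceneSpec",
    "GroundTruth",
    "generate_field",
    "generate_experiment",
    "match_cells",
]


@dataclass(frozen=True)
class SpotModel:
    """Per-gene molecule count model for one dye channel.

    ``kind='poisson'`` draws per-cell counts from Poisson(``lam``);
    ``kind='two_state'`` draws from a bursting mixture: with probability
    ``p_on`` the cell is ON and its count is Poisson(``lam_on``), otherwise
    Poisson(``lam_off``).
    """

    kind: str = "poisson"
    lam: float = 5.0
    p_on: float = 0.3
    lam_off: float = 0.3
    lam_on: float = 15.0
    f_nuc: float = 0.25

    def sample_counts(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "poisson":
            return rng.poisson(self.lam, size=n_cells)
        if self.kind == "two_state":
            on = rng.random(n_cells) < self.p_on
            lam = np.where(on, self.lam_on, self.lam_off)
            return rng.poisson(lam)
        raise ValueError(f"unknown spot model kind {self.kind!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic field of view."""

    field_shape: tuple[int, int, int] = (12, 256, 256)  # (n_z, height, width)
    z_step_nm: float = 200.0
    n_cells: int = 20
    n_border_cells: int = 0
    cell_radius_range: tuple[float, float] = (9.0, 12.0)
    nucleus_radius_range: tuple[float, float] = (3.0, 4.5)
    spot_models: dict[str, SpotModel] = field(
        default_factory=lambda: {"TMR": SpotModel(), "CY5": SpotModel(lam=3.0)}
    )
    psf_sigma: tuple[float, float] = (1.4, 1.2)  # (lateral, axial) voxels
    snr: float = 8.0
    background_offset: float = 100.0
    read_noise_sd: float = 2.0
    min_spot_separation: float = 6.0
    border_margin: int = 20
    cell_gap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.nucleus_radius_range[1] >= self.cell_radius_range[0]:
            raise ValueError("nuclei must be strictly smaller than cells")
        for model in self.spot_models.values():
            if not 0 <= model.f_nuc <= 1:
                raise ValueError("nuclear fraction must be in [0, 1]")
            if model.kind == "two_state" and not 0 <= model.p_on <= 1:
                raise ValueError("p_on must be in [0, 1]")

    @classmethod
    def full_geometry(cls, **overrides) -> "SceneSpec":
        """The acquisition-scale geometry: 25 z-planes of 2048x2048 pixels."""
        defaults = dict(
            field_shape=(25, 2048, 2048),
            n_cells=overrides.pop("n_cells", 50),
            border_margin=40,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def background_noise_sd(self) -> float:
        """SD of the background: shot noise on the offset plus read noise."""
        return math.sqrt(self.background_offset + self.read_noise_sd**2)

    @property
    def spot_amplitude(self) -> float:
        """Peak spot signal above background implied by the requested SNR."""
        return self.snr * self.background_noise_sd


@dataclass
class GroundTruth:
    """Exact scene content: geometry, individual spots, per-cell counts.

    ``cells``/``nuclei`` carry one row per cell (ellipse/ellipsoid
    parameters; ``valid`` False marks deliberately planted border cells).
    ``spots`` has one row per molecule with its true continuous position,
    channel, compartment and owning cell. ``counts`` aggregates spots per
    (cell, channel) into nuclear/cytoplasmic/total, including zero rows.
    """

    cells: pd.DataFrame
    nuclei: pd.DataFrame
    spots: pd.DataFrame
    counts: pd.DataFrame

    def channel_counts(self, channel: str, valid_only: bool = True) -> pd.DataFrame:
        sub = self.counts[self.counts["channel"] == channel]
        if valid_only:
            valid = set(self.cells.loc[self.cells["valid"], "cell"])
            sub = sub[sub["cell"].isin(valid)]
        return sub.set_index("cell")[["nuclear", "cytoplasmic", "total"]]


# ---------------------------------------------------------------------------
# geometry placement


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample non-overlapping ellipse centres; raises when packing fails."""
    nz, h, w = spec.field_shape
    rows: list[dict] = []
    total = spec.n_cells + spec.n_border_cells
    attempts_per_cell = 400
    for i in range(total):
        border_cell = i >= spec.n_cells
        placed = False
        for _ in range(attempts_per_cell):
            a = rng.uniform(*spec.cell_radius_range)  # semi-major
            b = a * rng.uniform(0.8, 1.0)  # semi-minor
            theta = rng.uniform(0, math.pi)
            r_eff = a
            if border_cell:
                # centre inside the margin strip so the cell touches the border zone
                side = rng.integers(4)
                edge_pos = rng.uniform(0, w if side < 2 else h)
                off = rng.uniform(0, spec.border_margin * 0.5)
                cx, cy = {
                    0: (edge_pos, off + r_eff * 0.3),
                    1: (edge_pos, h - 1 - off - r_eff * 0.3),
                    2: (off + r_eff * 0.3, edge_pos),
                    3: (w - 1 - off - r_eff * 0.3, edge_pos),
                }[int(side)]
            else:
                lo = spec.border_margin + r_eff + 1
                cx = rng.uniform(lo, w - 1 - lo)
                cy = rng.uniform(lo, h - 1 - lo)
            ok = True
            for r in rows:
                d = math.hypot(cx - r["cx"], cy - r["cy"])
                if d < a + r["a"] + spec.cell_gap:
                    ok = False
                    break
            if ok:
                rows.append(
                    dict(
                        cell=len(rows) + 1,
                        cx=float(cx),
                        cy=float(cy),
                        a=float(a),
                        b=float(b),
                        theta=float(theta),
                        valid=not border_cell,
                    )
                )
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{total}: field too crowded for "
                f"{total} cells of radius {spec.cell_radius_range}"
            )
    return pd.DataFrame(
        rows, columns=["cell", "cx", "cy", "a", "b", "theta", "valid"]
    )


def _place_nuclei(spec: SceneSpec, cells: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    nz = spec.field_shape[0]
    rows = []
    for r in cells.itertuples(index=False):
        ra = rng.uniform(*spec.nucleus_radius_range)
        rb = ra * rng.uniform(0.85, 1.0)
        # axial semi-axis in voxels, capped so the nucleus fits the stack
        rz = min(ra * 0.8, nz / 2 - 1.5)
        # offset the nucleus inside its cell, keeping it strictly interior
        max_off = max(r.b - ra - 1.0, 0.0)
        phi = rng.uniform(0, 2 * math.pi)
        off = rng.uniform(0, 0.5 * max_off)
        rows.append(
            dict(
                cell=r.cell,
                cx=r.cx + off * math.cos(phi),
                cy=r.cy + off * math.sin(phi),
                cz=(nz - 1) / 2.0,
                rx=float(ra),
                ry=float(rb),
                rz=float(rz),
                peak=float(rng.uniform(0.7, 1.3)),  # relative DAPI brightness
            )
        )
    return pd.DataFrame(
        rows, columns=["cell", "cx", "cy", "cz", "rx", "ry", "rz", "peak"]
    )


def _place_spots(
    spec: SceneSpec,
    cells: pd.DataFrame,
    nuclei: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place per-cell molecule positions with a minimum pairwise separation.

    Nuclear spots sit well inside the nucleus (normalized radius < 0.7) and
    cytoplasmic spots well outside it (> 1.35) but inside the cell at 80% of
    its radius, so compartment assignment against the segmented masks is
    unambiguous for resolvable scenes. The separation metric is anisotropic:
    axial distances are weighted by the lateral/axial PSF ratio, because
    resolvability along z is set by the (narrower, in voxels) axial PSF.

    A nuclear spot that cannot be placed resolvably in the (small) nucleus
    is placed in the cytoplasm instead and recorded there; only genuinely
    crowded cells fall back to the best-separated candidate found.
    """
    nz = spec.field_shape[0]
    nuc_by_cell = {r.cell: r for r in nuclei.itertuples(index=False)}
    z_weight = spec.psf_sigma[0] / spec.psf_sigma[1]  # lateral / axial
    sep = spec.min_spot_separation
    rows: list[dict] = []
    for ch, model in spec.spot_models.items():
        counts = model.sample_counts(len(cells), rng)
        for (cell_row, n) in zip(cells.itertuples(index=False), counts):
            if not n:
                continue
            nuc = nuc_by_cell[cell_row.cell]
            n_nuclear = rng.binomial(n, model.f_nuc)
            placed = np.empty((0, 3))
            for j in range(int(n)):
                nuclear = j < n_nuclear
                pos = _sample_position(
                    spec, cell_row, nuc, nuclear, rng, placed, sep, z_weight, nz
                )
                if pos is None and nuclear:
                    nuclear = False
                    pos = _sample_position(
                        spec, cell_row, nuc, False, rng, placed, sep, z_weight, nz
                    )
                if pos is None:
                    pos = _sample_position(
                        spec, cell_row, nuc, nuclear, rng, placed, sep, z_weight, nz,
                        best_effort=True,
                    )
                placed = np.vstack([placed, pos])
                rows.append(
                    dict(
                        channel=ch,
                        cell=cell_row.cell,
                        compartment="nuclear" if nuclear else "cytoplasmic",
                        x=pos[0],
                        y=pos[1],
                        z=pos[2],
                    )
                )
    return pd.DataFrame(
        rows, columns=["channel", "cell", "compartment", "x", "y", "z"]
    )


def _candidate_positions(
    spec: SceneSpec, cell_row, nuc, nuclear: bool, rng: np.random.Generator,
    n_cand: int, nz: int,
) -> np.ndarray:
    """Vectorized draw of candidate (x, y, z) positions in one compartment."""
    z_lo, z_hi = 1.5, nz - 2.5
    if nuclear:
        u = rng.normal(size=(n_cand, 3))
        u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-12)
        radius = 0.7 * rng.random(n_cand) ** (1 / 3)
        u *= radius[:, None]
        x = nuc.cx + u[:, 0] * nuc.rx
        y = nuc.cy + u[:, 1] * nuc.ry
        z = np.clip(nuc.cz + u[:, 2] * nuc.rz, z_lo, z_hi)
        return np.column_stack([x, y, z])
    phi = rng.uniform(0, 2 * math.pi, size=n_cand)
    rad = 0.8 * np.sqrt(rng.random(n_cand))
    ca, sa = math.cos(cell_row.theta), math.sin(cell_row.theta)
    ex, ey = rad * np.cos(phi), rad * np.sin(phi)
    x = cell_row.cx + cell_row.a * ex * ca - cell_row.b * ey * sa
    y = cell_row.cy + cell_row.a * ex * sa + cell_row.b * ey * ca
    z = rng.uniform(z_lo, z_hi, size=n_cand)
    keep = (
        ((x - nuc.cx) / nuc.rx) ** 2
        + ((y - nuc.cy) / nuc.ry) ** 2
        + ((z - nuc.cz) / nuc.rz) ** 2
    ) >= 1.35**2
    return np.column_stack([x, y, z])[keep]


def _sample_position(
    spec: SceneSpec,
    cell_row,
    nuc,
    nuclear: bool,
    rng: np.random.Generator,
    placed: np.ndarray,
    sep: float,
    z_weight: float,
    nz: int,
    n_batches: int = 5,
    batch: int = 40,
    best_effort: bool = False,
) -> np.ndarray | None:
    """Draw one spot position in the requested compartment.

    Returns None when no candidate satisfying the (anisotropic) pairwise
    separation was found, unless ``best_effort``, which returns the
    best-separated candidate seen.
    """
    best, best_d = None, -1.0
    for _ in range(n_batches):
        cand = _candidate_positions(spec, cell_row, nuc, nuclear, rng, batch, nz)
        if cand.size == 0:
            continue
        if placed.size == 0:
            return cand[0]
        diff = cand[:, None, :] - placed[None, :, :]
        diff[:, :, 2] *= z_weight
        d = (diff**2).sum(axis=2).min(axis=1)
        ok = np.flatnonzero(d >= sep**2)
        if ok.size:
            return cand[ok[0]]
        i = int(np.argmax(d))
        if d[i] > best_d:
            best_d, best = float(d[i]), cand[i]
    return best if best_effort else None


# ---------------------------------------------------------------------------
# rendering


def _render_spots(
    shape: tuple[int, int, int],
    spots: pd.DataFrame,
    amplitude: float,
    psf_sigma: tuple[float, float],
) -> np.ndarray:
    """Additive 3D Gaussian splats at the PSF scale (float32 signal image)."""
    nz, h, w = shape
    signal = np.zeros(shape, dtype=np.float32)
    s_lat, s_ax = psf_sigma
    ext_lat = int(math.ceil(4 * s_lat))
    ext_ax = int(math.ceil(4 * s_ax))
    for r in spots.itertuples(index=False):
        z0, y0, x0 = r.z, r.y, r.x
        zi = np.arange(max(0, int(z0) - ext_ax), min(nz, int(z0) + ext_ax + 1))
        yi = np.arange(max(0, int(y0) - ext_lat), min(h, int(y0) + ext_lat + 1))
        xi = np.arange(max(0, int(x0) - ext_lat), min(w, int(x0) + ext_lat + 1))
        if not (zi.size and yi.size and xi.size):
            continue
        gz = np.exp(-0.5 * ((zi - z0) / s_ax) ** 2)
        gy = np.exp(-0.5 * ((yi - y0) / s_lat) ** 2)
        gx = np.exp(-0.5 * ((xi - x0) / s_lat) ** 2)
        signal[np.ix_(zi, yi, xi)] += amplitude * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    return signal


def _render_dapi(
    shape: tuple[int, int, int], nuclei: pd.DataFrame, amplitude: float
) -> np.ndarray:
    """Smooth ellipsoidal DAPI blobs whose half-maximum surface is the
    true nucleus boundary (Gaussian profile in normalized ellipsoid radius)."""
    nz, h, w = shape
    signal = np.zeros(shape, dtype=np.float32)
    c = math.sqrt(2 * math.log(2))  # half max at normalized radius 1
    for r in nuclei.itertuples(index=False):
        ext_x = int(math.ceil(2.5 * r.rx))
        ext_y = int(math.ceil(2.5 * r.ry))
        xi = np.arange(max(0, int(r.cx) - ext_x), min(w, int(r.cx) + ext_x + 1))
        yi = np.arange(max(0, int(r.cy) - ext_y), min(h, int(r.cy) + ext_y + 1))
        zi = np.arange(nz)
        dx = ((xi - r.cx) / r.rx) ** 2
        dy = ((yi - r.cy) / r.ry) ** 2
        dz = ((zi - r.cz) / r.rz) ** 2
        d2 = dz[:, None, None] + dy[None, :, None] + dx[None, None, :]
        signal[np.ix_(zi, yi, xi)] += (r.peak * amplitude) * np.exp(
            -0.5 * (c**2) * d2
        ).astype(np.float32)
    return signal


def _render_widefield(
    shape: tuple[int, int, int], cells: pd.DataFrame, amplitude: float
) -> np.ndarray:
    """Bright, nearly flat cell interiors with a steep falloff at the edge.

    Touching cells meet at an intensity valley, the ridge the seeded
    watershed uses to separate them after background subtraction.
    """
    nz, h, w = shape
    plane = np.zeros((h, w), dtype=np.float32)
    for r in cells.itertuples(index=False):
        ext = int(math.ceil(max(r.a, r.b))) + 2
        x0, x1 = max(0, int(r.cx) - ext), min(w, int(r.cx) + ext + 1)
        y0, y1 = max(0, int(r.cy) - ext), min(h, int(r.cy) + ext + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xx, yy = np.meshgrid(
            np.arange(x0, x1, dtype=np.float32), np.arange(y0, y1, dtype=np.float32)
        )
        ca, sa = math.cos(r.theta), math.sin(r.theta)
        dx = xx - r.cx
        dy = yy - r.cy
        ex = (dx * ca + dy * sa) / r.a
        ey = (-dx * sa + dy * ca) / r.b
        rad2 = ex**2 + ey**2
        profile = np.where(
            rad2 <= 1.0, amplitude * (1.0 - 0.35 * rad2**2), 0.0
        ).astype(np.float32)
        window = plane[y0:y1, x0:x1]
        np.maximum(window, profile, out=window)
    return np.broadcast_to(plane, shape).copy()


def _apply_noise(
    signal: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counting noise on (signal + offset) plus Gaussian read noise."""
    # Poisson(signal + offset) = Poisson(offset) + Poisson(signal). The
    # signal image is sparse, so its shot noise is drawn exactly only where
    # signal > 0; the dense background term (offset counts, here >= tens of
    # photons) is Gaussian to excellent approximation and is folded into one
    # normal draw together with the read noise.
    noisy = np.full(signal.shape, spec.background_offset, dtype=np.float32)
    noisy += spec.background_noise_sd * rng.standard_normal(
        signal.shape, dtype=np.float32
    )
    nz = signal > 0
    if nz.any():
        noisy[nz] += rng.poisson(signal[nz].astype(np.float64)).astype(np.float32)
    return np.clip(noisy, 0, None)


def generate_field(spec: SceneSpec, source_id: str = "synthetic") -> tuple[ImageStack, GroundTruth]:
    """Render one field of view and its exact ground truth.

    Deterministic given ``spec.seed``: the same spec yields voxel-identical
    stacks and identical truth tables.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)
    nuclei = _place_nuclei(spec, cells, rng)
    spots = _place_spots(spec, cells, nuclei, rng)
    amplitude = spec.spot_amplitude
    shape = spec.field_shape

    channels: dict[str, np.ndarray] = {}
    for ch in ("TMR", "CY5"):
        ch_spots = spots[spots["channel"] == ch]
        signal = _render_spots(shape, ch_spots, amplitude, spec.psf_sigma)
        channels[ch] = _apply_noise(signal, spec, rng)
    dapi_amp = 30.0 * spec.background_noise_sd
    channels["DAPI"] = _apply_noise(_render_dapi(shape, nuclei, dapi_amp), spec, rng)
    wf_amp = 20.0 * spec.background_noise_sd
    channels["WIDEFIELD"] = _apply_noise(_render_widefield(shape, cells, wf_amp), spec, rng)

    stack = ImageStack(
        channels=channels,
        z_step_nm=spec.z_step_nm,
        channel_order=DEFAULT_CHANNEL_ORDER,
        source_id=source_id,
    )
    truth = GroundTruth(
        cells=cells, nuclei=nuclei, spots=spots, counts=_truth_counts(spec, cells, spots)
    )
    return stack, truth


def _truth_counts(spec: SceneSpec, cells: pd.DataFrame, spots: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for ch in spec.spot_models:
        ch_spots = spots[spots["channel"] == ch]
        grouped = ch_spots.groupby(["cell", "compartment"]).size()
        for cell in cells["cell"]:
            nuc = int(grouped.get((cell, "nuclear"), 0))
            cyt = int(grouped.get((cell, "cytoplasmic"), 0))
            rows.append(
                dict(cell=int(cell), channel=ch, nuclear=nuc, cytoplasmic=cyt, total=nuc + cyt)
            )
    return pd.DataFrame(rows, columns=["cell", "channel", "nuclear", "cytoplasmic", "total"])


def match_cells(
    truth: GroundTruth, records, max_dist: float = 6.0
) -> dict[int, int]:
    """Match segmented cells to planted cells by centroid proximity.

    Segmentation renumbers labels in raster order, so detected label k does
    not in general equal truth cell k. Returns detected label -> truth cell
    for every record whose centroid lies within ``max_dist`` pixels of a
    planted cell centre; each truth cell is matched at most once (closest
    detection wins).
    """
    from scipy.spatial import cKDTree

    if len(truth.cells) == 0:
        return {}
    tree = cKDTree(truth.cells[["cx", "cy"]].to_numpy())
    candidates = []
    for rec in records:
        d, i = tree.query(rec.centroid)
        if d <= max_dist:
            candidates.append((float(d), rec.label, int(truth.cells.iloc[int(i)].cell)))
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for _, label, cell in sorted(candidates):
        if cell not in used and label not in mapping:
            mapping[label] = cell
            used.add(cell)
    return mapping


def generate_experiment(
    manifest: ExperimentManifest,
    spec_per_timepoint: dict[float, SceneSpec],
    base_seed: int = 0,
) -> Iterator[tuple[float, int, ImageStack, GroundTruth]]:
    """Yield ``fields_per_timepoint`` fields per manifest timepoint.

    Field seeds are derived deterministically (and distinctly) from
    ``(base_seed, timepoint index, field index)`` via a seed sequence, so a
    whole experiment is reproducible from one integer.
    """
    missing = [t for t in manifest.timepoints_min if t not in spec_per_timepoint]
    if missing:
        raise ValueError(f"no scene spec for timepoints {missing}")
    for ti, tp in enumerate(manifest.timepoints_min):
        for fi in range(manifest.fields_per_timepoint):
            seed = int(
                np.random.SeedSequence([base_seed, ti, fi]).generate_state(1)[0]
                % (2**31 - 1)
            )
            spec = replace(spec_per_timepoint[tp], seed=seed)
            source_id = f"{manifest.experiment}_{tp:g}min_im{fi + 1}"
            stack, truth = generate_field(spec, source_id=source_id)
            yield tp, fi, stack, truth
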
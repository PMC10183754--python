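"""Synthetic ground-truth generators for FISH scenes, spliced reads and UMI matrices.

Every downstream stage of the package (segmentation, spot calling, splice
quantification, expression harmonization) is validated against data produced
here, because the generators export the exact truth they realized: spot
coordinates and per-cell counts, junction read tallies, and per-cell UMI draws.

The scene model is deliberately minimal: a single 2-D plane, disk-shaped nuclei
of constant radius rendered on the DAPI channel, and probe speckles rendered as
isotropic Gaussians (a standard smFISH point-spread approximation) with
additive Gaussian read-out noise.  Speckles for a cell are drawn i.i.d.
Poisson(lambda_channel) and placed inside the cell's cytoplasmic territory
(nucleus disk plus the radial expansion ring) with two resolvability
constraints — a minimum pairwise spot separation and a margin from the
equidistant boundary to neighbouring cells — so that per-cell recovery by
threshold/connected-component detection plus centroid assignment is exact by
construction rather than approximately so.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import tifffile

__all__ = [
    "SceneSpec",
    "CellPopulation",
    "GroundTruth",
    "CellTruth",
    "ImageBundle",
    "PlacementError",
    "generate_fish_scene",
    "generate_junction_reads",
    "generate_umi_matrix",
    "UMIProfile",
]


class PlacementError(RuntimeError):
    """Raised when nuclei or spots cannot be placed under the spacing constraints."""


@dataclass(frozen=True)
class CellPopulation:
    """A named cell class with its own per-channel Poisson spot rates.

    ``fraction`` values across the populations of a scene must sum to 1; cells
    are assigned to populations by an independent categorical draw.
    """

    name: str
    fraction: float
    channel_rates: Mapping[str, float]


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a synthetic RNAscope scene.

    The defaults encode the imaging geometry of the quantified sections:
    0.16 µm pixels (a 10-px radial expansion corresponds to 1.6 µm), 15-px
    nucleus disks, and a negative-control channel carrying sparse false
    speckles with a bimodal (mostly dim) intensity mix.
    """

    image_height_px: int = 1300
    image_width_px: int = 1300
    pixel_size_um: float = 0.16
    n_cells: int = 100
    nucleus_radius_px: float = 25.0
    min_center_spacing_px: float = 80.0
    expansion_radius_px: float = 10.0
    channel_rates: Mapping[str, float] = field(
        default_factory=lambda: {"KCC2": 8.0, "NKCC1": 8.0}
    )
    populations: tuple[CellPopulation, ...] | None = None
    background_spot_rate: float = 0.3
    background_amplitude_mix: tuple[tuple[float, float], ...] = (
        (250.0, 0.8),
        (1500.0, 0.2),
    )
    spot_sigma_px: float = 1.5
    spot_amplitude: float = 2500.0
    dapi_amplitude: float = 10000.0
    noise_sd: float = 100.0
    min_spot_separation_px: float = 8.0
    boundary_margin_px: float = 4.0
    negctrl_channel: str = "NEGCTRL"
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_px <= 0 or self.min_center_spacing_px <= 0:
            raise ValueError("nucleus radius and spacing must be positive")
        rates = self._all_rates()
        if any(r < 0 for r in rates):
            raise ValueError("all spot rates must be >= 0")
        if self.background_spot_rate < 0:
            raise ValueError("background_spot_rate must be >= 0")
        if self.populations is not None:
            total = sum(p.fraction for p in self.populations)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError("population fractions must sum to 1")

    def _all_rates(self) -> list[float]:
        rates = list(self.channel_rates.values())
        if self.populations:
            for pop in self.populations:
                rates.extend(pop.channel_rates.values())
        return rates

    @property
    def probe_channels(self) -> tuple[str, ...]:
        names: list[str] = list(self.channel_rates)
        if self.populations:
            for pop in self.populations:
                for ch in pop.channel_rates:
                    if ch not in names:
                        names.append(ch)
        return tuple(names)

    @property
    def territory_radius_px(self) -> float:
        """Radius of the disk in which a cell's speckles live (nucleus + ring)."""
        return self.nucleus_radius_px + self.expansion_radius_px


@dataclass
class CellTruth:
    cell_id: int
    center: tuple[float, float]  # (row, col)
    nucleus_radius_px: float
    true_class: str
    spots: dict[str, np.ndarray]  # channel -> (k, 2) float array of (row, col)

    def count(self, channel: str) -> int:
        arr = self.spots.get(channel)
        return 0 if arr is None else len(arr)


@dataclass
class GroundTruth:
    """Exact record of everything the generator placed."""

    cells: list[CellTruth]
    background_spots: np.ndarray  # (m, 2) coordinates on the negative-control channel
    background_amplitudes: np.ndarray
    channels: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "cell_id": c.cell_id,
                "center_row": c.center[0],
                "center_col": c.center[1],
                "true_class": c.true_class,
            }
            for ch in self.channels:
                row[f"{ch}_count"] = c.count(ch)
            rows.append(row)
        cols = ["cell_id", "center_row", "center_col", "true_class"] + [
            f"{ch}_count" for ch in self.channels
        ]
        return pd.DataFrame(rows, columns=cols)

    def spots_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            for ch, arr in c.spots.items():
                for r, col in arr:
                    rows.append(
                        {"cell_id": c.cell_id, "channel": ch, "row": r, "col": col}
                    )
        for (r, col), amp in zip(self.background_spots, self.background_amplitudes):
            rows.append(
                {"cell_id": 0, "channel": "negctrl", "row": r, "col": col}
            )
        return pd.DataFrame(rows, columns=["cell_id", "channel", "row", "col"])

    def save(self, directory: str | Path, stem: str = "ground_truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(directory / f"{stem}_cells.csv", index=False)
        self.spots_frame().to_csv(directory / f"{stem}_spots.csv", index=False)
        payload = {
            "channels": list(self.channels),
            "cells": [
                {
                    "cell_id": c.cell_id,
                    "center": list(c.center),
                    "nucleus_radius_px": c.nucleus_radius_px,
                    "true_class": c.true_class,
                    "spots": {ch: arr.tolist() for ch, arr in c.spots.items()},
                }
                for c in self.cells
            ],
            "background_spots": self.background_spots.tolist(),
        }
        (directory / f"{stem}.json").write_text(json.dumps(payload))


@dataclass
class ImageBundle:
    """A multi-channel 2-D scene; channel order is stable and named."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    name: str = "scene"

    def __post_init__(self) -> None:
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def save(self, directory: str | Path) -> Path:
        """Write a 16-bit multi-page TIFF plus a channel-name sidecar JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / f"{self.name}.tif"
        stack = np.stack(
            [np.clip(a, 0, 65535).astype(np.uint16) for a in self.channels.values()]
        )
        tifffile.imwrite(path, stack, photometric="minisblack")
        sidecar = {
            "channels": list(self.channels),
            "pixel_size_um": self.pixel_size_um,
            "name": self.name,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        return path

    @classmethod
    def load(cls, tiff_path: str | Path) -> "ImageBundle":
        tiff_path = Path(tiff_path)
        stack = tifffile.imread(tiff_path)
        meta = json.loads(tiff_path.with_suffix(".json").read_text())
        channels = {
            name: stack[i].astype(np.float64)
            for i, name in enumerate(meta["channels"])
        }
        return cls(channels, meta["pixel_size_um"], meta.get("name", tiff_path.stem))


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

_MAX_TRIES_PER_OBJECT = 2000
_MAX_CONFIG_RESTARTS = 200
_EDGE_MARGIN_PX = 8.0


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    margin = spec.territory_radius_px + _EDGE_MARGIN_PX
    lo_r, hi_r = margin, spec.image_height_px - margin
    lo_c, hi_c = margin, spec.image_width_px - margin
    if spec.n_cells > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise PlacementError("image too small for the cell territory margin")
    centers: list[tuple[float, float]] = []
    for _ in range(spec.n_cells):
        for _attempt in range(_MAX_TRIES_PER_OBJECT):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if all(
                math.hypot(r - cr, c - cc) >= spec.min_center_spacing_px
                for cr, cc in centers
            ):
                centers.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place {spec.n_cells} nuclei with "
                f"min_center_spacing_px={spec.min_center_spacing_px} in a "
                f"{spec.image_height_px}x{spec.image_width_px} image; "
                "reduce n_cells or the spacing constraint"
            )
    return np.asarray(centers, dtype=float).reshape(spec.n_cells, 2)


def _place_cell_spots(
    spec: SceneSpec,
    rng: np.random.Generator,
    center: np.ndarray,
    others: np.ndarray,
    k: int,
) -> np.ndarray:
    """Place k spots in a cell's territory honouring the resolvability margins."""
    if k == 0:
        return np.empty((0, 2))
    # keep the full thresholded footprint inside the owning territory
    radius = spec.territory_radius_px - 2.0
    for _restart in range(_MAX_CONFIG_RESTARTS):
        placed: list[np.ndarray] = []
        for _ in range(k):
            for _attempt in range(_MAX_TRIES_PER_OBJECT):
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = radius * math.sqrt(rng.uniform())
                p = center + rad * np.array([math.sin(ang), math.cos(ang)])
                if not (
                    _EDGE_MARGIN_PX <= p[0] < spec.image_height_px - _EDGE_MARGIN_PX
                    and _EDGE_MARGIN_PX <= p[1] < spec.image_width_px - _EDGE_MARGIN_PX
                ):
                    continue
                if placed and min(
                    float(np.hypot(*(p - q))) for q in placed
                ) < spec.min_spot_separation_px:
                    continue
                if len(others):
                    d_own = float(np.hypot(*(p - center)))
                    d_others = np.hypot(others[:, 0] - p[0], others[:, 1] - p[1])
                    # distance-to-bisector margin between this cell and every neighbour
                    if np.min(d_others) - d_own < 2.0 * spec.boundary_margin_px:
                        continue
                placed.append(p)
                break
            else:
                break  # sequential placement saturated; restart the configuration
        if len(placed) == k:
            return np.asarray(placed)
    raise PlacementError(
        f"could not place {k} spots with "
        f"min_spot_separation_px={spec.min_spot_separation_px} inside a "
        f"territory of radius {spec.territory_radius_px}"
    )


def _render_gaussian_spots(
    img: np.ndarray, coords: np.ndarray, amplitudes: np.ndarray, sigma: float
) -> None:
    """Accumulate isotropic Gaussian PSFs at sub-pixel positions in place."""
    if len(coords) == 0:
        return
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    for (r, c), amp in zip(coords, amplitudes):
        r0 = max(0, int(math.floor(r)) - half)
        r1 = min(h, int(math.floor(r)) + half + 1)
        c0 = max(0, int(math.floor(c)) - half)
        c1 = min(w, int(math.floor(c)) + half + 1)
        rr = np.arange(r0, r1, dtype=float)[:, None]
        cc = np.arange(c0, c1, dtype=float)[None, :]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma**2)
        )


def _render_dapi(spec: SceneSpec, centers: np.ndarray) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    img = np.zeros((spec.image_height_px, spec.image_width_px))
    if len(centers):
        rr = np.arange(spec.image_height_px, dtype=float)[:, None]
        cc = np.arange(spec.image_width_px, dtype=float)[None, :]
        for r, c in centers:
            r0 = max(0, int(r - spec.nucleus_radius_px - 3))
            r1 = min(spec.image_height_px, int(r + spec.nucleus_radius_px + 4))
            c0 = max(0, int(c - spec.nucleus_radius_px - 3))
            c1 = min(spec.image_width_px, int(c + spec.nucleus_radius_px + 4))
            patch = (rr[r0:r1] - r) ** 2 + (cc[:, c0:c1] - c) ** 2
            img[r0:r1, c0:c1][
                patch <= spec.nucleus_radius_px**2
            ] = spec.dapi_amplitude
        img = gaussian_filter(img, spec.spot_sigma_px)
    return img


def generate_fish_scene(spec: SceneSpec) -> tuple[ImageBundle, GroundTruth]:
    """Render a synthetic RNAscope scene and return it with its exact truth.

    The bundle holds one float intensity grid per channel: DAPI (nucleus
    disks), one grid per probe channel (per-cell Poisson speckles), and a
    negative-control channel carrying Poisson(background_spot_rate * n_cells)
    false speckles placed uniformly over the field.  Identical spec and seed
    give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)

    if spec.populations:
        names = [p.name for p in spec.populations]
        fracs = np.array([p.fraction for p in spec.populations])
        classes = rng.choice(names, size=spec.n_cells, p=fracs / fracs.sum())
        rate_for = {
            p.name: {ch: float(p.channel_rates.get(ch, 0.0)) for ch in spec.probe_channels}
            for p in spec.populations
        }
    else:
        classes = np.array(["cell"] * spec.n_cells, dtype=object)
        rate_for = {
            "cell": {ch: float(spec.channel_rates.get(ch, 0.0)) for ch in spec.probe_channels}
        }

    cells: list[CellTruth] = []
    for i in range(spec.n_cells):
        center = centers[i]
        others = np.delete(centers, i, axis=0)
        spots: dict[str, np.ndarray] = {}
        for ch in spec.probe_channels:
            lam = rate_for[str(classes[i])][ch]
            k = int(rng.poisson(lam)) if lam > 0 else 0
            spots[ch] = _place_cell_spots(spec, rng, center, others, k)
        cells.append(
            CellTruth(
                cell_id=i + 1,
                center=(float(center[0]), float(center[1])),
                nucleus_radius_px=spec.nucleus_radius_px,
                true_class=str(classes[i]),
                spots=spots,
            )
        )

    # negative-control false speckles: uniform over the field, bimodal amplitudes
    n_bg = int(rng.poisson(spec.background_spot_rate * spec.n_cells))
    bg_coords: list[np.ndarray] = []
    for _ in range(n_bg):
        for _attempt in range(_MAX_TRIES_PER_OBJECT):
            p = np.array(
                [
                    rng.uniform(_EDGE_MARGIN_PX, spec.image_height_px - _EDGE_MARGIN_PX),
                    rng.uniform(_EDGE_MARGIN_PX, spec.image_width_px - _EDGE_MARGIN_PX),
                ]
            )
            if not bg_coords or min(
                float(np.hypot(*(p - q))) for q in bg_coords
            ) >= spec.min_spot_separation_px:
                bg_coords.append(p)
                break
        else:  # pragma: no cover - only under absurd background rates
            raise PlacementError("could not place background spots with separation")
    bg_arr = (
        np.asarray(bg_coords) if bg_coords else np.empty((0, 2))
    )
    amps, weights = zip(*spec.background_amplitude_mix)
    w = np.array(weights, dtype=float)
    bg_amps = rng.choice(np.array(amps, dtype=float), size=n_bg, p=w / w.sum())

    channels: dict[str, np.ndarray] = {"DAPI": _render_dapi(spec, centers)}
    for ch in spec.probe_channels:
        img = np.zeros((spec.image_height_px, spec.image_width_px))
        for cell in cells:
            coords = cell.spots[ch]
            _render_gaussian_spots(
                img, coords, np.full(len(coords), spec.spot_amplitude), spec.spot_sigma_px
            )
        channels[ch] = img
    neg = np.zeros((spec.image_height_px, spec.image_width_px))
    _render_gaussian_spots(neg, bg_arr, bg_amps, spec.spot_sigma_px)
    channels[spec.negctrl_channel] = neg

    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name]
                + rng.normal(0.0, spec.noise_sd, size=channels[name].shape),
                0.0,
                None,
            )

    truth = GroundTruth(
        cells=cells,
        background_spots=bg_arr,
        background_amplitudes=np.asarray(bg_amps, dtype=float),
        channels=spec.probe_channels,
    )
    bundle = ImageBundle(channels, spec.pixel_size_um, name=f"scene_seed{spec.seed}")
    return bundle, truth


# ---------------------------------------------------------------------------
# spliced-read / junction-table generation
# ---------------------------------------------------------------------------


def generate_junction_reads(
    counts: Sequence[tuple[tuple[int, int], int]],
    out_path: str | Path,
    flank_len: int = 50,
    emit: str = "sam",
    chrom: str = "chr18",
) -> Path:
    """Materialize exact splice-junction evidence as a SAM file or a TSV table.

    SAM mode writes, for each ``((intron_start, intron_end), n)`` entry, ``n``
    gapped alignments whose CIGAR contains a single N operation spanning
    exactly the half-open intron interval (read starts ``flank_len`` bases
    upstream of the donor).  TSV mode writes one row per junction with columns
    ``chrom, intron_start, intron_end, n_reads`` (0-based half-open).  Either
    output round-trips through :func:`specklesplice.splicejx.extract_junctions`
    to the input counts exactly.
    """
    out_path = Path(out_path)
    for (start, end), n in counts:
        if end <= start:
            raise ValueError(f"zero- or negative-length intron ({start}, {end})")
        if start < 0:
            raise ValueError("intron coordinates must be >= 0")
        if n < 0:
            raise ValueError("read counts must be >= 0")
    if emit == "tsv":
        df = pd.DataFrame(
            [
                {"chrom": chrom, "intron_start": s, "intron_end": e, "n_reads": n}
                for (s, e), n in counts
            ],
            columns=["chrom", "intron_start", "intron_end", "n_reads"],
        )
        df.to_csv(out_path, sep="\t", index=False)
        return out_path
    if emit != "sam":
        raise ValueError("emit must be 'sam' or 'tsv'")

    max_end = max((e for (_, e), _n in counts), default=1000)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": int(max_end + flank_len + 10)}],
    }
    with pysam.AlignmentFile(str(out_path), "wh", header=header) as sam:
        serial = 0
        for (start, end), n in counts:
            if start - flank_len < 0:
                raise ValueError(
                    f"intron start {start} leaves no room for a {flank_len} nt flank"
                )
            for _ in range(n):
                serial += 1
                a = pysam.AlignedSegment(sam.header)
                a.query_name = f"jxread_{serial}"
                a.query_sequence = "A" * (2 * flank_len)
                a.flag = 0
                a.reference_id = 0
                a.reference_start = start - flank_len
                a.mapping_quality = 255
                a.cigartuples = [
                    (pysam.CMATCH, flank_len),
                    (pysam.CREF_SKIP, end - start),
                    (pysam.CMATCH, flank_len),
                ]
                a.query_qualities = pysam.qualitystring_to_array("I" * (2 * flank_len))
                sam.write(a)
    return out_path


# ---------------------------------------------------------------------------
# UMI count matrix generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UMIProfile:
    """Per-cell-type generative parameters for the UMI matrix."""

    n_cells: int
    gene_means: Mapping[str, float]  # per-gene mean UMI per cell
    total_umi_mean: float  # mean library size; a filler gene absorbs the rest

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if any(m < 0 for m in self.gene_means.values()):
            raise ValueError("gene means must be >= 0")
        if self.total_umi_mean <= 0:
            raise ValueError("total_umi_mean must be > 0")
        if sum(self.gene_means.values()) > self.total_umi_mean:
            raise ValueError("sum of gene means exceeds total_umi_mean")


FILLER_GENE = "_other"


def generate_umi_matrix(
    profiles: Mapping[str, UMIProfile], seed: int = 0
) -> tuple["scipy.sparse.csr_matrix", list[str], pd.DataFrame]:  # noqa: F821
    """Draw a sparse genes x cells UMI matrix with cell-type-specific rates.

    Each named gene's count is Poisson(gene mean) per cell; a filler gene
    (``_other``) absorbs the remaining library so the expected total UMI per
    cell equals ``total_umi_mean``.  Returns the matrix, the gene list (named
    genes in first-seen order plus the filler), and a cell annotation table
    with columns ``cell_id`` and ``cell_type``.
    """
    import scipy.sparse

    if not profiles:
        raise ValueError("profile map must not be empty")
    for prof in profiles.values():
        prof.validate()
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for prof in profiles.values():
        for g in prof.gene_means:
            if g not in genes:
                genes.append(g)
    genes.append(FILLER_GENE)

    blocks: list[np.ndarray] = []
    ann_rows: list[dict[str, object]] = []
    cell_serial = 0
    for ctype, prof in profiles.items():
        block = np.zeros((len(genes), prof.n_cells), dtype=np.int64)
        for gi, g in enumerate(genes[:-1]):
            mean = float(prof.gene_means.get(g, 0.0))
            if mean > 0:
                block[gi] = rng.poisson(mean, size=prof.n_cells)
        filler_mean = prof.total_umi_mean - sum(prof.gene_means.values())
        if filler_mean > 0:
            block[-1] = rng.poisson(filler_mean, size=prof.n_cells)
        blocks.append(block)
        for _ in range(prof.n_cells):
            cell_serial += 1
            ann_rows.append({"cell_id": f"cell_{cell_serial:05d}", "cell_type": ctype})
    matrix = scipy.sparse.csr_matrix(
        np.concatenate(blocks, axis=1) if blocks else np.zeros((len(genes), 0))
    )
    annotations = pd.DataFrame(ann_rows, columns=["cell_id", "cell_type"])
    return matrix, genes, annotations


def save_umi_matrix(
    matrix,
    genes: list[str],
    annotations: pd.DataFrame,
    directory: str | Path,
    stem: str = "umi",
) -> None:
    """Write MatrixMarket MTX plus genes/cells TSVs."""
    import scipy.io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / f"{stem}.mtx"), matrix)
    pd.Series(genes, name="gene").to_csv(
        directory / f"{stem}_genes.tsv", sep="\t", index=False
    )
    annotations.to_csv(directory / f"{stem}_cells.tsv", sep="\t", index=False)
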
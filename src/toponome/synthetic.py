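"""Synthetic cyclic-immunofluorescence image stacks with known ground truth.

Real input to this pipeline is a stack of per-marker grayscale images of
macrophages adhered to a slide, plus which subject (and treatment group) each
image came from.  This module fabricates such stacks with every latent variable
recorded: cells are random wobbly ellipses packed without overlap, each cell is
assigned a *phenotype* — a vector of per-marker expression probabilities — drawn
from its group's phenotype mixture, and marker signal inside a cell is laid down
as granular patches (a Poisson germ-grain / Boolean model of small disks) whose
intensity is tuned so every in-cell pixel is "on" with exactly the phenotype's
marker probability.  Granules mimic the punctate, organelle-scale staining of
the real markers and give codes realistic spatial clustering.  Per-marker
integer shifts emulate stage drift between imaging cycles, and a flat additive
background plus weak Gaussian noise emulate camera floor.

A dim cell-body base signal and an unstained shared granular texture (think
cellular autofluorescence visible in every channel) are added below the
binarization threshold; they carry the cross-channel structure that image
registration needs, exactly as cell morphology does in real stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .panel import DEFAULT_PANEL, MarkerPanel

# intensity layout (16-bit range); binarization threshold sits between
# the texture ceiling and the granule floor
BACKGROUND_LEVEL = 10
CELL_BASE = 30
TEXTURE_SIGNAL = 40
MARKER_SIGNAL = 200
NOISE_SD = 2.0
DEFAULT_THRESHOLD = 150.0

GRANULE_RADIUS = 2


@dataclass(frozen=True)
class PhenotypeProfile:
    """Per-marker expression probabilities for one planted phenotype.

    ``marker_prob[i]`` is the probability that any given in-cell pixel is
    positive for marker ``i``.  ``coexpression_blocks`` lists disjoint marker
    subsets whose granules are forced to coincide (the block shares one granule
    pattern), planting marker co-occurrence within pixels.
    """

    name: str
    marker_prob: tuple[float, ...]
    coexpression_blocks: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.marker_prob, dtype=float)
        if probs.ndim != 1:
            raise ValueError("marker_prob must be a flat vector")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("marker probabilities must lie in [0, 1]")
        seen: set[int] = set()
        for block in self.coexpression_blocks:
            for m in block:
                if not 0 <= m < len(probs):
                    raise ValueError(f"block marker {m} outside panel")
                if m in seen:
                    raise ValueError("coexpression blocks must be disjoint")
                seen.add(m)

    @property
    def n_markers(self) -> int:
        return len(self.marker_prob)


@dataclass
class SceneCell:
    """One planted cell: its pixels, phenotype label and subject of origin."""

    cell_id: str
    rows: np.ndarray
    cols: np.ndarray
    phenotype: str
    subject: str

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


@dataclass
class SyntheticScene:
    """Planted geometry and design for one synthetic field of view."""

    width: int
    height: int
    cells: list[SceneCell]
    group_design: dict[str, str]
    true_shifts: np.ndarray  # (n_markers, 2) int (dy, dx); marker 0 is (0, 0)
    background_level: float
    seed: int
    panel: MarkerPanel = DEFAULT_PANEL

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = dy**2 + dx**2 <= radius**2
    return dy[keep].ravel(), dx[keep].ravel()


_DISK_DY, _DISK_DX = _disk_offsets(GRANULE_RADIUS)
DISK_AREA = len(_DISK_DY)


def _rasterize_blob(
    rng: np.random.Generator,
    center: tuple[float, float],
    radii: tuple[float, float],
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels of a randomly oriented ellipse with a wobbly radial boundary."""
    cy, cx = center
    a, b = radii
    angle = rng.uniform(0, np.pi)
    # low-order sinusoidal boundary noise keeps the outline blob-like but closed
    n_modes = 3
    amps = rng.uniform(0.0, 0.08, size=n_modes)
    phases = rng.uniform(0, 2 * np.pi, size=n_modes)
    rmax = max(a, b) * 1.35
    y0, y1 = int(np.floor(cy - rmax)), int(np.ceil(cy + rmax)) + 1
    x0, x1 = int(np.floor(cx - rmax)), int(np.ceil(cx + rmax)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / a
    v = (-sa * dx + ca * dy) / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    wobble = np.ones_like(rho)
    for k in range(n_modes):
        wobble += amps[k] * np.cos((k + 2) * theta + phases[k])
    inside = rho <= wobble
    inside &= (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
    return yy[inside].ravel(), xx[inside].ravel()


def draw_phenotypes(
    rng: np.random.Generator, mixture: dict[str, float], n: int
) -> list[str]:
    """Draw n phenotype labels from a mixture (probabilities must sum to 1)."""
    names = sorted(mixture)
    probs = np.array([mixture[k] for k in names], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("mixture probabilities must be >= 0 and sum to 1")
    return [names[i] for i in rng.choice(len(names), size=n, p=probs)]


def generate_scene(
    group_design: dict[str, str],
    phenotype_mixtures: dict[str, dict[str, float]],
    n_cells_per_subject: int = 19,
    width: int = 512,
    height: int = 512,
    seed: int = 0,
    panel: MarkerPanel = DEFAULT_PANEL,
    cell_radius: tuple[float, float] = (12.0, 20.0),
    border_margin: int = 20,
    max_shift: int = 5,
    background_level: float = BACKGROUND_LEVEL,
    max_tries: int = 500,
) -> SyntheticScene:
    """Pack non-overlapping cells for every subject into one field of view.

    Each subject contributes ``n_cells_per_subject`` cells whose phenotypes are
    drawn from that subject's group mixture.  Per-marker integer stage shifts
    are drawn uniformly in ``[-max_shift, max_shift]`` (marker 0, the alignment
    reference, gets (0, 0)).  Deterministic under ``seed``.

    Raises
    ------
    RuntimeError
        When a cell cannot be placed after ``max_tries`` rejected positions
        (field too crowded for the requested cell count).
    """
    if n_cells_per_subject < 1:
        raise ValueError("n_cells_per_subject must be >= 1")
    if width < 64 or height < 64:
        raise ValueError("scene must be at least 64x64")
    for group in set(group_design.values()):
        if group not in phenotype_mixtures:
            raise ValueError(f"no phenotype mixture for group {group!r}")
    rng = np.random.default_rng(seed)
    occupancy = np.zeros((height, width), dtype=bool)
    cells: list[SceneCell] = []
    for subject in sorted(group_design):
        mixture = phenotype_mixtures[group_design[subject]]
        phenos = draw_phenotypes(rng, mixture, n_cells_per_subject)
        for k, pheno in enumerate(phenos):
            placed = False
            for _ in range(max_tries):
                a = rng.uniform(*cell_radius)
                b = rng.uniform(*cell_radius)
                rmax = max(a, b) * 1.35
                lo = border_margin + rmax
                if lo >= height - border_margin - rmax or lo >= width - border_margin - rmax:
                    raise RuntimeError("cells too large for the field of view")
                cy = rng.uniform(lo, height - lo)
                cx = rng.uniform(lo, width - lo)
                rows, cols = _rasterize_blob(rng, (cy, cx), (a, b), (height, width))
                if rows.size == 0 or occupancy[rows, cols].any():
                    continue
                occupancy[rows, cols] = True
                cells.append(
                    SceneCell(
                        cell_id=f"{subject}_c{k:02d}",
                        rows=rows,
                        cols=cols,
                        phenotype=pheno,
                        subject=subject,
                    )
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place cell {k} for subject {subject} "
                    f"after {max_tries} tries: field too crowded"
                )
    shifts = np.zeros((len(panel), 2), dtype=int)
    if max_shift > 0:
        shifts[1:] = rng.integers(-max_shift, max_shift + 1, size=(len(panel) - 1, 2))
    return SyntheticScene(
        width=width,
        height=height,
        cells=cells,
        group_design=dict(group_design),
        true_shifts=shifts,
        background_level=background_level,
        seed=seed,
        panel=panel,
    )


def _stamp_granules(
    rng: np.random.Generator,
    cell: SceneCell,
    prob: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean coverage of a Boolean disk model over a cell.

    Granule centers form a Poisson process over the cell's granule-radius-
    dilated bounding box with intensity lambda = -ln(1 - p) / disk_area, so the
    marginal probability that any in-cell pixel is covered is exactly p.
    """
    cover = np.zeros(shape, dtype=bool)
    if prob <= 0:
        return cover
    if prob >= 1 - 1e-9:
        cover[cell.rows, cell.cols] = True
        return cover
    r = GRANULE_RADIUS
    y0, y1 = int(cell.rows.min()) - r, int(cell.rows.max()) + r
    x0, x1 = int(cell.cols.min()) - r, int(cell.cols.max()) + r
    lam = -np.log1p(-prob) / DISK_AREA
    area = (y1 - y0 + 1) * (x1 - x0 + 1)
    n_centers = rng.poisson(lam * area)
    if n_centers == 0:
        return cover
    cys = rng.integers(y0, y1 + 1, size=n_centers)
    cxs = rng.integers(x0, x1 + 1, size=n_centers)
    ys = (cys[:, None] + _DISK_DY[None, :]).ravel()
    xs = (cxs[:, None] + _DISK_DX[None, :]).ravel()
    keep = (ys >= 0) & (ys < shape[0]) & (xs >= 0) & (xs < shape[1])
    cover[ys[keep], xs[keep]] = True
    cover &= cell.mask(shape)
    return cover


def render_marker_stack(
    scene: SyntheticScene,
    profiles: dict[str, PhenotypeProfile],
    marker_signal: float = MARKER_SIGNAL,
    cell_base: float = CELL_BASE,
    texture_signal: float = TEXTURE_SIGNAL,
    noise_sd: float = NOISE_SD,
    apply_shifts: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ``scene`` into a grayscale stack and its ground-truth binary stack.

    Returns
    -------
    gray : uint16 array (n_markers, H, W)
        Unaligned images: background + shared cell texture + granular marker
        signal, offset per marker by the scene's planted shifts.
    truth : bool array (n_markers, H, W)
        Exactly which pixels are "on" per marker, in the *aligned* frame.
    """
    for cell in scene.cells:
        if cell.phenotype not in profiles:
            raise ValueError(f"no profile for phenotype {cell.phenotype!r}")
        if profiles[cell.phenotype].n_markers != len(scene.panel):
            raise ValueError("profile length does not match panel")
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0xC311]))
    n = len(scene.panel)
    shape = scene.shape
    truth = np.zeros((n, *shape), dtype=bool)
    shared = np.zeros(shape, dtype=np.float64)  # sub-threshold, all channels
    for cell in scene.cells:
        profile = profiles[cell.phenotype]
        probs = np.asarray(profile.marker_prob)
        in_block = set()
        for block in profile.coexpression_blocks:
            block = tuple(block)
            in_block.update(block)
            cover = _stamp_granules(rng, cell, float(np.mean(probs[list(block)])), shape)
            for m in block:
                truth[m] |= cover
        for m in range(n):
            if m in in_block:
                continue
            truth[m] |= _stamp_granules(rng, cell, float(probs[m]), shape)
        shared[cell.rows, cell.cols] += cell_base
        shared += texture_signal * _stamp_granules(rng, cell, 0.3, shape)

    gray = np.empty((n, *shape), dtype=np.uint16)
    for m in range(n):
        img = (
            scene.background_level
            + shared
            + marker_signal * truth[m]
            + rng.normal(0.0, noise_sd, size=shape)
        )
        img = np.clip(img, 0, 65535)
        if apply_shifts:
            from .image_prep import apply_shift

            img = apply_shift(img, tuple(scene.true_shifts[m]), fill=scene.background_level)
        gray[m] = np.round(img).astype(np.uint16)
    return gray, truth


def generate_experiment(
    group_design: dict[str, str],
    phenotype_mixtures_by_subject: dict[str, dict[str, float]],
    profiles: dict[str, PhenotypeProfile] | dict[str, dict[str, PhenotypeProfile]],
    n_cells_per_subject: int = 19,
    width: int = 512,
    height: int = 512,
    seed: int = 0,
    **scene_kwargs,
) -> dict[str, tuple[SyntheticScene, np.ndarray, np.ndarray]]:
    """One field of view per subject (the real study's design: one slide each).

    ``phenotype_mixtures_by_subject`` maps each subject to its own mixture, and
    ``profiles`` is either one shared ``{name: profile}`` map or a per-subject
    ``{subject: {name: profile}}`` map, so per-subject heterogeneity can be
    planted in the mixture weights, in the phenotype programs themselves, or
    both.  Returns ``{subject: (scene, gray_stack, truth_stack)}``; each
    subject's seed is derived deterministically from ``seed``.
    """
    per_subject = profiles and isinstance(next(iter(profiles.values())), dict)
    out = {}
    for k, subject in enumerate(sorted(group_design)):
        sub_seed = int(
            np.random.SeedSequence([seed, k]).generate_state(1, dtype=np.uint32)[0] % (2**31)
        )
        scene = generate_scene(
            group_design={subject: group_design[subject]},
            phenotype_mixtures={
                group_design[subject]: phenotype_mixtures_by_subject[subject]
            },
            n_cells_per_subject=n_cells_per_subject,
            width=width,
            height=height,
            seed=sub_seed,
            **scene_kwargs,
        )
        subject_profiles = profiles[subject] if per_subject else profiles
        gray, truth = render_marker_stack(scene, subject_profiles)
        out[subject] = (scene, gray, truth)
    return out


# ---------------------------------------------------------------------------
# default planted experiment: 2 groups x 3 subjects x 19 cells, emulating the
# vehicle (KO) vs SP-A1-treated contrast the pipeline is built to detect
# ---------------------------------------------------------------------------

def default_profiles(n_markers: int = 13) -> dict[str, PhenotypeProfile]:
    """Four planted phenotypes with well-separated marker usage.

    Probabilities are free parameters (no quantitative co-expression rates
    exist for the real cells); values were chosen once to give each phenotype
    a distinct hi/lo pattern over the panel with every marker detectable.
    """
    base = np.full(n_markers, 0.15)

    def profile(name, hi, blocks=()):
        p = base.copy()
        p[list(hi)] = 0.75
        return PhenotypeProfile(name, tuple(p), tuple(tuple(b) for b in blocks))

    return {
        # hi-marker sets overlap partially, like real activation programs
        "A": profile("A", [3, 5, 7, 12], blocks=[(5, 7)]),
        "B": profile("B", [1, 3, 8, 12]),
        "C": profile("C", [2, 6, 9, 10], blocks=[(6, 9)]),
        "D": profile("D", [2, 4, 10, 11]),
    }


def jitter_profile(
    profile: PhenotypeProfile, rng: np.random.Generator, sd: float
) -> PhenotypeProfile:
    """Perturb a phenotype's marker probabilities with clipped Gaussian noise.

    Models subject-level drift of an expression program: the phenotype keeps
    its name but each marker probability moves by N(0, sd), clipped to
    [0.02, 0.95] so every marker stays detectable and non-saturated.
    """
    probs = np.clip(
        np.asarray(profile.marker_prob) + rng.normal(0.0, sd, size=profile.n_markers),
        0.02,
        0.95,
    )
    return PhenotypeProfile(profile.name, tuple(probs), profile.coexpression_blocks)


def default_experiment_design(
    jitter: float = 0.25,
    seed: int = 0,
    n_markers: int = 13,
) -> tuple[
    dict[str, str],
    dict[str, dict[str, float]],
    dict[str, dict[str, PhenotypeProfile]],
]:
    """Study-shaped design: 3 KO + 3 SP-A1 subjects, planted group difference.

    KO subjects share one homogeneous mixture (phenotypes A/B) and the exact
    same phenotype programs, making their abundant codes consistent across
    subjects.  SP-A1 subjects get per-subject mixtures over C/D (and some A)
    *and* per-subject jittered phenotype programs (marker probabilities
    perturbed with sd = ``jitter``): between-subject heterogeneity in which
    codes are abundant, not merely in their proportions — mixture weights alone
    leave the identity of the frequent codes nearly unchanged.  These are the
    two planted effects the group-comparison and gating stages must recover:
    a distinct SP-A1 marker program, and lower SP-A1 code conservation.

    Returns ``(group_design, mixtures_by_subject, profiles_by_subject)``.
    """
    group_design = {
        "ko1": "KO", "ko2": "KO", "ko3": "KO",
        "sp1": "SPA1", "sp2": "SPA1", "sp3": "SPA1",
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD151]))
    base = default_profiles(n_markers)
    mixtures: dict[str, dict[str, float]] = {}
    profiles_by_subject: dict[str, dict[str, PhenotypeProfile]] = {}
    for subject in ("ko1", "ko2", "ko3"):
        mixtures[subject] = {"A": 0.6, "B": 0.4}
        profiles_by_subject[subject] = base
    for subject in ("sp1", "sp2", "sp3"):
        w = rng.dirichlet(np.ones(3) * (1.0 / max(jitter, 1e-6)))
        mixtures[subject] = {"C": float(w[0]), "D": float(w[1]), "A": float(w[2])}
        profiles_by_subject[subject] = {
            name: jitter_profile(p, rng, jitter) for name, p in base.items()
        }
    return group_design, mixtures, profiles_by_subject


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------

def _rle_encode(rows: np.ndarray, cols: np.ndarray, width: int) -> list[int]:
    """Run-length encode a pixel set as [start, length, ...] over flat indices."""
    flat = np.sort(rows.astype(np.int64) * width + cols.astype(np.int64))
    runs: list[int] = []
    start = prev = int(flat[0])
    for v in flat[1:]:
        v = int(v)
        if v == prev + 1:
            prev = v
            continue
        runs.extend([start, prev - start + 1])
        start = prev = v
    runs.extend([start, prev - start + 1])
    return runs


def _rle_decode(runs: list[int], width: int) -> tuple[np.ndarray, np.ndarray]:
    flat = np.concatenate(
        [np.arange(runs[i], runs[i] + runs[i + 1]) for i in range(0, len(runs), 2)]
    )
    return (flat // width).astype(int), (flat % width).astype(int)


def write_scene(
    scene: SyntheticScene,
    gray: np.ndarray,
    truth: np.ndarray,
    out_dir: str | Path,
    sample_id: str = "sample",
) -> None:
    """Write a rendered scene the way a real acquisition would arrive on disk.

    Per-marker grayscale 16-bit TIFFs (``<sample>_m<idx>.tif``), ground-truth
    binary masks as 8-bit PNGs, scene geometry as JSON (cells run-length
    encoded), and the subject->group design as YAML.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for m in range(gray.shape[0]):
        tifffile.imwrite(out_dir / f"{sample_id}_m{m:02d}.tif", gray[m])
        Image.fromarray((truth[m].astype(np.uint8)) * 255, mode="L").save(
            out_dir / f"{sample_id}_m{m:02d}_truth.png"
        )
    meta = {
        "sample_id": sample_id,
        "width": scene.width,
        "height": scene.height,
        "seed": scene.seed,
        "background_level": scene.background_level,
        "true_shifts": scene.true_shifts.tolist(),
        "panel": list(scene.panel.names),
        "cells": [
            {
                "cell_id": c.cell_id,
                "subject": c.subject,
                "phenotype": c.phenotype,
                "rle": _rle_encode(c.rows, c.cols, scene.width),
            }
            for c in scene.cells
        ],
    }
    (out_dir / f"{sample_id}_scene.json").write_text(json.dumps(meta))
    with (out_dir / f"{sample_id}_groups.yaml").open("w") as fh:
        yaml.safe_dump({"group_design": scene.group_design}, fh)


def read_scene(out_dir: str | Path, sample_id: str = "sample") -> SyntheticScene:
    """Rebuild a :class:`SyntheticScene` from :func:`write_scene` output."""
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{sample_id}_scene.json").read_text())
    with (out_dir / f"{sample_id}_groups.yaml").open() as fh:
        design = yaml.safe_load(fh)["group_design"]
    cells = []
    for c in meta["cells"]:
        rows, cols = _rle_decode(c["rle"], meta["width"])
        cells.append(SceneCell(c["cell_id"], rows, cols, c["phenotype"], c["subject"]))
    return SyntheticScene(
        width=meta["width"],
        height=meta["height"],
        cells=cells,
        group_design=design,
        true_shifts=np.asarray(meta["true_shifts"], dtype=int),
        background_level=meta["background_level"],
        seed=meta["seed"],
        panel=MarkerPanel(tuple(meta["panel"])),
    )


def read_stack(out_dir: str | Path, sample_id: str, n_markers: int) -> np.ndarray:
    """Load the per-marker grayscale TIFFs back into an (n, H, W) stack."""
    out_dir = Path(out_dir)
    return np.stack(
        [tifffile.imread(out_dir / f"{sample_id}_m{m:02d}.tif") for m in range(n_markers)]
    )
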
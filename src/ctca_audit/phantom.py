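"""Synthetic contrast-enhanced coronary CT (CTCA) phantoms.

Each phantom is a 3D HU volume containing a six-branch coronary tree
(LM, LAD, LCx, D1, OM1, RCA) rasterised around analytic curves, with
ground-truth tree/branch masks, the analytic centreline, a surrogate
calcium score, and per-case metadata.  The generator controls the
quality factors the audit studies:

* lumen enhancement vs background tissue HU (contrast);
* isotropic Gaussian boundary blur (partial-volume softness);
* independent white noise of stated SD;
* calcified lesions: bright spheres at the lumen wall whose HU bleeds
  into lumen and tissue after blurring — a blooming artefact.

Segmentations of controllable quality come from a connected-component
HU-window pseudo-segmenter (a deliberate stand-in for trained networks:
its accuracy naturally degrades with lower contrast, higher noise,
stronger blur and near-lesion blooming, and the evaluation interface
accepts real model outputs unchanged) or from `degrade_segmentation`,
which injects controlled boundary jitter and branch dropout.

The surrogate calcium score weights each inserted lesion's analytic
volume (mm^3) by the Agatston density factor of its peak HU
(1/2/3/4 for 130-199 / 200-299 / 300-399 / >=400); it is a surrogate
computed from the known lesions, not an image-based Agatston score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import Centreline
from .io import BRANCH_CODES, CaseMeta, CTVolume, Mask

#: minimum HU a calcified lesion may peak at (Agatston detection floor)
MIN_LESION_HU = 130.0


@dataclass
class BranchCurve:
    """Analytic branch axis: a line, planar arc or helix, with a linearly
    tapering radius profile (mm), parametrised by t in [0, 1]."""

    kind: str                     # "line" | "arc" | "helix"
    r_start: float
    r_end: float
    # line: p0 -> p1
    p0: np.ndarray | None = None
    p1: np.ndarray | None = None
    # arc/helix: centre + orthonormal in-plane axes u, v; angles in radians
    centre: np.ndarray | None = None
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    arc_radius: float = 0.0
    angle0: float = 0.0
    angle1: float = 0.0
    pitch: float = 0.0            # helix: world-mm advance along u x v over the full sweep

    def point(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.kind == "line":
            return np.outer(1 - t, self.p0) + np.outer(t, self.p1)
        ang = self.angle0 + t * (self.angle1 - self.angle0)
        pts = (self.centre
               + self.arc_radius * (np.outer(np.cos(ang), self.u) + np.outer(np.sin(ang), self.v)))
        if self.kind == "helix":
            axis = np.cross(self.u, self.v)
            pts = pts + np.outer(t * self.pitch, axis)
        return pts

    def radius(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self.r_start + t * (self.r_end - self.r_start)

    def length(self) -> float:
        t = np.linspace(0, 1, 512)
        return float(np.linalg.norm(np.diff(self.point(t), axis=0), axis=1).sum())

    def scaled(self, radius_scale: float) -> "BranchCurve":
        return replace(self, r_start=self.r_start * radius_scale, r_end=self.r_end * radius_scale)


@dataclass
class Lesion:
    """Calcified lesion: a sphere at the lumen wall of `branch` at arc
    position t, with radius (mm) and peak attenuation (HU >= 130)."""

    branch: str
    t: float
    radius: float
    peak_hu: float

    def __post_init__(self) -> None:
        if self.peak_hu < MIN_LESION_HU:
            raise ValueError(f"lesion peak HU must be >= {MIN_LESION_HU}")
        if not 0 <= self.t <= 1:
            raise ValueError("lesion arc position t must be in [0, 1]")

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def density_weight(self) -> int:
        if self.peak_hu < 200:
            return 1
        if self.peak_hu < 300:
            return 2
        if self.peak_hu < 400:
            return 3
        return 4


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    branch_curves: dict[str, BranchCurve] = field(default_factory=lambda: default_tree())
    lumen_hu: float = 400.0
    tissue_hu: float = 50.0
    fat_hu: float | None = -80.0
    fat_margin_mm: float = 8.0    # tissue beyond this distance from the tree becomes fat
    blur_sigma: float = 0.0       # voxels
    noise_sd: float = 0.0         # HU
    lesions: list[Lesion] = field(default_factory=list)
    seed: int = 0
    case_id: str = "phantom"
    sex: str = "male"
    cohort: str = "synthetic"

    def __post_init__(self) -> None:
        if self.lumen_hu <= self.tissue_hu:
            raise ValueError("lumen_hu must exceed tissue_hu")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in self.branch_curves.values():
            if c.r_start <= 0 or c.r_end <= 0:
                raise ValueError("branch radii must be positive")


@dataclass
class PhantomCase:
    volume: CTVolume
    tree_mask: Mask
    labelled_mask: Mask
    centreline: Centreline
    calcium_score: float
    meta: CaseMeta


def default_tree(radius_scale: float = 1.0, rng: np.random.Generator | None = None,
                 shape_jitter: float = 0.0) -> dict[str, BranchCurve]:
    """A stylised six-branch coronary tree inside a 48 mm cube (world mm).

    The left system (LM bifurcating into LAD and LCx, with D1 off the LAD
    and OM1 off the LCx) descends from the top of the volume; the RCA
    sweeps down separately as a helix (the two coronary ostia are separate
    structures).  Radii taper distally; `radius_scale` shrinks the whole
    tree's calibre (used to emulate the smaller artery diameters of female
    cases), and `shape_jitter` perturbs arc radii and line endpoints by up
    to the stated relative amount so curvature varies across cases.
    """
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez_dn = np.array([0.0, 0.0, -1.0])
    deg = math.pi / 180.0

    def jit() -> float:
        if rng is None or shape_jitter == 0.0:
            return 1.0
        return float(rng.uniform(1 - shape_jitter, 1 + shape_jitter))

    # arcs keep their proximal point at the LM tip (24, 24, 36)
    r_lad, r_lcx = 12.0 * jit(), 12.0 * jit()
    lad = BranchCurve("arc", 1.7, 1.2, centre=np.array([24.0 - r_lad, 24.0, 36.0]),
                      u=ex, v=ez_dn, arc_radius=r_lad, angle0=0.0, angle1=80 * deg)
    lcx = BranchCurve("arc", 1.5, 1.1, centre=np.array([24.0, 24.0 - r_lcx, 36.0]),
                      u=ey, v=ez_dn, arc_radius=r_lcx, angle0=0.0, angle1=70 * deg)
    d1_origin = lad.point(0.5)[0]    # 40 deg along the LAD
    om1_origin = lcx.point(0.5)[0]   # 35 deg along the LCx
    d1_end = d1_origin + jit() * (np.array([32.0, 30.0, 20.0]) - d1_origin)
    om1_end = om1_origin + jit() * (np.array([16.0, 34.0, 18.0]) - om1_origin)
    tree = {
        "LM": BranchCurve("line", 2.0, 1.9,
                          p0=np.array([24.0, 24.0, 42.0]), p1=np.array([24.0, 24.0, 36.0])),
        "LAD": lad,
        "LCx": lcx,
        "D1": BranchCurve("line", 1.2, 0.9, p0=d1_origin, p1=d1_end),
        "OM1": BranchCurve("line", 1.1, 0.85, p0=om1_origin, p1=om1_end),
        "RCA": BranchCurve("helix", 1.8, 1.3, centre=np.array([34.0, 14.0, 40.0]),
                           u=ex, v=ey, arc_radius=6.0 * jit(), angle0=0.0, angle1=200 * deg,
                           pitch=-22.0 * jit()),
    }
    return {name: c.scaled(radius_scale) for name, c in tree.items()}


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = spacing
    return a


def _rasterise_tree(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Voxel is inside a branch iff its world distance to the branch axis is
    <= the local radius; overlap labels resolve to the nearest axis (the
    same rule per-branch Dice uses to attribute predicted voxels)."""
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing)
    extent = (np.asarray(shape) - 1) * spacing
    step = min(spec.spacing) / 2.0

    labels = np.zeros(shape, dtype=np.uint8)
    best = np.full(shape, np.inf)
    tree = np.zeros(shape, dtype=bool)
    rmax_all = max(max(c.r_start, c.r_end) for c in spec.branch_curves.values())
    pad = rmax_all + float(spacing.max())
    for name, curve in spec.branch_curves.items():
        n = max(int(np.ceil(curve.length() / step)) + 1, 8)
        t = np.linspace(0, 1, n)
        pts = curve.point(t)
        rad = curve.radius(t)
        if (pts - rad[:, None] < -1e-9).any() or (pts + rad[:, None] > extent + 1e-9).any():
            raise ValueError(f"branch {name} exits the volume")

        # the bbox pad covers every voxel this branch could be nearest to
        lo = np.maximum(np.floor((pts.min(axis=0) - pad) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((pts.max(axis=0) + pad) / spacing).astype(int) + 1, shape)
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        vox = np.stack([g.ravel() for g in grids], axis=1)
        world = vox * spacing
        dist, nearest = cKDTree(pts).query(world, workers=-1)
        inside = rad[nearest] - dist >= 0
        if not inside.any():
            raise ValueError(f"branch {name} rasterised to zero voxels")
        tree[tuple(vox[inside].T)] = True
        sel = tuple(vox.T)
        better = dist < best[sel]
        sel_b = tuple(v[better] for v in sel)
        labels[sel_b] = BRANCH_CODES[name]
        best[sel_b] = dist[better]

    labels[~tree] = 0
    for name in spec.branch_curves:
        if not (labels == BRANCH_CODES[name]).any():
            raise ValueError(f"branch {name} fully overlapped by other branches")
    return labels, best


def analytic_centreline(spec: PhantomSpec, step_mm: float | None = None) -> Centreline:
    """The generator's ground-truth centreline (world mm) with radii.

    The default sampling step matches the rasteriser's (half the smallest
    voxel dimension) so nearest-centreline-point attribution agrees with
    the labelled mask."""
    step = step_mm if step_mm is not None else min(spec.spacing) / 2.0
    branches, radius = {}, {}
    for name, curve in spec.branch_curves.items():
        n = max(int(np.ceil(curve.length() / step)) + 1, 5)
        t = np.linspace(0, 1, n)
        branches[name] = curve.point(t)
        radius[name] = curve.radius(t)
    return Centreline(branches, radius)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterise the tree, paint HU levels and lesions, blur, add noise.

    Deterministic given (spec, seed).  Lesion spheres are centred on the
    lumen wall (offset from the axis by the local radius), so after
    blurring their bright HU bleeds into both lumen and tissue — the
    blooming artefact.
    """
    labels, _ = _rasterise_tree(spec)
    tree = labels > 0
    affine = _affine(spec.spacing)
    spacing = np.asarray(spec.spacing)

    values = np.full(spec.shape, spec.tissue_hu, dtype=np.float64)
    if spec.fat_hu is not None:
        dist_to_tree = ndimage.distance_transform_edt(~tree, sampling=spec.spacing)
        values[dist_to_tree > spec.fat_margin_mm] = spec.fat_hu
    values[tree] = spec.lumen_hu

    for les in spec.lesions:
        curve = spec.branch_curves[les.branch]
        centre_axis = curve.point(les.t)[0]
        r_local = float(curve.radius(les.t)[0])
        tang = (curve.point(min(les.t + 0.01, 1.0))[0] - curve.point(max(les.t - 0.01, 0.0))[0])
        tang = tang / (np.linalg.norm(tang) + 1e-12)
        ref = np.array([0.0, 0.0, 1.0]) if abs(tang[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        normal = np.cross(tang, ref)
        normal /= np.linalg.norm(normal)
        centre = centre_axis + normal * r_local
        lo = np.maximum(np.floor((centre - les.radius) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((centre + les.radius) / spacing).astype(int) + 1, spec.shape)
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        vox = np.stack([g.ravel() for g in grids], axis=1)
        d = np.linalg.norm(vox * spacing - centre, axis=1)
        sel = tuple(vox[d <= les.radius].T)
        values[sel] = les.peak_hu

    if spec.blur_sigma > 0:
        values = ndimage.gaussian_filter(values, sigma=spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    calcium = sum(l.volume_mm3 * l.density_weight for l in spec.lesions)
    meta = CaseMeta(spec.case_id, spec.sex, float(calcium), spec.cohort)
    return PhantomCase(
        volume=CTVolume(values.astype(np.float32), spec.spacing, affine, spec.case_id),
        tree_mask=Mask(tree.astype(np.uint8), spec.spacing, affine, "binary", spec.case_id),
        labelled_mask=Mask(labels, spec.spacing, affine, "labelled", spec.case_id),
        centreline=analytic_centreline(spec),
        calcium_score=float(calcium),
        meta=meta,
    )


def threshold_segment(volume: CTVolume, seed_point: tuple[int, int, int],
                      hu_low: float, hu_high: float) -> Mask:
    """Connected component of the HU window [hu_low, hu_high] containing the
    seed voxel — the pseudo-segmenter used for synthetic cohorts."""
    seed_point = tuple(int(i) for i in seed_point)
    v = volume.values
    if not (hu_low <= v[seed_point] <= hu_high):
        raise ValueError(f"seed voxel HU {v[seed_point]:.1f} outside window [{hu_low}, {hu_high}]")
    window = (v >= hu_low) & (v <= hu_high)
    labels, _ = ndimage.label(window, structure=np.ones((3, 3, 3), bool))
    comp = labels == labels[seed_point]
    return Mask(comp.astype(np.uint8), volume.spacing, volume.affine, "binary", volume.id)


def degrade_segmentation(ref: Mask, boundary_jitter_voxels: int = 0,
                         dropout_branches: list[str] | None = None,
                         seed: int = 0, labels: Mask | None = None,
                         block: int = 24) -> Mask:
    """Controlled-error segmentation: blockwise random erosion/dilation up
    to the stated jitter, plus deletion of whole branches.

    Branch dropout needs the branch identity, so `labels` (a labelled mask
    aligned with `ref`) is required when `dropout_branches` is non-empty.
    """
    if boundary_jitter_voxels < 0:
        raise ValueError("jitter must be >= 0")
    fg = ref.foreground().copy()
    dropout_branches = dropout_branches or []
    if dropout_branches:
        if labels is None:
            raise ValueError("dropout_branches requires the labelled mask")
        for name in dropout_branches:
            fg &= labels.labels != BRANCH_CODES[name]

    j = boundary_jitter_voxels
    if j > 0:
        rng = np.random.default_rng(seed)
        out = np.zeros_like(fg)
        struct = ndimage.generate_binary_structure(3, 1)
        shape = fg.shape
        for i0 in range(0, shape[0], block):
            for j0 in range(0, shape[1], block):
                for k0 in range(0, shape[2], block):
                    k = int(rng.integers(-j, j + 1))
                    core = (slice(i0, min(i0 + block, shape[0])),
                            slice(j0, min(j0 + block, shape[1])),
                            slice(k0, min(k0 + block, shape[2])))
                    pad = (slice(max(i0 - j, 0), min(i0 + block + j, shape[0])),
                           slice(max(j0 - j, 0), min(j0 + block + j, shape[1])),
                           slice(max(k0 - j, 0), min(k0 + block + j, shape[2])))
                    sub = fg[pad]
                    if k > 0:
                        sub = ndimage.binary_dilation(sub, struct, iterations=k)
                    elif k < 0:
                        sub = ndimage.binary_erosion(sub, struct, iterations=-k)
                    off = tuple(c.start - p.start for c, p in zip(core, pad))
                    out[core] = sub[tuple(slice(o, o + (c.stop - c.start)) for o, c in zip(off, core))]
        fg = out
    return Mask(fg.astype(np.uint8), ref.spacing, ref.affine, "binary", ref.id)


# ---------------------------------------------------------------------------
# cohort generation

DEFAULT_FACTOR_RANGES: dict = {
    "lumen_hu": (250.0, 500.0),
    "noise_sd": (5.0, 25.0),
    "blur_sigma": (0.4, 1.2),
    "n_lesions": (0, 3),             # inclusive integer range
    "lesion_radius": (0.8, 2.0),     # mm
    "lesion_peak_hu": (150.0, 900.0),
    "radius_scale_male": (0.95, 1.15),
    "radius_scale_female": (0.75, 0.95),
    "shape_jitter": (0.12, 0.12),    # relative jitter of arc radii / line ends
}

#: HU window of the pseudo-segmenter; three members with jittered lower
#: thresholds emulate a small model committee for ensembling
SEGMENTER_WINDOWS = ((190.0, 3000.0), (200.0, 3000.0), (210.0, 3000.0))


@dataclass
class CohortCase:
    case: PhantomCase
    predictions: list[Mask]

    @property
    def prediction(self) -> Mask:
        from .evaluation import majority_vote

        if len(self.predictions) == 1:
            return self.predictions[0]
        return majority_vote(self.predictions)


def sample_spec(rng: np.random.Generator, case_id: str, sex: str,
                factor_ranges: dict | None = None,
                shape: tuple[int, int, int] = (96, 96, 96),
                spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
                cohort: str = "synthetic") -> PhantomSpec:
    """Draw one case's generating parameters from the factor ranges."""
    fr = dict(DEFAULT_FACTOR_RANGES)
    fr.update(factor_ranges or {})
    for key, rng_pair in fr.items():
        if np.ndim(rng_pair) == 0 or len(rng_pair) != 2:
            raise ValueError(f"factor range {key} must be a (lo, hi) pair")
    scale_key = f"radius_scale_{sex}"
    scale = float(rng.uniform(*fr[scale_key]))
    n_les_lo, n_les_hi = fr["n_lesions"]
    n_lesions = int(rng.integers(n_les_lo, n_les_hi + 1))
    lesions = []
    for _ in range(n_lesions):
        lesions.append(Lesion(
            branch=str(rng.choice(["LAD", "LCx", "RCA"])),
            t=float(rng.uniform(0.2, 0.8)),
            radius=float(rng.uniform(*fr["lesion_radius"])),
            peak_hu=float(rng.uniform(*fr["lesion_peak_hu"])),
        ))
    return PhantomSpec(
        shape=shape, spacing=spacing,
        branch_curves=default_tree(radius_scale=scale, rng=rng,
                                   shape_jitter=float(fr["shape_jitter"][1])),
        lumen_hu=float(rng.uniform(*fr["lumen_hu"])),
        tissue_hu=50.0,
        blur_sigma=float(rng.uniform(*fr["blur_sigma"])),
        noise_sd=float(rng.uniform(*fr["noise_sd"])),
        lesions=lesions,
        seed=int(rng.integers(0, 2**31 - 1)),
        case_id=case_id, sex=sex, cohort=cohort,
    )


def pseudo_segment(case: PhantomCase,
                   windows: tuple = SEGMENTER_WINDOWS) -> list[Mask]:
    """Run the HU-window pseudo-segmenter once per window, seeded at the
    proximal LM and RCA centreline points (the left tree and the RCA are
    separate connected structures, as the two coronary ostia are).  Each
    seed is shifted to the brightest voxel of its 5^3 neighbourhood so
    image noise cannot unseat it; the per-window prediction is the union
    of the seeded components."""
    seeds = []
    for root in ("LM", "RCA"):
        if root not in case.centreline.branches:
            continue
        seed_world = case.centreline.branches[root][0]
        seed_vox = np.rint(case.volume.world_to_voxel(seed_world)[0]).astype(int)
        lo = np.maximum(seed_vox - 2, 0)
        hi = np.minimum(seed_vox + 3, case.volume.shape)
        nb = case.volume.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        seeds.append(tuple(lo + np.array(np.unravel_index(np.argmax(nb), nb.shape))))
    vol = case.volume
    preds = []
    for w_lo, w_hi in windows:
        union = np.zeros(vol.shape, dtype=np.uint8)
        for s in seeds:
            try:
                comp = threshold_segment(vol, s, w_lo, w_hi)
            except ValueError:
                continue  # contrast too poor for this window: nothing found
            union |= comp.labels.astype(np.uint8)
        preds.append(Mask(union, vol.spacing, vol.affine, "binary", vol.id))
    return preds


def generate_cohort(n: int, factor_ranges: dict | None = None,
                    sex_ratio: float = 0.5, seed: int = 0,
                    shape: tuple[int, int, int] = (96, 96, 96),
                    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
                    cohort: str = "synthetic") -> list[CohortCase]:
    """Generate `n` phantoms spanning the factor ranges, each with a
    committee of pseudo-segmentations.  Both sexes are always represented
    (female branch radii are drawn from a smaller range)."""
    if n < 6:
        raise ValueError("generate_cohort needs n >= 6")
    rng = np.random.default_rng(seed)
    sexes = ["male" if rng.random() < sex_ratio else "female" for _ in range(n)]
    if len(set(sexes)) == 1:  # force both sexes present
        sexes[0] = "female" if sexes[0] == "male" else "male"
    out = []
    for i, sex in enumerate(sexes):
        spec = sample_spec(rng, f"case{i:03d}", sex, factor_ranges, shape, spacing, cohort)
        case = generate_phantom(spec)
        out.append(CohortCase(case=case, predictions=pseudo_segment(case)))
    return out


def write_cohort(cases: list[CohortCase], out_dir) -> None:
    """Write each case's volume, masks and predictions as NIfTI plus meta.csv."""
    from pathlib import Path

    from .io import write_mask, write_meta, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metas = []
    for cc in cases:
        cid = cc.case.meta.id
        write_volume(cc.case.volume, out / f"{cid}_image.nii.gz")
        write_mask(cc.case.tree_mask, out / f"{cid}_ref.nii.gz")
        write_mask(cc.case.labelled_mask, out / f"{cid}_ref_labels.nii.gz")
        for k, pred in enumerate(cc.predictions):
            write_mask(pred, out / f"{cid}_pred{k}.nii.gz")
        metas.append(cc.case.meta)
    write_meta(metas, out / "meta.csv")
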
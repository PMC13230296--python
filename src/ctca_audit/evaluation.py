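"""Dice evaluation and segmentation ensembling.

Tree-level accuracy is the Dice similarity coefficient (DSC) between the
predicted and reference coronary-tree masks.  Per-branch DSC maps every
predicted foreground voxel to the branch of its nearest reference
centreline point (in world mm) and scores each branch against the
reference branch labels — a voxel-space equivalent of splitting the tree
on a surface mesh and mapping the split back into the image domain.

Ensembling follows the two conventions used for cross-validation folds and
model committees: soft averaging of probability maps thresholded at 0.5
(inclusive), and majority voting over binary masks with ties broken to
background (a 3-member committee cannot tie; the rule matters only for
even ensembles and is deliberately conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import BRANCH_NAMES, Mask, check_aligned


@dataclass
class DiceResult:
    tree_dsc: float
    branch_dsc: dict[str, float] = field(default_factory=dict)


def dice(a: Mask, b: Mask) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 if both masks are empty (agreement convention)."""
    if a.kind != "binary" or b.kind != "binary":
        raise ValueError("dice requires binary masks")
    check_aligned(a, b)
    fa, fb = a.foreground(), b.foreground()
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((fa & fb).sum()) / denom


def majority_vote(masks: list[Mask]) -> Mask:
    """Voxelwise strict-majority vote; exact ties go to background."""
    if len(masks) < 2:
        raise ValueError("majority_vote needs at least 2 masks")
    for m in masks:
        if m.kind != "binary":
            raise ValueError("majority_vote requires binary masks")
        check_aligned(masks[0], m)
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += m.foreground()
    out = (votes * 2 > len(masks)).astype(np.uint8)
    return Mask(out, masks[0].spacing, masks[0].affine, "binary", masks[0].id)


def soft_ensemble(probs: list[Mask], threshold: float = 0.5) -> Mask:
    """Threshold the voxelwise mean probability (inclusive at the boundary)."""
    if len(probs) < 2:
        raise ValueError("soft_ensemble needs at least 2 probability maps")
    for p in probs:
        if p.kind != "probability":
            raise ValueError("soft_ensemble requires probability masks")
        check_aligned(probs[0], p)
    mean = np.mean([p.labels.astype(np.float64) for p in probs], axis=0)
    out = (mean >= threshold).astype(np.uint8)
    return Mask(out, probs[0].spacing, probs[0].affine, "binary", probs[0].id)


def per_branch_dice(pred: Mask, ref_labelled: Mask, ref_centreline) -> dict[str, float]:
    """Branch-wise DSC via nearest-centreline-point attribution.

    Each predicted foreground voxel is assigned the branch code of the
    nearest reference centreline point (world mm, over all branches); DSC
    is then computed per branch between the assigned prediction voxels and
    the reference branch-label voxels.  Branches absent from the reference
    labels are omitted.
    """
    check_aligned(pred, ref_labelled)
    ref_codes = sorted(int(c) for c in np.unique(ref_labelled.labels) if c > 0)
    if not ref_codes:
        raise ValueError("reference mask has no branch labels")

    pts, codes = [], []
    for name, branch_pts in ref_centreline.branches.items():
        code = _branch_code(name)
        if code not in ref_codes:
            raise ValueError(f"centreline branch {name} absent from reference labels")
        pts.append(np.asarray(branch_pts, dtype=float))
        codes.append(np.full(len(branch_pts), code, dtype=np.int32))
    missing = set(ref_codes) - {int(c[0]) for c in codes}
    if missing:
        raise ValueError(f"reference labels without centreline branch: {sorted(missing)}")
    all_pts = np.vstack(pts)
    code_of_point = np.concatenate(codes)
    # junction points shared by two branches: keep the first occurrence so
    # tie-breaks are deterministic (branch listed first wins)
    _, first = np.unique(all_pts, axis=0, return_index=True)
    keep = np.sort(first)
    tree = cKDTree(all_pts[keep])
    code_of_point = code_of_point[keep]

    pred_idx = np.argwhere(pred.foreground())
    if len(pred_idx):
        world = pred.voxel_to_world(pred_idx)
        _, nearest = tree.query(world, workers=-1)
        pred_codes = code_of_point[nearest]
    else:
        pred_codes = np.empty(0, dtype=np.int32)

    out: dict[str, float] = {}
    for code in ref_codes:
        ref_n = int((ref_labelled.labels == code).sum())
        if ref_n == 0:
            raise ValueError(f"empty reference branch {BRANCH_NAMES.get(code, code)}")
        pred_sel = pred_idx[pred_codes == code] if len(pred_idx) else pred_idx
        inter = int((ref_labelled.labels[tuple(pred_sel.T)] == code).sum()) if len(pred_sel) else 0
        out[BRANCH_NAMES.get(code, str(code))] = 2.0 * inter / (ref_n + len(pred_sel)) if (ref_n + len(pred_sel)) else 1.0
    return out


def _branch_code(name) -> int:
    from .io import BRANCH_CODES

    if isinstance(name, str):
        return BRANCH_CODES[name]
    return int(name)
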
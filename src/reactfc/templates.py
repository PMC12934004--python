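"""Molecular density templates and the two-stage analysis masks.

A :class:`TemplateMap` carries a transporter density volume (DAT, NET, SERT
or a synthetic label) together with its valid-voxel domain and the mask of
the reference region used when the template was constructed (occipital
cortex for DAT/NET, cerebellar grey for SERT). Before a template can act as
a spatial regressor its reference region is removed from the domain and the
remaining values are min-max rescaled to [0, 1].

The spatial regression (stage 1) runs on the intersection of all template
domains, a grey-matter mask and every session's fMRI coverage; the temporal
regression (stage 2) runs on all covered in-brain voxels, with the
reference-region voxels re-included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .io import check_same_grid, mask_array

logger = logging.getLogger(__name__)


@dataclass
class TemplateMap:
    """A molecular density volume with its valid domain and reference mask."""

    name: str
    img: nib.Nifti1Image
    domain: np.ndarray  # boolean, valid voxels
    reference_mask: np.ndarray = field(default=None)  # boolean
    rescaled: bool = False

    def __post_init__(self):
        data = np.asanyarray(self.img.dataobj)
        if data.ndim != 3:
            raise ValueError("a template must be a 3D volume")
        self.domain = np.asarray(self.domain, dtype=bool)
        if self.domain.shape != data.shape:
            raise ValueError("domain mask shape does not match the template volume")
        if self.reference_mask is None:
            logger.warning("template %r has no reference mask; treating it as empty", self.name)
            self.reference_mask = np.zeros(data.shape, dtype=bool)
        self.reference_mask = np.asarray(self.reference_mask, dtype=bool)
        if not np.all(np.isfinite(data[self.domain])):
            raise ValueError(f"template {self.name!r} has non-finite values in its domain")

    @property
    def values(self) -> np.ndarray:
        return np.asanyarray(self.img.dataobj)

    @property
    def affine(self) -> np.ndarray:
        return self.img.affine


def template_from_img(
    name: str,
    img: nib.Nifti1Image,
    reference_mask: nib.Nifti1Image | np.ndarray | None = None,
    domain: np.ndarray | None = None,
) -> TemplateMap:
    """Build a TemplateMap; by default the domain is the nonzero finite support."""
    data = np.asanyarray(img.dataobj)
    if domain is None:
        domain = np.isfinite(data) & (data != 0)
    if isinstance(reference_mask, nib.Nifti1Image):
        check_same_grid(img, reference_mask, f"template {name!r} and its reference mask")
        reference_mask = mask_array(reference_mask)
    return TemplateMap(name=name, img=img, domain=domain, reference_mask=reference_mask)


def mask_reference_region(t: TemplateMap) -> TemplateMap:
    """Remove the template's reference-region voxels from its valid domain."""
    new_domain = t.domain & ~t.reference_mask
    if not new_domain.any():
        raise ValueError(
            f"reference mask of template {t.name!r} covers its entire domain"
        )
    return replace(t, domain=new_domain)


def rescale_unit(t: TemplateMap) -> TemplateMap:
    """Min-max rescale the in-domain values to [0, 1] (min -> 0, max -> 1)."""
    data = t.values.astype(float)
    vals = data[t.domain]
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 0:
        raise ValueError(f"template {t.name!r} is constant over its domain; cannot rescale")
    out = np.zeros_like(data)
    out[t.domain] = (vals - lo) / (hi - lo)
    img = nib.Nifti1Image(out, t.img.affine, t.img.header)
    return replace(t, img=img, rescaled=True)


def prepare_template(t: TemplateMap) -> TemplateMap:
    """Reference-region masking followed by unit rescaling (in that order)."""
    return rescale_unit(mask_reference_region(t))


@dataclass
class AnalysisMask:
    """Stage-1 (spatial regression) and stage-2 (temporal GLM) voxel sets."""

    stage1: np.ndarray
    stage2: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.stage1 = np.asarray(self.stage1, dtype=bool)
        self.stage2 = np.asarray(self.stage2, dtype=bool)
        if not self.stage1.any():
            raise ValueError("stage-1 analysis mask is empty")
        if not self.stage2.any():
            raise ValueError("stage-2 analysis mask is empty")
        if (self.stage1 & ~self.stage2).any():
            raise ValueError("stage-1 mask must be a subset of the stage-2 mask")


def build_analysis_mask(
    templates: list[TemplateMap],
    grey: nib.Nifti1Image,
    coverage: list[nib.Nifti1Image],
    brain: nib.Nifti1Image | None = None,
) -> AnalysisMask:
    """Intersect template domains, grey matter and per-session coverage.

    stage1 = (intersection of template domains) & grey & (intersection of coverage)
    stage2 = (intersection of coverage) & brain, which re-includes the
    reference-region voxels excluded from stage 1. When no brain mask is
    supplied it defaults to grey matter plus all template domains and
    reference regions.
    """
    if not templates:
        raise ValueError("at least one template is required")
    if not coverage:
        raise ValueError("at least one coverage mask is required")
    ref_img = templates[0].img
    for t in templates[1:]:
        check_same_grid(ref_img, t.img, "templates")
    check_same_grid(ref_img, grey, "template and grey-matter mask")
    for c in coverage:
        check_same_grid(ref_img, c, "template and coverage mask")

    domain = np.ones(ref_img.shape[:3], dtype=bool)
    for t in templates:
        domain &= t.domain
    cov = np.ones(ref_img.shape[:3], dtype=bool)
    for c in coverage:
        cov &= mask_array(c)
    stage1 = domain & mask_array(grey) & cov
    if not stage1.any():
        raise ValueError("stage-1 mask is empty (template/grey/coverage intersection)")

    if brain is not None:
        check_same_grid(ref_img, brain, "template and brain mask")
        brain_arr = mask_array(brain)
    else:
        brain_arr = mask_array(grey).copy()
        for t in templates:
            brain_arr |= t.domain | t.reference_mask
    stage2 = cov & brain_arr
    stage2 |= stage1  # stage 1 voxels are by construction analyzable in stage 2
    return AnalysisMask(stage1=stage1, stage2=stage2, affine=np.asarray(ref_img.affine))


def template_spatial_correlation(
    templates: list[TemplateMap], mask: np.ndarray
) -> pd.DataFrame:
    """Pairwise Pearson correlation of template values over a voxel mask.

    This is the collinearity diagnostic for the spatial regressors: highly
    overlapping density maps (e.g. DAT and SERT, which share the striatum)
    produce off-diagonal correlations close to 1 and cannot be separated in
    a joint model.
    """
    if len(templates) < 2:
        raise ValueError("need at least two templates to correlate")
    mask = np.asarray(mask, dtype=bool)
    cols = []
    for t in templates:
        if (mask & ~t.domain).any():
            raise ValueError(f"mask extends beyond the domain of template {t.name!r}")
        v = t.values[mask].astype(float)
        if v.std() == 0:
            raise ValueError(f"template {t.name!r} is constant over the mask")
        cols.append(v)
    names = [t.name for t in templates]
    r = np.corrcoef(np.stack(cols))
    return pd.DataFrame(r, index=names, columns=names)
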
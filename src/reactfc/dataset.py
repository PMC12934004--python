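"""Load a materialized synthetic dataset back from disk.

`load_cohort_dir` reconstructs a cohort-like object from the BIDS-like tree
written by :func:`reactfc.synth.write_cohort`, reading the stored NIfTI and
TSV files rather than regenerating arrays, so the downstream pipeline
exercises the same I/O path a real dataset would.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .io import mask_array, read_events, read_volume
from .patlak import FrameSchedule
from .synth import SESSIONS, SynthConfig
from .templates import (
    build_analysis_mask,
    prepare_template,
    template_from_img,
)


@dataclass
class DiskTruth:
    """The scalar portion of the ground truth stored with a dataset."""

    affine: np.ndarray
    subject_ids: list
    target_names: list
    ki: np.ndarray
    rpe_effect: np.ndarray
    brain: np.ndarray
    grey: np.ndarray

    @property
    def ki_sample_mean(self) -> float:
        return float(self.ki.mean())


class DiskCohort:
    """Cohort interface backed by files under a dataset directory."""

    def __init__(self, root: str):
        self.root = os.fspath(root)
        truth_file = os.path.join(self.root, "truth.json")
        if not os.path.exists(truth_file):
            raise FileNotFoundError(f"{self.root} does not look like a dataset (no truth.json)")
        with open(truth_file) as fh:
            meta = json.load(fh)
        cfg = dict(meta["config"])
        cfg["shape"] = tuple(cfg["shape"])
        cfg["frame_blocks"] = tuple(tuple(b) for b in cfg["frame_blocks"])
        self.config = SynthConfig(**cfg)
        brain = mask_array(read_volume(os.path.join(self.root, "study", "brain.nii.gz")))
        grey_img = read_volume(os.path.join(self.root, "study", "grey.nii.gz"))
        self.truth = DiskTruth(
            affine=self.config.affine,
            subject_ids=list(meta["subject_ids"]),
            target_names=list(meta["target_names"]),
            ki=np.asarray(meta["ki"], dtype=float),
            rpe_effect=np.asarray(meta["rpe_effect"], dtype=float),
            brain=brain,
            grey=mask_array(grey_img),
        )
        self._grey_img = grey_img
        self._brain_img = read_volume(os.path.join(self.root, "study", "brain.nii.gz"))

    def template_maps(self):
        out = []
        for name in self.truth.target_names:
            img = read_volume(os.path.join(self.root, "study", f"template-{name}.nii.gz"))
            ref = read_volume(
                os.path.join(self.root, "study", f"template-{name}_refmask.nii.gz")
            )
            out.append(
                template_from_img(name, img, reference_mask=ref, domain=self.truth.brain)
            )
        return out

    def prepared_templates(self):
        return [prepare_template(t) for t in self.template_maps()]

    def analysis_mask(self):
        return build_analysis_mask(
            self.prepared_templates(),
            self._grey_img,
            [self._brain_img],
            brain=self._brain_img,
        )

    def session_runs(self, subject: int, session: str):
        sub = self.truth.subject_ids[subject]
        if session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        func = os.path.join(self.root, sub, f"ses-{session}", "func")
        runs, events = [], []
        for r in range(self.config.runs_per_session):
            stem = f"{sub}_ses-{session}_task-reversal_run-{r + 1}"
            runs.append(read_volume(os.path.join(func, f"{stem}_bold.nii.gz")))
            events.append(read_events(os.path.join(func, f"{stem}_events.tsv")))
        return runs, events

    def pet(self, subject: int):
        sub = self.truth.subject_ids[subject]
        pet_dir = os.path.join(self.root, sub, "pet")
        pet = read_volume(os.path.join(pet_dir, f"{sub}_pet.nii.gz"))
        ref = read_volume(os.path.join(pet_dir, f"{sub}_refmask.nii.gz"))
        roi = read_volume(os.path.join(pet_dir, f"{sub}_roi.nii.gz"))
        schedule = FrameSchedule.read_tsv(os.path.join(pet_dir, "frames.tsv"))
        return pet, ref, roi, schedule


def load_cohort_dir(root) -> DiskCohort:
    return DiskCohort(root)
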
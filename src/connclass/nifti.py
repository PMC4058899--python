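"""Optional adapter from already-registered 4D NIfTI data to recordings.

The manifest is a JSON file listing, per subject, a 4D BOLD image, a label
image on the same grid (integer codes: 1-56 node ids, 1000 white matter,
2000 CSF, 0 background/excluded), a 6-column motion TSV, and the group label.
Scanner-side operations (slice timing, realignment, normalization, smoothing)
are out of scope: images are expected to be registered already.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .atlas import NetworkAtlas
from .simulate import SubjectRecording

__all__ = ["load_nifti_cohort", "WM_CODE", "CSF_CODE"]

WM_CODE = 1000
CSF_CODE = 2000


def load_nifti_cohort(
    manifest: str | Path, atlas: NetworkAtlas | None = None
) -> tuple[list[SubjectRecording], NetworkAtlas | None]:
    """Load recordings listed in a manifest; returns (recordings, atlas).

    If an atlas is given, a copy with voxel membership mapped through the
    label image of the first subject is returned (all subjects must share
    one label grid per manifest entry convention).
    """
    manifest = Path(manifest)
    spec = json.loads(manifest.read_text())
    root = manifest.parent
    tr = float(spec.get("tr", 2.0))
    recordings: list[SubjectRecording] = []
    membership: dict[int, np.ndarray] | None = None
    for sub in spec["subjects"]:
        for key in ("bold", "labels", "motion"):
            if key not in sub:
                raise ValueError(f"manifest subject entry missing {key!r}")
            if not (root / sub[key]).exists():
                raise FileNotFoundError(f"missing {key} file: {sub[key]}")
        bold = nib.load(root / sub["bold"])
        labels_img = nib.load(root / sub["labels"])
        if bold.shape[:3] != labels_img.shape[:3]:
            raise ValueError(
                f"{sub.get('subject_id', '?')}: BOLD grid {bold.shape[:3]} "
                f"!= label grid {labels_img.shape[:3]}"
            )
        codes = np.asarray(labels_img.dataobj).astype(int).ravel()
        in_brain = np.flatnonzero(codes > 0)
        vol = np.asarray(bold.dataobj, dtype=float)
        data = vol.reshape(-1, vol.shape[3]).T[:, in_brain]  # T x V
        motion = np.loadtxt(root / sub["motion"], delimiter="\t", ndmin=2)
        if motion.shape[0] != data.shape[0]:
            raise ValueError(
                f"{sub.get('subject_id', '?')}: {data.shape[0]} volumes but "
                f"{motion.shape[0]} motion rows"
            )
        sub_codes = codes[in_brain]
        tissue = np.empty(sub_codes.size, dtype=object)
        tissue[:] = "unknown"
        tissue[sub_codes == WM_CODE] = "WM"
        tissue[sub_codes == CSF_CODE] = "CSF"
        node_mask = (sub_codes >= 1) & (sub_codes < WM_CODE)
        for vi in np.flatnonzero(node_mask):
            tissue[vi] = f"node:{sub_codes[vi]}"
        if membership is None:
            membership = {
                int(nid): np.flatnonzero(sub_codes == nid)
                for nid in np.unique(sub_codes[node_mask])
            }
        recordings.append(
            SubjectRecording(
                data=data,
                motion=motion,
                tr=tr,
                label=int(sub.get("group", sub.get("label", 0))),
                subject_id=str(sub.get("subject_id", f"sub-{len(recordings):03d}")),
                tissue=tissue,
            )
        )
    geo_atlas = None
    if atlas is not None and membership is not None:
        geo_atlas = NetworkAtlas(
            networks=list(atlas.networks),
            nodes=list(atlas.nodes),
            voxel_membership=membership,
        )
    return recordings, geo_atlas
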
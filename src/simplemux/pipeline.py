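"""Study manifests and the end-to-end assemble-and-export pipeline.

A study manifest is a YAML file describing one multiplexing experiment:
the reference acquisition, the ordered staining rounds with their images
and control-point files, the stain vectors and background white point.
``run_pipeline`` wires registration, unmixing, assembly and OME-TIFF
export together and returns a QC report (per-round residual RMSE,
clipped-pixel fractions, carryover estimates, software version).
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from .assembly import (
    AssemblyReport,
    MultiplexStack,
    RoundAcquisition,
    build_stack,
    carryover_qc,
    export_ome_tiff,
)
from .registration import ControlPointSet
from .stains import StainMatrix, complete_stain_matrix, default_stain_matrix

__all__ = ["load_manifest", "run_pipeline", "default_config"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """The printable defaults a manifest may override."""
    sm = default_stain_matrix()
    return {
        "background": [255.0, 255.0, 255.0],
        "pixel_size_um": None,
        "stain_vectors": {
            "hematoxylin": [round(float(v), 6) for v in sm.hematoxylin],
            "aec": [round(float(v), 6) for v in sm.aec],
        },
    }


def _load_acquisition(entry: dict, base: Path, need_points: bool) -> RoundAcquisition:
    img_path = base / entry["image"]
    image = np.asarray(iio.imread(img_path))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[..., :3]
    cps = None
    if "points" in entry and entry["points"]:
        cps = ControlPointSet.read_csv(base / entry["points"])
    elif need_points:
        raise ValueError(f"acquisition {entry.get('antigen')!r} lists no control points")
    color = tuple(entry["color"]) if "color" in entry else None
    return RoundAcquisition(
        image=image,
        round_index=int(entry.get("round", 1)),
        antigen=entry.get("antigen"),
        control_points=cps,
        antibody=entry.get("antibody", ""),
        display_color=color,
    )


def load_manifest(path) -> dict:
    """Parse a study manifest into acquisitions plus processing parameters.

    Image and points paths are resolved relative to the manifest's
    directory. Returns a dict with keys reference, rounds, stain_matrix,
    background, pixel_size_um.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "reference" not in doc:
        raise ValueError(f"{path}: manifest must be a mapping with a 'reference' entry")
    base = path.parent
    cfg = default_config()
    sv = {**cfg["stain_vectors"], **doc.get("stain_vectors", {})}
    sm = complete_stain_matrix(sv["hematoxylin"], sv["aec"])
    reference = _load_acquisition(doc["reference"], base, need_points=False)
    rounds = [_load_acquisition(e, base, need_points=True)
              for e in doc.get("rounds", [])]
    return {
        "reference": reference,
        "rounds": rounds,
        "stain_matrix": sm,
        "background": tuple(doc.get("background", cfg["background"])),
        "pixel_size_um": doc.get("pixel_size_um", cfg["pixel_size_um"]),
    }


def run_pipeline(manifest_path, out_path) -> tuple[MultiplexStack, dict]:
    """Register, unmix, assemble and export one study; return (stack, report).

    Any stage failure removes the partial output file and re-raises with
    the stage name attached.
    """
    study = load_manifest(manifest_path)
    report = AssemblyReport()
    stage = "assembly"
    try:
        stack = build_stack(study["reference"], study["rounds"], study["stain_matrix"],
                            bg=study["background"], pixel_size_um=study["pixel_size_um"],
                            report=report)
        stage = "export"
        export_ome_tiff(stack, out_path)
    except Exception as e:
        if os.path.exists(out_path):
            os.unlink(out_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed for {manifest_path}: {e}") from e

    carryover = {}
    by_round = sorted(stack.names[1:], key=lambda n: stack.metadata(n).round_index)
    for earlier, later in zip(by_round, by_round[1:]):
        carryover[f"{earlier}->{later}"] = carryover_qc(stack, earlier, later)

    summary = {
        "version": __version__,
        "channels": stack.names,
        "registration_rmse_px": {k: v.rmse_px for k, v in report.registration.items()},
        "registration_max_residual_px": {k: v.max_residual_px
                                         for k, v in report.registration.items()},
        "clipped_fraction": report.clipped_fraction,
        "carryover_estimate": carryover,
    }
    return stack, summary
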
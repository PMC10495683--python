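"""Assemble aligned per-antigen channels into a multiplexed OME-TIFF stack.

Each staining round of a sequential chromogenic experiment yields one RGB
acquisition per revealed antigen (hematoxylin counterstain + AEC chromogen).
Assembly unmixes every acquisition, registers it to a chosen reference
acquisition via its control points, and collects the warped AEC maps as one
channel per antigen — plus the reference round's hematoxylin — into a single
multi-channel stack written as OME-TIFF (float32 planes, channel names,
display colours and physical pixel size in the OME-XML).

The hematoxylin channel comes from the reference acquisition only: the
counterstain is re-applied every cycle, and the reference defines the frame.
Every round is registered directly to the reference rather than chained
round-to-round, avoiding error accumulation.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .registration import (
    AffineTransform2D,
    ControlPointSet,
    RegistrationReport,
    estimate_affine,
    residual_report,
    warp_image,
)
from .stains import StainMatrix, rgb_to_od, unmix

__all__ = [
    "RoundAcquisition",
    "ChannelMetadata",
    "MultiplexStack",
    "AssemblyReport",
    "build_stack",
    "export_ome_tiff",
    "read_ome_tiff",
    "render_composite",
    "carryover_qc",
]

logger = logging.getLogger(__name__)

#: Pseudocolours for the study's marker panel (arbitrary but stable defaults).
DEFAULT_DISPLAY_COLORS = {
    "hematoxylin": (70, 70, 255),
    "CD31": (0, 255, 0),
    "SFTPC": (64, 224, 208),
    "RAGE": (255, 0, 0),
    "ACTA2": (160, 32, 240),
    "TUBB4B": (255, 255, 255),
}


@dataclass
class RoundAcquisition:
    """One brightfield image of one revealed antigen within one staining round."""

    image: np.ndarray  # H x W x 3 uint8
    round_index: int
    antigen: str | None = None
    control_points: ControlPointSet | None = None
    antibody: str = ""
    display_color: tuple[int, int, int] | None = None

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("acquisition image must be H x W x 3 RGB")
        if self.round_index < 1:
            raise ValueError("round_index is 1-based and must be >= 1")
        self.image = img


@dataclass
class ChannelMetadata:
    name: str
    round_index: int
    antibody: str = ""
    display_color: tuple[int, int, int] = (255, 255, 255)


@dataclass
class MultiplexStack:
    """Aligned single-channel maps in the reference frame, one per antigen."""

    channels: list[tuple[ChannelMetadata, np.ndarray]]
    pixel_size_um: float | None = None

    def __post_init__(self):
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        names = [m.name for m, _ in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")
        shapes = {c.shape for _, c in self.channels}
        if len(shapes) != 1:
            raise ValueError("all channel maps must share one shape")
        for m, c in self.channels:
            if c.ndim != 2:
                raise ValueError("channel maps must be 2-D")
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ValueError(f"channel {m.name!r} has negative or non-finite values")

    @property
    def names(self) -> list[str]:
        return [m.name for m, _ in self.channels]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0][1].shape

    def get(self, name: str) -> np.ndarray:
        for m, c in self.channels:
            if m.name == name:
                return c
        raise KeyError(f"no channel named {name!r}; have {self.names}")

    def metadata(self, name: str) -> ChannelMetadata:
        for m, _ in self.channels:
            if m.name == name:
                return m
        raise KeyError(f"no channel named {name!r}; have {self.names}")


@dataclass
class AssemblyReport:
    """Per-round registration and unmixing QC collected during assembly."""

    registration: dict[str, RegistrationReport] = field(default_factory=dict)
    clipped_fraction: dict[str, float] = field(default_factory=dict)


def build_stack(reference: RoundAcquisition, rounds, M: StainMatrix,
                bg=(255.0, 255.0, 255.0), pixel_size_um: float | None = None,
                report: AssemblyReport | None = None) -> MultiplexStack:
    """Unmix, register and merge acquisitions into one aligned stack.

    The reference contributes the hematoxylin channel (unwarped) and, when it
    carries an antigen, its AEC map unwarped. Every other acquisition needs
    control points; its AEC map is warped into the reference frame through
    the fitted affine. Channel order: hematoxylin first, then antigens by
    (round_index, input order).
    """
    rounds = list(rounds)
    antigens = [a.antigen for a in [reference, *rounds] if a.antigen is not None]
    if len(set(antigens)) != len(antigens):
        raise ValueError(f"duplicate antigen labels: {antigens}")

    ref_shape = reference.image.shape[:2]
    ref_maps = unmix(rgb_to_od(reference.image, bg), M)

    def color_for(acq):
        if acq.display_color is not None:
            return tuple(acq.display_color)
        return DEFAULT_DISPLAY_COLORS.get(acq.antigen, (255, 255, 255))

    entries: list[tuple[int, int, ChannelMetadata, np.ndarray]] = []
    hema_meta = ChannelMetadata("hematoxylin", reference.round_index, "",
                                DEFAULT_DISPLAY_COLORS["hematoxylin"])
    if report is not None:
        report.clipped_fraction["reference"] = ref_maps.clipped_fraction
    if reference.antigen is not None:
        meta = ChannelMetadata(reference.antigen, reference.round_index,
                               reference.antibody, color_for(reference))
        entries.append((reference.round_index, -1, meta, ref_maps.aec))

    for order, acq in enumerate(rounds):
        if acq.antigen is None:
            raise ValueError(f"non-reference acquisition #{order} has no antigen label")
        if acq.control_points is None:
            raise ValueError(f"acquisition {acq.antigen!r} has no control points")
        maps = unmix(rgb_to_od(acq.image, bg), M)
        T = estimate_affine(acq.control_points)
        rep = residual_report(acq.control_points, T)
        logger.info("round %d %s: rmse %.3f px over %d points, clip %.4f",
                    acq.round_index, acq.antigen, rep.rmse_px, rep.n_points,
                    maps.clipped_fraction)
        if report is not None:
            report.registration[acq.antigen] = rep
            report.clipped_fraction[acq.antigen] = maps.clipped_fraction
        warped = warp_image(maps.aec, T, out_shape=ref_shape,
                            interpolation="bilinear", fill_value=0.0)
        warped = np.maximum(warped, 0.0)
        meta = ChannelMetadata(acq.antigen, acq.round_index, acq.antibody, color_for(acq))
        entries.append((acq.round_index, order, meta, warped))

    entries.sort(key=lambda e: (e[0], e[1]))
    channels = [(hema_meta, ref_maps.hematoxylin)]
    channels += [(meta, arr) for _, _, meta, arr in entries]
    return MultiplexStack(channels, pixel_size_um=pixel_size_um)


def _color_to_ome(rgb: tuple[int, int, int]) -> int:
    """RGB triple -> signed 32-bit RGBA integer as OME stores channel colours."""
    r, g, b = (int(v) & 0xFF for v in rgb)
    packed = (r << 24) | (g << 16) | (b << 8) | 0xFF
    return packed - (1 << 32) if packed >= (1 << 31) else packed


def _color_from_ome(value: int) -> tuple[int, int, int]:
    packed = int(value) & 0xFFFFFFFF
    return ((packed >> 24) & 0xFF, (packed >> 16) & 0xFF, (packed >> 8) & 0xFF)


def export_ome_tiff(stack: MultiplexStack, path) -> None:
    """Write the stack as a float32 multi-channel OME-TIFF.

    Channel name and display colour map to the OME Channel Name/Color
    attributes; the staining round and antibody ride in the free-text Fluor
    attribute as ``round=<n>;antibody=<text>`` (OME has no dedicated slot for
    a chromogenic staining round).
    """
    data = np.stack([c for _, c in stack.channels]).astype(np.float32)
    metas = [m for m, _ in stack.channels]
    metadata = {
        "axes": "CYX",
        "Channel": {
            "Name": [m.name for m in metas],
            "Color": [_color_to_ome(m.display_color) for m in metas],
            "Fluor": [f"round={m.round_index};antibody={m.antibody}" for m in metas],
        },
    }
    if stack.pixel_size_um is not None:
        metadata.update(
            PhysicalSizeX=float(stack.pixel_size_um), PhysicalSizeXUnit="µm",
            PhysicalSizeY=float(stack.pixel_size_um), PhysicalSizeYUnit="µm",
        )
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def read_ome_tiff(path) -> MultiplexStack:
    """Read a stack written by :func:`export_ome_tiff` (or a conforming OME-TIFF)."""
    try:
        with tifffile.TiffFile(path) as tf:
            if tf.ome_metadata is None:
                raise ValueError("no OME-XML metadata found")
            data = tf.series[0].asarray()
            root = ET.fromstring(tf.ome_metadata)
    except (tifffile.TiffFileError, ET.ParseError, ValueError) as e:
        raise ValueError(f"{path}: not a readable OME-TIFF ({e})") from e
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        raise ValueError(f"{path}: OME-XML lacks a Pixels element")
    data = np.atleast_3d(np.asarray(data, dtype=np.float64))
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a C x Y x X series, got shape {data.shape}")
    px = pixels.get("PhysicalSizeX")
    channels = []
    for i, ch in enumerate(pixels.findall("ome:Channel", ns)):
        name = ch.get("Name", f"channel_{i}")
        color = _color_from_ome(int(ch.get("Color", "255")))
        round_index, antibody = 1, ""
        fluor = ch.get("Fluor", "")
        for token in fluor.split(";"):
            key, _, val = token.partition("=")
            if key == "round" and val:
                round_index = int(val)
            elif key == "antibody":
                antibody = val
        channels.append((ChannelMetadata(name, round_index, antibody, color), data[i]))
    if len(channels) != data.shape[0]:
        raise ValueError(f"{path}: {len(channels)} Channel elements for "
                         f"{data.shape[0]} planes")
    return MultiplexStack(channels, pixel_size_um=float(px) if px else None)


def render_composite(stack: MultiplexStack, channel_subset=None,
                     percentile: float = 99.0) -> np.ndarray:
    """Additive pseudocolour composite of the requested channels, uint8 RGB.

    Each channel is scaled to [0, 1] by its own intensity percentile
    (default 99th; robust to hot pixels), multiplied by its display colour,
    and summed; the sum is clipped to [0, 255].
    """
    names = stack.names if channel_subset is None else list(channel_subset)
    out = np.zeros(stack.shape + (3,), dtype=np.float64)
    for name in names:
        c = stack.get(name)  # raises KeyError for unknown names
        meta = stack.metadata(name)
        scale = float(np.percentile(c, percentile))
        norm = np.clip(c / scale, 0.0, 1.0) if scale > 0 else np.zeros_like(c)
        out += norm[..., None] * np.asarray(meta.display_color, dtype=np.float64)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def carryover_qc(stack: MultiplexStack, earlier: str, later: str,
                 positivity_threshold: float = 0.1) -> float:
    """Median later/earlier signal ratio over earlier-positive pixels.

    Estimates the fraction of an earlier round's chromogen surviving erasure
    into a later round, assuming the two antigens occupy (mostly) disjoint
    tissue patterns. Returns 0 when no pixel of the earlier channel exceeds
    the positivity threshold.
    """
    e = stack.get(earlier)
    l = stack.get(later)
    mask = e > positivity_threshold
    if not np.any(mask):
        return 0.0
    return float(np.median(l[mask] / e[mask]))
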
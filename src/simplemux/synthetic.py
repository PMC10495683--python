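"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators:

* an imaging phantom emulating sequential chromogenic rounds — one shared
  tissue layout (hematoxylin-stained nuclei) plus one AEC antigen pattern
  per acquisition, each acquisition observed through its own small affine
  misalignment, with Gaussian camera noise and a tunable fraction of the
  previous round's chromogen surviving erasure (carryover);
* a DIA-like long-format precursor intensity table with a known protein /
  peptide / precursor hierarchy, planted group effects and detection-limit
  missingness.

Nuclei are Gaussian blobs and antigen patterns smooth parametric fields;
no histological realism is attempted — the point is exact ground truth
(concentration fields, affine transforms, landmark positions, planted
fold changes) against which estimates can be scored.

All randomness flows from an explicit integer seed through
``numpy.random.default_rng``; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import RoundAcquisition
from .registration import AffineTransform2D, ControlPointSet, _spread_area
from .stains import StainMatrix, default_stain_matrix, od_to_rgb

__all__ = [
    "AntigenSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "StudySpec",
    "generate_phantom",
    "generate_phantom_truth",
    "generate_control_points",
    "generate_precursor_study",
]

#: The study's marker panel and staining-round order: CD31 and SFTPC in
#: round 1, RAGE and ACTA2 in round 2, TUBB4B in round 3.
DEFAULT_PANEL = (
    ("CD31", "scattered", 1),
    ("SFTPC", "blob", 1),
    ("RAGE", "ring", 2),
    ("ACTA2", "ring", 2),
    ("TUBB4B", "blob", 3),
)


@dataclass(frozen=True)
class AntigenSpec:
    name: str
    pattern: str  # blob | ring | scattered
    round_index: int
    max_concentration: float = 1.0


@dataclass
class PhantomSpec:
    """Parameters of the multi-round imaging phantom.

    Geometry perturbations are per acquisition: rotation and isotropic
    scale about the image centre plus a translation whose norm is bounded
    by ``max_translation_px``. ``carryover_fraction`` of the immediately
    preceding acquisition's AEC field leaks into each image, emulating
    incomplete ethanol erasure. ``rgb_noise_sigma`` is the std of additive
    Gaussian camera noise in 8-bit intensity units.
    """

    seed: int
    height: int = 192
    width: int = 192
    n_nuclei: int = 60
    nucleus_radius_px: tuple[float, float] = (2.5, 5.0)
    antigens: tuple[AntigenSpec, ...] = tuple(AntigenSpec(*a) for a in DEFAULT_PANEL)
    hema_max_od: float = 0.8
    max_rotation_deg: float = 3.0
    max_translation_px: float = 8.0
    max_scale_dev: float = 0.02
    rgb_noise_sigma: float = 2.0
    carryover_fraction: float = 0.05
    stain_matrix: StainMatrix = field(default_factory=default_stain_matrix)
    background: tuple[float, float, float] = (255.0, 255.0, 255.0)

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be >= 32 px")
        if not 0.0 <= self.carryover_fraction < 1.0:
            raise ValueError("carryover_fraction must be in [0, 1)")
        if not self.antigens:
            raise ValueError("antigen list must not be empty")


@dataclass
class PhantomGroundTruth:
    """Everything the generator knows and estimators must recover."""

    hematoxylin_field: np.ndarray
    antigen_fields: dict[str, np.ndarray]  # reference frame
    transforms: dict[str, AffineTransform2D]  # moving -> reference, per acquisition
    shifts: dict[str, np.ndarray]  # pure-translation component (2,)
    rounds: dict[str, int]
    order: list[str]  # acquisition order (reference first)
    landmarks: np.ndarray  # nucleus centroids, reference frame, (n, 2) x,y
    stain_matrix: StainMatrix
    carryover_fraction: float
    shape: tuple[int, int]


def _gauss2d(h, w, cx, cy, sigma, amp=1.0):
    y, x = np.ogrid[:h, :w]
    return amp * np.exp(-(((x - cx) ** 2) + ((y - cy) ** 2)) / (2.0 * sigma**2))


def _antigen_field(spec: PhantomSpec, a: AntigenSpec, rng) -> np.ndarray:
    h, w = spec.height, spec.width
    f = np.zeros((h, w))
    if a.pattern == "blob":
        for _ in range(rng.integers(3, 6)):
            cx, cy = rng.uniform(0.15, 0.85, 2) * (w, h)
            f += _gauss2d(h, w, cx, cy, rng.uniform(w / 12, w / 7))
    elif a.pattern == "ring":
        cx, cy = rng.uniform(0.3, 0.7, 2) * (w, h)
        radius = rng.uniform(w / 6, w / 4)
        width = rng.uniform(w / 40, w / 25)
        y, x = np.ogrid[:h, :w]
        dist = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        f = np.exp(-((dist - radius) ** 2) / (2.0 * width**2))
    elif a.pattern == "scattered":
        for _ in range(rng.integers(20, 35)):
            cx = rng.uniform(0.05, 0.95) * w
            cy = rng.uniform(0.05, 0.95) * h
            f += _gauss2d(h, w, cx, cy, rng.uniform(1.5, 3.5))
    elif a.pattern in ("blob_left", "blob_right"):
        # Half-frame confined blobs: two such antigens on opposite sides have
        # disjoint support, which the carryover QC estimator assumes.
        lo, hi = (0.10, 0.30) if a.pattern == "blob_left" else (0.70, 0.90)
        for _ in range(rng.integers(2, 4)):
            cx = rng.uniform(lo, hi) * w
            cy = rng.uniform(0.2, 0.8) * h
            f += _gauss2d(h, w, cx, cy, rng.uniform(w / 24, w / 16))
    else:
        raise ValueError(f"unknown antigen pattern {a.pattern!r}")
    peak = f.max()
    return f * (a.max_concentration / peak) if peak > 0 else f


def _random_transform(spec: PhantomSpec, rng) -> tuple[AffineTransform2D, np.ndarray]:
    """Rotation+scale about the image centre composed with a bounded shift."""
    theta = np.radians(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
    s = 1.0 + rng.uniform(-spec.max_scale_dev, spec.max_scale_dev)
    ang = rng.uniform(0, 2 * np.pi)
    mag = rng.uniform(0, spec.max_translation_px)
    shift = mag * np.array([np.cos(ang), np.sin(ang)])
    A = s * np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
    c = np.array([(spec.width - 1) / 2.0, (spec.height - 1) / 2.0])
    t = c - A @ c + shift
    return AffineTransform2D(A, t), shift


def _build_truth(spec: PhantomSpec, rng) -> PhantomGroundTruth:
    h, w = spec.height, spec.width
    margin = max(spec.nucleus_radius_px) + 2
    centers = np.column_stack([
        rng.uniform(margin, w - margin, spec.n_nuclei),
        rng.uniform(margin, h - margin, spec.n_nuclei),
    ])
    radii = rng.uniform(*spec.nucleus_radius_px, spec.n_nuclei)
    hema = np.zeros((h, w))
    for (cx, cy), r in zip(centers, radii):
        hema += _gauss2d(h, w, cx, cy, r / 2.0)
    hema *= spec.hema_max_od / hema.max()

    fields = {a.name: _antigen_field(spec, a, rng) for a in spec.antigens}

    order = [a.name for a in spec.antigens]
    transforms, shifts = {}, {}
    for i, a in enumerate(spec.antigens):
        if i == 0:  # reference acquisition defines the frame
            transforms[a.name] = AffineTransform2D.identity()
            shifts[a.name] = np.zeros(2)
        else:
            transforms[a.name], shifts[a.name] = _random_transform(spec, rng)

    return PhantomGroundTruth(
        hematoxylin_field=hema,
        antigen_fields=fields,
        transforms=transforms,
        shifts=shifts,
        rounds={a.name: a.round_index for a in spec.antigens},
        order=order,
        landmarks=centers,
        stain_matrix=spec.stain_matrix,
        carryover_fraction=spec.carryover_fraction,
        shape=(h, w),
    )


def generate_phantom_truth(spec: PhantomSpec) -> PhantomGroundTruth:
    """Ground truth only (fields, transforms, landmarks) — no image rendering.

    Shares its RNG stream prefix with :func:`generate_phantom`, so for a
    given spec the truth is identical whether or not images are rendered.
    """
    return _build_truth(spec, np.random.default_rng(spec.seed))


def generate_phantom(spec: PhantomSpec) -> tuple[list[RoundAcquisition], PhantomGroundTruth]:
    """Render the full acquisition series plus its ground truth.

    Each acquisition mixes (shared hematoxylin + its antigen's AEC field +
    carryover x previous acquisition's AEC field) through the stain matrix,
    converts to 8-bit RGB, is observed through the inverse of its true
    affine (the reference stays unwarped), and receives Gaussian noise.
    """
    from .registration import warp_image  # local import avoids cycle at module load

    rng = np.random.default_rng(spec.seed)
    gt = _build_truth(spec, rng)
    M = spec.stain_matrix
    h_vec, a_vec = M.hematoxylin, M.aec

    acquisitions: list[RoundAcquisition] = []
    prev_aec = None
    for i, a in enumerate(spec.antigens):
        aec = gt.antigen_fields[a.name]
        if prev_aec is not None and spec.carryover_fraction > 0:
            aec = aec + spec.carryover_fraction * prev_aec
        od = gt.hematoxylin_field[..., None] * h_vec + aec[..., None] * a_vec
        scene = od_to_rgb(od, spec.background)
        if i == 0:
            img = scene
        else:
            img = warp_image(scene, gt.transforms[a.name].invert(),
                             interpolation="bilinear", fill_value=255)
        if spec.rgb_noise_sigma > 0:
            noisy = img.astype(np.float64) + rng.normal(0, spec.rgb_noise_sigma, img.shape)
            img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        acquisitions.append(RoundAcquisition(
            image=img, round_index=a.round_index,
            antigen=a.name, control_points=None,
        ))
        prev_aec = gt.antigen_fields[a.name]
    return acquisitions, gt


def generate_control_points(gt: PhantomGroundTruth, antigen: str, n_points: int = 12,
                            jitter_sigma_px: float = 0.5, seed: int = 0,
                            max_attempts: int = 100) -> ControlPointSet:
    """Sample jittered landmark pairs for one acquisition, emulating manual clicking.

    Reference coordinates are true nucleus centroids; moving coordinates are
    their true-inverse-mapped positions plus i.i.d. Gaussian jitter of
    ``jitter_sigma_px`` per axis. Only landmarks whose moving position lies
    inside the frame are eligible; near-collinear draws are rejected and
    resampled.
    """
    if n_points < 3:
        raise ValueError("need at least 3 control points")
    T = gt.transforms[antigen]
    tinv = T.invert()
    ref = gt.landmarks
    mov_true = tinv(ref)
    h, w = gt.shape
    ok = ((mov_true[:, 0] >= 0) & (mov_true[:, 0] <= w - 1)
          & (mov_true[:, 1] >= 0) & (mov_true[:, 1] <= h - 1))
    eligible = np.nonzero(ok)[0]
    if len(eligible) < 3:
        raise ValueError("fewer than 3 landmarks visible in the moving frame")
    n = min(n_points, len(eligible))
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        idx = rng.choice(eligible, size=n, replace=False)
        mov = mov_true[idx] + rng.normal(0, jitter_sigma_px, (n, 2))
        if _spread_area(mov) > 1e-6:
            return ControlPointSet(mov, ref[idx])
    raise RuntimeError("could not draw a non-collinear control point set")


# ---------------------------------------------------------------------------
# DIA-like precursor study


@dataclass
class StudySpec:
    """Parameters of the synthetic DIA precursor study.

    Intensities are log-normal: a protein baseline (log2 scale) plus
    peptide and precursor response offsets, a per-(protein, sample)
    biological term shared by all the protein's precursors in that sample,
    and per-measurement technical noise. A fraction of proteins carries a
    planted group effect: their group-B intensities are multiplied by
    ``2**fc`` with ``fc`` drawn as ``effect_log2fc`` times a random sign.
    Intensities below ``detection_limit`` are recorded missing.
    """

    seed: int
    n_proteins: int = 2000
    n_per_group: int = 5
    group_labels: tuple[str, str] = ("A", "B")
    peptides_per_protein_mean: float = 2.5  # peptides ~ 1 + Poisson(mean)
    precursors_per_peptide_mean: float = 1.0  # precursors ~ 1 + Poisson(mean)
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    peptide_log2_sd: float = 1.0
    precursor_log2_sd: float = 0.5
    biological_log2_sd: float = 0.3
    noise_log2_sd: float = 0.5
    effect_fraction: float = 0.0
    effect_log2fc: float = 2.0
    detection_limit: float = 2.0**15

    def __post_init__(self):
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must be in [0, 1]")
        for name in ("baseline_log2_sd", "peptide_log2_sd", "precursor_log2_sd",
                     "biological_log2_sd", "noise_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_precursor_study(spec: StudySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format precursor table plus the planted-effect truth record.

    Returns ``(table, truth)``: the table has columns protein, peptide,
    precursor, sample, group, intensity (rows below the detection limit are
    dropped — they were never observed); the truth record lists each planted
    protein with its ``log2_fc`` as applied to group B.
    """
    rng = np.random.default_rng(spec.seed)
    ga, gb = spec.group_labels
    samples = [f"{ga}{i + 1}" for i in range(spec.n_per_group)] + \
              [f"{gb}{i + 1}" for i in range(spec.n_per_group)]
    groups = [ga] * spec.n_per_group + [gb] * spec.n_per_group
    n_samples = len(samples)

    n_pep = 1 + rng.poisson(spec.peptides_per_protein_mean, spec.n_proteins)
    base = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_proteins)

    planted = rng.random(spec.n_proteins) < spec.effect_fraction
    fc = np.where(planted,
                  spec.effect_log2fc * rng.choice([-1.0, 1.0], spec.n_proteins),
                  0.0)

    # Flatten the protein -> peptide -> precursor hierarchy into index arrays
    # so every random draw is a single vectorised call.
    pep_protein = np.repeat(np.arange(spec.n_proteins), n_pep)  # (n_peptides,)
    n_peptides = len(pep_protein)
    pep_rank = np.arange(n_peptides) - np.repeat(
        np.concatenate([[0], np.cumsum(n_pep)[:-1]]), n_pep)
    pep_off = rng.normal(0, spec.peptide_log2_sd, n_peptides)

    n_prec = 1 + rng.poisson(spec.precursors_per_peptide_mean, n_peptides)
    prec_peptide = np.repeat(np.arange(n_peptides), n_prec)  # (n_precursors,)
    n_precursors = len(prec_peptide)
    prec_rank = np.arange(n_precursors) - np.repeat(
        np.concatenate([[0], np.cumsum(n_prec)[:-1]]), n_prec)
    prec_off = rng.normal(0, spec.precursor_log2_sd, n_precursors)
    prec_protein = pep_protein[prec_peptide]

    bio = rng.normal(0, spec.biological_log2_sd, (spec.n_proteins, n_samples))
    noise = rng.normal(0, spec.noise_log2_sd, (n_precursors, n_samples))
    is_b = np.array([g == gb for g in groups], dtype=float)
    effect = fc[:, None] * is_b[None, :]  # (n_proteins, n_samples)

    log2i = (base[prec_protein][:, None] + pep_off[prec_peptide][:, None]
             + prec_off[:, None] + bio[prec_protein] + effect[prec_protein] + noise)

    digits = len(str(spec.n_proteins))
    protein_ids = np.array([f"P{p + 1:0{digits}d}" for p in range(spec.n_proteins)])
    peptide_ids = np.array([f"{protein_ids[pep_protein[j]]}_pep{pep_rank[j] + 1:02d}"
                            for j in range(n_peptides)])
    precursor_ids = np.array([f"{peptide_ids[prec_peptide[k]]}_z{prec_rank[k] + 1}"
                              for k in range(n_precursors)])

    tbl = pd.DataFrame({
        "protein": np.repeat(protein_ids[prec_protein], n_samples),
        "peptide": np.repeat(peptide_ids[prec_peptide], n_samples),
        "precursor": np.repeat(precursor_ids, n_samples),
        "sample": np.tile(samples, n_precursors),
        "group": np.tile(groups, n_precursors),
        "intensity": np.exp2(log2i.ravel()),
    })
    tbl = tbl[tbl["intensity"] >= spec.detection_limit].reset_index(drop=True)

    truth = pd.DataFrame({
        "protein": [f"P{p + 1:0{digits}d}" for p in np.nonzero(planted)[0]],
        "log2_fc": fc[planted],
    })
    return tbl, truth
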
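"""Synthetic tractography cohort generator.

Emulates the statistical structure of surface-seeded probabilistic
tractography output: each subject hemisphere yields a nonnegative
vertex x voxel visitation matrix that is a low-rank sum of planted
"bundles" (outer products of a gray-matter termination profile and a
white-matter tract core) plus counting noise.

Two bundle classes of scientific interest are always planted:

* ``ATF`` — anterior temporal-frontal: gray mass split between the
  anterior temporal pole and prefrontal cortex (uncinate-like).
* ``OTF`` — occipitotemporal-frontal: gray mass split between occipital
  cortex and prefrontal cortex (IFOF-like), with a tract core running
  along the anterior-posterior axis.

plus a configurable number of ``DISTRACTOR`` bundles connecting other
parcel pairs. The species-level parameter ``ofc_fraction`` controls the
fraction of each ATF/OTF bundle's prefrontal termination mass that falls
inside the orbitofrontal cortex (OFC); it is perturbed per hemisphere on
the log-odds scale to create a hemisphere-level random effect.

Geometry is an abstract indexed vertex set (no mesh): vertices carry a
parcel and hemisphere label, and the two hemispheres carry identical
parcel label sequences so that a right-hemisphere matrix can be mirrored
onto the left index block by swapping row halves.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, InvalidSpecError, ShapeError

PARCELS = (
    "OFC",
    "PFC_OTHER",
    "TEMPORAL_POLE",
    "TEMPORAL_OTHER",
    "OCCIPITAL",
    "PARIETAL",
    "OTHER",
)
HEMISPHERES = ("LEFT", "RIGHT")
BUNDLE_CLASSES = ("ATF", "OTF", "DISTRACTOR")

#: Default per-hemisphere parcel area fractions (vertex-count shares).
DEFAULT_PARCEL_FRACTIONS: dict[str, float] = {
    "OFC": 0.05,
    "PFC_OTHER": 0.15,
    "TEMPORAL_POLE": 0.05,
    "TEMPORAL_OTHER": 0.15,
    "OCCIPITAL": 0.15,
    "PARIETAL": 0.15,
    "OTHER": 0.30,
}

# Nominal parcel anchor coordinates in the white-matter box. Axis 0 is
# posterior (0) -> anterior (1); axis 1 is medial-lateral; axis 2 is
# ventral (0) -> dorsal (1). Used only to shape tract cores.
_ANCHORS: dict[str, tuple[float, float, float]] = {
    "OFC": (0.85, 0.50, 0.15),
    "PFC_OTHER": (0.85, 0.50, 0.55),
    "PFC": (0.85, 0.50, 0.30),
    "TEMPORAL_POLE": (0.65, 0.78, 0.18),
    "TEMPORAL_OTHER": (0.45, 0.80, 0.30),
    "OCCIPITAL": (0.05, 0.50, 0.30),
    "PARIETAL": (0.30, 0.50, 0.85),
    "OTHER": (0.50, 0.18, 0.60),
}

# Waypoints inserted between endpoints to shape the tract core. The ATF
# dips ventrally (hook under the lateral sulcus); the OTF stays ventral
# and nearly parallel to the anterior-posterior axis.
_WAYPOINTS: dict[str, list[tuple[float, float, float]]] = {
    "ATF": [(0.74, 0.70, 0.05)],
    "OTF": [(0.45, 0.50, 0.28)],
}

# Endpoint parcel pairs cycled through when planting distractor bundles.
# None involves prefrontal cortex, so distractors never contribute
# prefrontal termination mass.
_DISTRACTOR_PAIRS: list[tuple[str, str]] = [
    ("PARIETAL", "OTHER"),
    ("OCCIPITAL", "PARIETAL"),
    ("TEMPORAL_OTHER", "PARIETAL"),
    ("TEMPORAL_OTHER", "OTHER"),
    ("OCCIPITAL", "OTHER"),
    ("TEMPORAL_OTHER", "OCCIPITAL"),
]


@dataclass(frozen=True)
class CohortGeometry:
    """Shared vertex/voxel index space with parcel and hemisphere labels."""

    n_vertices: int
    n_voxels: int
    parcel_of: np.ndarray  # (n_vertices,) str
    hemisphere_of: np.ndarray  # (n_vertices,) str
    voxel_position: np.ndarray  # (n_voxels, 3) float

    @property
    def n_half(self) -> int:
        return self.n_vertices // 2

    def vertices_of(self, parcels: str | Sequence[str],
                    hemisphere: str | None = None) -> np.ndarray:
        """Indices of vertices in the given parcel(s), optionally
        restricted to one hemisphere."""
        if isinstance(parcels, str):
            parcels = (parcels,)
        mask = np.isin(self.parcel_of, list(parcels))
        if hemisphere is not None:
            if hemisphere not in HEMISPHERES:
                raise DomainError(f"unknown hemisphere {hemisphere!r}")
            mask &= self.hemisphere_of == hemisphere
        return np.flatnonzero(mask)

    def parcel_counts(self, hemisphere: str | None = None) -> dict[str, int]:
        counts = {}
        for p in PARCELS:
            counts[p] = int(len(self.vertices_of(p, hemisphere)))
        return counts


@dataclass
class GroundTruthBundle:
    """A planted connection: gray termination profile x white tract core."""

    bundle_id: str
    bundle_class: str  # ATF | OTF | DISTRACTOR
    gray_loading: np.ndarray  # (n_vertices,) >= 0
    white_loading: np.ndarray  # (n_voxels,) >= 0
    ofc_fraction: float  # share of prefrontal gray mass inside OFC
    species: str = ""
    subject_id: str = ""
    hemisphere: str = ""

    def prefrontal_mass(self, geometry: CohortGeometry) -> float:
        return float(self.gray_loading[
            geometry.vertices_of(("OFC", "PFC_OTHER"))].sum())

    def true_obi(self, geometry: CohortGeometry) -> float:
        """Analytic orbitofrontal bias index of the planted loading."""
        n_ofc = len(geometry.vertices_of("OFC"))
        n_pfc = n_ofc + len(geometry.vertices_of("PFC_OTHER"))
        return self.ofc_fraction / (n_ofc / n_pfc)


@dataclass(frozen=True)
class SpeciesSpec:
    """One species in the cohort design.

    ``ofc_fraction`` may be a single float (applied to both ATF and OTF
    bundles) or a mapping ``{"ATF": f_atf, "OTF": f_otf}``.
    """

    name: str
    n_subjects: int
    ofc_fraction: float | Mapping[str, float]

    def fraction_for(self, bundle_class: str) -> float:
        if isinstance(self.ofc_fraction, Mapping):
            return float(self.ofc_fraction[bundle_class])
        return float(self.ofc_fraction)


@dataclass(frozen=True)
class NoiseModel:
    kind: str = "POISSON"  # POISSON | TRUNCATED_GAUSSIAN
    scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("POISSON", "TRUNCATED_GAUSSIAN"):
            raise InvalidSpecError(f"unknown noise model {self.kind!r}")
        if self.scale < 0:
            raise InvalidSpecError("noise scale must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort design: species, random effects, noise and seeding."""

    species_list: tuple[SpeciesSpec, ...]
    hemisphere_sd: float = 0.2
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    subject_gain: float = 50.0
    gain_sd: float = 0.2  # lognormal SD of per-subject intensity gain
    n_distractors: int = 6
    bundle_width: float = 0.08  # Gaussian tract-core radius (box units)
    seed: int = 0

    def __post_init__(self):
        if not self.species_list:
            raise InvalidSpecError("at least one species required")
        for sp in self.species_list:
            if sp.n_subjects < 1:
                raise InvalidSpecError(
                    f"species {sp.name!r}: n_subjects must be >= 1")
            for cls in ("ATF", "OTF"):
                f = sp.fraction_for(cls)
                if not 0.0 <= f <= 1.0:
                    raise InvalidSpecError(
                        f"species {sp.name!r}: ofc_fraction {f} outside [0, 1]")
        if self.hemisphere_sd < 0:
            raise InvalidSpecError("hemisphere_sd must be >= 0")

    def species(self, name: str) -> SpeciesSpec:
        for sp in self.species_list:
            if sp.name == name:
                return sp
        raise InvalidSpecError(f"species {name!r} not in cohort spec")


@dataclass
class ConnectivityMatrix:
    """One subject hemisphere's nonnegative vertex x voxel visitation
    matrix (the NMF input V)."""

    subject_id: str
    species: str
    hemisphere: str
    values: np.ndarray  # (n_vertices, n_voxels)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise DomainError("connectivity values must be finite")
        if v.size and v.min() < 0:
            raise DomainError("connectivity values must be nonnegative")
        self.values = v


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """Cohort design mirroring the study: 3 species x 3 subjects, with
    species OFC fractions back-derived from the reported per-species OBI
    means under the default parcel sizes (|OFC|/|PFC| = 1/4)."""
    return CohortSpec(
        species_list=(
            SpeciesSpec("macaque_like", 3, {"ATF": 0.38, "OTF": 0.29}),
            SpeciesSpec("squirrel_like", 3, {"ATF": 0.47, "OTF": 0.32}),
            SpeciesSpec("lemur_like", 3, {"ATF": 0.93, "OTF": 0.77}),
        ),
        seed=seed,
    )


def make_geometry(n_vertices: int = 2000, n_voxels: int = 3000,
                  parcel_fractions: Mapping[str, float] | None = None,
                  seed: int = 0) -> CohortGeometry:
    """Build a label-symmetric two-hemisphere vertex space plus a random
    voxel cloud.

    Per hemisphere, each parcel receives ``round(fraction * n_vertices/2)``
    vertices; the OTHER parcel absorbs the rounding residual so counts sum
    exactly. Label positions are shuffled within the hemisphere
    (deterministically for a fixed seed); the right hemisphere repeats the
    left hemisphere's label sequence, so index ``i + n_vertices/2`` is the
    mirror of index ``i``.
    """
    if n_vertices <= 0 or n_vertices % 2:
        raise InvalidSpecError("n_vertices must be a positive even integer")
    if n_voxels <= 0:
        raise InvalidSpecError("n_voxels must be positive")
    fractions = dict(DEFAULT_PARCEL_FRACTIONS if parcel_fractions is None
                     else parcel_fractions)
    unknown = set(fractions) - set(PARCELS)
    if unknown:
        raise InvalidSpecError(f"unknown parcels {sorted(unknown)}")
    vals = np.array([fractions.get(p, 0.0) for p in PARCELS], dtype=float)
    if vals.min() < 0:
        raise InvalidSpecError("parcel fractions must be nonnegative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise InvalidSpecError(
            f"parcel fractions must sum to 1 (got {vals.sum():.12g})")

    half = n_vertices // 2
    counts = {p: int(round(fractions.get(p, 0.0) * half)) for p in PARCELS}
    counts["OTHER"] += half - sum(counts.values())
    if counts["OTHER"] < 0:
        raise InvalidSpecError("rounding residual exceeds OTHER parcel size")
    for required in ("OFC", "PFC_OTHER"):
        if counts[required] < 1:
            raise InvalidSpecError(
                f"parcel {required} received 0 vertices per hemisphere")

    rng = np.random.default_rng(seed)
    labels_half = np.repeat(list(PARCELS), [counts[p] for p in PARCELS])
    labels_half = rng.permutation(labels_half)
    parcel_of = np.concatenate([labels_half, labels_half])
    hemisphere_of = np.array(["LEFT"] * half + ["RIGHT"] * half)
    voxel_position = rng.uniform(size=(n_voxels, 3))
    return CohortGeometry(n_vertices, n_voxels, parcel_of, hemisphere_of,
                          voxel_position)


def _tract_core(geometry: CohortGeometry, waypoints: list[tuple[float, ...]],
                width: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian tube along a polyline through the voxel cloud, peak 1."""
    pts = []
    wp = np.asarray(waypoints, dtype=float)
    for a, b in zip(wp[:-1], wp[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / (width / 2))), 2)
        t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
        pts.append(a + t * (b - a))
    pts.append(wp[-1:])
    pts = np.vstack(pts)
    d2 = ((geometry.voxel_position[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    core = np.exp(-d2.min(axis=1) / (2 * width ** 2))
    core *= rng.uniform(0.8, 1.2, size=core.shape)
    peak = core.max()
    if peak > 0:
        core /= peak
    return core


def _block_scaled(values: np.ndarray, idx: np.ndarray, target_mass: float):
    """Scale values[idx] in place so their sum equals target_mass exactly."""
    if target_mass == 0:
        values[idx] = 0.0
        return
    s = values[idx].sum()
    if s > 0:
        values[idx] *= target_mass / s


def _gray_profile(geometry: CohortGeometry,
                  end_a: np.ndarray,
                  end_b_blocks: Sequence[tuple[np.ndarray, float]],
                  rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant-with-jitter termination profile.

    Half the gray mass goes to the ``end_a`` vertex block, half to the
    end-B blocks with the given mass shares (summing to 1), enforced
    exactly by block rescaling.
    """
    gray = np.zeros(geometry.n_vertices)
    if len(end_a) == 0:
        raise InvalidSpecError("empty endpoint vertex block")
    gray[end_a] = rng.uniform(0.8, 1.2, size=len(end_a))
    _block_scaled(gray, end_a, 0.5)
    for idx, share in end_b_blocks:
        if len(idx) == 0 and share > 0:
            raise InvalidSpecError("empty endpoint vertex block")
        gray[idx] = rng.uniform(0.8, 1.2, size=len(idx))
        _block_scaled(gray, idx, 0.5 * share)
    peak = gray.max()
    if peak > 0:
        gray /= peak
    return gray


def make_bundles(geometry: CohortGeometry, spec: CohortSpec, species: str,
                 hemisphere: str, rng: np.random.Generator | None = None,
                 ofc_fraction_override: Mapping[str, float] | None = None,
                 ) -> list[GroundTruthBundle]:
    """Plant one ATF bundle, one OTF bundle, and ``spec.n_distractors``
    distractor bundles on the requested hemisphere.

    For ATF/OTF, prefrontal gray mass is allocated to OFC vs PFC_OTHER so
    the OFC share equals the species' ``ofc_fraction`` (or the per-class
    override, used by :func:`make_cohort` for hemisphere random effects).
    """
    sp = spec.species(species)
    if hemisphere not in HEMISPHERES:
        raise DomainError(f"unknown hemisphere {hemisphere!r}")
    if rng is None:
        # standalone determinism: derive from spec seed + identity
        # (crc32 is a process-stable string hash, unlike builtin hash())
        ss = np.random.SeedSequence(
            [spec.seed, zlib.crc32(species.encode()),
             HEMISPHERES.index(hemisphere)])
        rng = np.random.default_rng(ss)

    bundles: list[GroundTruthBundle] = []
    for cls in ("ATF", "OTF"):
        f = sp.fraction_for(cls)
        if ofc_fraction_override is not None:
            f = float(ofc_fraction_override[cls])
        if not 0.0 <= f <= 1.0:
            raise InvalidSpecError(f"ofc_fraction {f} outside [0, 1]")
        end_a_parcel = "TEMPORAL_POLE" if cls == "ATF" else "OCCIPITAL"
        gray = _gray_profile(
            geometry, geometry.vertices_of(end_a_parcel, hemisphere),
            [(geometry.vertices_of("OFC", hemisphere), f),
             (geometry.vertices_of("PFC_OTHER", hemisphere), 1.0 - f)], rng)
        waypts = [_ANCHORS[end_a_parcel], *_WAYPOINTS[cls], _ANCHORS["PFC"]]
        white = _tract_core(geometry, waypts, spec.bundle_width, rng)
        bundles.append(GroundTruthBundle(cls, cls, gray, white, f,
                                         species=species,
                                         hemisphere=hemisphere))

    # Distractor endpoints take disjoint sub-parcel patches: when several
    # distractors terminate in the same parcel, each receives its own
    # contiguous slice of that parcel's vertices. Whole-parcel endpoints
    # shared across bundles make the factorization non-identifiable
    # (bundle mass can be reshuffled among components without changing
    # the product); focal patches also better resemble real termination
    # fields.
    pairs = [_DISTRACTOR_PAIRS[i % len(_DISTRACTOR_PAIRS)]
             for i in range(spec.n_distractors)]
    uses: dict[str, int] = {}
    for a, b in pairs:
        uses[a] = uses.get(a, 0) + 1
        uses[b] = uses.get(b, 0) + 1
    cursor: dict[str, int] = {p: 0 for p in uses}

    def _patch(parcel: str) -> np.ndarray:
        verts = geometry.vertices_of(parcel, hemisphere)
        m = uses[parcel]
        j = cursor[parcel]
        cursor[parcel] += 1
        lo = (j * len(verts)) // m
        hi = ((j + 1) * len(verts)) // m
        return verts[lo:hi] if hi > lo else verts

    for i, (a, b) in enumerate(pairs):
        gray = _gray_profile(geometry, _patch(a), [(_patch(b), 1.0)], rng)
        white = _tract_core(geometry, [_ANCHORS[a], _ANCHORS[b]],
                            spec.bundle_width, rng)
        bundles.append(GroundTruthBundle(f"D{i + 1}_{a}_{b}", "DISTRACTOR",
                                         gray, white, 0.0, species=species,
                                         hemisphere=hemisphere))
    return bundles


def sample_connectivity(geometry: CohortGeometry,
                        bundles: Sequence[GroundTruthBundle],
                        subject_gain: float,
                        noise_model: NoiseModel,
                        seed: int | np.random.Generator = 0,
                        subject_id: str = "", species: str = "",
                        hemisphere: str = "") -> ConnectivityMatrix:
    """Render a cohort member's visitation matrix.

    The noiseless signal is ``subject_gain * sum_k outer(gray_k, white_k)``.
    POISSON noise draws counts with mean ``scale * signal`` (scale 0 means
    no noise); TRUNCATED_GAUSSIAN adds N(0, scale) and clips at zero.
    """
    if subject_gain <= 0:
        raise InvalidSpecError("subject_gain must be positive")
    signal = np.zeros((geometry.n_vertices, geometry.n_voxels))
    for b in bundles:
        if (b.gray_loading.shape != (geometry.n_vertices,)
                or b.white_loading.shape != (geometry.n_voxels,)):
            raise ShapeError(
                f"bundle {b.bundle_id!r} does not match the geometry")
        signal += np.outer(b.gray_loading, b.white_loading)
    signal *= subject_gain

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if noise_model.scale == 0:
        values = signal
    elif noise_model.kind == "POISSON":
        values = rng.poisson(noise_model.scale * signal).astype(float)
    else:  # TRUNCATED_GAUSSIAN
        values = np.clip(
            signal + rng.normal(0.0, noise_model.scale, size=signal.shape),
            0.0, None)
    return ConnectivityMatrix(subject_id, species, hemisphere, values)


def _logit_perturb(f: float, delta: float) -> float:
    """Perturb a fraction on the log-odds scale; fixed points 0 and 1."""
    if f <= 0.0 or f >= 1.0 or delta == 0.0:
        return f
    return float(1.0 / (1.0 + np.exp(-(np.log(f / (1 - f)) + delta))))


def make_cohort(spec: CohortSpec, geometry: CohortGeometry
                ) -> tuple[list[ConnectivityMatrix], list[GroundTruthBundle]]:
    """Generate one connectivity matrix per subject x hemisphere, with
    hemisphere-level random effects on the OFC fraction, and return the
    realized ground-truth bundles for benchmarking."""
    root = np.random.SeedSequence(spec.seed)
    matrices: list[ConnectivityMatrix] = []
    truth: list[GroundTruthBundle] = []
    units = [(sp, s, hemi) for sp in spec.species_list
             for s in range(sp.n_subjects) for hemi in HEMISPHERES]
    children = root.spawn(len(units))
    for (sp, s, hemi), child in zip(units, children):
        rng = np.random.default_rng(child)
        subject_id = f"{sp.name}_{s + 1}"
        delta = rng.normal(0.0, spec.hemisphere_sd) if spec.hemisphere_sd > 0 else 0.0
        override = {cls: _logit_perturb(sp.fraction_for(cls), delta)
                    for cls in ("ATF", "OTF")}
        bundles = make_bundles(geometry, spec, sp.name, hemi, rng=rng,
                               ofc_fraction_override=override)
        for b in bundles:
            b.subject_id = subject_id
        gain = spec.subject_gain * (
            np.exp(rng.normal(0.0, spec.gain_sd)) if spec.gain_sd > 0 else 1.0)
        matrices.append(sample_connectivity(
            geometry, bundles, gain, spec.noise_model, seed=rng,
            subject_id=subject_id, species=sp.name, hemisphere=hemi))
        truth.extend(bundles)
    return matrices, truth


def mirror_to_canonical(values: np.ndarray, geometry: CohortGeometry,
                        hemisphere: str) -> np.ndarray:
    """Map a subject-hemisphere matrix (or per-vertex vector) into the
    canonical left-indexed frame by swapping vertex-index halves for
    RIGHT-hemisphere data. Labels are hemisphere-symmetric by
    construction, so parcels are preserved."""
    if hemisphere == "LEFT":
        return values
    if hemisphere != "RIGHT":
        raise DomainError(f"unknown hemisphere {hemisphere!r}")
    half = geometry.n_half
    out = np.empty_like(values)
    out[:half] = values[half:]
    out[half:] = values[:half]
    return out
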
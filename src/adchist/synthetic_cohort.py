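"""Synthetic cohorts of voxel-level ADC values.

Emulates a 73-patient parotid-tumor cohort (30 pleomorphic adenomas, 22
Warthin tumors, 21 malignant tumors) whose class-conditional voxel
distributions carry the qualitative structure reported for these entities:
Warthin tumors concentrate at low ADC; pleomorphic adenomas sit high with a
negative (left) skew; malignant tumors sit in between with a positive
(right) skew, modeled mechanistically as a mixture of a dominant densely
cellular (low-ADC) population and a minority necrotic (high-ADC) population.

Each class is a finite mixture of truncated-at-zero normal components on the
10^-6 mm^2/s ADC scale. Mixtures encode the two-population skewness story
directly and their moments have closed forms, which the tests use as
oracles. The numeric locations and scales are this package's own choices —
no published per-class ADC summaries stand behind them — and are plain
configuration.

Voxels are drawn i.i.d. within a patient (no spatial correlation): every
downstream computation is histogram-based, so spatial structure would be
invisible to it; the map/mask round trip is value-preserving regardless.

``overlap_factor`` interpolates every class spec toward one common
truncated normal at the grand mean: 0 keeps the defaults, 1 makes the three
class distributions coincide exactly (the chance-level stress test for any
classifier built on them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binning import CLASSES
from .data_io import Cohort, PatientSample
from .errors import ValidationError

#: Scale of the common component that ``overlap_factor`` interpolates toward.
COMMON_SCALE = 300.0


@dataclass(frozen=True)
class ClassGeneratorSpec:
    """A finite mixture of truncated-at-zero normal components for one class.

    ``components`` is a tuple of ``(weight, location, scale)`` triples;
    weights are positive and sum to one, scales positive. Locations and
    scales are on the 10^-6 mm^2/s ADC scale.
    """

    tumor_class: str
    components: tuple

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(loc), float(s))
                      for w, loc, s in self.components)
        object.__setattr__(self, "components", comps)
        if self.tumor_class not in CLASSES:
            raise ValidationError(f"unknown tumor class {self.tumor_class!r}")
        if not comps:
            raise ValidationError("mixture needs at least one component")
        weights = np.array([w for w, _, _ in comps])
        if np.any(weights <= 0):
            raise ValidationError("mixture weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights sum to {weights.sum()!r}, not 1")
        if any(s <= 0 for _, _, s in comps):
            raise ValidationError("mixture scales must be positive")

    def mixture_mean(self) -> float:
        """Closed-form mixture mean, ignoring the (negligible) truncation.

        Every default component sits at least 5 standard deviations above
        zero, so the truncated and untruncated moments agree to far better
        than the tolerances any test uses.
        """
        return sum(w * loc for w, loc, _ in self.components)

    def mixture_third_central_moment(self) -> float:
        """Closed-form third central moment (skewness sign), untruncated."""
        mu = self.mixture_mean()
        return sum(w * ((loc - mu) ** 3 + 3 * (loc - mu) * s ** 2)
                   for w, loc, s in self.components)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` voxels; negative draws are redrawn within their component."""
        weights = np.array([w for w, _, _ in self.components])
        locs = np.array([loc for _, loc, _ in self.components])
        scales = np.array([s for _, _, s in self.components])
        comp = rng.choice(len(weights), size=n, p=weights)
        values = rng.normal(locs[comp], scales[comp])
        negative = values < 0
        while negative.any():
            values[negative] = rng.normal(locs[comp[negative]],
                                          scales[comp[negative]])
            negative = values < 0
        return values


def default_class_specs() -> dict:
    """The default class-conditional mixtures.

    WT: one low component; PA: dominant high component plus a lighter lower
    one (left skew); MT: dominant low-ADC cellular component plus a minority
    high-ADC necrotic component (right skew). Mixture means order
    WT (850) < MT (1140) < PA (1845).
    """
    return {
        "PA": ClassGeneratorSpec("PA", ((0.85, 1950.0, 200.0),
                                        (0.15, 1250.0, 250.0))),
        "WT": ClassGeneratorSpec("WT", ((1.0, 850.0, 120.0),)),
        "MT": ClassGeneratorSpec("MT", ((0.80, 950.0, 150.0),
                                        (0.20, 1900.0, 300.0))),
    }


def apply_overlap(specs: Mapping[str, ClassGeneratorSpec],
                  overlap_factor: float) -> dict:
    """Interpolate all class specs toward one common component.

    At factor ``f`` (clamped to [0, 1]) each component keeps weight
    ``w*(1-f)``, its location moves a fraction ``f`` of the way to the grand
    mean of the class mixture means, and its scale toward ``COMMON_SCALE``;
    a shared component ``(f, grand_mean, COMMON_SCALE)`` absorbs the rest of
    the weight. At ``f = 1`` every class is exactly the same single
    truncated normal.
    """
    if overlap_factor < 0:
        raise ValidationError("overlap_factor must be non-negative")
    f = min(float(overlap_factor), 1.0)
    if f == 0:
        return dict(specs)
    grand = float(np.mean([specs[c].mixture_mean() for c in CLASSES]))
    out = {}
    for c in CLASSES:
        comps = [(w * (1 - f), loc + f * (grand - loc),
                  (1 - f) * s + f * COMMON_SCALE)
                 for w, loc, s in specs[c].components if w * (1 - f) > 0]
        comps.append((f, grand, COMMON_SCALE))
        out[c] = ClassGeneratorSpec(c, tuple(comps))
    return out


@dataclass(frozen=True)
class CohortGeneratorConfig:
    """Study-condition knobs for cohort generation.

    Defaults emulate the 73-patient cohort composition (30 PA / 22 WT /
    21 MT). The lower voxel bound of 50 corresponds to the smallest eligible
    lesion (~1 cm^3) at a 2x2x5 mm voxel size.
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"PA": 30, "WT": 22, "MT": 21})
    voxel_count_range: tuple = (50, 5000)
    seed: int = 0
    class_specs: Mapping[str, ClassGeneratorSpec] | None = None
    overlap_factor: float = 0.0

    def __post_init__(self) -> None:
        for c in CLASSES:
            if c not in self.n_per_class:
                raise ValidationError(f"n_per_class missing class {c}")
            if self.n_per_class[c] < 0:
                raise ValidationError(f"n_per_class[{c}] must be >= 0")
        lo, hi = self.voxel_count_range
        if lo < 1 or hi < lo:
            raise ValidationError(
                f"invalid voxel_count_range {self.voxel_count_range}"
            )

    def resolved_specs(self) -> dict:
        base = dict(self.class_specs) if self.class_specs else default_class_specs()
        return apply_overlap(base, self.overlap_factor)


def generate_cohort(config: CohortGeneratorConfig | None = None) -> Cohort:
    """Generate a reproducible synthetic cohort.

    Patients are generated class by class in the fixed order PA, WT, MT with
    ids like ``PA-01``; each patient's voxel count is uniform on the
    (inclusive) ``voxel_count_range`` and its voxels are i.i.d. draws from
    the class mixture. The same seed always yields the same cohort.
    """
    config = config or CohortGeneratorConfig()
    rng = np.random.default_rng(config.seed)
    specs = config.resolved_specs()
    lo, hi = config.voxel_count_range
    samples = []
    for c in CLASSES:
        for j in range(config.n_per_class[c]):
            n_vox = int(rng.integers(lo, hi + 1))
            voxels = specs[c].sample(n_vox, rng)
            samples.append(PatientSample(patient_id=f"{c}-{j + 1:02d}",
                                         true_class=c, voxels=voxels))
    return Cohort(samples=tuple(samples))


def generate_map_and_mask(patient: PatientSample,
                          grid_shape: tuple = (32, 32, 16),
                          seed: int = 0,
                          background: tuple = (1100.0, 150.0)) -> tuple:
    """Embed a patient's voxels in a 3-D ADC map under an ellipsoidal VOI.

    The mask is the set of grid points closest to the grid center in
    normalized ellipsoidal distance, trimmed deterministically to exactly the
    patient's voxel count; the patient's values are placed at mask positions
    in row-major order, so mask extraction recovers them exactly (order
    included). Background voxels are parenchyma-like truncated-normal draws.
    """
    n = patient.voxels.size
    volume = int(np.prod(grid_shape))
    if volume < n:
        raise ValidationError(
            f"grid {grid_shape} holds {volume} voxels < patient's {n}"
        )
    rng = np.random.default_rng(seed)
    mean, sd = background
    bg = rng.normal(mean, sd, size=volume)
    negative = bg < 0
    while negative.any():
        bg[negative] = rng.normal(mean, sd, size=int(negative.sum()))
        negative = bg < 0
    adc_map = bg.reshape(grid_shape)

    coords = np.indices(grid_shape).reshape(len(grid_shape), -1).T
    center = (np.asarray(grid_shape) - 1) / 2.0
    half = np.asarray(grid_shape) / 2.0
    dist = np.sum(((coords - center) / half) ** 2, axis=1)
    # stable sort: ties broken by flat (row-major) index
    chosen = np.sort(np.argsort(dist, kind="stable")[:n])
    mask = np.zeros(volume, dtype=np.int16)
    mask[chosen] = 1
    flat = adc_map.ravel()
    flat[chosen] = patient.voxels
    return flat.reshape(grid_shape), mask.reshape(grid_shape)
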
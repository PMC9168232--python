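"""Synthetic-cohort generator with controllable, known ground truth.

Emulates the structure of a multi-modal imaging + multi-omics disease cohort:
several imaging modalities per scan, a variable number of scans per subject
(1 + Poisson), several omics types of very different dimensionality, severe
class imbalance, and class-informative signal confined to chosen omics types
and/or imaging modalities.

Generative model (all draws from one seeded generator):

* each subject gets a class label ~ Bernoulli(1 - pi) (pi = majority-class
  fraction) and a latent factor vector z ~ N(0, I_d) shared by every data
  type of that subject;
* a scan's connectivity matrix is a fixed modality template plus a
  class-specific rank-one component scaled by the modality's effect size,
  plus a subject component driven by z, plus per-scan noise — symmetrized
  with unit diagonal and vectorized to the strict upper triangle;
* an omics feature is a shared baseline profile (large variance, so subjects
  correlate strongly, as real methylation/expression panels do), plus a
  symmetric class mean shift of the stated effect size on a random 10% of
  features when the type is informative, plus a weak subject-latent term and
  i.i.d. noise.

The subject-latent term makes every population omics graph carry subject
similarity structure even when the type is uninformative; the baseline
profile keeps inter-subject correlations high so the WGCNA powering has
contrast to work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgraphs import ConnectivityFeatures, OmicsTable, ScanManifest
from .training import DataBundle

__all__ = [
    "ModalitySpec",
    "OmicsSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "desk_scale_config",
    "null_config",
    "write_cohort",
    "upper_triangle",
    "square_from_upper",
]

# relative scales of the generative components, in units of the feature noise sd
_OMICS_BASELINE_SCALE = 2.0   # shared profile: inter-subject corr ~ 0.7-0.8
_OMICS_LATENT_SCALE = 0.15    # subject-latent loading
_CONN_SUBJECT_SCALE = 1.0     # subject component of connectivity
_INFORMATIVE_FRACTION = 0.1   # share of features carrying the class shift


@dataclass(frozen=True)
class ModalitySpec:
    name: str
    noise_sd: float = 1.0
    class_effect_size: float = 0.0

    def __post_init__(self):
        if self.noise_sd <= 0 or self.class_effect_size < 0:
            raise ValueError(f"modality {self.name!r}: invalid scales")


@dataclass(frozen=True)
class OmicsSpec:
    name: str
    n_features: int
    informative: bool = False
    effect_size: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.n_features < 2:
            raise ValueError(f"omics {self.name!r}: need >= 2 features")
        if self.noise_sd <= 0 or self.effect_size < 0:
            raise ValueError(f"omics {self.name!r}: invalid scales")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_subjects: int = 120
    imbalance: float = 0.75  # majority-class fraction pi
    atlas_size: int = 20
    modalities: tuple = (ModalitySpec("dti"), ModalitySpec("fmri"))
    omics_types: tuple = (
        OmicsSpec("mirna", 50),
        OmicsSpec("met", 200),
        OmicsSpec("snp", 500),
    )
    scans_per_subject_mean: float = 1.5
    latent_dim: int = 8

    def __post_init__(self):
        if not (0.0 < self.imbalance < 1.0):
            raise ValueError("imbalance must lie in (0, 1)")
        if self.atlas_size < 4:
            raise ValueError("atlas_size must be >= 4")
        if self.scans_per_subject_mean < 1.0:
            raise ValueError("scans_per_subject_mean must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class SyntheticCohort:
    manifest: ScanManifest
    connectivity: list  # of ConnectivityFeatures
    omics: list  # of OmicsTable
    truth: dict

    def bundle(self) -> DataBundle:
        return DataBundle(self.manifest, self.connectivity, self.omics)


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle, row-major over pairs (i < j), 0-based regions."""
    m = np.asarray(matrix)
    r = m.shape[0]
    iu = np.triu_indices(r, k=1)
    return m[iu]


def square_from_upper(vector: np.ndarray, atlas_size: int,
                      diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric R x R matrix from its strict upper triangle."""
    out = np.full((atlas_size, atlas_size), diagonal)
    iu = np.triu_indices(atlas_size, k=1)
    out[iu] = vector
    out[(iu[1], iu[0])] = vector
    return out


def _symmetric(rng: np.random.Generator, r: int) -> np.ndarray:
    m = rng.standard_normal((r, r))
    return (m + m.T) / np.sqrt(2.0)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort; bitwise reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    s, d, r = config.n_subjects, config.latent_dim, config.atlas_size

    labels = (rng.random(s) >= config.imbalance).astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() == 0:
        raise ValueError(
            f"degenerate draw: class counts {counts.tolist()} — a class is "
            f"empty at imbalance {config.imbalance} with {s} subjects"
        )
    z = rng.standard_normal((s, d))
    scans_per_subject = 1 + rng.poisson(config.scans_per_subject_mean - 1.0, size=s)

    subject_ids = [f"sub{i:04d}" for i in range(s)]
    scan_ids, scan_subject, scan_labels, scan_subject_index = [], [], [], []
    for i in range(s):
        for j in range(scans_per_subject[i]):
            scan_ids.append(f"{subject_ids[i]}_scan{j}")
            scan_subject.append(subject_ids[i])
            scan_labels.append(int(labels[i]))
            scan_subject_index.append(i)
    scan_subject_index = np.asarray(scan_subject_index)
    p = len(scan_ids)
    manifest = ScanManifest(
        tuple(scan_ids), tuple(scan_subject), tuple(scan_labels)
    )

    # class sign: symmetric +/- 1/2 so both classes shift by half the effect
    csign = labels - 0.5

    connectivity = []
    for spec in config.modalities:
        template = _symmetric(rng, r)
        g = rng.standard_normal(r)
        class_pattern = np.outer(g, g)
        off = upper_triangle(class_pattern)
        class_pattern /= off.std() if off.std() > 0 else 1.0
        subject_basis = np.stack([_symmetric(rng, r) for _ in range(d)])
        subject_comp = np.einsum("sd,dij->sij", z, subject_basis) / np.sqrt(d)
        rows = np.empty((p, r * (r - 1) // 2))
        for q in range(p):
            i = scan_subject_index[q]
            noise = _symmetric(rng, r) * spec.noise_sd
            mat = (
                template
                + spec.class_effect_size * spec.noise_sd * csign[i] * class_pattern
                + _CONN_SUBJECT_SCALE * spec.noise_sd * subject_comp[i]
                + noise
            )
            mat = (mat + mat.T) / 2.0
            np.fill_diagonal(mat, 1.0)
            rows[q] = upper_triangle(mat)
        connectivity.append(ConnectivityFeatures(spec.name, rows, r))

    omics = []
    informative_features: dict[str, np.ndarray] = {}
    for spec in config.omics_types:
        k = spec.n_features
        sd = spec.noise_sd
        baseline = rng.standard_normal(k) * _OMICS_BASELINE_SCALE * sd
        loadings = rng.standard_normal((d, k)) / np.sqrt(d)
        table = (
            baseline[None, :]
            + _OMICS_LATENT_SCALE * sd * (z @ loadings)
            + rng.standard_normal((s, k)) * sd
        )
        if spec.informative and spec.effect_size > 0:
            n_inf = max(1, int(round(_INFORMATIVE_FRACTION * k)))
            idx = rng.choice(k, size=n_inf, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_inf)
            shift = np.zeros(k)
            shift[idx] = spec.effect_size * sd * signs
            table = table + csign[:, None] * shift[None, :]
            informative_features[spec.name] = np.sort(idx)
        omics.append(
            OmicsTable(
                spec.name,
                table,
                tuple(subject_ids),
                tuple(f"{spec.name}_f{j}" for j in range(k)),
            )
        )

    truth = {
        "subject_ids": tuple(subject_ids),
        "labels": labels,
        "latent": z,
        "scans_per_subject": scans_per_subject,
        "informative_omics": tuple(
            o.name for o in config.omics_types if o.informative and o.effect_size > 0
        ),
        "informative_modalities": tuple(
            m.name for m in config.modalities if m.class_effect_size > 0
        ),
        "informative_features": informative_features,
        "majority_fraction": float(counts.max() / s),
    }
    return SyntheticCohort(manifest, connectivity, omics, truth)


def desk_scale_config(
    seed: int,
    informative_omics: tuple = ("snp",),
    omics_effect: float = 2.0,
    imaging_effect: float = 0.0,
) -> SimulationConfig:
    """The desk-scale preset: 120 subjects, 20 regions, two modalities, three
    omics types (50/200/500 features), majority fraction 0.75, ~1.5 scans per
    subject.  By default the class signal lives in one omics type only."""
    return SimulationConfig(
        seed=seed,
        modalities=(
            ModalitySpec("dti", class_effect_size=imaging_effect),
            ModalitySpec("fmri", class_effect_size=imaging_effect),
        ),
        omics_types=(
            OmicsSpec("mirna", 50, informative="mirna" in informative_omics,
                      effect_size=omics_effect),
            OmicsSpec("met", 200, informative="met" in informative_omics,
                      effect_size=omics_effect),
            OmicsSpec("snp", 500, informative="snp" in informative_omics,
                      effect_size=omics_effect),
        ),
    )


def null_config(seed: int) -> SimulationConfig:
    """Desk-scale preset with every effect size zero (no class signal)."""
    return desk_scale_config(seed, informative_omics=(), omics_effect=0.0,
                             imaging_effect=0.0)


def write_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write the cohort in the external formats the readers consume.

    Layout: ``manifest.tsv`` (scan_id, subject_id, label, one path column per
    modality), ``connectivity/<modality>/<scan_id>.tsv`` square matrices with
    region labels, ``omics_<type>.tsv`` subject tables.  Values carry 10
    significant digits, which bounds the round-trip error.
    """
    from . import cli_io  # local import to avoid a cycle

    cli_io.write_cohort_tree(cohort, directory)
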
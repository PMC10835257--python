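"""Feature-table container and synthetic cohort generator.

The modeling stack exchanges a single object, :class:`FeatureTable`: a
patients x features real matrix with optional primary-site labels and
optional clinical covariates (sex, age, HPV status).

Because the MRI cohort the method was designed for is not publicly
deposited, :func:`generate_cohort` emulates its statistical structure at the
feature-table level: four imbalanced primary-site classes (HL, OC, OPC,
NPC), a minority of class-informative features among many uninformative
ones, blocks of strongly inter-correlated features (radiomic features within
a family are highly redundant), and clinical covariates with class-dependent
prevalence (HPV positivity enriched in the nasopharynx class).
:func:`generate_replicate` emulates a second reading of each feature under a
small region-of-interest perturbation, with a controllable target
reliability, so that the ICC-based stability filter has something real to
measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import build_feature_catalog

CLASSES = ("HL", "OC", "OPC", "NPC")
MERGED_CLASSES = ("Fusion", "OPC", "NPC")
CLINICAL_COLUMNS = ("sex", "age", "hpv")

#: Primary-site class sizes of the cohort the pipelines were designed for.
DEFAULT_CLASS_SIZES = {"HL": 38, "OC": 63, "OPC": 162, "NPC": 137}


@dataclass
class ClinicalSpec:
    """Per-class distributions of the clinical covariates.

    ``hpv_prevalence`` and ``male_ratio`` are Bernoulli success
    probabilities; ``age_mean``/``age_sd`` are in years.  Defaults put a
    clear HPV enrichment in the nasopharynx class, a weaker one in the
    oropharynx class, and keep sex and age only mildly class-dependent.
    """

    hpv_prevalence: dict[str, float] = field(
        default_factory=lambda: {"HL": 0.30, "OC": 0.35, "OPC": 0.70, "NPC": 0.85}
    )
    male_ratio: dict[str, float] = field(
        default_factory=lambda: {"HL": 0.60, "OC": 0.50, "OPC": 0.45, "NPC": 0.50}
    )
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"HL": 60.0, "OC": 58.0, "OPC": 56.0, "NPC": 52.0}
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: {c: 11.0 for c in CLASSES}
    )


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Parameters
    ----------
    class_sizes
        Patients per primary-site class; defaults to the 38/63/162/137
        imbalance of the design cohort (400 patients).
    n_features
        Number of radiomic feature columns, named from the feature catalog
        (T1w first, then T2w); at most 1072.
    n_informative
        Leading features given class-dependent means (the planted signal).
    effect_size
        Scale (in within-class SD units) of the class mean shifts.
    n_redundant_blocks, block_size, rho_block
        Blocks of features sharing a latent factor, giving pairwise
        correlation ~= ``rho_block`` within each block.
    replicate_icc
        Default target reliability used by :func:`generate_replicate`.
    fusion_separable
        If True, plant a hierarchical signal: the first ~2/3 of the
        informative features separate the merged minority group (HL+OC)
        from OPC and NPC but carry no HL-vs-OC information, while the
        remaining informative features separate HL from OC only (at
        ``fine_effect_ratio`` times the coarse effect; by default the fine
        split is as well-expressed as the coarse one, so any advantage of
        a two-step cascade comes from routing and dedicated minority
        reclassification, not from feature availability).
    fine_effect_ratio
        Strength of the HL-vs-OC features relative to ``effect_size``
        (only used with ``fusion_separable``).
    """

    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    n_features: int = 536
    n_informative: int = 20
    effect_size: float = 1.0
    n_redundant_blocks: int = 10
    block_size: int = 5
    rho_block: float = 0.9
    replicate_icc: float = 0.85
    clinical_spec: ClinicalSpec = field(default_factory=ClinicalSpec)
    fusion_separable: bool = False
    fine_effect_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.class_sizes) != set(CLASSES):
            raise ValueError(f"class_sizes must have exactly the classes {CLASSES}")
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("all class counts must be positive")
        if not 0.0 <= self.replicate_icc <= 1.0:
            raise ValueError("replicate_icc must be in [0, 1]")
        if not 0.0 <= self.rho_block < 1.0:
            raise ValueError("rho_block must be in [0, 1)")
        n_structured = self.n_informative + self.n_redundant_blocks * self.block_size
        if n_structured > self.n_features:
            raise ValueError("informative + block features exceed n_features")
        if self.n_features > 1072:
            raise ValueError("at most 1072 catalog feature names are available")

    @property
    def n_patients(self) -> int:
        return sum(self.class_sizes.values())


class FeatureTable:
    """Patients x named features, with optional labels and clinical columns.

    Attributes
    ----------
    features : pandas.DataFrame
        Real-valued matrix; index = unique patient ids, columns = unique
        feature names.
    labels : pandas.Series or None
        Primary-site class per patient; either the four-class set
        (HL/OC/OPC/NPC) or the merged three-class set (Fusion/OPC/NPC).
    clinical : pandas.DataFrame or None
        Columns ``sex`` (binary), ``age`` (years), ``hpv`` (binary).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: pd.Series | None = None,
        clinical: pd.DataFrame | None = None,
    ) -> None:
        if features.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        if features.columns.has_duplicates:
            raise ValueError("duplicate feature names")
        if not np.isfinite(features.to_numpy(dtype=float)).all():
            raise ValueError("feature values must be finite")
        if labels is not None:
            labels = labels.reindex(features.index)
            if labels.isna().any():
                raise ValueError("labels missing for some patients")
            seen = set(labels.unique())
            if not (seen <= set(CLASSES) or seen <= set(MERGED_CLASSES)):
                raise ValueError(f"unknown class labels: {seen}")
        if clinical is not None:
            clinical = clinical.reindex(features.index)
            missing = set(CLINICAL_COLUMNS) - set(clinical.columns)
            if missing:
                raise ValueError(f"clinical table missing columns {sorted(missing)}")
            clinical = clinical[list(CLINICAL_COLUMNS)]
        self.features = features
        self.labels = labels
        self.clinical = clinical

    # -- basic geometry ---------------------------------------------------
    @property
    def patient_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_patients(self) -> int:
        return len(self.features.index)

    @property
    def n_features(self) -> int:
        return len(self.features.columns)

    # -- derivation -------------------------------------------------------
    def select_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        return FeatureTable(self.features[names].copy(), self._lab(), self._clin())

    def subset_rows(self, indices: np.ndarray | list[int]) -> "FeatureTable":
        f = self.features.iloc[list(indices)].copy()
        lab = self.labels.iloc[list(indices)].copy() if self.labels is not None else None
        cl = self.clinical.iloc[list(indices)].copy() if self.clinical is not None else None
        return FeatureTable(f, lab, cl)

    def with_labels(self, labels: pd.Series) -> "FeatureTable":
        return FeatureTable(self.features.copy(), labels, self._clin())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self._lab(), self._clin())

    def _lab(self) -> pd.Series | None:
        return self.labels.copy() if self.labels is not None else None

    def _clin(self) -> pd.DataFrame | None:
        return self.clinical.copy() if self.clinical is not None else None

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write one CSV: patient_id, label, sex, age, hpv, then features."""
        out = self.features.copy()
        front = []
        if self.clinical is not None:
            for c in reversed(CLINICAL_COLUMNS):
                out.insert(0, c, self.clinical[c])
            front = list(CLINICAL_COLUMNS)
        if self.labels is not None:
            out.insert(0, "label", self.labels)
        out.index.name = "patient_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="patient_id")
        df.index = df.index.astype(str)
        labels = df.pop("label") if "label" in df.columns else None
        clinical = None
        if all(c in df.columns for c in CLINICAL_COLUMNS):
            clinical = df[list(CLINICAL_COLUMNS)].copy()
            df = df.drop(columns=list(CLINICAL_COLUMNS))
        return cls(df, labels, clinical)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        same = self.features.equals(other.features)
        same &= (self.labels is None) == (other.labels is None)
        if same and self.labels is not None:
            same &= self.labels.equals(other.labels)
        same &= (self.clinical is None) == (other.clinical is None)
        if same and self.clinical is not None:
            same &= self.clinical.equals(other.clinical)
        return same


def _informative_means(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Class-mean matrix (4 classes x n_informative) of the planted signal."""
    means = np.zeros((len(CLASSES), spec.n_informative))
    if not spec.fusion_separable:
        means[:] = rng.normal(0.0, spec.effect_size, size=means.shape)
        return means
    # Hierarchical structure: coarse features separate {HL, OC} vs OPC vs
    # NPC with identical HL/OC means; fine features separate HL vs OC only.
    n_fine = max(2, spec.n_informative // 3)
    n_coarse = spec.n_informative - n_fine
    d = spec.effect_size
    coarse_patterns = [(d, -d, 0.0), (-d, 0.0, d), (0.0, d, -d)]
    for j in range(n_coarse):
        g_fusion, g_opc, g_npc = coarse_patterns[j % 3]
        means[0, j] = means[1, j] = g_fusion  # HL and OC share the mean
        means[2, j] = g_opc
        means[3, j] = g_npc
    d_f = spec.fine_effect_ratio * spec.effect_size
    for j in range(n_coarse, spec.n_informative):
        sign = 1.0 if (j - n_coarse) % 2 == 0 else -1.0
        means[0, j] = sign * d_f   # HL
        means[1, j] = -sign * d_f  # OC
    return means


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a synthetic cohort with the structure described by ``spec``.

    Feature layout: columns ``[0, n_informative)`` carry the planted
    class signal (unit within-class SD); the next
    ``n_redundant_blocks * block_size`` columns form correlated blocks
    (``x = sqrt(rho) * z_block + sqrt(1 - rho) * eps``); the remainder are
    independent standard-normal noise.  Feature names are taken from the
    radiomic catalog in order, so the table looks like a real extraction.
    The same spec (including seed) yields a bitwise-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    p = spec.n_features

    labels = np.concatenate([[c] * spec.class_sizes[c] for c in CLASSES])
    class_idx = np.concatenate(
        [[i] * spec.class_sizes[c] for i, c in enumerate(CLASSES)]
    )

    X = rng.normal(size=(n, p))
    means = _informative_means(spec, rng)
    X[:, : spec.n_informative] += means[class_idx, :]

    start = spec.n_informative
    for b in range(spec.n_redundant_blocks):
        z = rng.normal(size=n)
        cols = slice(start + b * spec.block_size, start + (b + 1) * spec.block_size)
        X[:, cols] = (
            np.sqrt(spec.rho_block) * z[:, None]
            + np.sqrt(1.0 - spec.rho_block) * X[:, cols]
        )

    names = build_feature_catalog({"T1w", "T2w"}).names[:p]
    ids = [f"P{i:04d}" for i in range(n)]
    features = pd.DataFrame(X, index=ids, columns=names)

    cs = spec.clinical_spec
    hpv = np.array([rng.random() < cs.hpv_prevalence[c] for c in labels], dtype=int)
    sex = np.array([rng.random() < cs.male_ratio[c] for c in labels], dtype=int)
    age = np.array(
        [rng.normal(cs.age_mean[c], cs.age_sd[c]) for c in labels]
    ).clip(18.0, 90.0).round(1)
    clinical = pd.DataFrame({"sex": sex, "age": age, "hpv": hpv}, index=ids)

    return FeatureTable(features, pd.Series(labels, index=ids), clinical)


def generate_replicate(
    table: FeatureTable, replicate_icc: float, seed: int
) -> FeatureTable:
    """Simulate a second reading of every feature at a target reliability.

    The replicate is the original column plus zero-mean Gaussian noise with
    variance ``2 * var(x) * (1 - icc) / icc``.  With readings ``(x, x + e)``
    the two-way mean-squares give an expected ICC(2,1) of
    ``var(x) / (var(x) + var(e)/2)``, so this noise level targets
    ``replicate_icc`` exactly in expectation.  ``replicate_icc = 1`` returns
    an identical table; ``replicate_icc = 0`` returns an independent reading
    with the same per-feature scale (ICC ~= 0).
    """
    if not 0.0 <= replicate_icc <= 1.0:
        raise ValueError("replicate_icc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    X = table.features.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if replicate_icc >= 1.0:
        rep = X.copy()
    elif replicate_icc <= 1e-9:
        rep = table.features.mean(axis=0).to_numpy() + rng.normal(size=X.shape) * sd
    else:
        noise_sd = sd * np.sqrt(2.0 * (1.0 - replicate_icc) / replicate_icc)
        rep = X + rng.normal(size=X.shape) * noise_sd
    features = pd.DataFrame(rep, index=table.features.index, columns=table.features.columns)
    return FeatureTable(features, table._lab(), table._clin())
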
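"""Student cohort data model, CSV I/O, feature scaling and synthetic cohorts.

A cohort is a table of students. Each student has a block-organised feature
vector (learning behaviour, social interaction, physical health, mental
state), an optional overall well-being label on [0, 1], optional labels for
the five PERMA dimensions (Positive emotions, Engagement, Relationships,
Meaning, Achievement), a cultural background identifier, a categorical
learning style, and an ordinal stress level.

The synthetic generator emulates the statistical structure the predictor
assumes: latent per-student PERMA factors drawn from culture-specific
truncated normals on [0, 1], bounded features produced by a nonnegative
block-aligned loading matrix plus noise, and an overall well-being label
equal to the mean of the five latent factors plus label noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

BLOCKS = ("learn", "social", "physical", "mental")
PERMA_DIMS = ("P", "E", "R", "M", "A")
STRESS_LEVELS = ("low", "medium", "high")

#: reserved (non-feature) CSV columns
PERMA_COLUMNS = tuple(f"perma_{p}" for p in PERMA_DIMS)
RESERVED_COLUMNS = ("wellbeing", *PERMA_COLUMNS, "culture", "learning_style", "stress_level")

#: default dominant PERMA dimension for each feature block
BLOCK_DOMINANT_DIM: Mapping[str, str] = {
    "learn": "E",
    "social": "R",
    "physical": "P",
    "mental": "M",
}


class CohortError(ValueError):
    """Raised for invalid cohort data or schema violations."""


@dataclass(frozen=True)
class FeatureSchema:
    """Names, block assignment and value range for each feature."""

    feature_names: tuple[str, ...]
    block_of: Mapping[str, str]
    value_range: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        names = tuple(self.feature_names)
        object.__setattr__(self, "feature_names", names)
        if len(set(names)) != len(names):
            raise CohortError("duplicate feature names")
        for name in names:
            if name in RESERVED_COLUMNS:
                raise CohortError(f"feature name {name!r} clashes with a reserved column")
            block = self.block_of.get(name)
            if block not in BLOCKS:
                raise CohortError(f"feature {name!r} has invalid block {block!r}")
            lo, hi = self.value_range[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise CohortError(f"feature {name!r} has invalid range ({lo}, {hi})")
        present = {self.block_of[n] for n in names}
        missing = set(BLOCKS) - present
        if missing:
            raise CohortError(f"empty feature blocks: {sorted(missing)}")

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def block_indices(self, block: str) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.feature_names) if self.block_of[n] == block],
            dtype=int,
        )

    def ranges_array(self) -> np.ndarray:
        """(d, 2) array of per-feature (min, max)."""
        return np.array([self.value_range[n] for n in self.feature_names], dtype=float)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "block_of": {n: self.block_of[n] for n in self.feature_names},
            "value_range": {n: list(self.value_range[n]) for n in self.feature_names},
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FeatureSchema":
        return cls(
            feature_names=tuple(payload["feature_names"]),
            block_of=dict(payload["block_of"]),
            value_range={k: (float(v[0]), float(v[1])) for k, v in payload["value_range"].items()},
        )


@dataclass(frozen=True)
class StudentRecord:
    """One student's features, labels and attributes."""

    features: np.ndarray
    culture: str
    learning_style: str
    stress_level: str
    wellbeing: float | None = None
    perma_labels: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        if self.stress_level not in STRESS_LEVELS:
            raise CohortError(f"invalid stress level {self.stress_level!r}")
        if self.wellbeing is not None and not (0.0 <= self.wellbeing <= 1.0):
            raise CohortError(f"wellbeing {self.wellbeing} outside [0, 1]")
        if self.perma_labels is not None:
            labels = np.asarray(self.perma_labels, dtype=float)
            if labels.shape != (5,):
                raise CohortError("perma_labels must have length 5")
            if np.any(labels < 0) or np.any(labels > 1):
                raise CohortError("perma labels outside [0, 1]")
            object.__setattr__(self, "perma_labels", labels)


@dataclass
class CohortTable:
    """A cohort: schema plus aligned per-student arrays.

    ``features`` is (n, d); labels are all-or-none per label type.
    """

    schema: FeatureSchema
    features: np.ndarray
    cultures: np.ndarray
    learning_styles: np.ndarray
    stress_levels: np.ndarray
    wellbeing: np.ndarray | None = None
    perma_labels: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != self.schema.d:
            raise CohortError(
                f"features shape {self.features.shape} does not match schema d={self.schema.d}"
            )
        n = self.features.shape[0]
        if n == 0:
            raise CohortError("cohort must contain at least one student")
        for name, arr in (
            ("cultures", self.cultures),
            ("learning_styles", self.learning_styles),
            ("stress_levels", self.stress_levels),
        ):
            arr = np.asarray(arr)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise CohortError(f"{name} must have length n={n}")
        if not set(np.unique(self.stress_levels)) <= set(STRESS_LEVELS):
            raise CohortError("stress levels must be low/medium/high")
        if self.wellbeing is not None:
            self.wellbeing = np.asarray(self.wellbeing, dtype=float)
            if self.wellbeing.shape != (n,):
                raise CohortError("wellbeing labels must have length n")
            _check_unit_interval(self.wellbeing, "wellbeing")
        if self.perma_labels is not None:
            self.perma_labels = np.asarray(self.perma_labels, dtype=float)
            if self.perma_labels.shape != (n, 5):
                raise CohortError("perma labels must have shape (n, 5)")
            _check_unit_interval(self.perma_labels, "perma labels")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def has_wellbeing(self) -> bool:
        return self.wellbeing is not None

    @property
    def has_perma(self) -> bool:
        return self.perma_labels is not None

    def record(self, i: int) -> StudentRecord:
        return StudentRecord(
            features=self.features[i],
            culture=str(self.cultures[i]),
            learning_style=str(self.learning_styles[i]),
            stress_level=str(self.stress_levels[i]),
            wellbeing=None if self.wellbeing is None else float(self.wellbeing[i]),
            perma_labels=None if self.perma_labels is None else self.perma_labels[i],
        )

    def permuted(self, perm: np.ndarray) -> "CohortTable":
        """Reorder students by ``perm`` (used for equivariance checks)."""
        return CohortTable(
            schema=self.schema,
            features=self.features[perm],
            cultures=self.cultures[perm],
            learning_styles=self.learning_styles[perm],
            stress_levels=self.stress_levels[perm],
            wellbeing=None if self.wellbeing is None else self.wellbeing[perm],
            perma_labels=None if self.perma_labels is None else self.perma_labels[perm],
        )

    def equals(self, other: "CohortTable", atol: float = 1e-9) -> bool:
        if self.schema.to_dict() != other.schema.to_dict():
            return False
        if self.has_wellbeing != other.has_wellbeing or self.has_perma != other.has_perma:
            return False
        same = np.allclose(self.features, other.features, atol=atol)
        same &= bool(np.all(self.cultures == other.cultures))
        same &= bool(np.all(self.learning_styles == other.learning_styles))
        same &= bool(np.all(self.stress_levels == other.stress_levels))
        if self.has_wellbeing:
            same &= np.allclose(self.wellbeing, other.wellbeing, atol=atol)
        if self.has_perma:
            same &= np.allclose(self.perma_labels, other.perma_labels, atol=atol)
        return bool(same)


def _check_unit_interval(values: np.ndarray, what: str) -> None:
    if np.any(~np.isfinite(values)) or np.any(values < 0) or np.any(values > 1):
        bad = np.argwhere((values < 0) | (values > 1) | ~np.isfinite(values))
        raise CohortError(f"{what} outside [0, 1] at positions {bad[:5].tolist()}")


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CultureSpec:
    """A cultural group: mixture proportion and latent factor distribution."""

    name: str
    proportion: float
    latent_mean: tuple[float, float, float, float, float]
    latent_sd: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort draw."""

    n: int
    schema: FeatureSchema
    cultures: tuple[CultureSpec, ...]
    loading: np.ndarray  # (d, 5) nonnegative ground-truth feature loadings
    feature_noise_sd: float = 0.05
    label_noise_sd: float = 0.05
    n_styles: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise CohortError("n must be positive")
        if self.n_styles < 1:
            raise CohortError("n_styles must be >= 1")
        props = np.array([c.proportion for c in self.cultures], dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise CohortError(f"culture proportions sum to {props.sum()}, not 1")
        loading = np.asarray(self.loading, dtype=float)
        if loading.shape != (self.schema.d, 5):
            raise CohortError(f"loading must be (d={self.schema.d}, 5)")
        if np.any(loading < 0):
            raise CohortError("loading matrix must be nonnegative")
        object.__setattr__(self, "loading", loading)
        if self.feature_noise_sd < 0 or self.label_noise_sd < 0:
            raise CohortError("noise sds must be nonnegative")
        # block alignment: dominant loading column must match the block's dimension
        dim_index = {p: k for k, p in enumerate(PERMA_DIMS)}
        for i, name in enumerate(self.schema.feature_names):
            dominant = int(np.argmax(loading[i]))
            expected = dim_index[BLOCK_DOMINANT_DIM[self.schema.block_of[name]]]
            if dominant != expected:
                raise CohortError(
                    f"feature {name!r}: dominant loading column {dominant} does not "
                    f"match its block's dimension {expected}"
                )


#: realistic 23-feature survey schema, 4 blocks, mirroring a work-life style
#: well-being questionnaire (all items rescaled to [0, 1] on generation)
_DEFAULT_FEATURES_23 = {
    "learn": (
        "daily_study_hours", "course_completion", "skill_development",
        "todo_completion", "flow_at_work", "personal_growth_rating",
    ),
    "social": (
        "close_friends", "social_events_per_month", "peer_support",
        "family_time", "helping_others", "community_belonging",
    ),
    "physical": (
        "sleep_hours", "exercise_sessions", "diet_quality",
        "daily_steps", "bmi_healthiness", "energy_level",
    ),
    "mental": (
        "optimism_rating", "calmness_rating", "self_esteem",
        "life_meaning_rating", "mindfulness_minutes",
    ),
}


def default_schema(d: int = 23) -> FeatureSchema:
    """A block-complete schema with ``d`` features (survey-style names for 23)."""
    if d == 23:
        names, blocks = [], {}
        for block, feats in _DEFAULT_FEATURES_23.items():
            for f in feats:
                names.append(f)
                blocks[f] = block
    else:
        if d < 4:
            raise CohortError("need at least one feature per block")
        names, blocks = [], {}
        for i in range(d):
            block = BLOCKS[i % 4]
            name = f"{block}_{i // 4 + 1:02d}"
            names.append(name)
            blocks[name] = block
    ranges = {n: (0.0, 1.0) for n in names}
    return FeatureSchema(tuple(names), blocks, ranges)


def default_loading(schema: FeatureSchema, dominant: float = 0.6, other: float = 0.1) -> np.ndarray:
    """Block-aligned loading matrix: ``dominant`` on the block's dimension."""
    loading = np.full((schema.d, 5), other, dtype=float)
    dim_index = {p: k for k, p in enumerate(PERMA_DIMS)}
    for i, name in enumerate(schema.feature_names):
        loading[i, dim_index[BLOCK_DOMINANT_DIM[schema.block_of[name]]]] = dominant
    return loading


#: two cultural groups with shifted latent well-being profiles
DEFAULT_CULTURES = (
    CultureSpec("western", 0.5, (0.62, 0.58, 0.60, 0.55, 0.58), 0.15),
    CultureSpec("east_asian", 0.5, (0.52, 0.56, 0.50, 0.58, 0.54), 0.15),
)


def default_spec(n: int = 512, d: int = 23, seed: int = 0, **overrides) -> SyntheticSpec:
    """The default synthetic cohort: two cultures, block-aligned loadings."""
    schema = overrides.pop("schema", default_schema(d))
    loading = overrides.pop("loading", default_loading(schema))
    return SyntheticSpec(
        n=n, schema=schema, cultures=overrides.pop("cultures", DEFAULT_CULTURES),
        loading=loading, seed=seed, **overrides,
    )


def preset_spec(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Named size presets: ``large`` (12757 x 23) and ``small`` (268 x 23)."""
    sizes = {"large": 12757, "small": 268}
    if name not in sizes:
        raise CohortError(f"unknown preset {name!r}; choose from {sorted(sizes)}")
    return default_spec(n=sizes[name], seed=seed, **overrides)


def _truncnorm01(mean: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Draw a synthetic cohort; bit-identical for identical spec (incl. seed).

    Latent PERMA factors pi_i in [0,1]^5 are drawn from the student's culture
    distribution; features are clip01(L @ pi + noise) then min-max rescaled
    per feature; perma labels equal the latents; the well-being label is
    clip01(mean(pi) + noise); stress level is the tertile of 1 - pi_P.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n, spec.schema.d

    # culture assignment by exact proportions (largest remainder), then shuffle
    counts = _apportion(n, [c.proportion for c in spec.cultures])
    culture_idx = np.repeat(np.arange(len(spec.cultures)), counts)
    rng.shuffle(culture_idx)
    cultures = np.array([spec.cultures[k].name for k in culture_idx])

    latents = np.empty((n, 5))
    for k, cspec in enumerate(spec.cultures):
        mask = culture_idx == k
        m = int(mask.sum())
        if m:
            mean = np.broadcast_to(np.asarray(cspec.latent_mean, dtype=float), (m, 5))
            latents[mask] = _truncnorm01(mean, cspec.latent_sd, rng)

    raw = latents @ spec.loading.T
    if spec.feature_noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.feature_noise_sd, size=(n, d))
    raw = np.clip(raw, 0.0, 1.0)
    # per-feature min-max rescale to fill [0, 1]
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    features = np.where(span > 0, (raw - lo) / np.where(span > 0, span, 1.0), 0.5)

    wellbeing = latents.mean(axis=1)
    if spec.label_noise_sd > 0:
        wellbeing = wellbeing + rng.normal(0.0, spec.label_noise_sd, size=n)
    wellbeing = np.clip(wellbeing, 0.0, 1.0)

    styles = np.array([f"style_{k}" for k in rng.integers(0, spec.n_styles, size=n)])
    stress = _tertile_levels(1.0 - latents[:, 0])

    return CohortTable(
        schema=spec.schema,
        features=features,
        cultures=cultures,
        learning_styles=styles,
        stress_levels=stress,
        wellbeing=wellbeing,
        perma_labels=latents,
    )


def _apportion(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer counts summing to n, proportional by largest remainder."""
    exact = np.asarray(proportions, dtype=float) * n
    counts = np.floor(exact).astype(int)
    order = np.argsort(-(exact - counts), kind="stable")
    for i in range(n - counts.sum()):
        counts[order[i % len(counts)]] += 1
    return counts


def _tertile_levels(score: np.ndarray) -> np.ndarray:
    """Rank-based tertiles of ``score``: low / medium / high stress."""
    n = len(score)
    ranks = np.argsort(np.argsort(score, kind="stable"), kind="stable")
    bounds = _apportion(n, [1 / 3, 1 / 3, 1 / 3])
    edges = np.cumsum(bounds)
    levels = np.empty(n, dtype=object)
    levels[ranks < edges[0]] = "low"
    levels[(ranks >= edges[0]) & (ranks < edges[1])] = "medium"
    levels[ranks >= edges[1]] = "high"
    return levels.astype(str)


# ---------------------------------------------------------------------------
# I/O and scaling
# ---------------------------------------------------------------------------

def write_cohort(table: CohortTable, table_path, schema_path) -> None:
    """Write the cohort CSV and schema JSON (lossless for read_cohort)."""
    df = pd.DataFrame(table.features, columns=list(table.schema.feature_names))
    if table.has_wellbeing:
        df["wellbeing"] = table.wellbeing
    if table.has_perma:
        for k, col in enumerate(PERMA_COLUMNS):
            df[col] = table.perma_labels[:, k]
    df["culture"] = table.cultures
    df["learning_style"] = table.learning_styles
    df["stress_level"] = table.stress_levels
    df.to_csv(table_path, index=False, float_format="%.15g")
    Path(schema_path).write_text(json.dumps(table.schema.to_dict(), indent=1))


def read_cohort(table_path, schema_path) -> CohortTable:
    """Read a cohort CSV + schema JSON written by :func:`write_cohort`."""
    schema = FeatureSchema.from_dict(json.loads(Path(schema_path).read_text()))
    df = pd.read_csv(table_path)
    missing = [c for c in schema.feature_names if c not in df.columns]
    if missing:
        raise CohortError(f"missing feature columns: {missing}")
    feats = df[list(schema.feature_names)]
    non_numeric = [c for c in feats.columns if not np.issubdtype(feats[c].dtype, np.number)]
    if non_numeric or feats.isna().any().any():
        raise CohortError(f"non-numeric or missing feature values in columns {non_numeric}")
    features = feats.to_numpy(dtype=float)

    wellbeing = None
    if "wellbeing" in df.columns and df["wellbeing"].notna().all():
        wellbeing = df["wellbeing"].to_numpy(dtype=float)
        _check_label_column(wellbeing, "wellbeing")
    perma = None
    if all(c in df.columns for c in PERMA_COLUMNS):
        block = df[list(PERMA_COLUMNS)]
        if block.notna().all().all():
            perma = block.to_numpy(dtype=float)
            for k, col in enumerate(PERMA_COLUMNS):
                _check_label_column(perma[:, k], col)

    def _col(name: str, default: str) -> np.ndarray:
        if name in df.columns:
            return df[name].astype(str).to_numpy()
        return np.full(len(df), default)

    return CohortTable(
        schema=schema,
        features=features,
        cultures=_col("culture", "unknown"),
        learning_styles=_col("learning_style", "style_0"),
        stress_levels=_col("stress_level", "medium"),
        wellbeing=wellbeing,
        perma_labels=perma,
    )


def _check_label_column(values: np.ndarray, column: str) -> None:
    bad = np.where((values < 0) | (values > 1))[0]
    if bad.size:
        raise CohortError(
            f"label column {column!r} outside [0, 1] at row {int(bad[0])} "
            f"(value {values[bad[0]]})"
        )


def scale_features(table: CohortTable) -> CohortTable:
    """Min-max scale features into [0, 1] using the schema's declared ranges.

    Degenerate (constant-range) declarations cannot occur by schema invariant;
    a feature column observed outside its declared range is an error. The
    returned table's schema declares (0, 1) ranges, so the map is idempotent.
    """
    ranges = table.schema.ranges_array()
    lo, hi = ranges[:, 0], ranges[:, 1]
    below = table.features < lo - 1e-12
    above = table.features > hi + 1e-12
    if below.any() or above.any():
        offenders = sorted(
            {table.schema.feature_names[j] for j in np.unique(np.argwhere(below | above)[:, 1])}
        )
        raise CohortError(f"features outside declared range: {offenders}")
    scaled = (table.features - lo) / (hi - lo)
    # guard: a column that is constant across the cohort maps to 0.5
    const = scaled.std(axis=0) == 0.0
    if const.any():
        scaled = scaled.copy()
        scaled[:, const] = 0.5
    new_schema = FeatureSchema(
        feature_names=table.schema.feature_names,
        block_of=dict(table.schema.block_of),
        value_range={n: (0.0, 1.0) for n in table.schema.feature_names},
    )
    return replace(table, schema=new_schema, features=scaled)
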
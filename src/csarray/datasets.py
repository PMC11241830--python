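"""Synthetic sensor-array datasets.

Emulates the data structure of a four-channel colorimetric sensor array
read out as RGB well means: every sample is a 12-dimensional dRGB vector
(4 channels x R,G,B).  Laboratory RGB readings for this kind of array are
rarely published, so these generators stand in for them in every test:
single-analyte saturation series, mixed-acid class grids, multi-class
fingerprint populations, and volumetric adulteration blends.

All generators are deterministic given a :class:`NoiseSpec` (parameters +
seed), and their noise-free expectations are simple closed forms that the
test suite asserts to machine precision.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

N_CHANNELS = 4
N_FEATURES = 12
CHANNEL_NAMES = tuple(f"S{i}" for i in range(1, N_CHANNELS + 1))
FEATURE_COLUMNS = tuple(f"{ch}_{c}" for ch in CHANNEL_NAMES for c in "RGB")
GAMUT = 255.0

#: Molar masses (g/mol) of the nine organic acids the array targets.
MOLAR_MASS_G_PER_MOL = {
    "benzoic": 122.12,
    "lactic": 90.08,
    "acetic": 60.05,
    "butyric": 88.11,
    "isobutyric": 88.11,
    "valeric": 102.13,
    "isovaleric": 102.13,
    "hexanoic": 116.16,
    "octanoic": 144.21,
}


def _as_feature_vector(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.full(N_FEATURES, float(arr[0]))
    if arr.shape != (N_FEATURES,):
        raise ValueError(
            f"{name} must be a scalar or a length-{N_FEATURES} vector, got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class AnalyteFingerprint:
    """Saturating dRGB fingerprint of one analyte.

    The expected response at concentration ``c`` (mmol/L) follows a Hill
    form per feature::

        r_k(c) = max_response_k * c**shape_k / (half_saturation_k**shape_k + c**shape_k)

    ``half_saturation`` and ``shape`` may be scalars or per-feature
    vectors; per-channel values model the four distinct reducing-agent
    chemistries saturating at different acid loads.  The Hill form is
    monotone, bounded by the color gamut, and linear at low concentration.
    """

    name: str
    max_response: np.ndarray
    half_saturation: np.ndarray | float
    shape: np.ndarray | float

    def __post_init__(self):
        object.__setattr__(self, "max_response", _as_feature_vector(self.max_response, "max_response"))
        object.__setattr__(self, "half_saturation", _as_feature_vector(self.half_saturation, "half_saturation"))
        object.__setattr__(self, "shape", _as_feature_vector(self.shape, "shape"))
        if np.any(self.half_saturation <= 0):
            raise ValueError("half_saturation must be strictly positive")
        if np.any(self.shape <= 0):
            raise ValueError("shape must be strictly positive")

    def expected_response(self, concentration: float) -> np.ndarray:
        """Noise-free dRGB response (12-vector) at one concentration."""
        c = float(concentration)
        if c < 0:
            raise ValueError(f"concentration must be non-negative, got {c}")
        if c == 0.0:
            return np.zeros(N_FEATURES)
        cs = c ** self.shape
        return self.max_response * cs / (self.half_saturation ** self.shape + cs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "max_response": self.max_response.tolist(),
            "half_saturation": self.half_saturation.tolist(),
            "shape": self.shape.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalyteFingerprint":
        return cls(d["name"], d["max_response"], d["half_saturation"], d["shape"])


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise model: i.i.d. additive Gaussian per feature."""

    replicate_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class LabeledResponseSet:
    """A feature table (m x 12 dRGB) with aligned labels and provenance.

    ``metadata`` records every generator parameter, so the set can be
    regenerated bit-identically.
    """

    features: np.ndarray
    labels: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must be m x {N_FEATURES}")
        if len(self.labels) != len(self.features):
            raise ValueError("labels must align 1:1 with feature rows")

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_COLUMNS))
        return pd.concat([df, self.labels.reset_index(drop=True)], axis=1)


def write_response_set(path, dataset: LabeledResponseSet) -> None:
    """CSV of features + labels, with generator metadata in a YAML sidecar."""
    path = str(path)
    dataset.to_frame().to_csv(path, index=False)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(dataset.metadata, fh, sort_keys=False)


def read_response_set(path) -> LabeledResponseSet:
    path = str(path)
    df = pd.read_csv(path)
    feats = df[list(FEATURE_COLUMNS)].to_numpy(float)
    labels = df.drop(columns=list(FEATURE_COLUMNS))
    try:
        with open(_sidecar(path)) as fh:
            meta = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        meta = {}
    return LabeledResponseSet(feats, labels, meta)


def _sidecar(path: str) -> str:
    return path[:-4] + ".yaml" if path.endswith(".csv") else path + ".yaml"


# ---------------------------------------------------------------------------
# Built-in fingerprint library
# ---------------------------------------------------------------------------
# Nine fixed synthetic fingerprints named after the organic acids the array
# targets (A1..A9).  Values are arbitrary but frozen so tests are stable.
# They were drawn once under two design constraints: (i) pairwise-distinct
# sign patterns with amplitude magnitudes 80-100 color units, so the noise
# floor relative to the full fingerprint norm is small; (ii) channel
# specialization — per acid, two channels respond in the low range
# (half-saturation 0.8-2 mmol/L, gentle Hill exponents 0.4-0.6) and two
# in the high range (8-16 mmol/L, cooperative exponents 1.0-1.5) — with a
# draw accepted only if the single-sample information bound keeps the
# relative concentration uncertainty below 15% at 1 umol/L and below 0.7%
# at 10 mmol/L under 0.5%-of-amplitude replicate noise.  This encodes the qualitative design
# requirement that every fingerprint stays informative across the whole
# 0.001-10 mmol/L calibration range: a single shared saturation constant
# would leave either the lowest or the highest decade undiscriminated.
_FINGERPRINT_TABLE = {
    # name: (amplitudes[12], half_saturation per channel[4], shape per channel[4])
    "benzoic": ([-93.2, 88.7, -84.4, -84.5, -81.6, -94.0, -84.9, 85.5, 89.3, -83.3, 95.5, 86.0],
                [13.05, 1.18, 1.66, 9.75], [1.35, 0.49, 0.44, 1.29]),
    "lactic": ([-89.2, 82.9, -98.6, 89.6, 81.6, -87.6, -82.2, -80.0, 86.4, -94.6, -94.1, 93.6],
               [8.84, 1.35, 1.14, 11.48], [1.2, 0.44, 0.41, 1.33]),
    "acetic": ([95.0, -85.0, -91.0, 87.4, -98.8, -91.9, -97.5, 89.0, -83.1, -98.1, -93.2, -85.7],
               [11.65, 1.38, 11.19, 1.41], [1.36, 0.53, 1.3, 0.41]),
    "butyric": ([91.6, -89.9, -95.6, -81.8, -84.2, -98.0, -80.7, -80.4, -84.0, 93.5, -83.3, -97.1],
                [0.84, 0.99, 9.92, 9.22], [0.53, 0.44, 1.14, 1.47]),
    "isobutyric": ([89.7, -92.3, -98.7, -89.2, 93.8, -96.6, 83.3, 91.2, -91.5, 99.4, -96.3, -81.7],
                   [1.51, 15.53, 1.04, 10.16], [0.44, 1.39, 0.41, 1.16]),
    "valeric": ([90.0, -99.8, -90.4, 99.6, -82.1, -97.5, -90.0, 83.7, 94.6, -88.9, -92.6, -89.9],
                [11.16, 0.98, 1.01, 11.57], [1.47, 0.42, 0.43, 1.2]),
    "isovaleric": ([92.6, -80.1, -91.0, -95.8, -86.4, -98.3, 80.5, -98.5, -90.9, -88.7, -98.3, 98.3],
                   [1.3, 0.93, 15.77, 13.15], [0.42, 0.52, 1.43, 1.48]),
    "hexanoic": ([89.2, 93.2, 90.6, -93.8, -89.2, 86.2, 80.8, 90.4, -83.4, 80.8, 95.7, -96.1],
                 [9.58, 11.37, 1.17, 1.29], [1.49, 1.2, 0.54, 0.4]),
    "octanoic": ([-93.8, 85.4, -97.3, -80.6, -90.0, -80.2, -93.5, 96.7, -90.7, -96.7, 93.1, 98.6],
                 [13.83, 8.65, 0.99, 1.17], [1.25, 1.46, 0.5, 0.48]),
}

ACID_NAMES = tuple(_FINGERPRINT_TABLE)


def default_fingerprints() -> dict[str, AnalyteFingerprint]:
    """The nine built-in acid fingerprints (fresh instances)."""
    out = {}
    for name, (amp, k4, s4) in _FINGERPRINT_TABLE.items():
        out[name] = AnalyteFingerprint(
            name=name,
            max_response=np.array(amp),
            half_saturation=np.repeat(k4, 3),
            shape=np.repeat(s4, 3),
        )
    return out


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

#: The calibration series used for quantitation (mmol/L).
CALIBRATION_CONCENTRATIONS = (0.001, 0.005, 0.01, 0.025, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)
DEFAULT_N_REPLICATES = 24
#: Default mixture grid for the variable acids (mmol/L); the fixed acid runs at 6.
MIXTURE_GRID = (0.1, 0.5, 1.0, 3.0, 5.0)
MIXTURE_FIXED_CONC = 6.0


def generate_single_analyte(
    fp: AnalyteFingerprint,
    concentrations: Sequence[float],
    n_rep: int,
    noise: NoiseSpec,
) -> LabeledResponseSet:
    """Concentration series of one analyte, ``n_rep`` replicates per level."""
    concentrations = [float(c) for c in concentrations]
    for c in concentrations:
        if c < 0:
            raise ValueError(f"negative concentration not allowed: {c}")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    expected = np.array([fp.expected_response(c) for c in concentrations])
    feats = np.repeat(expected, n_rep, axis=0)
    rng = noise.rng()
    if noise.replicate_sd > 0:
        feats = feats + rng.normal(0.0, noise.replicate_sd, feats.shape)
    labels = pd.DataFrame({"concentration": np.repeat(concentrations, n_rep)})
    meta = {
        "generator": "single_analyte",
        "fingerprint": fp.to_dict(),
        "concentrations": concentrations,
        "n_rep": int(n_rep),
        "replicate_sd": float(noise.replicate_sd),
        "seed": int(noise.seed),
    }
    return LabeledResponseSet(feats, labels, meta)


def _composition_rng(interaction_seed: int, composition: Sequence[float]) -> np.random.Generator:
    """Deterministic RNG keyed by (seed, composition) — stable across runs."""
    key = f"{int(interaction_seed)}|" + "|".join(f"{c:.9g}" for c in composition)
    digest = hashlib.sha256(key.encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


def mixture_expected_response(
    fps: Sequence[AnalyteFingerprint],
    composition: Sequence[float],
    interaction_strength: float = 0.6,
    interaction_seed: int = 20240613,
) -> np.ndarray:
    """Noise-free dRGB response of a mixture.

    The base is the sum of the single-analyte responses.  When two or more
    components are present, a composition-specific synergy offset is added:
    a fixed pseudo-random 12-vector (deterministic in the composition and
    ``interaction_seed``) whose magnitude is ``interaction_strength`` times
    the mean single-component response norm.  This emulates the
    composition-dependent interaction chemistry of co-existing acids
    competing for one chromogenic reagent; it vanishes when at most one
    component is present, and the total is clipped to the dRGB gamut.
    """
    responses = [fp.expected_response(c) for fp, c in zip(fps, composition)]
    total = np.sum(responses, axis=0)
    norms = [float(np.linalg.norm(r)) for c, r in zip(composition, responses) if c > 0]
    if len(norms) >= 2 and interaction_strength > 0:
        rng = _composition_rng(interaction_seed, composition)
        z = rng.normal(size=N_FEATURES)
        z /= np.linalg.norm(z)
        total = total + interaction_strength * float(np.mean(norms)) * z
    return np.clip(total, -GAMUT, GAMUT)


def generate_mixture_grid(
    fps: Sequence[AnalyteFingerprint],
    fixed_conc: float,
    grid: Sequence[float],
    n_rep: int,
    noise: NoiseSpec,
    interaction_strength: float = 0.6,
    interaction_seed: int = 20240613,
) -> LabeledResponseSet:
    """Two-way mixture grid over three analytes.

    ``fps[0]`` is held at ``fixed_conc``; ``fps[1]`` and ``fps[2]`` run over
    ``grid`` x ``grid`` (row-major), one class per cell labeled h1..h{g^2}.
    """
    if len(fps) != 3:
        raise ValueError(f"exactly 3 fingerprints required, got {len(fps)}")
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if fixed_conc < 0:
        raise ValueError(f"negative concentration not allowed: {fixed_conc}")
    grid = [float(g) for g in grid]
    rows, labels, concs = [], [], []
    cls = 0
    for g1 in grid:
        for g2 in grid:
            cls += 1
            comp = (float(fixed_conc), g1, g2)
            expected = mixture_expected_response(fps, comp, interaction_strength, interaction_seed)
            rows.append(np.tile(expected, (n_rep, 1)))
            labels.extend([f"h{cls}"] * n_rep)
            concs.extend([comp] * n_rep)
    feats = np.vstack(rows)
    rng = noise.rng()
    if noise.replicate_sd > 0:
        feats = feats + rng.normal(0.0, noise.replicate_sd, feats.shape)
    lab = pd.DataFrame({"label": labels})
    for j, fp in enumerate(fps):
        lab[f"c_{fp.name}"] = [c[j] for c in concs]
    meta = {
        "generator": "mixture_grid",
        "fingerprints": [fp.to_dict() for fp in fps],
        "fixed_conc": float(fixed_conc),
        "grid": grid,
        "n_rep": int(n_rep),
        "replicate_sd": float(noise.replicate_sd),
        "seed": int(noise.seed),
        "interaction_strength": float(interaction_strength),
        "interaction_seed": int(interaction_seed),
    }
    return LabeledResponseSet(feats, lab, meta)


def generate_class_population(
    centroids: np.ndarray,
    n_rep: int,
    noise: NoiseSpec,
) -> LabeledResponseSet:
    """k classes of Gaussian scatter around pairwise-distinct centroids (f1..fk)."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != N_FEATURES:
        raise ValueError(f"centroids must be k x {N_FEATURES}")
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("at least 2 classes required")
    for i in range(k):
        for j in range(i + 1, k):
            if np.array_equal(centroids[i], centroids[j]):
                raise ValueError(f"duplicate centroids ({i}, {j}): classes would be unidentifiable")
    feats = np.repeat(centroids, n_rep, axis=0)
    rng = noise.rng()
    if noise.replicate_sd > 0:
        feats = feats + rng.normal(0.0, noise.replicate_sd, feats.shape)
    labels = pd.DataFrame({"label": np.repeat([f"f{i + 1}" for i in range(k)], n_rep)})
    meta = {
        "generator": "class_population",
        "centroids": centroids.tolist(),
        "n_rep": int(n_rep),
        "replicate_sd": float(noise.replicate_sd),
        "seed": int(noise.seed),
    }
    return LabeledResponseSet(feats, labels, meta)


def generate_adulteration(
    pure_fp: np.ndarray,
    adulterant_fp: np.ndarray,
    fractions: Sequence[float],
    n_rep: int,
    noise: NoiseSpec,
) -> LabeledResponseSet:
    """Volumetric blends of two fingerprints.

    ``fraction`` is the volume share of the adulterant: the expected
    response is ``(1 - fraction) * pure + fraction * adulterant``, so a
    1:9 genuine:adulterant blend maps to fraction 0.9.
    """
    pure = _as_feature_vector(pure_fp, "pure_fp")
    adult = _as_feature_vector(adulterant_fp, "adulterant_fp")
    fractions = [float(f) for f in fractions]
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {f}")
    expected = np.array([(1.0 - f) * pure + f * adult for f in fractions])
    feats = np.repeat(expected, n_rep, axis=0)
    rng = noise.rng()
    if noise.replicate_sd > 0:
        feats = feats + rng.normal(0.0, noise.replicate_sd, feats.shape)
    labels = pd.DataFrame({"fraction": np.repeat(fractions, n_rep)})
    meta = {
        "generator": "adulteration",
        "pure_fp": pure.tolist(),
        "adulterant_fp": adult.tolist(),
        "fractions": fractions,
        "n_rep": int(n_rep),
        "replicate_sd": float(noise.replicate_sd),
        "seed": int(noise.seed),
    }
    return LabeledResponseSet(feats, labels, meta)


def draw_class_centroids(
    n_classes: int, seed: int, scale: float = 100.0
) -> np.ndarray:
    """Pairwise-distinct random centroids in the dRGB gamut (uniform +-scale)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-scale, scale, size=(n_classes, N_FEATURES))


def min_separation(centroids: np.ndarray) -> float:
    """Smallest pairwise Euclidean distance between class centroids."""
    centroids = np.asarray(centroids, float)
    d = np.inf
    for i in range(len(centroids)):
        for j in range(i + 1, len(centroids)):
            d = min(d, float(np.linalg.norm(centroids[i] - centroids[j])))
    return d
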
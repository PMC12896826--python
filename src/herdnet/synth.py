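"""Synthetic herd sensor data and the single-frame preprocessing chain.

A collar-mounted device samples a 9-axis IMU (tri-axial accelerometer,
gyroscope, magnetometer) at 1 Hz and records a GPS fix at the start and end
of each 10 s window.  One *frame* summarises a window as ten features: the
nine per-axis IMU means plus the great-circle displacement between the two
fixes.  Behaviors (Grazing, Lying, Standing, Walking in the 4-class scheme;
posture x ruminating splits in the 6-class scheme) differ mainly in
displacement scale and accelerometer posture, with deliberate overlap
between Standing and the Grazing/Lying classes.

The module also implements the preprocessing chain applied to such frames:
SMOTE minority oversampling, a 7:3 train/test split, and per-feature
standardization with training-set statistics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

#: Earth radius used for the displacement feature, km.
EARTH_RADIUS_KM = 6371.393

#: Floor applied to per-feature standard deviations to keep constant
#: features finite (they standardize to all zeros).
SIGMA_FLOOR = 1e-8

FEATURE_NAMES = ["ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz", "d"]

CLASS_NAMES_4 = ["Grazing", "Lying", "Standing", "Walking"]
CLASS_NAMES_6 = [
    "Grazing",
    "Walking",
    "Lying-Ruminating",
    "Lying-Resting",
    "Standing-Ruminating",
    "Standing-Resting",
]


@dataclass(frozen=True)
class GpsFix:
    """A single GPS fix: latitude/longitude in degrees, time in seconds."""

    lat: float
    lon: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError("GPS coordinates must be finite")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")


@dataclass
class SensorWindow:
    """One observation window: 1 Hz IMU samples plus bracketing GPS fixes."""

    imu_samples: np.ndarray  # (n_samples, 9)
    fix_start: GpsFix
    fix_end: GpsFix

    def __post_init__(self) -> None:
        self.imu_samples = np.asarray(self.imu_samples, dtype=float)
        if self.imu_samples.ndim != 2 or self.imu_samples.shape[1] != 9:
            raise ValueError("imu_samples must have shape (n, 9)")


@dataclass
class HerdDataset:
    """Labeled feature frames: X is (n, 10) float, y is (n,) int."""

    X: np.ndarray
    y: np.ndarray
    class_names: list[str]
    standardization: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise ValueError("X must have shape (n, 10)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= len(self.class_names)):
            raise ValueError("labels outside the class range")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=FEATURE_NAMES)
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, class_names: Sequence[str]) -> "HerdDataset":
        df = pd.read_csv(path)
        missing = [c for c in FEATURE_NAMES + ["label"] if c not in df.columns]
        if missing:
            raise ValueError(f"frames CSV missing columns: {missing}")
        return cls(
            df[FEATURE_NAMES].to_numpy(float),
            df["label"].to_numpy(int),
            list(class_names),
        )

    def replace(self, **kw) -> "HerdDataset":
        return dataclasses.replace(self, **kw)


def haversine_displacement(
    p1: GpsFix, p2: GpsFix, radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance between two fixes in km (haversine form)."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lat1, lon1, lat2, lon2 = map(
        math.radians, (p1.lat, p1.lon, p2.lat, p2.lon)
    )
    s = math.sqrt(
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * radius_km * math.asin(min(1.0, s))


def assemble_frame(
    window: SensorWindow, radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Reduce a window to its 10-feature frame (IMU means + displacement)."""
    if window.imu_samples.shape[0] == 0:
        raise ValueError("cannot assemble a frame from an empty window")
    means = window.imu_samples.mean(axis=0)
    d = haversine_displacement(window.fix_start, window.fix_end, radius_km)
    return np.concatenate([means, [d]])


def smote_oversample(
    ds: HerdDataset,
    k: int = 5,
    target_counts: Sequence[int] | None = None,
    seed: int | None = None,
) -> HerdDataset:
    """SMOTE: synthesize minority samples as x + u*(x_nn - x), u ~ U(0, 1).

    x_nn is drawn uniformly from x's ``k`` nearest same-class neighbors
    (Euclidean, on the raw unstandardized features).  Originals are kept;
    per-class output counts match ``target_counts`` (default: balance every
    class up to the majority count).
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    counts = ds.class_counts()
    if target_counts is None:
        target_counts = np.full(ds.n_classes, counts.max())
    target_counts = np.asarray(target_counts, dtype=int)
    if target_counts.shape != (ds.n_classes,):
        raise ValueError("target_counts must give one count per class")
    if np.any(target_counts < counts):
        raise ValueError("target_counts must be >= current class counts")
    deficits = target_counts - counts
    for c in np.nonzero(deficits > 0)[0]:
        if counts[c] < k + 1:
            raise ValueError(
                f"class {ds.class_names[c]!r} has {counts[c]} samples; "
                f"SMOTE with k={k} needs at least {k + 1}"
            )
    if not deficits.any():
        return ds

    rng = np.random.default_rng(seed)
    new_X, new_y = [ds.X], [ds.y]
    for c in np.nonzero(deficits > 0)[0]:
        Xc = ds.X[ds.y == c]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        # column 0 is the point itself
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xc), size=deficits[c])
        pick = neigh[base, rng.integers(0, k, size=deficits[c])]
        u = rng.uniform(0.0, 1.0, size=(deficits[c], 1))
        new_X.append(Xc[base] + u * (Xc[pick] - Xc[base]))
        new_y.append(np.full(deficits[c], c, dtype=int))
    return ds.replace(
        X=np.concatenate(new_X), y=np.concatenate(new_y), standardization=None
    )


def standardize(
    train: HerdDataset, *others: HerdDataset
) -> tuple[tuple[HerdDataset, ...], np.ndarray, np.ndarray]:
    """Standardize every partition with the training set's mean and
    population (1/n) standard deviation per feature."""
    if len(train) == 0:
        raise ValueError("training partition is empty")
    mu = train.X.mean(axis=0)
    sigma = np.maximum(train.X.std(axis=0, ddof=0), SIGMA_FLOOR)
    out = tuple(
        ds.replace(X=(ds.X - mu) / sigma, standardization=(mu, sigma))
        for ds in (train, *others)
    )
    return out, mu, sigma


def split(
    ds: HerdDataset,
    ratio: float = 0.7,
    seed: int | None = None,
    stratify: bool = True,
) -> tuple[HerdDataset, HerdDataset]:
    """Random frame-level partition into (train, test) at ``ratio``."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    if len(ds) < 2:
        raise ValueError("need at least 2 frames to split")
    idx_train, idx_test = train_test_split(
        np.arange(len(ds)),
        train_size=ratio,
        random_state=seed,
        stratify=ds.y if stratify else None,
    )
    mk = lambda idx: ds.replace(X=ds.X[idx], y=ds.y[idx], standardization=None)
    return mk(np.sort(idx_train)), mk(np.sort(idx_test))


# --------------------------------------------------------------------------
# Generator
# --------------------------------------------------------------------------

@dataclass
class ClassEmission:
    """Class-conditional emission parameters for one behavior.

    IMU units are arbitrary sensor units (accelerometer ~g, gyroscope
    ~deg/s, magnetometer ~uT); standardization later makes the pipeline
    unit-free.  ``imu_jitter`` is a per-window shift of the 9 IMU means
    (animal/posture variability); ``imu_noise`` is per-second sample noise.
    Displacement is normal, truncated at zero, in km per window.
    """

    imu_mean: np.ndarray  # (9,)
    imu_jitter: np.ndarray  # (9,)
    imu_noise: np.ndarray  # (9,)
    disp_mean_km: float
    disp_std_km: float

    def __post_init__(self) -> None:
        for name in ("imu_mean", "imu_jitter", "imu_noise"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (9,):
                raise ValueError(f"{name} must have 9 entries")
            setattr(self, name, v)
        if self.disp_std_km < 0 or not np.isfinite(self.disp_mean_km):
            raise ValueError("invalid displacement parameters")


def _em(accel, gyro, mag, gyro_sd, disp, disp_sd) -> ClassEmission:
    return ClassEmission(
        imu_mean=np.array(accel + gyro + mag, dtype=float),
        imu_jitter=np.array([0.13] * 3 + [0.8] * 3 + [3.5] * 3),
        imu_noise=np.array([0.25] * 3 + [gyro_sd] * 3 + [6.0] * 3),
        disp_mean_km=disp,
        disp_std_km=disp_sd,
    )


def default_emissions(scheme: int) -> dict[str, ClassEmission]:
    """Built-in per-behavior emission parameters.

    Posture is carried by the accelerometer means (head-down Grazing,
    horizontal Lying, upright Standing/Walking), activity by the gyroscope
    level, and locomotion by the displacement scale
    (Walking >> Grazing > Standing ~ Lying ~ 0).  Standing sits between
    Grazing and Lying in posture with matched noise so the two confusions
    seen in collar data survive in the synthetic draws.
    """
    if scheme == 4:
        return {
            "Grazing": _em([0.52, 0.12, -0.78], [3.2, 3.0, 2.2], [24.0, 6.0, -35.0], 2.2, 0.0020, 0.0010),
            "Lying": _em([0.06, 0.62, -0.70], [0.6, 0.6, 0.5], [28.0, 13.0, -30.0], 0.9, 0.0002, 0.0002),
            "Standing": _em([0.24, 0.30, -0.86], [1.2, 1.2, 1.0], [26.0, 9.0, -33.0], 1.4, 0.0005, 0.0004),
            "Walking": _em([0.22, 0.14, -0.92], [7.5, 7.0, 4.5], [26.0, 8.0, -33.0], 3.0, 0.0100, 0.0025),
        }
    if scheme == 6:
        return {
            "Grazing": _em([0.52, 0.12, -0.78], [3.2, 3.0, 2.2], [24.0, 6.0, -35.0], 2.2, 0.0020, 0.0010),
            "Walking": _em([0.22, 0.14, -0.92], [7.5, 7.0, 4.5], [26.0, 8.0, -33.0], 3.0, 0.0100, 0.0025),
            "Lying-Ruminating": _em([0.08, 0.62, -0.70], [2.4, 2.2, 1.6], [28.0, 13.0, -30.0], 1.8, 0.0002, 0.0002),
            "Lying-Resting": _em([0.05, 0.64, -0.69], [0.5, 0.5, 0.4], [28.0, 13.0, -30.0], 0.8, 0.0002, 0.0002),
            "Standing-Ruminating": _em([0.26, 0.30, -0.85], [2.5, 2.3, 1.7], [26.0, 9.0, -33.0], 1.8, 0.0005, 0.0004),
            "Standing-Resting": _em([0.23, 0.31, -0.87], [0.9, 0.9, 0.8], [26.0, 9.0, -33.0], 1.2, 0.0005, 0.0004),
        }
    raise ValueError("scheme must be 4 or 6")


#: Default imbalanced class mix (fractions of the total herd-day), chosen to
#: follow typical grazing time budgets with Walking as the rare class.
DEFAULT_PROPORTIONS = {
    4: [0.40, 0.30, 0.20, 0.10],
    6: [0.30, 0.08, 0.18, 0.16, 0.14, 0.14],
}

#: Bounding box of the synthetic pasture (degrees).
SITE_LAT = (49.32, 49.34)
SITE_LON = (119.94, 119.96)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic herd-sensor generator."""

    scheme: int = 4
    n_per_class: Sequence[int] | None = None
    n_total: int = 2000
    emissions: dict[str, ClassEmission] | None = None
    window_len_s: int = 10
    radius_km: float = EARTH_RADIUS_KM
    seed: int | None = None

    def resolve(self) -> tuple[list[str], np.ndarray, dict[str, ClassEmission]]:
        names = CLASS_NAMES_4 if self.scheme == 4 else CLASS_NAMES_6
        if self.scheme not in (4, 6):
            raise ValueError("scheme must be 4 or 6")
        emissions = self.emissions or default_emissions(self.scheme)
        missing = [n for n in names if n not in emissions]
        if missing:
            raise ValueError(f"missing emission parameters for {missing}")
        if self.n_per_class is not None:
            counts = np.asarray(self.n_per_class, dtype=int)
            if counts.shape != (len(names),) or np.any(counts < 0):
                raise ValueError("n_per_class must be nonnegative, one per class")
        else:
            props = np.array(DEFAULT_PROPORTIONS[self.scheme])
            counts = np.maximum(np.round(props * self.n_total), 1).astype(int)
        if counts.sum() == 0:
            raise ValueError("total frame count is zero")
        if self.window_len_s < 1:
            raise ValueError("window length must be >= 1 s")
        return list(names), counts, emissions


def _destination_fix(start: GpsFix, d_km: float, bearing: float,
                     radius_km: float, t1: float) -> GpsFix:
    # planar offset; exact enough for the <100 m in-window displacements
    dlat = math.degrees((d_km / radius_km) * math.cos(bearing))
    dlon = math.degrees(
        (d_km / radius_km) * math.sin(bearing) / math.cos(math.radians(start.lat))
    )
    return GpsFix(start.lat + dlat, start.lon + dlon, t1)


def sample_window(
    em: ClassEmission,
    rng: np.random.Generator,
    window_len_s: int = 10,
    radius_km: float = EARTH_RADIUS_KM,
    t0: float = 0.0,
) -> SensorWindow:
    """Draw one class-conditional sensor window."""
    center = em.imu_mean + rng.normal(0.0, em.imu_jitter)
    samples = center + rng.normal(0.0, em.imu_noise, size=(window_len_s, 9))
    d = max(0.0, rng.normal(em.disp_mean_km, em.disp_std_km))
    start = GpsFix(rng.uniform(*SITE_LAT), rng.uniform(*SITE_LON), t0)
    end = _destination_fix(start, d, rng.uniform(0.0, 2 * math.pi),
                           radius_km, t0 + window_len_s)
    return SensorWindow(samples, start, end)


def generate_synthetic_herd(cfg: GeneratorConfig) -> HerdDataset:
    """Generate a labeled synthetic dataset of 10-feature frames.

    Every frame is produced by sampling a full SensorWindow and reducing it
    with :func:`assemble_frame`, so the generator exercises the same
    preprocessing path as real collar data.
    """
    names, counts, emissions = cfg.resolve()
    rng = np.random.default_rng(cfg.seed)
    X = np.empty((int(counts.sum()), len(FEATURE_NAMES)))
    y = np.empty(int(counts.sum()), dtype=int)
    i = 0
    for label, name in enumerate(names):
        em = emissions[name]
        for _ in range(counts[label]):
            w = sample_window(em, rng, cfg.window_len_s, cfg.radius_km,
                              t0=float(i) * cfg.window_len_s)
            X[i] = assemble_frame(w, cfg.radius_km)
            y[i] = label
            i += 1
    return HerdDataset(X, y, names)


def make_pipeline_datasets(
    cfg: GeneratorConfig,
    ratio: float = 0.7,
    smote_k: int = 5,
    seed: int | None = None,
    smote_before_split: bool = True,
    val_fraction: float = 0.0,
):
    """Generate, oversample, split and standardize in the reference order.

    Default order is SMOTE -> split -> standardize; set
    ``smote_before_split=False`` to oversample the training partition only
    (the leakage-free variant).  With ``val_fraction`` > 0 a validation
    partition is carved out of the training side before standardization
    (statistics come from the remaining training frames only) and the
    return value is (train, val, test) instead of (train, test).
    """
    root = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    s_gen, s_smote, s_split, s_val = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )
    ds = generate_synthetic_herd(dataclasses.replace(cfg, seed=s_gen))
    if smote_before_split:
        ds = smote_oversample(ds, k=smote_k, seed=s_smote)
        train, test = split(ds, ratio=ratio, seed=s_split)
    else:
        train, test = split(ds, ratio=ratio, seed=s_split)
        train = smote_oversample(train, k=smote_k, seed=s_smote)
    if val_fraction > 0.0:
        train, val = split(train, ratio=1.0 - val_fraction, seed=s_val)
        (train, val, test), _, _ = standardize(train, val, test)
        return train, val, test
    (train, test), _, _ = standardize(train, test)
    return train, test
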
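"""Synthetic MEG-connectome data with known ground truth.

The study design being emulated: two groups of military participants — 23
with combat-related PTSD and 21 trauma-exposed controls — each contributing
one resting-state functional connectome per frequency band, built from wPLI
synchrony between the 90 AAL atlas regions (4005 edges). A modest subset of
edges (a few dozen per band) genuinely differs between groups, in mixed
directions.

Two generation modes:

``direct_edges`` (default)
    Edge weights drawn logit-normal around a baseline mean — the logistic
    transform keeps wPLI support in [0, 1] without truncation — with the
    planted edges' case-group mean shifted on the logit scale by
    ``effect_size × edge_noise_sd`` in the stated direction. Fast and with
    exact control of effect sizes; this is the pipeline's test bed.

``timeseries``
    Band-limited noise per region plus, for coupled pairs, a shared carrier
    oscillation injected with a fixed phase lag, reduced to connectomes with
    the package's own wPLI estimator. Exists to validate the estimator, not
    to be spectrally realistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.special import expit, logit

from .dataset import ConnectomeDataset
from .edges import EdgeIndex, edge_count
from .rng import derive_rng
from .wpli import wpli_matrix

__all__ = [
    "Band",
    "STUDY_BANDS",
    "PlantedEdge",
    "GroundTruth",
    "SyntheticSpec",
    "study_spec",
    "generate_edge_dataset",
    "generate_coupled_timeseries",
    "timeseries_dataset",
]

INCREASE, DECREASE = "increase", "decrease"


@dataclass(frozen=True)
class Band:
    """A frequency band: name plus (f_low, f_high) edges in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"degenerate band {self.name}: ({self.f_low}, {self.f_high})")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


#: The five canonical bands analysed in the study design.
STUDY_BANDS: tuple[Band, ...] = (
    Band("Theta", 4.0, 7.0),
    Band("Alpha", 8.0, 14.0),
    Band("Beta", 15.0, 30.0),
    Band("L.Gamma", 30.0, 80.0),
    Band("H.Gamma", 80.0, 150.0),
)


@dataclass(frozen=True)
class PlantedEdge:
    """One ground-truth discriminative edge."""

    edge: int
    direction: str  # "increase" | "decrease": case-group mean relative to control
    effect_size: float  # Cohen-d-like shift in units of edge_noise_sd

    def __post_init__(self) -> None:
        if self.direction not in (INCREASE, DECREASE):
            raise ValueError(f"direction must be increase/decrease, got {self.direction!r}")
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ValueError(f"effect size must be finite and >= 0, got {self.effect_size}")

    @property
    def sign(self) -> int:
        return 1 if self.direction == INCREASE else -1


@dataclass
class GroundTruth:
    """Planted discriminative edges per band — consumed only by tests."""

    planted: dict[str, tuple[PlantedEdge, ...]]

    def edges(self, band: str) -> tuple[PlantedEdge, ...]:
        return self.planted.get(band, ())

    def edge_ids(self, band: str) -> np.ndarray:
        return np.array(sorted(p.edge for p in self.edges(band)), dtype=int)

    def to_json(self, path) -> None:
        payload = {
            b: [{"edge": p.edge, "direction": p.direction, "effect_size": p.effect_size} for p in ps]
            for b, ps in self.planted.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            {
                b: tuple(PlantedEdge(d["edge"], d["direction"], d["effect_size"]) for d in ps)
                for b, ps in payload.items()
            }
        )


@dataclass
class SyntheticSpec:
    """Full description of a synthetic study.

    Defaults are the emulated study conditions: 23 cases vs 21 controls,
    90 regions (4005 edges), the five canonical bands.
    """

    n_group1: int = 23  # cases
    n_group2: int = 21  # controls
    n_regions: int = 90
    bands: tuple[Band, ...] = STUDY_BANDS
    planted: dict[str, tuple[PlantedEdge, ...]] = field(default_factory=dict)
    baseline_edge_mean: float = 0.2
    edge_noise_sd: float = 0.5  # on the logit scale
    seed: int = 0
    mode: str = "direct_edges"
    # timeseries-mode parameters
    sampling_rate: float = 600.0
    n_epochs: int = 60
    epoch_length: float = 2.0
    coupling_phase_lag: float = np.pi / 2
    coupling_strength: float = 0.5  # control-group coupling of planted pairs

    def __post_init__(self) -> None:
        if min(self.n_group1, self.n_group2) < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0 < self.baseline_edge_mean < 1:
            raise ValueError("baseline_edge_mean must lie in (0, 1)")
        if self.edge_noise_sd <= 0:
            raise ValueError("edge_noise_sd must be positive")
        if self.mode not in ("direct_edges", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        n_edges = edge_count(self.n_regions)
        for band_name, ps in self.planted.items():
            if band_name not in names:
                raise ValueError(f"planted edges reference unknown band {band_name!r}")
            ids = [p.edge for p in ps]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate planted edges in band {band_name!r}")
            bad = [e for e in ids if not 0 <= e < n_edges]
            if bad:
                raise ValueError(f"planted edge ids out of range: {bad[:5]}")

    @property
    def n_edges(self) -> int:
        return edge_count(self.n_regions)

    @property
    def n_subjects(self) -> int:
        return self.n_group1 + self.n_group2

    def band(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"unknown band {name!r}; spec has {[b.name for b in self.bands]}")

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(dict(self.planted))

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def study_spec(
    seed: int = 0,
    n_planted: int = 40,
    effect_size: float = 1.2,
    increase_fraction: float = 0.5,
    **overrides,
) -> SyntheticSpec:
    """A :class:`SyntheticSpec` matching the emulated study conditions.

    Per band, ``n_planted`` edges are drawn uniformly without replacement and
    assigned increase/decrease directions (half and half by default, matching
    the roughly even split of significant-edge directions reported for real
    data), all with the same effect size.
    """
    base = SyntheticSpec(seed=seed, **{k: v for k, v in overrides.items() if k != "planted"})
    rng = derive_rng(seed, "plant")
    planted: dict[str, tuple[PlantedEdge, ...]] = {}
    for band in base.bands:
        ids = rng.choice(base.n_edges, size=n_planted, replace=False)
        n_up = int(round(increase_fraction * n_planted))
        dirs = np.array([INCREASE] * n_up + [DECREASE] * (n_planted - n_up))
        rng.shuffle(dirs)
        planted[band.name] = tuple(
            PlantedEdge(int(e), str(d), float(effect_size)) for e, d in zip(sorted(ids), dirs)
        )
    return replace(base, planted=planted)


def _generic_index(n_regions: int) -> EdgeIndex:
    if n_regions == 90:
        from .edges import aal90_index

        return aal90_index()
    return EdgeIndex([f"R{i:03d}" for i in range(n_regions)])


def _subject_ids(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    ids = [f"case_{i + 1:02d}" for i in range(spec.n_group1)]
    ids += [f"ctrl_{i + 1:02d}" for i in range(spec.n_group2)]
    labels = np.r_[np.ones(spec.n_group1, int), np.zeros(spec.n_group2, int)]
    return ids, labels


def generate_edge_dataset(spec: SyntheticSpec, band: str) -> ConnectomeDataset:
    """Direct-mode synthetic connectomes for one band.

    Edge weights are inverse-logit of Gaussian draws centred at
    ``logit(baseline_edge_mean)`` with SD ``edge_noise_sd``; each planted
    edge's case-group centre is shifted by ``±effect_size × edge_noise_sd``
    on the logit scale, so the group difference survives the bounded
    transform monotonically instead of being clipped away at the boundary.
    """
    b = spec.band(band)  # raises on invalid band
    rng = derive_rng(spec.seed, "edges", b.name)
    n, e = spec.n_subjects, spec.n_edges
    z = rng.standard_normal((n, e))
    loc = logit(spec.baseline_edge_mean) + spec.edge_noise_sd * z
    for p in spec.planted.get(b.name, ()):
        loc[: spec.n_group1, p.edge] += p.sign * p.effect_size * spec.edge_noise_sd
    subject_ids, labels = _subject_ids(spec)
    return ConnectomeDataset(
        subject_ids=subject_ids,
        labels=labels,
        band=b.name,
        X=expit(loc),
        edge_index=_generic_index(spec.n_regions),
    )


# -- timeseries mode ---------------------------------------------------------

# A planted pair's case-group coupling is control coupling +/- this factor
# times the effect size, clipped to [0, 1].
_COUPLING_PER_D = 0.3


def _pair_strengths(spec: SyntheticSpec, band: str, is_case: bool) -> dict[int, float]:
    out = {}
    for p in spec.planted.get(band, ()):
        s = spec.coupling_strength
        if is_case:
            s = float(np.clip(s + p.sign * _COUPLING_PER_D * p.effect_size, 0.0, 1.0))
        out[p.edge] = s
    return out


def _bandpass_noise(rng, band: Band, sfreq: float, shape) -> np.ndarray:
    white = rng.standard_normal(shape)
    nyq = sfreq / 2
    lo, hi = max(band.f_low, 0.5) / nyq, min(band.f_high, nyq * 0.98) / nyq
    taps = signal.firwin(129, [lo, hi], pass_zero=False)
    out = signal.filtfilt(taps, [1.0], white, axis=-1)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_coupled_timeseries(spec: SyntheticSpec, band: str, subject: int) -> np.ndarray:
    """Epoched region signals ``(n_epochs, n_regions, n_times)`` for one subject.

    Each region carries unit-variance band-limited noise. For each planted
    pair the two regions additionally receive a shared carrier at the band
    centre (snapped to an FFT bin) with random phase per epoch; the second
    region's copy is delayed by ``coupling_phase_lag`` radians. Signal and
    noise are mixed as ``sqrt(1 - s^2) * noise + s * carrier`` so coupling
    strength ``s = 1`` means a pure, noiseless oscillation.
    """
    if spec.mode != "timeseries":
        raise ValueError("generate_coupled_timeseries requires mode='timeseries'")
    b = spec.band(band)
    lag = spec.coupling_phase_lag
    if abs(np.sin(lag)) < 1e-9:
        warnings.warn(
            "coupling_phase_lag is 0 (mod pi): wPLI is blind to zero-lag coupling",
            UserWarning,
            stacklevel=2,
        )
    is_case = subject < spec.n_group1
    strengths = _pair_strengths(spec, b.name, is_case)
    rng = derive_rng(spec.seed, "timeseries", b.name, f"subject{subject}")
    n_times = int(round(spec.epoch_length * spec.sampling_rate))
    t = np.arange(n_times) / spec.sampling_rate
    # carrier on an exact FFT bin keeps its energy out of neighbouring bins
    f0 = max(1.0, round(b.center * spec.epoch_length)) / spec.epoch_length
    x = _bandpass_noise(rng, b, spec.sampling_rate, (spec.n_epochs, spec.n_regions, n_times))
    idx = _generic_index(spec.n_regions)
    scale = np.ones(spec.n_regions)
    carrier = np.zeros_like(x)
    for edge, s in strengths.items():
        i, j = idx.edge_regions(edge)
        phases = rng.uniform(0, 2 * np.pi, size=spec.n_epochs)[:, None]
        carrier[:, i, :] += s * np.sqrt(2) * np.cos(2 * np.pi * f0 * t[None, :] + phases)
        carrier[:, j, :] += s * np.sqrt(2) * np.cos(2 * np.pi * f0 * t[None, :] + phases - lag)
        scale[i] = scale[j] = np.sqrt(max(1.0 - s**2, 0.0))
    return scale[None, :, None] * x + carrier


def timeseries_dataset(spec: SyntheticSpec, band: str) -> ConnectomeDataset:
    """Timeseries-mode connectomes: simulate every subject, reduce with wPLI."""
    b = spec.band(band)
    idx = _generic_index(spec.n_regions)
    mats = []
    for subject in range(spec.n_subjects):
        epochs = generate_coupled_timeseries(spec, band, subject)
        mats.append(
            wpli_matrix(epochs, spec.sampling_rate, (b.f_low, b.f_high), edge_index=idx)
        )
    from .edges import vectorize_matrix

    subject_ids, labels = _subject_ids(spec)
    X = np.vstack([vectorize_matrix(m, idx) for m in mats])
    return ConnectomeDataset(
        subject_ids=subject_ids, labels=labels, band=b.name, X=X, edge_index=idx
    )
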
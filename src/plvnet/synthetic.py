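"""Synthetic phase-coupled EEG-like cohorts with known ground truth.

Each band contribution of a channel is a sinusoid whose instantaneous phase
is a shared component phase (linear drift plus a slow random walk) plus
independent von Mises(0, kappa) jitter, held constant over short blocks of
samples so the signal stays narrow-band enough for analytic-signal phase
estimation.  For a coupled pair in which both channels carry independent
von Mises(0, kappa) jitter, the expected phase-locking value has the closed
form ``(I1(kappa) / I0(kappa)) ** 2``.

Uncoupled channels receive uniform (kappa = 0) jitter around their own
private component phase, so their expected cross-PLV is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.special import i0, i1

from .errors import ConfigurationError, InvalidParameterError
from .preprocess import BANDS, DEFAULT_MONTAGE, EEGRecording, Montage

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "RTModel",
    "GroundTruth",
    "von_mises_plv",
    "simulate_channel_pair",
    "simulate_cohort",
    "demo_cohort_spec",
    "true_global_efficiency",
]

#: samples per independent jitter draw (keeps the jitter spectrum narrow
#: relative to the carrier while leaving enough independent draws for the
#: time average to converge)
DEFAULT_JITTER_BLOCK = 5
#: sd of the per-sample increment of the shared slow phase random walk (rad)
DEFAULT_PHASE_WALK_SD = 0.02


def von_mises_plv(kappa: float) -> float:
    """Expected PLV of two channels with independent von Mises(0, k) jitter.

    ``(I1(k)/I0(k))**2``; 0 at k = 0 (uniform jitter), 1 in the k -> inf
    (no jitter) limit.
    """
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float((i1(kappa) / i0(kappa)) ** 2)


def _block_jitter(
    rng: np.random.Generator, kappa: float, n_samples: int, block: int
) -> np.ndarray:
    """Piecewise-constant von Mises jitter, one draw per `block` samples."""
    if np.isinf(kappa):
        return np.zeros(n_samples)
    n_blocks = -(-n_samples // block)
    draws = rng.vonmises(0.0, kappa, size=n_blocks)
    return np.repeat(draws, block)[:n_samples]


def simulate_channel_pair(
    kappa: float,
    n_samples: int,
    band_center_hz: float,
    sampling_rate_hz: float,
    seed: int | np.random.Generator | None = None,
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    jitter_block: int = DEFAULT_JITTER_BLOCK,
    phase_walk_sd: float = DEFAULT_PHASE_WALK_SD,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate one coupled channel pair; returns ``(x_a, x_b, true_plv)``.

    Both channels share a common phase (linear drift at ``band_center_hz``
    plus a slow Gaussian random walk) and carry independent von Mises
    (0, ``kappa``) jitter, so the true PLV is ``von_mises_plv(kappa)``.
    """
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if n_samples <= 0:
        raise InvalidParameterError("n_samples must be positive")
    if sampling_rate_hz <= 0 or band_center_hz <= 0:
        raise InvalidParameterError("rates must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = np.arange(n_samples) / sampling_rate_hz
    common = (
        2 * np.pi * band_center_hz * t
        + rng.uniform(0, 2 * np.pi)
        + np.cumsum(rng.normal(0.0, phase_walk_sd, n_samples))
    )
    x_a = amplitude * np.cos(common + _block_jitter(rng, kappa, n_samples, jitter_block))
    x_b = amplitude * np.cos(common + _block_jitter(rng, kappa, n_samples, jitter_block))
    if noise_sd > 0:
        x_a = x_a + rng.normal(0.0, noise_sd, n_samples)
        x_b = x_b + rng.normal(0.0, noise_sd, n_samples)
    return x_a, x_b, von_mises_plv(kappa)


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling within one frequency band.

    ``pairs`` lists ``(node_i, node_j, kappa)`` with node indices into the
    montage channel list.  Pairs must be channel-disjoint so that each
    pair's ground-truth PLV is exactly the closed form (a channel coupled
    into two pairs would correlate the pairs).

    ``background_kappa`` additionally couples every channel *not* in an
    explicit pair to one shared band-wide component: channel ``i`` carries
    von Mises(0, bg_i) jitter around the common phase, so the true PLV of
    two background channels is ``R(bg_i) * R(bg_j)`` with
    ``R(k) = I1(k)/I0(k)``.  A scalar broadcasts to all channels; 0 (the
    default) makes the channel independent of everything.
    """

    band_center_hz: float
    pairs: tuple[tuple[int, int, float], ...] = ()
    background_kappa: float | tuple[float, ...] = 0.0
    background_noise_sd: float = 0.1
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.band_center_hz <= 0:
            raise InvalidParameterError("band_center_hz must be positive")
        seen_pairs: set[tuple[int, int]] = set()
        seen_nodes: set[int] = set()
        for i, j, kappa in self.pairs:
            if i == j:
                raise InvalidParameterError(f"self-coupling ({i}, {j})")
            if i < 0 or j < 0:
                raise InvalidParameterError("negative node index")
            if kappa < 0:
                raise InvalidParameterError("kappa must be >= 0")
            key = (min(i, j), max(i, j))
            if key in seen_pairs:
                raise InvalidParameterError(f"duplicate pair {key}")
            seen_pairs.add(key)
            if i in seen_nodes or j in seen_nodes:
                raise ConfigurationError(
                    f"pair {key} shares a channel with another pair; "
                    "coupling pairs must be channel-disjoint"
                )
            seen_nodes.update(key)
        bg = self.background_kappa
        bg_values = (bg,) if np.isscalar(bg) else tuple(bg)
        if any(v < 0 for v in bg_values):
            raise InvalidParameterError("background_kappa must be >= 0")

    def background_vector(self, n_channels: int) -> np.ndarray:
        bg = self.background_kappa
        if np.isscalar(bg):
            return np.full(n_channels, float(bg))
        vec = np.asarray(bg, dtype=float)
        if vec.size != n_channels:
            raise ConfigurationError(
                f"background_kappa has {vec.size} entries for "
                f"{n_channels} channels"
            )
        return vec

    def validate_for(self, n_channels: int) -> None:
        for i, j, _ in self.pairs:
            if i >= n_channels or j >= n_channels:
                raise ConfigurationError(
                    f"pair ({i}, {j}) outside 0..{n_channels - 1}"
                )
        self.background_vector(n_channels)


@dataclass(frozen=True)
class RTModel:
    """Linear model tying true alpha global efficiency to mean RT (ms)."""

    intercept_ms: float = 600.0
    slope_ms: float = -800.0
    noise_sd_ms: float = 15.0


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a two-group synthetic cohort."""

    n_per_group: int
    coupling: Mapping[str, CouplingSpec]
    #: TC-only kappa increments on explicit pairs: band -> [(i, j, delta)]
    group_effect: Mapping[str, Sequence[tuple[int, int, float]]] = field(
        default_factory=dict
    )
    #: TC-only background-kappa increments: band -> [(channel, delta)]
    group_channel_effect: Mapping[str, Sequence[tuple[int, float]]] = field(
        default_factory=dict
    )
    n_channels: int = 30
    sampling_rate_hz: float = 250.0
    duration_s: float = 240.0
    epoch_length_s: float = 15.0
    rt_model: RTModel = RTModel()
    subject_kappa_sd: float = 0.25
    psycap_group_shift: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")
        n_ep = self.duration_s / self.epoch_length_s
        if n_ep < 1 or abs(n_ep - round(n_ep)) > 1e-9:
            raise ConfigurationError(
                f"duration {self.duration_s}s is not a whole number of "
                f"{self.epoch_length_s}s epochs"
            )
        for band, cs in self.coupling.items():
            if band not in BANDS:
                raise ConfigurationError(f"unknown band {band!r}")
            cs.validate_for(self.n_channels)
        for band, deltas in self.group_effect.items():
            if band not in BANDS:
                raise ConfigurationError(f"unknown band {band!r} in group_effect")
            for i, j, _ in deltas:
                if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                    raise ConfigurationError(
                        f"group_effect pair ({i}, {j}) outside montage"
                    )
        for band, ch_deltas in self.group_channel_effect.items():
            if band not in BANDS:
                raise ConfigurationError(
                    f"unknown band {band!r} in group_channel_effect"
                )
            for ch, _ in ch_deltas:
                if not 0 <= ch < self.n_channels:
                    raise ConfigurationError(
                        f"group_channel_effect channel {ch} outside montage"
                    )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class GroundTruth:
    """Per-subject generative truth for downstream recovery tests."""

    #: subject_id -> band -> N x N true PLV matrix
    true_plv: dict[str, dict[str, np.ndarray]]
    #: subject_id -> group label
    groups: dict[str, str]
    #: subject_id -> noiseless expected reaction time (ms)
    expected_rt_ms: dict[str, float]


def _merged_coupling(
    spec: CohortSpec, group: str
) -> dict[str, CouplingSpec]:
    """Base coupling with the TC group's deltas folded in."""
    merged = dict(spec.coupling)
    if group != "TC":
        return merged
    for band, deltas in spec.group_effect.items():
        base = merged.get(
            band, CouplingSpec(band_center_hz=BANDS[band].center_hz, pairs=())
        )
        by_key = {(min(i, j), max(i, j)): kappa for i, j, kappa in base.pairs}
        for i, j, delta in deltas:
            key = (min(i, j), max(i, j))
            by_key[key] = by_key.get(key, 0.0) + delta
        merged[band] = replace(
            base, pairs=tuple((i, j, k) for (i, j), k in sorted(by_key.items()))
        )
    for band, ch_deltas in spec.group_channel_effect.items():
        base = merged.get(
            band, CouplingSpec(band_center_hz=BANDS[band].center_hz, pairs=())
        )
        bg = base.background_vector(spec.n_channels)
        for ch, delta in ch_deltas:
            bg[ch] += delta
        merged[band] = replace(base, background_kappa=tuple(bg))
    return merged


def _von_mises_r(kappa: float) -> float:
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def _true_plv_matrix(
    coupling: CouplingSpec, n_channels: int, kappa_scale: float
) -> np.ndarray:
    bg = coupling.background_vector(n_channels)
    paired: set[int] = set()
    for i, j, _ in coupling.pairs:
        paired.update((i, j))
    r = np.array(
        [
            0.0 if ch in paired else _von_mises_r(bg[ch] * kappa_scale)
            for ch in range(n_channels)
        ]
    )
    mat = np.outer(r, r)
    for i, j, kappa in coupling.pairs:
        v = von_mises_plv(kappa * kappa_scale)
        mat[i, j] = mat[j, i] = v
    np.fill_diagonal(mat, 1.0)
    return mat


def true_global_efficiency(true_plv: np.ndarray) -> float:
    """Global efficiency of the weighted true-PLV graph (lengths 1/PLV).

    Used as the latent driver of the reaction-time model; continuous in the
    coupling strengths, unlike metrics of a binarized graph.
    """
    n = true_plv.shape[0]
    with np.errstate(divide="ignore"):
        lengths = 1.0 / np.where(true_plv > 0, true_plv, np.nan)
    lengths = np.where(np.isnan(lengths), np.inf, lengths)
    np.fill_diagonal(lengths, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    inv = np.zeros_like(dist)
    mask = np.isfinite(dist) & (dist > 0)
    inv[mask] = 1.0 / dist[mask]
    return float(inv.sum() / (n * (n - 1)))


def _subject_signals(
    spec: CohortSpec,
    coupling: Mapping[str, CouplingSpec],
    kappa_scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n, t_len = spec.n_channels, spec.n_samples
    t = np.arange(t_len) / spec.sampling_rate_hz
    data = np.zeros((n, t_len))
    total_noise_var = 0.0
    for band in sorted(coupling):
        cs = coupling[band]
        total_noise_var += cs.background_noise_sd**2
        paired: set[int] = set()
        # explicit coupled pairs: each shares a private component phase
        for i, j, kappa in cs.pairs:
            common = (
                2 * np.pi * cs.band_center_hz * t
                + rng.uniform(0, 2 * np.pi)
                + np.cumsum(rng.normal(0.0, DEFAULT_PHASE_WALK_SD, t_len))
            )
            k_eff = kappa * kappa_scale
            for ch in (i, j):
                jit = _block_jitter(rng, k_eff, t_len, DEFAULT_JITTER_BLOCK)
                data[ch] += cs.amplitude * np.cos(common + jit)
            paired.update((i, j))
        # remaining channels jitter around one shared band-wide component;
        # kappa 0 (uniform jitter) makes a channel independent of everything
        bg = cs.background_vector(n)
        common = (
            2 * np.pi * cs.band_center_hz * t
            + rng.uniform(0, 2 * np.pi)
            + np.cumsum(rng.normal(0.0, DEFAULT_PHASE_WALK_SD, t_len))
        )
        for ch in range(n):
            if ch in paired:
                continue
            jit = _block_jitter(
                rng, bg[ch] * kappa_scale, t_len, DEFAULT_JITTER_BLOCK
            )
            data[ch] += cs.amplitude * np.cos(common + jit)
    if total_noise_var > 0:
        data += rng.normal(0.0, np.sqrt(total_noise_var), size=data.shape)
    return data


def simulate_cohort(
    spec: CohortSpec, montage: Montage | None = None
) -> tuple[list[EEGRecording], pd.DataFrame, GroundTruth]:
    """Simulate a two-group cohort.

    Returns the recordings, a cohort covariate table (columns
    ``subject_id, group, age, sex, rt_ms, psycap_total``) and the
    generative :class:`GroundTruth`.  Deterministic given ``spec.seed``;
    each subject draws from its own seed stream (master seed + subject
    index) so subjects are independently reproducible.
    """
    montage = montage or DEFAULT_MONTAGE
    if spec.n_channels > montage.n_channels:
        raise ConfigurationError(
            f"{spec.n_channels} channels requested but montage has "
            f"{montage.n_channels}"
        )
    labels = montage.channels[: spec.n_channels]

    recordings: list[EEGRecording] = []
    rows = []
    truth = GroundTruth(true_plv={}, groups={}, expected_rt_ms={})

    subject_index = 0
    for group in ("TC", "CT"):
        coupling = _merged_coupling(spec, group)
        for k in range(spec.n_per_group):
            sid = f"{group}{k + 1:02d}"
            rng = np.random.default_rng([spec.seed, subject_index])
            subject_index += 1

            age = int(rng.integers(20, 25))
            sex = "M" if rng.random() < 0.7 else "F"
            kappa_scale = float(
                np.exp(rng.normal(0.0, spec.subject_kappa_sd))
            )
            band_truth = {
                band: _true_plv_matrix(cs, spec.n_channels, kappa_scale)
                for band, cs in coupling.items()
            }
            alpha_truth = band_truth.get("alpha", np.eye(spec.n_channels))
            eff = true_global_efficiency(alpha_truth)
            rt_expect = spec.rt_model.intercept_ms + spec.rt_model.slope_ms * eff
            rt = rt_expect + rng.normal(0.0, spec.rt_model.noise_sd_ms)
            psycap = 100.0 + rng.normal(0.0, 10.0)
            if group == "TC":
                psycap += spec.psycap_group_shift

            data = _subject_signals(spec, coupling, kappa_scale, rng)
            recordings.append(
                EEGRecording(
                    data=data,
                    sampling_rate_hz=spec.sampling_rate_hz,
                    channel_labels=list(labels),
                    subject_id=sid,
                )
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "rt_ms": round(float(rt), 3),
                    "psycap_total": round(float(psycap), 3),
                }
            )
            truth.true_plv[sid] = band_truth
            truth.groups[sid] = group
            truth.expected_rt_ms[sid] = float(rt_expect)

    cohort = pd.DataFrame(rows)
    return recordings, cohort, truth


#: frontal/temporal channels carrying the demo group effect
_EFFECT_CHANNELS = ("FP1", "FP2", "F3", "F4", "F7", "F8", "T3", "T4", "FT7", "FT8")


def demo_cohort_spec(
    n_per_group: int = 10,
    n_channels: int = 30,
    duration_s: float = 60.0,
    epoch_length_s: float = 15.0,
    sampling_rate_hz: float = 250.0,
    effect_kappa: float = 1.0,
    background_kappa: float = 0.8,
    seed: int = 0,
) -> CohortSpec:
    """A ready-made cohort spec with an alpha-band group effect on frontal
    and temporal channels, used by the CLI demo and the recovery tests.

    Every channel shares moderate band-wide synchrony (background kappa);
    the TC group additionally gains ``effect_kappa`` of background
    concentration on frontal/temporal channels in the alpha band only, so
    group differences concentrate there.  ``effect_kappa=0`` yields a null
    cohort.
    """
    montage = DEFAULT_MONTAGE
    labels = montage.channels[:n_channels]
    idx = {c: i for i, c in enumerate(labels)}
    effect_idx = [idx[c] for c in _EFFECT_CHANNELS if c in idx]
    if not effect_idx:  # very small montages: first half of channels
        effect_idx = list(range(max(1, n_channels // 2)))

    coupling = {
        "alpha": CouplingSpec(
            band_center_hz=BANDS["alpha"].center_hz,
            background_kappa=background_kappa,
        ),
        "beta": CouplingSpec(
            band_center_hz=BANDS["beta"].center_hz,
            background_kappa=background_kappa,
        ),
    }
    channel_effect = (
        {"alpha": [(ch, effect_kappa) for ch in effect_idx]}
        if effect_kappa
        else {}
    )
    return CohortSpec(
        n_per_group=n_per_group,
        coupling=coupling,
        group_channel_effect=channel_effect,
        n_channels=n_channels,
        sampling_rate_hz=sampling_rate_hz,
        duration_s=duration_s,
        epoch_length_s=epoch_length_s,
        seed=seed,
    )
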
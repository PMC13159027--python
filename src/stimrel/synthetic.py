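"""Synthetic multi-subject, two-viewing, multi-modality cohorts.

The generator emulates the structure of a repeated naturalistic-viewing
study with three independent cohorts: an electrophysiology cohort on a
regular source grid, a hemodynamic cohort on a voxel support, and an
electrode montage pooled across pseudo-patients that is analysed as a
single composite subject.  Every channel's band-limited log-amplitude is
a known variance decomposition

    x_{s,v} = sqrt(a) g_c + sqrt(b) u_s + sqrt(1 - a - b) eps_{s,v}

with a stimulus-locked component ``g_c`` shared across subjects and
viewings, a subject-specific stable component ``u_s`` shared across the
two viewings, and viewing-specific noise.  All components have unit
sample variance, so the expected within-subject correlation is ``a + b``
and the expected between-subject correlation is ``a``.

The hemodynamic modality couples to the band latents through a
double-gamma response kernel with a band-dependent sign (negative for
the low bands, positive for the gamma / high-frequency bands, emulating
the known inverse relationship between low-frequency oscillatory power
and the BOLD signal) plus a pure stimulus delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import signal as sps

from .containers import (
    ANALYSIS_RATE_HZ,
    ChannelGeometry,
    EnvelopeSet,
    Recording,
    band_table,
    stable_stream,
)

__all__ = [
    "SyntheticConfig",
    "LatentStimulus",
    "CohortDataset",
    "generate_latent_stimulus",
    "generate_ephys_cohort",
    "generate_montage_cohort",
    "generate_hemo_cohort",
    "double_gamma_hrf",
]

#: Default hemodynamic coupling signs: inverse at low frequencies,
#: positive in the gamma and high-frequency range.
DEFAULT_COUPLING_SIGNS: dict[str, int] = {
    "delta": -1,
    "theta": -1,
    "alpha": -1,
    "beta": -1,
    "gamma1": 1,
    "gamma2": 1,
    "hf": 1,
}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``shared_frac`` (a) and ``subject_frac`` (b) are the variance
    fractions of the stimulus-locked and subject-stable components;
    ``mode='envelope'`` generates log-amplitude series directly on the
    20 Hz analysis grid, ``mode='raw'`` synthesizes band-limited carriers
    at ``fs_ephys`` whose envelopes follow the same decomposition (to
    exercise the full filter chain).
    """

    n_subjects_ephys: int = 10
    n_subjects_hemo: int = 11
    n_electrodes: int = 656
    n_pseudo_patients: int = 5
    grid_shape: tuple[int, int, int] = (5, 5, 2)
    grid_spacing_mm: float = 8.0
    duration_s: float = 297.0
    fs_ephys: float = 256.0
    tr_s: float = 1.5
    shared_frac: float = 0.1
    subject_frac: float = 0.1
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma1", "gamma2", "hf", "bb")
    band_coupling_signs: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING_SIGNS)
    )
    hemo_lag_s: float = 4.5
    hrf_peak_s: float = 5.0
    hrf_undershoot_s: float = 15.0
    ar1_rho: float = 0.5
    latent_cutoff_hz: float = 0.2
    mode: str = "envelope"
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.shared_frac, self.subject_frac
        if not (0 <= a < 1 and 0 <= b <= 1 - a):
            raise ValueError(f"need 0 <= a < 1 and 0 <= b <= 1 - a, got a={a}, b={b}")
        if self.duration_s <= 0 or self.tr_s <= 0 or self.hemo_lag_s < 0:
            raise ValueError("durations must be positive and lag non-negative")
        if self.mode not in ("envelope", "raw"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "raw":
            top = max(b.f_hi for b in band_table(self.bands))
            if self.fs_ephys <= 2 * top:
                raise ValueError(
                    f"fs_ephys={self.fs_ephys} must exceed twice the top band edge {top} Hz"
                )
        for sign in self.band_coupling_signs.values():
            if sign not in (-1, 1):
                raise ValueError("coupling signs must be -1 or +1")

    @property
    def n_channels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * ANALYSIS_RATE_HZ))


@dataclass
class LatentStimulus:
    """Stimulus-locked latent structure shared by every cohort."""

    shared: np.ndarray  # (n_bands, n_channels, T) unit-variance series
    drive: np.ndarray  # (T,) scalar stimulus drive behind the audio envelope
    audio_envelope: np.ndarray  # (T,) non-negative, 20 Hz
    band_names: tuple[str, ...]
    grid_geometry: ChannelGeometry

    @property
    def region_tags(self) -> list[str]:
        return self.grid_geometry.region_tags


@dataclass
class CohortDataset:
    """All recordings of one modality cohort plus geometry and ground truth."""

    recordings: list[Recording]
    geometry: dict[str, ChannelGeometry]
    latent: LatentStimulus
    truth: SyntheticConfig
    modality: str

    def __post_init__(self) -> None:
        keys = [
            (r.modality, r.meta.get("band"), r.subject_id, r.viewing_id) for r in self.recordings
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (modality, band, subject, viewing) entries")
        for r in self.recordings:
            geom = self.geometry[r.modality]
            if r.n_channels != geom.n_channels:
                raise ValueError("channel count does not match geometry")

    def subjects(self) -> list[Any]:
        return sorted({r.subject_id for r in self.recordings})

    def to_envelope_set(self, correlation_method: str | None = None) -> EnvelopeSet:
        """Assemble an EnvelopeSet from envelope-mode recordings (already on
        the analysis grid)."""
        method = correlation_method or ("spearman" if self.modality == "montage" else "pearson")
        envelopes = {}
        for r in self.recordings:
            band = r.meta.get("band", "bold")
            envelopes[(band, r.subject_id, r.viewing_id)] = r.data
        return EnvelopeSet(
            envelopes=envelopes,
            geometry=self.geometry[self.modality],
            fs=ANALYSIS_RATE_HZ,
            correlation_method=method,
            modality=self.modality,
        )


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _slow_noise(rng: np.random.Generator, shape: tuple[int, ...], cutoff_hz: float) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed at ``cutoff_hz`` (20 Hz grid)."""
    w = rng.standard_normal(shape)
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=ANALYSIS_RATE_HZ, output="sos")
    return _standardize(sps.sosfiltfilt(sos, w, axis=-1))


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], rho: float) -> np.ndarray:
    """Unit-variance AR(1) noise along the last axis."""
    w = rng.standard_normal(shape)
    if rho == 0:
        return _standardize(w)
    out = sps.lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], w, axis=-1)
    return _standardize(out)


def _grid_geometry(config: SyntheticConfig) -> ChannelGeometry:
    nx, ny, nz = config.grid_shape
    idx = np.indices((nx, ny, nz)).reshape(3, -1).T
    coords = idx * config.grid_spacing_mm
    n = coords.shape[0]
    # region tags: an 'auditory' block at the low-x corner, a 'visual' block
    # at the high-x corner, the remainder 'association'
    x = coords[:, 0]
    tags = np.where(
        x <= np.quantile(x, 0.25),
        "auditory",
        np.where(x >= np.quantile(x, 0.75), "visual", "association"),
    )
    labels = [f"grid{i:04d}" for i in range(n)]
    return ChannelGeometry(
        coords=coords.astype(float),
        labels=labels,
        region_tags=list(tags),
        kind="grid",
        spacing_mm=config.grid_spacing_mm,
    )


def _drive_band_index(bands: tuple[str, ...]) -> int:
    """The band whose auditory channels track the stimulus drive.

    High-frequency amplitude is the classic signature of temporally precise
    stimulus-locked auditory engagement, so the drive loads on 'hf' when
    present (falling back to the first band of a reduced table).
    """
    return bands.index("hf") if "hf" in bands else 0


def _shared_components(
    rng: np.random.Generator,
    drive: np.ndarray,
    bands: tuple[str, ...],
    tags: list[str],
    cutoff_hz: float,
) -> np.ndarray:
    """Per-band, per-channel unit-variance shared series; auditory-tagged
    channels of the drive band load sqrt(0.5) on the common stimulus
    drive (other bands stay independent of it, keeping their hemodynamic
    coupling signs clean)."""
    n_channels = len(tags)
    T = len(drive)
    g = _slow_noise(rng, (len(bands), n_channels, T), cutoff_hz)
    aud = np.array([t == "auditory" for t in tags])
    alpha2 = 0.5
    bi = _drive_band_index(bands)
    g[bi, aud, :] = np.sqrt(alpha2) * drive + np.sqrt(1 - alpha2) * g[bi, aud, :]
    return _standardize(g)


def generate_latent_stimulus(config: SyntheticConfig) -> LatentStimulus:
    """Stimulus-locked latents: shared band components, the scalar drive,
    and a non-negative audio envelope that tracks the drive."""
    rng = stable_stream(config.seed, "latent")
    geom = _grid_geometry(config)
    T = config.n_samples
    drive = _slow_noise(rng, (T,), config.latent_cutoff_hz)
    shared = _shared_components(rng, drive, config.bands, geom.region_tags, config.latent_cutoff_hz)
    noise = _slow_noise(rng, (T,), config.latent_cutoff_hz)
    audio = 0.95 * drive + np.sqrt(1 - 0.95**2) * noise
    audio = audio - audio.min()  # non-negative amplitude envelope
    return LatentStimulus(
        shared=shared,
        drive=drive,
        audio_envelope=audio,
        band_names=tuple(config.bands),
        grid_geometry=geom,
    )


def _envelope_series(
    latent_g: np.ndarray,
    u: np.ndarray,
    eps: np.ndarray,
    a: float,
    b: float,
) -> np.ndarray:
    return np.sqrt(a) * latent_g + np.sqrt(b) * u + np.sqrt(max(1 - a - b, 0.0)) * eps


def _carrier_from_logamp(
    logamp: np.ndarray, band_name: str, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Raw-mode synthesis: an amplitude-modulated sinusoidal carrier at the
    band centre whose log analytic amplitude is an affine image of
    ``logamp`` (channels x T20)."""
    (band,) = band_table([band_name])
    f_c = 0.5 * (band.f_lo + band.f_hi)
    C, T20 = logamp.shape
    n = int(round(T20 / ANALYSIS_RATE_HZ * fs))
    t_new = np.arange(n) / fs
    t_old = np.arange(T20) / ANALYSIS_RATE_HZ
    amp = np.empty((C, n))
    for c in range(C):
        amp[c] = np.interp(t_new, t_old, logamp[c])
    phase0 = rng.uniform(0, 2 * np.pi, size=(C, 1))
    return np.exp(0.5 * amp) * np.cos(2 * np.pi * f_c * t_new + phase0)


def _ephys_recordings(
    latent: LatentStimulus,
    config: SyntheticConfig,
    geometry: ChannelGeometry,
    shared: np.ndarray,
    modality: str,
    subjects: list[Any],
    stream_tag: str,
) -> list[Recording]:
    a, b = config.shared_frac, config.subject_frac
    T = config.n_samples
    n_channels = geometry.n_channels
    # raw mode needs slow modulators so carriers stay band-limited
    slow = config.mode == "raw"
    recs = []
    for s in subjects:
        rng_u = stable_stream(config.seed, stream_tag, "subject", s)
        if slow:
            u = _slow_noise(rng_u, (len(config.bands), n_channels, T), 1.0)
        else:
            u = _ar1_noise(rng_u, (len(config.bands), n_channels, T), config.ar1_rho)
        for v in (1, 2):
            rng_e = stable_stream(config.seed, stream_tag, "noise", s, v)
            if slow:
                eps = _slow_noise(rng_e, (len(config.bands), n_channels, T), 1.0)
            else:
                eps = _ar1_noise(rng_e, (len(config.bands), n_channels, T), config.ar1_rho)
            env = _envelope_series(shared, u, eps, a, b)
            if config.mode == "envelope":
                for bi, band in enumerate(config.bands):
                    recs.append(
                        Recording(
                            data=env[bi],
                            fs=ANALYSIS_RATE_HZ,
                            subject_id=s,
                            viewing_id=v,
                            modality=modality,
                            geometry=geometry,
                            meta={"band": band},
                        )
                    )
            else:
                rng_c = stable_stream(config.seed, stream_tag, "carrier", s, v)
                raw = np.zeros((n_channels, int(round(config.duration_s * config.fs_ephys))))
                for bi, band in enumerate(config.bands):
                    if band == "bb":
                        continue  # broadband is an analysis construct, not a source
                    raw += _carrier_from_logamp(env[bi], band, config.fs_ephys, rng_c)
                recs.append(
                    Recording(
                        data=raw,
                        fs=config.fs_ephys,
                        subject_id=s,
                        viewing_id=v,
                        modality=modality,
                        geometry=geometry,
                        meta={"band": None},
                    )
                )
    return recs


def generate_ephys_cohort(latent: LatentStimulus, config: SyntheticConfig) -> CohortDataset:
    """Electrophysiology cohort on the source grid (one subject group,
    two viewings each)."""
    geometry = latent.grid_geometry
    subjects = list(range(1, config.n_subjects_ephys + 1))
    recs = _ephys_recordings(
        latent, config, geometry, latent.shared, "ephys", subjects, "ephys"
    )
    return CohortDataset(
        recordings=recs,
        geometry={"ephys": geometry},
        latent=latent,
        truth=config,
        modality="ephys",
    )


def _montage_geometry(config: SyntheticConfig, rng: np.random.Generator) -> ChannelGeometry:
    # uniform points on a 70 mm-radius spherical shell; pseudo-patients in
    # contiguous blocks; an auditory cap around the -x pole
    n = config.n_electrodes
    vec = rng.standard_normal((n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    coords = 70.0 * vec
    tags = np.where(coords[:, 0] < -45.0, "auditory", "other")
    if not (tags == "auditory").any():
        tags[np.argmin(coords[:, 0])] = "auditory"
    per = int(np.ceil(n / config.n_pseudo_patients))
    labels = [f"p{(i // per) + 1:02d}_e{i % per:03d}" for i in range(n)]
    return ChannelGeometry(
        coords=coords, labels=labels, region_tags=list(tags), kind="montage"
    )


def generate_montage_cohort(latent: LatentStimulus, config: SyntheticConfig) -> CohortDataset:
    """Electrode montage pooled across pseudo-patients, analysed as one
    composite subject with two viewings.

    Electrodes carry their own latent shared components (driven by the
    same scalar stimulus drive on auditory-tagged contacts), so the
    montage is stimulus-locked to the identical movie as the other
    cohorts.
    """
    rng = stable_stream(config.seed, "montage-geom")
    geometry = _montage_geometry(config, rng)
    rng_g = stable_stream(config.seed, "montage-latent")
    shared = _shared_components(
        rng_g, latent.drive, config.bands, geometry.region_tags, config.latent_cutoff_hz
    )
    recs = _ephys_recordings(
        latent, config, geometry, shared, "montage", ["pooled"], "montage"
    )
    return CohortDataset(
        recordings=recs,
        geometry={"montage": geometry},
        latent=latent,
        truth=config,
        modality="montage",
    )


def double_gamma_hrf(
    fs: float, peak_s: float = 5.0, undershoot_s: float = 15.0, duration_s: float = 32.0
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel, normalized to
    unit sum.  Peak at ``peak_s``, undershoot peak at ``undershoot_s``
    with 1/6 relative amplitude."""
    t = np.arange(0, duration_s, 1 / fs)
    from scipy.stats import gamma as gamma_dist

    peak = gamma_dist.pdf(t, peak_s, scale=1.0)
    under = gamma_dist.pdf(t, undershoot_s, scale=1.0)
    h = peak - under / 6.0
    return h / h.sum()


def generate_hemo_cohort(latent: LatentStimulus, config: SyntheticConfig) -> CohortDataset:
    """Hemodynamic cohort: band latents mixed with coupling signs,
    convolved with the response kernel, delayed by ``hemo_lag_s``, sampled
    at the repetition rate 1/tr_s on a voxel support co-located with the
    source grid."""
    grid = latent.grid_geometry
    geometry = ChannelGeometry(
        coords=grid.coords.copy(),
        labels=[lb.replace("grid", "vox") for lb in grid.labels],
        region_tags=list(grid.region_tags),
        kind="voxel",
    )
    a = config.shared_frac
    coupled = [b for b in config.bands if b in config.band_coupling_signs]
    if not coupled:
        raise ValueError("no coupled bands: band_coupling_signs shares no name with bands")
    signs = np.array([config.band_coupling_signs[b] for b in coupled], dtype=float)
    idx = [config.bands.index(b) for b in coupled]
    mix = np.tensordot(signs, latent.shared[idx], axes=(0, 0)) / np.sqrt(len(coupled))

    h = double_gamma_hrf(ANALYSIS_RATE_HZ, config.hrf_peak_s, config.hrf_undershoot_s)
    # circular (wrap-around) causal convolution and delay: the stationary
    # latent stands in for a stimulus with continuous context outside the
    # analysis window, so no startup transient is introduced
    T_mix = mix.shape[-1]
    H = np.fft.rfft(h, n=T_mix)
    conv = np.fft.irfft(np.fft.rfft(mix, axis=-1) * H, n=T_mix, axis=-1)
    lag_n = int(round(config.hemo_lag_s * ANALYSIS_RATE_HZ))
    delayed = np.roll(conv, lag_n, axis=-1) if lag_n else conv
    T = config.n_samples
    tr_idx = np.arange(0, T, config.tr_s * ANALYSIS_RATE_HZ).round().astype(int)
    tr_idx = tr_idx[tr_idx < T]
    shared_tr = _standardize(delayed[:, tr_idx])

    recs = []
    fs_hemo = 1.0 / config.tr_s
    for s in range(1, config.n_subjects_hemo + 1):
        for v in (1, 2):
            rng = stable_stream(config.seed, "hemo", s, v)
            eta = _standardize(rng.standard_normal(shared_tr.shape))
            y = np.sqrt(a) * shared_tr + np.sqrt(1 - a) * eta
            recs.append(
                Recording(
                    data=y,
                    fs=fs_hemo,
                    subject_id=s,
                    viewing_id=v,
                    modality="hemo",
                    geometry=geometry,
                    meta={"band": "bold"},
                )
            )
    return CohortDataset(
        recordings=recs,
        geometry={"hemo": geometry},
        latent=latent,
        truth=config,
        modality="hemo",
    )
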